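"""R-peak, QRS-boundary and T-wave detection.

R peaks are detected with a continuous wavelet transform whose mother
wavelet is the first derivative of a Gaussian (``gaus1``).  The transform
modulus is aggregated over a scale set matched to QRS widths of 20–120 ms,
lightly smoothed (the gaus1 response to a symmetric peak has a zero exactly
at the peak, so the raw modulus is bimodal per beat), thresholded against a
rolling 95th-percentile amplitude estimate, pruned with a refractory rule
that keeps the larger response, and finally localized on the raw-signal
extremum near each wavelet event.

QRS boundaries use the same gaus1 transform at the dyadic level-4 detail
band (the fs/32–fs/16 octave of a four-level decomposition); the T wave is
found on a 0.5–10 Hz zero-phase Butterworth copy of the signal with the QRS
samples zeroed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pywt
from scipy import ndimage
from scipy import signal as sps

from .io import AnnotationSet

__all__ = [
    "DetectorConfig",
    "QrsBoundaries",
    "TWaveMarks",
    "detect_r_peaks",
    "detect_qrs_boundaries",
    "detect_t_waves",
]

log = logging.getLogger(__name__)

_GAUS1_FC = pywt.central_frequency("gaus1")  # ~0.2 cycles/sample at scale 1


@dataclasses.dataclass(frozen=True)
class DetectorConfig:
    """CWT R-peak detector settings.

    ``qrs_width_range`` (s) fixes the scale set; ``k`` is the threshold as a
    fraction of the rolling 95th-percentile wavelet amplitude (2 s window);
    ``refractory`` suppresses secondary events (default 0.25 s, suitable for
    fetal rates; use ~0.4 s for maternal signals); ``rate_band`` (bpm) is a
    plausibility band used by callers, not by the detector itself.
    """

    qrs_width_range: tuple[float, float] = (0.02, 0.12)
    n_scales: int = 6
    k: float = 0.4
    refractory: float = 0.25
    rate_band: tuple[float, float] = (50.0, 200.0)
    refine_window: float = 0.02

    def __post_init__(self):
        if not 0 < self.k < 1:
            raise ValueError("threshold factor k must lie in (0, 1)")
        if self.refractory <= 0:
            raise ValueError("refractory period must be positive")


FETAL_DETECTOR = DetectorConfig(refractory=0.25)
MATERNAL_DETECTOR = DetectorConfig(refractory=0.4, rate_band=(50.0, 110.0))


@dataclasses.dataclass
class QrsBoundaries:
    """Per-beat QRS onset/offset sample indices (onset < R < offset)."""

    onsets: np.ndarray
    offsets: np.ndarray
    r_peaks: np.ndarray


@dataclasses.dataclass
class TWaveMarks:
    """Per-beat T-peak index and signed amplitude in the 0.5–10 Hz signal."""

    indices: np.ndarray
    amplitudes: np.ndarray
    beat_mask: np.ndarray  # False where the search window ran past the record


def _cwt_scales(fs: float, cfg: DetectorConfig) -> np.ndarray:
    w_lo, w_hi = cfg.qrs_width_range
    freqs = np.geomspace(1.0 / w_hi, 1.0 / w_lo, cfg.n_scales)
    return _GAUS1_FC * fs / freqs


def _wavelet_envelope(x: np.ndarray, fs: float, cfg: DetectorConfig) -> np.ndarray:
    scales = _cwt_scales(fs, cfg)
    coefs, _ = pywt.cwt(x, scales, "gaus1")
    envelope = np.max(np.abs(coefs), axis=0)
    # merge the two gaus1 lobes flanking each peak
    sigma = max(1.0, 0.01 * fs)
    return ndimage.gaussian_filter1d(envelope, sigma)


def _rolling_p95(envelope: np.ndarray, fs: float, window_s: float = 2.0) -> np.ndarray:
    """Piecewise 95th percentile on half-overlapping windows, interpolated."""
    n = len(envelope)
    win = max(2, int(window_s * fs))
    hop = max(1, win // 2)
    centers, values = [], []
    for start in range(0, n, hop):
        block = envelope[start : start + win]
        centers.append(start + len(block) / 2)
        values.append(np.percentile(block, 95))
    if len(values) == 1:
        return np.full(n, values[0])
    return np.interp(np.arange(n), centers, values)


def detect_r_peaks(
    signal: np.ndarray, fs: float, cfg: DetectorConfig = FETAL_DETECTOR
) -> AnnotationSet:
    """Detect R peaks; returns a (possibly empty) annotation set at ``fs``."""
    x = np.asarray(signal, dtype=float)
    if x.size < 4 or not np.any(x):
        return AnnotationSet(np.empty(0, dtype=np.int64), fs, "R")
    envelope = _wavelet_envelope(x, fs, cfg)
    threshold = cfg.k * _rolling_p95(envelope, fs)

    peaks, _ = sps.find_peaks(envelope)
    peaks = peaks[envelope[peaks] > threshold[peaks]]
    if peaks.size == 0:
        return AnnotationSet(np.empty(0, dtype=np.int64), fs, "R")

    # refractory pruning: strongest responses win
    refractory = int(round(cfg.refractory * fs))
    order = peaks[np.argsort(envelope[peaks])[::-1]]
    keep: list[int] = []
    for p in order:
        if all(abs(p - q) >= refractory for q in keep):
            keep.append(int(p))
    keep.sort()

    # localize on the raw-signal extremum near each wavelet event
    half = max(1, int(round(cfg.refine_window * fs)))
    refined = []
    for p in keep:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    return AnnotationSet(np.unique(refined), fs, "R")


# ---------------------------------------------------------------------------
# QRS boundaries and T waves
# ---------------------------------------------------------------------------

_LEVEL4_BAND_CENTER = 3.0 / 64.0  # center of the fs/32..fs/16 detail octave
_BOUNDARY_FRACTION = 0.35


def _level4_detail(x: np.ndarray, fs: float) -> np.ndarray:
    scale = _GAUS1_FC / _LEVEL4_BAND_CENTER
    coefs, _ = pywt.cwt(x, [scale], "gaus1")
    detail = np.abs(coefs[0])
    return ndimage.gaussian_filter1d(detail, max(1.0, 0.008 * fs))


def detect_qrs_boundaries(
    signal: np.ndarray, fs: float, r_peaks: AnnotationSet | np.ndarray
) -> QrsBoundaries:
    """Per-beat onset/offset from the level-4 wavelet detail magnitude.

    Onset is the last sub-threshold sample before R and offset the first
    after, both clipped to +-100 ms around R (narrower when beats crowd).
    """
    x = np.asarray(signal, dtype=float)
    r = np.asarray(getattr(r_peaks, "indices", r_peaks), dtype=np.int64)
    detail = _level4_detail(x, fs)
    clip = int(round(0.1 * fs))
    onsets, offsets = [], []
    for i, peak in enumerate(r):
        left = clip
        right = clip
        if i > 0:
            gap = peak - r[i - 1]
            if gap < 0.2 * fs:
                left = min(left, gap // 2)
                log.warning("beats closer than 0.2 s near sample %d; clip narrowed", peak)
        if i + 1 < len(r):
            gap = r[i + 1] - peak
            if gap < 0.2 * fs:
                right = min(right, gap // 2)
        lo = max(0, peak - left)
        hi = min(len(x) - 1, peak + right)
        window = detail[lo : hi + 1]
        thr = _BOUNDARY_FRACTION * np.max(window) if window.size else 0.0
        onset = lo
        for j in range(peak - 1, lo - 1, -1):
            if detail[j] < thr:
                onset = j
                break
        offset = hi
        for j in range(peak + 1, hi + 1):
            if detail[j] < thr:
                offset = j
                break
        onset = min(onset, peak - 1) if peak > 0 else peak
        offset = max(offset, peak + 1) if peak < len(x) - 1 else peak
        onsets.append(max(0, onset))
        offsets.append(min(len(x) - 1, offset))
    return QrsBoundaries(
        onsets=np.asarray(onsets, dtype=np.int64),
        offsets=np.asarray(offsets, dtype=np.int64),
        r_peaks=r,
    )


def t_band_filter(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, 0.5–10 Hz."""
    sos = sps.butter(4, [0.5, 10.0], btype="bandpass", fs=fs, output="sos")
    padlen = min(len(x) - 1, 3 * (2 * sos.shape[0] + 1) * 10)
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def detect_t_waves(
    signal: np.ndarray, fs: float, boundaries: QrsBoundaries, search: float = 0.35
) -> TWaveMarks:
    """Locate the T peak after each QRS offset in the 0.5–10 Hz signal.

    The QRS samples are excised (bridged by linear interpolation, padded by
    30 ms so the Q/S recovery tails go with them) before filtering, so the
    sharp complex cannot leak into the T band; the T peak is the maximum
    absolute value in ``(offset, offset + search]`` seconds, amplitude
    signed as in the filtered signal.  Beats whose window exceeds the
    record are skipped.
    """
    x = np.asarray(signal, dtype=float).copy()
    pad = int(round(0.03 * fs))
    for onset, offset in zip(boundaries.onsets, boundaries.offsets):
        lo = max(0, onset - pad)
        hi = min(len(x) - 1, offset + pad)
        x[lo : hi + 1] = np.linspace(x[lo], x[hi], hi - lo + 1)
    filtered = t_band_filter(x, fs)
    blanked = filtered.copy()
    for onset, offset in zip(boundaries.onsets, boundaries.offsets):
        blanked[onset : offset + 1] = 0.0
    span = int(round(search * fs))
    indices, amplitudes, mask = [], [], []
    for offset in boundaries.offsets:
        lo, hi = offset + 1, offset + 1 + span
        if hi > len(x):
            log.warning("T-wave window exceeds record end at sample %d; beat skipped", offset)
            indices.append(-1)
            amplitudes.append(np.nan)
            mask.append(False)
            continue
        window = blanked[lo:hi]
        t_idx = lo + int(np.argmax(np.abs(window)))
        indices.append(t_idx)
        amplitudes.append(filtered[t_idx])
        mask.append(True)
    return TWaveMarks(
        indices=np.asarray(indices, dtype=np.int64),
        amplitudes=np.asarray(amplitudes, dtype=float),
        beat_mask=np.asarray(mask, dtype=bool),
    )
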