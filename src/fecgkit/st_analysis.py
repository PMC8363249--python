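"""STAN-style T/QRS ratio analysis of the extracted fetal ECG.

Mirrors the clinical ST analyser: beats are amplitude-normalized by their
own R peak, averaged in non-overlapping blocks of 30 consecutive cycles
over a fixed 600 ms window (190 ms before the R wave, 410 ms after), and
each averaged complex yields one T/QRS ratio — the signed T-peak amplitude
(0.5–10 Hz band) over the QRS peak-to-peak amplitude inside the detected
QRS boundaries.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .detectors import QrsBoundaries, detect_qrs_boundaries, detect_t_waves
from .io import AnnotationSet
from .metrics import BlandAltmanResult, bland_altman

__all__ = [
    "AveragedBeat",
    "TQRSSeries",
    "average_beats",
    "t_qrs_ratio",
    "t_qrs_series",
    "st_compare",
    "PRE_R_S",
    "POST_R_S",
]

log = logging.getLogger(__name__)

PRE_R_S = 0.19
POST_R_S = 0.41
WINDOW_S = PRE_R_S + POST_R_S


@dataclasses.dataclass
class AveragedBeat:
    """Mean of one block of R-normalized beat windows.

    ``r_sample`` marks the R wave (the 0.19 s point); the window always has
    ``round(0.6 * fs) + 1`` samples.
    """

    waveform: np.ndarray
    fs: float
    r_sample: int
    n_beats: int
    block_index: int
    start_time: float  # time (s) of the first beat in the block


@dataclasses.dataclass
class TQRSSeries:
    ratios: np.ndarray
    times: np.ndarray     # block start times (s)
    flags: np.ndarray     # True where the T wave was undetectable


def _window_geometry(fs: float) -> tuple[int, int]:
    total = int(round(WINDOW_S * fs)) + 1
    pre = int(round(PRE_R_S * fs))
    return pre, total


def average_beats(
    signal: np.ndarray, r: AnnotationSet, fs: float, block: int = 30
) -> list[AveragedBeat]:
    """Normalize and average beats in non-overlapping blocks of ``block``.

    Each window is divided by its own signed R amplitude before averaging,
    which both scales the cycle and aligns its polarity (blind source
    separation leaves the extracted polarity arbitrary, and it can alternate
    between biphasic beats).  Beats whose window crosses a record edge are
    dropped (and logged); an incomplete trailing block yields no averaged
    beat.
    """
    x = np.asarray(signal, dtype=float)
    pre, total = _window_geometry(fs)
    post = total - pre - 1
    windows = []
    starts = []
    for idx in r.indices:
        lo, hi = idx - pre, idx + post + 1
        if lo < 0 or hi > len(x):
            log.info("beat at sample %d dropped: window outside record", idx)
            continue
        w = x[lo:hi]
        r_amp = w[pre]
        if r_amp == 0:
            log.info("beat at sample %d dropped: zero R amplitude", idx)
            continue
        windows.append(w / r_amp)
        starts.append(idx / fs)
    beats: list[AveragedBeat] = []
    n_blocks = len(windows) // block
    if n_blocks == 0:
        log.warning("fewer than %d usable beats; no averaged beat produced", block)
        return beats
    for b in range(n_blocks):
        chunk = np.asarray(windows[b * block : (b + 1) * block])
        beats.append(
            AveragedBeat(
                waveform=chunk.mean(axis=0),
                fs=fs,
                r_sample=pre,
                n_beats=block,
                block_index=b,
                start_time=starts[b * block],
            )
        )
    return beats


def t_qrs_ratio(beat: AveragedBeat, fs: float | None = None) -> tuple[float, bool]:
    """Signed T/QRS of one averaged complex; ``(0.0, True)`` when the tail is flat.

    QRS amplitude is the peak-to-peak range inside the detected QRS
    boundaries; T amplitude is the signed T peak of the 0.5–10 Hz filtered
    beat.  A T peak below 2% of the R amplitude counts as undetectable.
    """
    fs = fs or beat.fs
    x = beat.waveform
    bounds = detect_qrs_boundaries(x, fs, np.asarray([beat.r_sample]))
    onset, offset = int(bounds.onsets[0]), int(bounds.offsets[0])
    qrs_pp = float(np.max(x[onset : offset + 1]) - np.min(x[onset : offset + 1]))
    # embed the 600 ms window in a 2 s zero context: the 0.5 Hz high-pass
    # corner needs more support than the window itself provides
    pad = int(round(2.0 * fs))
    padded = np.concatenate([np.zeros(pad), x - x[0], np.zeros(pad)])
    shifted = QrsBoundaries(
        onsets=bounds.onsets + pad, offsets=bounds.offsets + pad,
        r_peaks=bounds.r_peaks + pad,
    )
    marks = detect_t_waves(padded, fs, shifted, search=0.35)
    r_amp = abs(x[beat.r_sample])
    if not marks.beat_mask[0]:
        return 0.0, True
    t_amp = float(marks.amplitudes[0])
    if abs(t_amp) < 0.02 * r_amp or qrs_pp == 0:
        return 0.0, True
    return t_amp / qrs_pp, False


def t_qrs_series(
    signal: np.ndarray, r: AnnotationSet, fs: float, block: int = 30
) -> TQRSSeries:
    """Blockwise T/QRS series of a record (one value per 30 beats)."""
    beats = average_beats(signal, r, fs, block)
    ratios, times, flags = [], [], []
    for beat in beats:
        ratio, flag = t_qrs_ratio(beat, fs)
        ratios.append(ratio)
        times.append(beat.start_time)
        flags.append(flag)
    return TQRSSeries(
        ratios=np.asarray(ratios, dtype=float),
        times=np.asarray(times, dtype=float),
        flags=np.asarray(flags, dtype=bool),
    )


def st_compare(est: TQRSSeries, ref: TQRSSeries) -> BlandAltmanResult:
    """Bland–Altman agreement of estimated vs reference T/QRS series.

    Series are truncated to the shorter block count before pairing.
    """
    n = min(len(est.ratios), len(ref.ratios))
    return bland_altman(ref.ratios[:n], est.ratios[:n])
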