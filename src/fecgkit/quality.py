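"""Signal-quality indices of abdominal channels and their link to accuracy.

Three record-level difficulty proxies:

* **mR:fR ratio** — mean absolute maternal-R amplitude over mean absolute
  fetal-R amplitude, per channel, averaged over the channels used.  High
  values mean the fetal component is buried under the maternal one.
* **sSQI** — sample skewness of the amplitude distribution.
* **kSQI** — Pearson (non-excess) kurtosis; a Gaussian signal scores 3,
  clean spiky ECG scores far above (typically 10–26).

``correlate_with_accuracy`` relates any of these to per-record detection
accuracy with a Pearson coefficient and a Fisher-z 95% CI.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .errors import ParameterError
from .io import AnnotationSet, Recording

__all__ = ["SQIReport", "mr_fr_ratio", "sqi", "correlate_with_accuracy", "sqi_report"]


@dataclasses.dataclass
class SQIReport:
    mr_fr: float
    ssqi: float
    ksqi: float
    per_channel_mr_fr: np.ndarray
    per_channel_ssqi: np.ndarray
    per_channel_ksqi: np.ndarray
    channels: tuple[int, ...]


def mr_fr_ratio(
    rec: Recording,
    m_peaks: AnnotationSet,
    f_peaks: AnnotationSet,
    channels: tuple[int, ...] | None = None,
) -> float:
    """Mean maternal-to-fetal R amplitude ratio over the chosen channels."""
    return float(np.mean(_per_channel_mr_fr(rec, m_peaks, f_peaks, channels)))


def _per_channel_mr_fr(rec, m_peaks, f_peaks, channels) -> np.ndarray:
    if len(m_peaks) == 0 or len(f_peaks) == 0:
        raise ParameterError("both annotation sets must be non-empty")
    channels = tuple(channels) if channels is not None else tuple(range(rec.n_channels))
    if any(c < 0 or c >= rec.n_channels for c in channels):
        raise ParameterError("channel index out of range")
    m_idx = m_peaks.indices[m_peaks.indices < rec.n_samples]
    f_idx = f_peaks.indices[f_peaks.indices < rec.n_samples]
    out = []
    for c in channels:
        ch = rec.data[c]
        out.append(np.mean(np.abs(ch[m_idx])) / np.mean(np.abs(ch[f_idx])))
    return np.asarray(out)


def sqi(signal: np.ndarray) -> tuple[float, float]:
    """Sample skewness and Pearson (non-excess) kurtosis.

    Returns ``(nan, nan)`` for a constant signal (undefined).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 8:
        raise ParameterError("need at least 8 samples")
    if np.ptp(x) == 0:
        return math.nan, math.nan
    return float(stats.skew(x)), float(stats.kurtosis(x, fisher=False))


def correlate_with_accuracy(values, acc_values) -> tuple[float, tuple[float, float]]:
    """Pearson r of a quality index against accuracy, with Fisher-z 95% CI.

    Returns ``(nan, (nan, nan))`` when either input has zero variance.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(acc_values, dtype=float)
    if v.shape != a.shape or v.size < 3:
        raise ParameterError("need equal-length sequences with at least 3 pairs")
    if np.ptp(v) == 0 or np.ptp(a) == 0:
        return math.nan, (math.nan, math.nan)
    r = float(stats.pearsonr(v, a).statistic)
    if abs(r) >= 1.0:
        return r, (r, r)
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(v.size - 3)
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return r, (float(lo), float(hi))


def sqi_report(
    rec: Recording,
    m_peaks: AnnotationSet,
    f_peaks: AnnotationSet,
    channels: tuple[int, ...] | None = None,
) -> SQIReport:
    """All quality indices of a record in one pass (per-channel + means)."""
    channels = tuple(channels) if channels is not None else tuple(range(rec.n_channels))
    per_mr_fr = _per_channel_mr_fr(rec, m_peaks, f_peaks, channels)
    ss, ks = zip(*(sqi(rec.data[c]) for c in channels))
    return SQIReport(
        mr_fr=float(np.mean(per_mr_fr)),
        ssqi=float(np.mean(ss)),
        ksqi=float(np.mean(ks)),
        per_channel_mr_fr=per_mr_fr,
        per_channel_ssqi=np.asarray(ss),
        per_channel_ksqi=np.asarray(ks),
        channels=channels,
    )
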