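"""Beat matching, detection statistics, Bland–Altman agreement, fHR traces.

A detected beat is correct when its R-peak lies within 50 ms of a reference
annotation; matching is one-to-one, nearest pair first.  From the matched
counts the four statistics are

    ACC = TP / (TP + FP + FN) * 100
    SE  = TP / (TP + FN) * 100
    PPV = TP / (TP + FP) * 100
    F1  = 2 TP / (2 TP + FP + FN) * 100

each with an exact (Clopper–Pearson) binomial 95% confidence interval on
its (numerator, denominator) pair; the F1 interval treats F1 as the
proportion 2TP out of 2TP + FP + FN.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .errors import ParameterError
from .io import AnnotationSet

__all__ = [
    "MatchCounts",
    "Metrics",
    "BlandAltmanResult",
    "FHRTrace",
    "match_peaks",
    "compute_metrics",
    "clopper_pearson",
    "bland_altman",
    "fhr_trace",
]


@dataclasses.dataclass
class MatchCounts:
    TP: int
    FP: int
    FN: int
    pairs: list[tuple[int, int]] = dataclasses.field(default_factory=list)

    @classmethod
    def from_counts(cls, TP: int, FP: int, FN: int) -> "MatchCounts":
        return cls(TP=TP, FP=FP, FN=FN)


@dataclasses.dataclass
class Metrics:
    """The four statistics in percent with 95% CIs; NaN where undefined."""

    acc: float
    se: float
    ppv: float
    f1: float
    acc_ci: tuple[float, float]
    se_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    f1_ci: tuple[float, float]
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "SE": self.se, "PPV": self.ppv, "F1": self.f1}


@dataclasses.dataclass
class BlandAltmanResult:
    mu: float
    loa_lower: float
    loa_upper: float
    sigma: float
    n: int
    mu_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]


@dataclasses.dataclass
class FHRTrace:
    time: np.ndarray     # seconds, one point per RR interval
    rate: np.ndarray     # smoothed instantaneous rate, bpm
    raw_rate: np.ndarray
    zones: np.ndarray    # 'physiological' | 'increased-risk' | 'high-risk'


def match_peaks(
    ref: AnnotationSet, det: AnnotationSet, fs: float | None = None, tol: float = 0.05
) -> MatchCounts:
    """Greedy nearest-pair one-to-one matching within ``tol`` seconds.

    Candidate pairs closer than ``tol`` are sorted by |dt| ascending and
    accepted while both members are unused; leftovers become FP/FN.  Both
    annotation sets must refer to the same rate (rescale first).
    """
    if ref.fs != det.fs:
        raise ParameterError("annotation sets are at different rates; rescale first")
    rate = fs or ref.fs
    tol_samples = tol * rate
    ref_idx = np.asarray(ref.indices)
    det_idx = np.asarray(det.indices)
    candidates = []
    j_start = 0
    for i, r in enumerate(ref_idx):
        for j in range(j_start, len(det_idx)):
            d = det_idx[j]
            if d < r - tol_samples:
                j_start = j + 1
                continue
            if d > r + tol_samples:
                break
            candidates.append((abs(int(d) - int(r)), i, j))
    candidates.sort()
    ref_used = np.zeros(len(ref_idx), dtype=bool)
    det_used = np.zeros(len(det_idx), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if not ref_used[i] and not det_used[j]:
            ref_used[i] = det_used[j] = True
            pairs.append((int(ref_idx[i]), int(det_idx[j])))
    tp = len(pairs)
    return MatchCounts(TP=tp, FP=len(det_idx) - tp, FN=len(ref_idx) - tp, pairs=pairs)


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial 95% interval as percentages (Beta quantiles)."""
    if n < 1:
        raise ParameterError("need at least one trial")
    if not 0 <= x <= n:
        raise ParameterError("successes must lie in [0, n]")
    lower = 0.0 if x == 0 else stats.beta.ppf(alpha / 2, x, n - x + 1)
    upper = 1.0 if x == n else stats.beta.ppf(1 - alpha / 2, x + 1, n - x)
    return 100.0 * lower, 100.0 * upper


def compute_metrics(c: MatchCounts) -> Metrics:
    """ACC/SE/PPV/F1 in percent with exact binomial CIs."""
    undefined = set()

    def ratio(num: int, den: int, name: str) -> tuple[float, tuple[float, float]]:
        if den < 1:
            undefined.add(name)
            return math.nan, (math.nan, math.nan)
        return 100.0 * num / den, clopper_pearson(num, den)

    acc, acc_ci = ratio(c.TP, c.TP + c.FP + c.FN, "ACC")
    se, se_ci = ratio(c.TP, c.TP + c.FN, "SE")
    ppv, ppv_ci = ratio(c.TP, c.TP + c.FP, "PPV")
    f1, f1_ci = ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, "F1")
    return Metrics(
        acc=acc, se=se, ppv=ppv, f1=f1,
        acc_ci=acc_ci, se_ci=se_ci, ppv_ci=ppv_ci, f1_ci=f1_ci,
        undefined=frozenset(undefined),
    )


def bland_altman(ref_values, est_values) -> BlandAltmanResult:
    """Limits of agreement mu +- 1.96 sigma for paired differences est - ref.

    The CI of mu uses the t-based standard error s/sqrt(n); the CIs of the
    limits use the standard Bland–Altman variance, SE = sqrt(3) s / sqrt(n).
    """
    ref = np.asarray(ref_values, dtype=float)
    est = np.asarray(est_values, dtype=float)
    if ref.shape != est.shape:
        raise ParameterError("paired sequences must have equal length")
    n = ref.size
    if n < 3:
        raise ParameterError("need at least three pairs")
    diff = est - ref
    mu = float(np.mean(diff))
    sigma = float(np.std(diff, ddof=1))
    loa = 1.96 * sigma
    t = stats.t.ppf(0.975, n - 1)
    se_mu = sigma / math.sqrt(n)
    se_loa = math.sqrt(3.0) * sigma / math.sqrt(n)
    return BlandAltmanResult(
        mu=mu,
        loa_lower=mu - loa,
        loa_upper=mu + loa,
        sigma=sigma,
        n=n,
        mu_ci=(mu - t * se_mu, mu + t * se_mu),
        loa_lower_ci=(mu - loa - t * se_loa, mu - loa + t * se_loa),
        loa_upper_ci=(mu + loa - t * se_loa, mu + loa + t * se_loa),
    )


def _zone(rate: float, eps: float = 1e-9) -> str:
    if rate < 80.0 - eps or rate > 180.0 + eps:
        return "high-risk"
    if 110.0 - eps <= rate <= 150.0 + eps:
        return "physiological"
    return "increased-risk"


def fhr_trace(r: AnnotationSet, fs: float | None = None, window: int = 30) -> FHRTrace:
    """Instantaneous 60/RR rates smoothed with a centered moving average.

    Needs at least ``window + 1`` beats.  Zone labels follow the FIGO-style
    bands: 110–150 bpm physiological, 90–110 and 150–180 increased risk
    (80–90 also labeled increased risk), below 80 or above 180 high risk.
    """
    if len(r) < window + 1:
        raise ParameterError(f"need at least {window + 1} beats for the trace")
    times = r.times()
    rr = np.diff(times)
    raw = 60.0 / rr
    kernel = np.ones(window) / window
    smoothed = np.convolve(raw, kernel, mode="same")
    # correct the shrinking-support edges of the centered average
    support = np.convolve(np.ones_like(raw), kernel, mode="same")
    smoothed = smoothed / support
    zones = np.asarray([_zone(v) for v in smoothed])
    return FHRTrace(time=times[1:], rate=smoothed, raw_rate=raw, zones=zones)
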