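"""Exponentially-weighted recursive least squares maternal cancellation.

The maternal ICA component (reference ``x``) is adapted to the shape of the
maternal residue inside the fetal-enhanced component (primary ``d``); the
filter output ``y`` is the adjusted maternal estimate and the error
``e = d - y`` is the fetal ECG estimate.  The recursion is the standard
EW-RLS:

    k(n) = P(n-1) u(n) / (lambda + u(n)' P(n-1) u(n))
    e(n) = d(n) - w(n-1)' u(n)
    w(n) = w(n-1) + k(n) e(n)
    P(n) = (P(n-1) - k(n) u(n)' P(n-1)) / lambda

with u(n) the last M reference samples (zero-padded before the record
start), P(0) = I/delta and w(0) = 0.  With lambda = 1 the recursion is
exactly the growing-window regularized least-squares solution
w(N) = (sum u u' + delta I)^-1 sum u d.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DegenerateInputError, NumericalInstabilityError, ParameterError

__all__ = ["RLSConfig", "RLSOutput", "center_align", "rls_filter", "cancel_maternal"]


@dataclasses.dataclass(frozen=True)
class RLSConfig:
    """Filter order M (taps), forgetting factor lambda, P(0) scale delta."""

    M: int = 16
    lam: float = 1.0
    delta: float = 0.01

    def __post_init__(self):
        if self.M < 1:
            raise ParameterError("RLS filter order must be >= 1")
        if not 0 < self.lam <= 1:
            raise ParameterError("forgetting factor must lie in (0, 1]")
        if self.delta <= 0:
            raise ParameterError("delta must be positive")


@dataclasses.dataclass
class RLSOutput:
    y: np.ndarray        # adjusted maternal estimate (mECG_RLS)
    e: np.ndarray        # error signal = fetal ECG estimate
    weights: np.ndarray  # final weight vector (length M)


def center_align(primary: np.ndarray, reference: np.ndarray, fs: float | None = None,
                 max_lag_s: float = 0.1) -> tuple[np.ndarray, np.ndarray, int]:
    """Time and amplitude centering of the RLS inputs.

    Both signals are mean-subtracted and scaled to unit standard deviation;
    the reference is then shifted by the integer lag (within +-0.1 s, or
    +-10% of the record when ``fs`` is unknown) maximizing cross-correlation
    with the primary, zero-padding the displaced end.  Returns ``(d, x,
    lag)``.
    """
    d = np.asarray(primary, dtype=float)
    x = np.asarray(reference, dtype=float)
    if len(d) != len(x):
        raise ParameterError("primary and reference must have equal length")
    for name, sig in (("primary", d), ("reference", x)):
        if np.std(sig) == 0:
            raise DegenerateInputError(f"{name} signal has zero variance")
    d = (d - d.mean()) / d.std()
    x = (x - x.mean()) / x.std()

    max_lag = int(round(max_lag_s * fs)) if fs else max(1, len(d) // 10)
    corr = np.correlate(d, x, mode="full")
    center = len(x) - 1
    lo, hi = center - max_lag, center + max_lag + 1
    # positive lag = reference is delayed w.r.t. the primary; advance it
    lag = -(int(np.argmax(corr[lo:hi])) - max_lag)
    shifted = np.zeros_like(x)
    if lag > 0:
        shifted[: len(x) - lag] = x[lag:]
    elif lag < 0:
        shifted[-lag:] = x[: len(x) + lag]
    else:
        shifted[:] = x
    return d, shifted, lag


def rls_filter(d: np.ndarray, x: np.ndarray, cfg: RLSConfig = RLSConfig()) -> RLSOutput:
    """Run the EW-RLS recursion; deterministic, O(N M^2)."""
    d = np.asarray(d, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(d) != len(x):
        raise ParameterError("desired and reference must have equal length")
    n = len(d)
    if n < cfg.M:
        raise ParameterError("signal shorter than the filter order")
    M, lam = cfg.M, cfg.lam
    P = np.eye(M) / cfg.delta
    w = np.zeros(M)
    y = np.empty(n)
    e = np.empty(n)
    xpad = np.concatenate([np.zeros(M - 1), x])
    for i in range(n):
        u = xpad[i : i + M][::-1]
        Pu = P @ u
        denom = lam + u @ Pu
        k = Pu / denom
        y[i] = w @ u
        e[i] = d[i] - y[i]
        if not np.isfinite(e[i]):
            raise NumericalInstabilityError(
                f"RLS recursion diverged at sample {i}", sample_index=i
            )
        w = w + k * e[i]
        P = (P - np.outer(k, Pu)) / lam
    return RLSOutput(y=y, e=e, weights=w)


def cancel_maternal(
    aecg_star: np.ndarray,
    mecg: np.ndarray,
    cfg: RLSConfig = RLSConfig(),
    fs: float | None = None,
) -> RLSOutput:
    """Subtract the RLS-adjusted maternal estimate from the fetal-enhanced channel.

    Returns the full :class:`RLSOutput`; ``.e`` is the fetal ECG estimate and
    ``.y`` the adjusted maternal component kept for inspection.
    """
    d, x, _ = center_align(aecg_star, mecg, fs=fs)
    return rls_filter(d, x, cfg)
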