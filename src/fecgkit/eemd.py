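"""Empirical mode decomposition with noise-assisted ensemble averaging.

Plain EMD sifts the signal into intrinsic mode functions (IMFs) using cubic
-spline envelopes of the local extrema with mirror boundary extension and a
Cauchy-style stopping criterion.  The ensemble variant (EEMD) adds white
Gaussian noise of standard deviation ``N_std * sd(signal)`` to the input,
decomposes each noisy copy, and averages the IMFs row-wise over the ``N``
trials, which suppresses mode mixing.  The stack is always zero-padded to
``max_imfs`` rows (default 12) so IMF index sets such as "2+3+4+7" always
address valid rows; the residual trend is kept separately and is never
addressable as an IMF.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import FecgkitError, ParameterError

__all__ = ["EMDConfig", "EEMDConfig", "IMFStack", "emd", "eemd", "reconstruct"]


@dataclasses.dataclass(frozen=True)
class EMDConfig:
    max_imfs: int = 12
    sd_threshold: float = 0.2   # Cauchy sifting stop
    max_sifts: int = 50

    def __post_init__(self):
        if self.max_imfs < 1:
            raise ParameterError("max_imfs must be >= 1")


@dataclasses.dataclass(frozen=True)
class EEMDConfig:
    N: int = 10           # ensemble trials (study grid: 10, 30, 60)
    N_std: float = 0.2    # added-noise sd as a fraction of the signal sd
    seed: int = 0

    def __post_init__(self):
        if self.N < 1:
            raise ParameterError("ensemble size must be >= 1")
        if self.N_std < 0:
            raise ParameterError("noise fraction must be >= 0")


@dataclasses.dataclass
class IMFStack:
    """``max_imfs x samples`` IMF matrix (row 0 = IMF 1, highest frequency)."""

    imfs: np.ndarray
    residual: np.ndarray

    @property
    def max_imfs(self) -> int:
        return self.imfs.shape[0]


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dx = np.diff(x)
    rising = dx > 0
    falling = dx < 0
    maxima = np.flatnonzero(rising[:-1] & falling[1:]) + 1
    minima = np.flatnonzero(falling[:-1] & rising[1:]) + 1
    return maxima, minima


def _mirror_envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema with mirror boundary extension."""
    pad = min(2, len(idx))
    left_i = -idx[:pad][::-1]
    right_i = 2 * (n - 1) - idx[-pad:][::-1]
    xs = np.concatenate([left_i, idx, right_i])
    ys = np.concatenate([x[idx[:pad]][::-1], x[idx], x[idx[-pad:]][::-1]])
    xs, keep = np.unique(xs, return_index=True)
    return CubicSpline(xs, ys[keep])(np.arange(n))


def _is_imf_like(h: np.ndarray) -> bool:
    """Extrema and zero-crossing counts differ by at most one."""
    maxima, minima = _local_extrema(h)
    sign = np.sign(h)
    sign = sign[sign != 0]
    n_zc = int(np.sum(np.diff(sign) != 0))
    return abs(len(maxima) + len(minima) - n_zc) <= 1


def emd(signal: np.ndarray, cfg: EMDConfig = EMDConfig()) -> IMFStack:
    """Plain EMD.  Completeness: ``sum(imfs) + residual == signal`` exactly."""
    x = np.asarray(signal, dtype=float)
    if x.size < 8:
        raise ParameterError("signal too short to decompose")
    if not np.all(np.isfinite(x)):
        raise FecgkitError("non-finite values in EMD input")
    n = x.size
    residual = x.copy()
    rows = np.zeros((cfg.max_imfs, n))
    for k in range(cfg.max_imfs):
        maxima, minima = _local_extrema(residual)
        if len(maxima) + len(minima) < 3:
            break
        h = residual.copy()
        for _ in range(cfg.max_sifts):
            maxima, minima = _local_extrema(h)
            if len(maxima) < 2 or len(minima) < 2:
                break
            upper = _mirror_envelope(h, maxima, n)
            lower = _mirror_envelope(h, minima, n)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = np.sum(h * h)
            sd = np.sum(mean_env * mean_env) / denom if denom > 0 else 0.0
            h = h_new
            if sd < cfg.sd_threshold and _is_imf_like(h):
                break
        rows[k] = h
        residual = residual - h
    return IMFStack(imfs=rows, residual=residual)


def eemd(
    signal: np.ndarray,
    ecfg: EEMDConfig = EEMDConfig(),
    cfg: EMDConfig = EMDConfig(),
) -> IMFStack:
    """Noise-assisted ensemble EMD; deterministic for a given seed.

    Each trial decomposes ``signal + w`` with ``w ~ N(0, (N_std * sd)^2)``
    white noise, and the IMF rows (and residuals) are averaged over trials.
    With ``N=1, N_std=0`` this is exactly plain EMD.
    """
    x = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(ecfg.seed)
    noise_sd = ecfg.N_std * float(np.std(x))
    acc: IMFStack | None = None
    for _ in range(ecfg.N):
        noisy = x + rng.normal(0.0, noise_sd, x.size) if noise_sd > 0 else x
        stack = emd(noisy, cfg)
        if acc is None:
            acc = stack
        else:
            acc.imfs += stack.imfs
            acc.residual += stack.residual
    assert acc is not None
    acc.imfs /= ecfg.N
    acc.residual /= ecfg.N
    return acc


def reconstruct(stack: IMFStack, indices) -> np.ndarray:
    """Sum the selected IMF rows (1-based indices, residual not addressable)."""
    idx = sorted(set(int(i) for i in indices))
    if not idx:
        raise ParameterError("IMF index set must be nonempty")
    if idx[0] < 1 or idx[-1] > stack.max_imfs:
        raise ParameterError(
            f"IMF indices must lie in 1..{stack.max_imfs}, got {idx}"
        )
    return stack.imfs[[i - 1 for i in idx]].sum(axis=0)


def parse_imf_set(text: str) -> frozenset[int]:
    """Parse the config notation '2+3+5' into an index set."""
    try:
        return frozenset(int(tok) for tok in text.split("+"))
    except ValueError as exc:
        raise ParameterError(f"cannot parse IMF set {text!r}") from exc
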