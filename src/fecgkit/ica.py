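"""Kurtosis-based FastICA with component role assignment and polarity fix.

The abdominal channels are separated into (up to) three independent
components with the symmetric fixed-point FastICA iteration using the
kurtosis contrast (nonlinearity u^3).  The iteration budget is fixed at 20
sweeps; running out of sweeps is not an error, only flagged.  The three
components are then assigned physiological roles — the maternal ECG, the
fetal-enhanced channel (aECG*), and noise — from the rate and regularity of
the beats each component carries, and each assigned component's polarity is
corrected by majority vote over the signs of its beat extrema.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .detectors import DetectorConfig, detect_r_peaks
from .errors import DegenerateInputError, RoleAssignmentError
from .io import AnnotationSet

__all__ = [
    "ICAConfig",
    "ICAResult",
    "whiten",
    "fastica",
    "assign_roles",
    "correct_polarity",
]

MATERNAL_BAND = (50.0, 110.0)
FETAL_BAND = (110.0, 200.0)


@dataclasses.dataclass(frozen=True)
class ICAConfig:
    n_components: int = 3
    max_iter: int = 20
    tol: float = 1e-4
    seed: int = 0


@dataclasses.dataclass
class ICAResult:
    components: np.ndarray          # n_components x samples, zero mean unit variance
    mixing: np.ndarray              # channels x n_components
    unmixing: np.ndarray            # n_components x channels
    converged: bool
    n_iter: int
    roles: dict[str, int] | None = None
    polarity_flipped: np.ndarray | None = None


def whiten(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and sphere the channel matrix.

    Returns ``(Z, W_white, mean)`` with ``Z = W_white @ (X - mean)`` having
    identity covariance.  Rank-deficient input raises.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DegenerateInputError("need at least two channels to whiten")
    if X.shape[1] < 2 * X.shape[0]:
        raise DegenerateInputError("too few samples to estimate covariance")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    cov = (Xc @ Xc.T) / Xc.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[-1] <= 0 or eigval[0] / eigval[-1] < 1e-10:
        raise DegenerateInputError("rank-deficient channel matrix")
    W_white = (eigvec / np.sqrt(eigval)).T[::-1]  # strongest component first
    return W_white @ Xc, W_white, mean


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    s, u = np.linalg.eigh(W @ W.T)
    return (u / np.sqrt(s)) @ u.T @ W


def fastica(X: np.ndarray, cfg: ICAConfig = ICAConfig()) -> ICAResult:
    """Symmetric kurtosis FastICA on the (possibly reduced) whitened data.

    Keeps the ``cfg.n_components`` strongest whitened directions (PCA
    reduction when there are more channels than components).  Deterministic
    for a given seed.
    """
    X = np.asarray(X, dtype=float)
    n_comp = min(cfg.n_components, X.shape[0])
    Z, W_white, mean = whiten(X)
    Z = Z[:n_comp]
    W_white = W_white[:n_comp]
    n = Z.shape[1]

    rng = np.random.default_rng(cfg.seed)
    W = _sym_decorrelate(rng.standard_normal((n_comp, n_comp)))
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        U = W @ Z
        # kurtosis contrast: g(u) = u^3, g'(u) = 3u^2
        W_new = (U**3) @ Z.T / n - 3.0 * W
        W_new = _sym_decorrelate(W_new)
        delta = np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0))
        W = W_new
        if delta < cfg.tol:
            converged = True
            break

    components = W @ Z
    std = components.std(axis=1, keepdims=True)
    components = components / std
    unmixing = (W / std) @ W_white
    mixing = np.linalg.pinv(unmixing)
    return ICAResult(
        components=components,
        mixing=mixing,
        unmixing=unmixing,
        converged=converged,
        n_iter=it,
    )


def _component_stats(component: np.ndarray, fs: float) -> tuple[float, float]:
    """Detected beat rate (bpm) and RR coefficient of variation."""
    cfg = DetectorConfig(refractory=0.25)
    ann = detect_r_peaks(component, fs, cfg)
    duration = len(component) / fs
    if len(ann) < 3:
        return 0.0, np.inf
    rate = 60.0 * (len(ann) - 1) / (ann.times()[-1] - ann.times()[0])
    rr = np.diff(ann.times())
    cv = float(np.std(rr) / np.mean(rr)) if np.mean(rr) > 0 else np.inf
    return float(rate), cv


def assign_roles(components: np.ndarray, fs: float) -> dict[str, int]:
    """Map the components to {mECG, aECG*, noise} from their beat statistics.

    The component with the lowest detected rate inside the maternal band is
    the mECG; among the rest, the one inside the fetal band with the most
    regular RR series (lowest coefficient of variation) is the aECG*; the
    leftover (if three components) is noise.
    """
    components = np.atleast_2d(components)
    stats = [_component_stats(c, fs) for c in components]
    maternal_candidates = [
        i for i, (rate, _) in enumerate(stats) if MATERNAL_BAND[0] <= rate <= MATERNAL_BAND[1]
    ]
    if not maternal_candidates:
        raise RoleAssignmentError(
            "no component has a detected rate in the maternal band "
            f"{MATERNAL_BAND} bpm (rates: {[round(r, 1) for r, _ in stats]})"
        )
    m_idx = min(maternal_candidates, key=lambda i: stats[i][0])

    remaining = [i for i in range(len(components)) if i != m_idx]
    fetal_candidates = [
        i for i in remaining if FETAL_BAND[0] <= stats[i][0] <= FETAL_BAND[1]
    ]
    pool = fetal_candidates or remaining
    f_idx = min(pool, key=lambda i: stats[i][1])

    roles = {"mecg": m_idx, "aecg_star": f_idx}
    leftover = [i for i in remaining if i != f_idx]
    if leftover:
        roles["noise"] = leftover[0]
    return roles


def correct_polarity(
    component: np.ndarray, fs: float, window: int = 50
) -> tuple[np.ndarray, bool]:
    """Negate the component if most beats have a dominant negative extremum.

    Beats are detected on ``|component|``; for each event the positive and
    negative extrema within +-``window`` samples are compared and the whole
    component is flipped when the negative extremum wins a strict majority.
    """
    x = np.asarray(component, dtype=float)
    events = detect_r_peaks(np.abs(x), fs, DetectorConfig(refractory=0.25))
    if len(events) == 0:
        return x, False
    negative_wins = 0
    for idx in events.indices:
        lo, hi = max(0, idx - window), min(len(x), idx + window + 1)
        seg = x[lo:hi]
        if -np.min(seg) > np.max(seg):
            negative_wins += 1
    if negative_wins * 2 > len(events):
        return -x, True
    return x, False
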