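"""Sensitivity weights from the Jacobian of the inverse regression map.

The sensitivity matrix S holds the partial derivatives of every regression
target (z-scored lambda(theta) component) with respect to every normalized
data coordinate, evaluated at the observed data.  Per-target normalization of
|S| yields a weight

    q_i = sum_l |S_{i,l}| / sum_j |S_{j,l}|

for data coordinate i, quantifying how informative that coordinate is of the
parameters.  q is computed once at training time and held fixed; the robust
scale sigma keeps adapting each generation, giving effective distance weights
r = q / sigma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .distance import DistanceState
from .regression import TrainedRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityMatrix",
    "central_jacobian",
    "sensitivity_weights",
    "compute_sensitivity_state",
]

# geometric ladder for automatic step-size control
_STEP_LADDER = (1e-1, 1e-2, 1e-3)


@dataclass(frozen=True)
class SensitivityMatrix:
    """S[i, l] = d f_l / d x_i at x0, with the step sizes retained per input."""

    S: np.ndarray
    steps: np.ndarray


def central_jacobian(f: Callable[[np.ndarray], np.ndarray], x0: np.ndarray) -> SensitivityMatrix:
    """Central-difference Jacobian with per-coordinate automatic step size.

    For each input coordinate, central differences are evaluated on the ladder
    h in {1e-1, 1e-2, 1e-3} * max(1, |x0_i|); of the two adjacent pairs, the
    one with the smallest relative discrepancy wins and its smaller-h estimate
    is kept.  This balances truncation error against regressor noise.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    f0 = np.atleast_1d(np.asarray(f(x0), dtype=float))
    m = f0.size
    S = np.zeros((n, m))
    steps = np.zeros(n)
    for i in range(n):
        scale = max(1.0, abs(x0[i]))
        ests, hs = [], []
        for h_rel in _STEP_LADDER:
            h = h_rel * scale
            xp = x0.copy()
            xm = x0.copy()
            xp[i] += h
            xm[i] -= h
            fp = np.atleast_1d(np.asarray(f(xp), dtype=float))
            fm = np.atleast_1d(np.asarray(f(xm), dtype=float))
            est = (fp - fm) / (2.0 * h)
            if np.all(np.isfinite(est)):
                ests.append(est)
                hs.append(h)
        if not ests:
            raise FloatingPointError(f"no finite derivative estimate for coordinate {i}")
        if len(ests) == 1:
            best = 0
        else:
            discrepancies = []
            for a, b in zip(ests[:-1], ests[1:]):
                denom = max(float(np.linalg.norm(a)), float(np.linalg.norm(b)), 1e-300)
                discrepancies.append(float(np.linalg.norm(a - b)) / denom)
            best = int(np.argmin(discrepancies)) + 1  # smaller-h member of best pair
        S[i] = ests[best]
        steps[i] = hs[best]
    return SensitivityMatrix(S=S, steps=steps)


def sensitivity_weights(S: np.ndarray | SensitivityMatrix, normalize: bool = True) -> np.ndarray:
    """Per-coordinate weights q from the absolute sensitivity matrix.

    With per-target normalization (default), each target column of |S| is
    scaled to sum 1 before summing over targets, which levels the impact of
    targets and yields more conservative weights; a target with no sensitivity
    anywhere is skipped.  Setting ``normalize=False`` sums raw |S| per row.
    """
    A = np.abs(S.S if isinstance(S, SensitivityMatrix) else np.asarray(S, dtype=float))
    if not np.all(np.isfinite(A)):
        raise ValueError("sensitivity matrix must be finite")
    if not normalize:
        return A.sum(axis=1)
    colsum = A.sum(axis=0)
    active = colsum > 0
    if not np.any(active):
        logger.warning("all-zero sensitivity matrix: all weights zero")
        return np.zeros(A.shape[0])
    return (A[:, active] / colsum[active]).sum(axis=1)


def compute_sensitivity_state(
    reg: TrainedRegressor,
    y_obs: np.ndarray,
    sigma: np.ndarray,
    scale_kind: str = "mad",
    p: float = 1.0,
    normalize: bool = True,
    t: int = 0,
) -> tuple[DistanceState, SensitivityMatrix]:
    """Differentiate the trained inverse map at the observed data and return
    the sensitivity-weighted distance state (r = q/sigma).

    The Jacobian is taken on the regressor's own normalized input scale (plain
    MAD even when the distance uses PCMAD: folding the outlier correction into
    the regressor inputs would inversely re-scale the sensitivities).  Rows
    for input coordinates dropped at training time (zero scale) are zero.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    if y_obs.size != reg.n_y:
        raise ValueError(f"expected observation of dimension {reg.n_y}, got {y_obs.size}")
    x0 = reg.normalize_input(y_obs)
    sub = central_jacobian(reg.predict_normalized, x0)
    S = np.zeros((reg.n_y, reg.n_lambda))
    steps = np.zeros(reg.n_y)
    S[reg.keep] = sub.S
    steps[reg.keep] = sub.steps
    q: Optional[np.ndarray] = sensitivity_weights(S, normalize=normalize)
    if not np.any(q > 0):
        logger.warning(
            "degenerate regressor: all sensitivity weights zero; "
            "falling back to scale-only distance weights"
        )
        q = None
    state = DistanceState(p=p, sigma=np.asarray(sigma, dtype=float), q=q, scale_kind=scale_kind, t=t)
    return state, SensitivityMatrix(S=S, steps=steps)
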