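"""Weighted Minkowski distances with adaptive scale normalization.

The distance between a simulation y and the observation y_obs is

    d(y, y_obs) = ( sum_i |r_i * (y_i - y_obs_i)|^p )^(1/p),   p >= 1,

with per-coordinate weights r_i = q_i / sigma_i: sigma is a robust scale
(MAD, or the outlier-aware PCMAD) recomputed each ABC-SMC generation from all
simulations of the previous generation, and q an optional fixed sensitivity
weight quantifying informativeness.  A coordinate with zero spread gets weight
zero (it carries no comparison scale) rather than an infinite weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceState",
    "minkowski_distance",
    "mad",
    "pcmad",
    "update_scale_weights",
]

SCALE_KINDS = ("mad", "pcmad", "none")


@dataclass(frozen=True)
class DistanceState:
    """Configuration of the generation-t distance d_t.

    sigma : per-coordinate robust scale (None => uniform scales).
    q     : optional per-coordinate sensitivity weights, fixed after training.
    """

    p: float = 1.0
    sigma: Optional[np.ndarray] = None
    q: Optional[np.ndarray] = None
    scale_kind: str = "mad"
    t: int = 0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError(f"Minkowski order must satisfy p >= 1, got {self.p}")
        if self.scale_kind not in SCALE_KINDS:
            raise ValueError(f"scale_kind must be one of {SCALE_KINDS}, got {self.scale_kind!r}")
        if self.sigma is not None:
            object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.q is not None:
            object.__setattr__(self, "q", np.asarray(self.q, dtype=float))

    def weights(self, n: Optional[int] = None) -> np.ndarray:
        """Effective weights r = q/sigma (zero where sigma = 0)."""
        if self.sigma is None:
            if n is None:
                raise ValueError("need dimension n when sigma is unset")
            sigma = np.ones(n)
        else:
            sigma = self.sigma
        q = np.ones_like(sigma) if self.q is None else self.q
        r = np.zeros_like(sigma)
        pos = sigma > 0
        r[pos] = q[pos] / sigma[pos]
        return r

    def __call__(self, y: np.ndarray, y_obs: np.ndarray) -> float:
        y = np.asarray(y, dtype=float)
        return minkowski_distance(y, y_obs, self.weights(y.size), self.p)


def minkowski_distance(
    y: np.ndarray,
    y_obs: np.ndarray,
    r: Optional[np.ndarray] = None,
    p: float = 1.0,
) -> float:
    """Weighted Minkowski distance; ``inf`` sentinel on non-finite input."""
    y = np.asarray(y, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    if y.shape != y_obs.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_obs.shape}")
    if p < 1:
        raise ValueError(f"Minkowski order must satisfy p >= 1, got {p}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(y_obs))):
        return math.inf
    diff = y - y_obs
    if r is not None:
        r = np.asarray(r, dtype=float)
        if r.shape != y.shape:
            raise ValueError(f"weight vector shape {r.shape} does not match data {y.shape}")
        if np.any(r < 0):
            raise ValueError("weights must be non-negative")
        diff = r * diff
    return float(np.linalg.norm(diff, ord=p))


def mad(samples: np.ndarray) -> np.ndarray:
    """Per-coordinate median absolute deviation from the sample median."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 2:
        raise ValueError("need at least two samples to estimate a scale")
    return stats.median_abs_deviation(samples, axis=0, scale=1.0)


def pcmad(samples: np.ndarray, y_obs: np.ndarray) -> np.ndarray:
    """Outlier-aware scale: MAD where the observation is consistent with the
    sample (MADO < MAD), else MAD + MADO.

    MADO is the median absolute deviation of the sample from the observed
    value; adding it inflates the scale (deflates the weight) of coordinates
    where simulations systematically miss the observation, e.g. outliers.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    y_obs = np.asarray(y_obs, dtype=float)
    m = mad(samples)
    mado = np.median(np.abs(samples - y_obs[None, :]), axis=0)
    return np.where(mado < m, m, m + mado)


def update_scale_weights(
    samples: np.ndarray,
    y_obs: np.ndarray,
    state: DistanceState,
) -> DistanceState:
    """Recompute sigma for the next generation from all previous-generation
    simulations (accepted and rejected); q is carried over unchanged.

    Rows containing non-finite entries (failed simulations) are excluded.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    finite = np.all(np.isfinite(samples), axis=1)
    samples = samples[finite]
    if state.scale_kind == "none":
        sigma = np.ones(samples.shape[1])
    elif state.scale_kind == "mad":
        sigma = mad(samples)
    else:
        sigma = pcmad(samples, y_obs)
    n_dead = int(np.sum(sigma == 0))
    if n_dead:
        logger.warning(
            "generation %d: %d coordinate(s) with zero spread get distance weight 0",
            state.t + 1,
            n_dead,
        )
    return replace(state, sigma=sigma, t=state.t + 1)
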