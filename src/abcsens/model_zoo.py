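"""Benchmark inference problems: priors, stochastic simulators, observed data.

Every problem couples an independent per-parameter prior with a stochastic
simulator ``(theta, rng) -> y`` of fixed output dimension and a synthetic
observed vector.  The zoo covers:

* ``demo`` -- a four-parameter, five-data-block toy built to exhibit
  heterogeneous scales, an uninformative data block, and a parameter that is
  only quadratically identifiable,
* ``quadratic`` -- the one-parameter non-identifiable toy y ~ N(theta^2, 0.1^2),
* ``T1``--``T6`` -- a conversion-reaction ODE, an informative/uninformative
  Gaussian pair, g-and-k order statistics (small/large), and Lotka-Volterra
  Markov jump processes (small/large),
* ``gauss1d`` -- a conjugate Gaussian problem with a known analytic posterior.

Gaussian convention: the second argument of every N(., .) below is a VARIANCE.
All simulators accept a ``noise_scale`` multiplier (a test hook; 0 disables
observation noise) and are deterministic given an ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from numba import njit
from scipy import stats

__all__ = [
    "PriorSpec",
    "ProblemSpec",
    "SimulationFailure",
    "simulate_demo",
    "simulate_quadratic",
    "simulate_t2",
    "gk_quantile",
    "simulate_gk_order_stats",
    "gillespie_lv",
    "simulate_conversion",
    "make_observed",
    "list_problems",
]


class SimulationFailure(RuntimeError):
    """A simulator could not produce a finite output (e.g. event-cap hit)."""


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-parameter prior.

    Each entry is ``("uniform", lower, upper)`` or ``("normal", mean, variance)``.
    """

    components: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for fam, a, b in self.components:
            if fam == "uniform":
                if not a < b:
                    raise ValueError(f"uniform prior needs lower < upper, got ({a}, {b})")
            elif fam == "normal":
                if not b > 0:
                    raise ValueError(f"normal prior needs variance > 0, got {b}")
            else:
                raise ValueError(f"unknown prior family {fam!r}")

    @property
    def dim(self) -> int:
        return len(self.components)

    def sample(self, rng: np.random.Generator, size: Optional[int] = None) -> np.ndarray:
        """Draw ``size`` parameter vectors (or one, as a 1-d array)."""
        m = 1 if size is None else size
        out = np.empty((m, self.dim))
        for j, (fam, a, b) in enumerate(self.components):
            if fam == "uniform":
                out[:, j] = rng.uniform(a, b, size=m)
            else:
                out[:, j] = rng.normal(a, math.sqrt(b), size=m)
        return out[0] if size is None else out

    def pdf(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.dim,):
            raise ValueError(f"expected parameter of dimension {self.dim}, got shape {theta.shape}")
        p = 1.0
        for x, (fam, a, b) in zip(theta, self.components):
            if fam == "uniform":
                if x < a or x > b:
                    return 0.0
                p /= b - a
            else:
                p *= math.exp(-0.5 * (x - a) ** 2 / b) / math.sqrt(2 * math.pi * b)
        return p

    def in_support(self, theta: np.ndarray) -> bool:
        return self.pdf(np.asarray(theta, dtype=float)) > 0.0


# ---------------------------------------------------------------------------
# problem container
# ---------------------------------------------------------------------------


@dataclass
class ProblemSpec:
    """A fully specified inference problem."""

    name: str
    prior: PriorSpec
    simulator: Callable[[np.ndarray, np.random.Generator], np.ndarray]
    observed: np.ndarray
    ground_truth: Optional[np.ndarray] = None
    parameter_names: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.ground_truth is not None:
            self.ground_truth = np.asarray(self.ground_truth, dtype=float)
        if not self.parameter_names:
            self.parameter_names = tuple(f"theta_{j + 1}" for j in range(self.n_theta))

    @property
    def n_theta(self) -> int:
        return self.prior.dim

    @property
    def n_y(self) -> int:
        return self.observed.size

    def to_csv(self, path) -> None:
        """Export observed data (and ground truth if known) as one-row CSV."""
        import pandas as pd

        cols = {f"y_{i + 1}": [v] for i, v in enumerate(self.observed)}
        if self.ground_truth is not None:
            cols.update({name: [v] for name, v in zip(self.parameter_names, self.ground_truth)})
        pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------


def simulate_demo(theta: np.ndarray, rng: np.random.Generator, noise_scale: float = 1.0) -> np.ndarray:
    """Demonstration problem: 4 parameters, 17 data coordinates in 5 blocks.

    y1 ~ N(theta1, 0.1^2), y2 ~ N(theta2, 100^2), y3 ~ N(theta3, 4*100^2)^{x4},
    y4 ~ N(theta4^2, 0.1^2), y5 ~ N(0, 10)^{x10} (variance 10, uninformative).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (4,):
        raise ValueError(f"demo simulator expects 4 parameters, got shape {theta.shape}")
    s = noise_scale
    y1 = rng.normal(theta[0], s * 0.1, size=1)
    y2 = rng.normal(theta[1], s * 100.0, size=1)
    y3 = rng.normal(theta[2], s * 200.0, size=4)
    y4 = rng.normal(theta[3] ** 2, s * 0.1, size=1)
    y5 = rng.normal(0.0, s * math.sqrt(10.0), size=10)
    return np.concatenate([y1, y2, y3, y4, y5])


def simulate_quadratic(theta: np.ndarray, rng: np.random.Generator, noise_scale: float = 1.0) -> np.ndarray:
    """Quadratic toy: one draw from N(theta^2, 0.1^2)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if theta.shape != (1,):
        raise ValueError(f"quadratic simulator expects a scalar parameter, got shape {theta.shape}")
    return np.array([rng.normal(theta[0] ** 2, noise_scale * 0.1)])


def simulate_t2(theta: np.ndarray, rng: np.random.Generator, noise_scale: float = 1.0) -> np.ndarray:
    """T2: informative y1 ~ N(theta, 0.1^2) and uninformative y2 ~ N(0, 1)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if theta.shape != (1,):
        raise ValueError(f"T2 simulator expects a scalar parameter, got shape {theta.shape}")
    return np.array(
        [rng.normal(theta[0], noise_scale * 0.1), rng.normal(0.0, noise_scale * 1.0)]
    )


GK_C = 0.8


def gk_quantile(p, A, B, g, k):
    """Quantile function of the g-and-k distribution (c = 0.8).

    Q(p) = A + B * (1 + c*(1-e^{-g z})/(1+e^{-g z})) * (1+z^2)^k * z,
    with z the standard-normal quantile of p.  Requires B > 0, k > -0.5.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("p must lie strictly inside (0, 1)")
    if B <= 0:
        raise ValueError("scale B must be positive")
    if k <= -0.5:
        raise ValueError("kurtosis k must exceed -0.5")
    z = stats.norm.ppf(p)
    egz = np.exp(-g * z)
    return A + B * (1.0 + GK_C * (1.0 - egz) / (1.0 + egz)) * (1.0 + z * z) ** k * z


def _order_stat_indices(n_samples: int, n_stats: int) -> np.ndarray:
    # evenly spaced ranks ceil(j*n/(n_stats+1)), j = 1..n_stats (1-based)
    j = np.arange(1, n_stats + 1)
    return np.ceil(j * n_samples / (n_stats + 1)).astype(int) - 1


def simulate_gk_order_stats(
    theta: np.ndarray,
    n_samples: int,
    n_stats: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evenly ranked order statistics of i.i.d. g-and-k samples."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (4,):
        raise ValueError(f"g-and-k simulator expects 4 parameters, got shape {theta.shape}")
    if n_samples <= 0 or n_stats <= 0:
        raise ValueError("sample and statistic counts must be positive")
    if n_stats > n_samples:
        raise ValueError("cannot take more order statistics than samples")
    u = rng.random(n_samples)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    x = gk_quantile(u, *theta)
    x.sort()
    return x[_order_stat_indices(n_samples, n_stats)]


@njit(cache=True)
def _gillespie_core(th1, th2, th3, x0, y0, times, out, max_events, rng):  # pragma: no cover
    x = x0
    y = y0
    t = 0.0
    i = 0
    n_t = times.shape[0]
    events = 0
    while i < n_t:
        a1 = th1 * x
        a2 = th2 * x * y
        a3 = th3 * y
        a0 = a1 + a2 + a3
        if a0 <= 0.0:
            # absorbed: state persists to the horizon
            while i < n_t:
                out[i] = x
                out[n_t + i] = y
                i += 1
            return 0
        t_new = t + (-math.log(rng.random()) / a0)
        while i < n_t and times[i] < t_new:
            out[i] = x
            out[n_t + i] = y
            i += 1
        t = t_new
        u = rng.random() * a0
        if u < a1:
            x += 1
        elif u < a1 + a2:
            x -= 1
            y += 1
        else:
            y -= 1
        events += 1
        if events >= max_events:
            return 1
    return 0


def gillespie_lv(
    theta: np.ndarray,
    x0: Sequence[int],
    obs_times: np.ndarray,
    rng: np.random.Generator,
    max_events: int = 10_000_000,
) -> np.ndarray:
    """Exact stochastic simulation of the Lotka-Volterra Markov jump process.

    Reactions: prey birth at rate theta1*X; predation (prey-1, predator+1) at
    rate theta2*X*Y; predator death at rate theta3*Y.  Returns prey counts at
    ``obs_times`` followed by predator counts.  If the event cap is hit the
    trajectory is declared failed and an all-inf sentinel is returned (treated
    downstream as infinite distance).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (3,):
        raise ValueError(f"Lotka-Volterra simulator expects 3 rates, got shape {theta.shape}")
    if np.any(theta < 0):
        raise ValueError("reaction rates must be non-negative")
    if len(x0) != 2 or any(int(v) != v or v < 0 for v in x0):
        raise ValueError("initial state must be two non-negative integer counts")
    obs_times = np.ascontiguousarray(obs_times, dtype=np.float64)
    out = np.empty(2 * obs_times.size, dtype=np.float64)
    status = _gillespie_core(
        theta[0], theta[1], theta[2], int(x0[0]), int(x0[1]), obs_times, out, max_events, rng
    )
    if status != 0:
        out.fill(np.inf)
    return out


def simulate_conversion(
    theta: np.ndarray,
    rng: np.random.Generator,
    noise_scale: float = 1.0,
    obs_times: Optional[np.ndarray] = None,
    noise_sd: float = 0.02,
) -> np.ndarray:
    """Conversion reaction x1 <-> x2 with rates theta1 (forward), theta2 (back).

    dx1/dt = -theta1*x1 + theta2*x2 with x1 + x2 = 1, x0 = (1, 0); x2 observed
    at 10 evenly spaced times in (0, 30] with additive N(0, noise_sd^2) noise.
    The linear system has the exact solution
    x2(t) = theta1/(theta1+theta2) * (1 - exp(-(theta1+theta2) t)).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (2,):
        raise ValueError(f"conversion simulator expects 2 rates, got shape {theta.shape}")
    if np.any(theta <= 0):
        raise ValueError("conversion rates must be positive")
    if obs_times is None:
        obs_times = np.linspace(3.0, 30.0, 10)
    s = theta[0] + theta[1]
    x2 = theta[0] / s * (1.0 - np.exp(-s * obs_times))
    return x2 + rng.normal(0.0, noise_scale * noise_sd, size=obs_times.size)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_T6_TIMES = np.linspace(0.0, 20.0, 100)
_T4_TIMES = np.linspace(0.0, 20.0, 16)
_LV_X0 = (50, 100)
_LV_MAX_EVENTS = 1_000_000

_U010 = PriorSpec((("uniform", 0.0, 10.0),) * 4)
_LV_PRIOR = PriorSpec((("uniform", 0.0, 2.0), ("uniform", 0.0, 0.1), ("uniform", 0.0, 1.0)))


def _demo_observed() -> np.ndarray:
    obs = np.zeros(17)
    obs[6] = 0.7  # y4, the quadratically informative block
    return obs


_REGISTRY: dict[str, dict] = {
    "demo": dict(
        prior=PriorSpec(
            (
                ("uniform", -7.0, 7.0),
                ("uniform", -700.0, 700.0),
                ("uniform", -700.0, 700.0),
                ("uniform", -1.0, 1.0),
            )
        ),
        simulator=simulate_demo,
        fixed_observed=_demo_observed(),
        ground_truth=None,
    ),
    "quadratic": dict(
        prior=PriorSpec((("uniform", -1.0, 1.0),)),
        simulator=simulate_quadratic,
        fixed_observed=np.array([0.7]),
        ground_truth=None,
    ),
    "gauss1d": dict(
        prior=PriorSpec((("normal", 0.0, 1.0),)),
        simulator=lambda th, rng, noise_scale=1.0: np.array(
            [rng.normal(np.atleast_1d(th)[0], noise_scale * 1.0)]
        ),
        fixed_observed=np.array([1.0]),
        ground_truth=None,
    ),
    "T1": dict(
        prior=PriorSpec((("uniform", 0.0, 0.4),) * 2),
        simulator=simulate_conversion,
        default_truth=np.array([0.1, 0.1]),
    ),
    "T2": dict(
        prior=PriorSpec((("normal", 0.0, 100.0**2),)),
        simulator=simulate_t2,
        default_truth=np.array([0.7]),
    ),
    "T3": dict(
        prior=_U010,
        simulator=lambda th, rng: simulate_gk_order_stats(th, 1000, 7, rng),
        default_truth=np.array([3.0, 1.0, 2.0, 0.5]),
    ),
    "T4": dict(
        prior=_LV_PRIOR,
        simulator=lambda th, rng: gillespie_lv(th, _LV_X0, _T4_TIMES, rng, _LV_MAX_EVENTS),
        default_truth=np.array([0.5, 0.0025, 0.3]),
    ),
    "T5": dict(
        prior=_U010,
        simulator=lambda th, rng: simulate_gk_order_stats(th, 10_000, 100, rng),
        default_truth=np.array([3.0, 1.0, 2.0, 0.5]),
    ),
    "T6": dict(
        prior=_LV_PRIOR,
        simulator=lambda th, rng: gillespie_lv(th, _LV_X0, _T6_TIMES, rng, _LV_MAX_EVENTS),
        default_truth=np.array([0.5, 0.0025, 0.3]),
    ),
}


def list_problems() -> list[str]:
    """Names of all registered benchmark problems."""
    return sorted(_REGISTRY)


def make_observed(
    name: str,
    theta_true: Optional[np.ndarray] = None,
    seed: int = 0,
) -> ProblemSpec:
    """Build a fully populated :class:`ProblemSpec` for a registered problem.

    Problems with a fixed observed vector (``demo``, ``quadratic``, ``gauss1d``)
    ignore ``theta_true``/``seed``; for all others the observed data are one
    simulator draw at ``theta_true`` (default: the registered ground truth)
    with the given seed.
    """
    if name not in _REGISTRY:
        raise KeyError(f"unknown problem {name!r}; available: {', '.join(list_problems())}")
    entry = _REGISTRY[name]
    prior = entry["prior"]
    simulator = entry["simulator"]
    if "fixed_observed" in entry:
        return ProblemSpec(
            name=name,
            prior=prior,
            simulator=simulator,
            observed=entry["fixed_observed"].copy(),
            ground_truth=entry.get("ground_truth"),
        )
    if theta_true is None:
        theta_true = entry["default_truth"]
    theta_true = np.asarray(theta_true, dtype=float)
    if not prior.in_support(theta_true):
        raise ValueError(f"ground truth {theta_true} lies outside the prior support of {name}")
    rng = np.random.default_rng(seed)
    observed = np.asarray(simulator(theta_true, rng), dtype=float)
    if not np.all(np.isfinite(observed)):
        raise SimulationFailure(f"observed-data simulation failed for problem {name}")
    return ProblemSpec(
        name=name,
        prior=prior,
        simulator=simulator,
        observed=observed,
        ground_truth=theta_true.copy(),
    )
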