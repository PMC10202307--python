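"""ABC-SMC engine with adaptive distances, mid-run regression training, and
sensitivity-weighted comparisons.

The sampler propagates particle populations through generations with
decreasing acceptance thresholds.  Each generation t:

1. recomputes the robust scale sigma from ALL particles (accepted and
   rejected) of generation t-1;
2. if the training boundary is reached, fits the inverse regression model on
   those same particles and either switches the comparison to summary
   statistics s(y) vs s(y_obs), or derives fixed sensitivity weights q so
   that subsequent distances use r = q/sigma on the raw data;
3. re-scores the previous accepted particles under the new distance and sets
   epsilon to their median (thresholds under different distances are
   incommensurable, so the threshold is always re-anchored);
4. samples from a Gaussian-mixture proposal (generation 1: the prior) until N
   particles are accepted or the simulation budget is exhausted;
5. computes importance weights w = prior(theta)/proposal(theta) and
   normalizes them.

All randomness flows from one seed via ``numpy.random.SeedSequence`` spawning,
so reruns with the same configuration are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.linalg import solve_triangular

from . import regression as reg_mod
from . import sensitivity as sens_mod
from .distance import DistanceState, update_scale_weights
from .model_zoo import PriorSpec, ProblemSpec, SimulationFailure, make_observed

logger = logging.getLogger(__name__)

__all__ = [
    "Particle",
    "Generation",
    "Proposal",
    "RunConfig",
    "RunResult",
    "calibrate",
    "build_proposal",
    "propose_and_weight",
    "next_epsilon",
    "run",
]

_MAX_SUPPORT_REJECTIONS = 1_000_000


@dataclass
class Particle:
    """One (parameter, simulation, distance, importance weight) record."""

    theta: np.ndarray
    data: np.ndarray
    distance: float
    importance_weight: float = 0.0
    accepted: bool = False


@dataclass
class Generation:
    """All particles of one SMC iteration plus its threshold and distance."""

    t: int
    epsilon: float
    distance_state: DistanceState
    thetas: np.ndarray  # (m, n_theta), accepted and rejected
    data: np.ndarray  # (m, n_y) raw simulations
    distances: np.ndarray  # (m,)
    accepted: np.ndarray  # (m,) bool
    weights: np.ndarray  # normalized importance weights of accepted particles
    n_simulations: int
    partial: bool = False
    eps_next: Optional[float] = None

    @property
    def accepted_thetas(self) -> np.ndarray:
        return self.thetas[self.accepted]

    @property
    def accepted_data(self) -> np.ndarray:
        return self.data[self.accepted]

    @property
    def accepted_distances(self) -> np.ndarray:
        return self.distances[self.accepted]

    @property
    def n_accepted(self) -> int:
        return int(np.sum(self.accepted))

    def particles(self) -> list[Particle]:
        """Materialize per-particle records (accepted carry their weight)."""
        w = np.zeros(len(self.thetas))
        w[self.accepted] = self.weights
        return [
            Particle(th, y, float(d), float(wi), bool(a))
            for th, y, d, wi, a in zip(self.thetas, self.data, self.distances, w, self.accepted)
        ]


def _regularized_cholesky(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    jitter = 0.0
    for _ in range(15):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(d))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * max(np.trace(cov), 1.0))
    raise np.linalg.LinAlgError("proposal covariance could not be regularized")


class Proposal:
    """Gaussian mixture kernel centered at the previous accepted parameters.

    ``covs`` is either one shared (d, d) covariance or a per-center
    (N, d, d) stack (local kernels).  Singular covariances are regularized by
    an escalating diagonal jitter starting at 1e-10 * trace.
    """

    def __init__(self, centers: np.ndarray, weights: np.ndarray, covs: np.ndarray):
        self.centers = np.atleast_2d(np.asarray(centers, dtype=float))
        self.weights = np.asarray(weights, dtype=float)
        self.weights = self.weights / self.weights.sum()
        covs = np.asarray(covs, dtype=float)
        n, d = self.centers.shape
        self.shared = covs.ndim == 2
        if self.shared:
            chol = _regularized_cholesky(covs)
            self.cov = chol @ chol.T
            self._chols = chol[None, :, :]
        else:
            self._chols = np.empty((n, d, d))
            for i in range(n):
                self._chols[i] = _regularized_cholesky(covs[i])
            self.cov = None
        # inverse from the Cholesky factor (stable also for barely-PD matrices)
        eye = np.eye(d)
        self._invs = np.stack(
            [
                solve_triangular(L, solve_triangular(L, eye, lower=True), lower=True, trans="T")
                for L in self._chols
            ]
        )
        self._log_norm = -0.5 * d * math.log(2 * math.pi) - np.log(
            np.diagonal(self._chols, axis1=1, axis2=2)
        ).sum(axis=1)
        self._cumw = np.cumsum(self.weights)

    @property
    def dim(self) -> int:
        return self.centers.shape[1]

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        idx = int(np.searchsorted(self._cumw, rng.random()))
        idx = min(idx, len(self.centers) - 1)
        chol = self._chols[0] if self.shared else self._chols[idx]
        return self.centers[idx] + chol @ rng.standard_normal(self.dim)

    def pdf(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        diff = theta[None, :] - self.centers
        if self.shared:
            sol = solve_triangular(self._chols[0], diff.T, lower=True)
            quad = np.sum(sol * sol, axis=0)
            log_norm = self._log_norm[0]
        else:
            quad = np.einsum("ij,ijk,ik->i", diff, self._invs, diff)
            log_norm = self._log_norm
        return float(np.sum(self.weights * np.exp(log_norm - 0.5 * quad)))


def build_proposal(thetas: np.ndarray, weights: np.ndarray) -> Proposal:
    """Global-kernel Gaussian mixture: shared covariance twice the weighted
    empirical covariance of the accepted population."""
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if thetas.shape[0] < 2:
        raise ValueError("need at least two accepted particles to build a proposal")
    if weights.sum() <= 0:
        raise ValueError("total importance weight must be positive")
    w = weights / weights.sum()
    mu = w @ thetas
    centered = thetas - mu
    cov = 2.0 * (centered.T * w) @ centered
    return Proposal(thetas, w, cov)


def build_local_proposal(
    thetas: np.ndarray,
    weights: np.ndarray,
    distances: np.ndarray,
    eps_next: float,
) -> Proposal:
    """Optimal-local-covariance Gaussian mixture.

    The mixture is built from the previous accepted particles that already
    satisfy the next threshold (particles outside it cannot seed acceptable
    proposals); each such center theta_i carries its own kernel covariance
    Sigma_i = sum_k lambda_k (theta_k - theta_i)(theta_k - theta_i)^T over
    that same subset, with lambda its renormalized importance weights.  Local
    kernels adapt to curved posterior ridges far better than one global
    covariance and markedly raise acceptance rates at small budgets.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    weights = np.asarray(weights, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if thetas.shape[0] < 2:
        raise ValueError("need at least two accepted particles to build a proposal")
    sel = distances <= eps_next
    if np.sum(sel) < 2 or weights[sel].sum() <= 0:
        sel = np.ones(len(thetas), dtype=bool)
    pts = thetas[sel]
    lam = weights[sel] / weights[sel].sum()
    n, d = pts.shape
    covs = np.empty((n, d, d))
    for i in range(n):
        diff = pts - pts[i]
        covs[i] = (diff.T * lam) @ diff
    return Proposal(pts, lam, covs)


def propose_and_weight(
    proposal: Optional[Proposal],
    prior: PriorSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Draw a parameter with positive prior density and its importance weight.

    Generation 1 (``proposal is None``) samples the prior directly, weight 1.
    Otherwise draws from the mixture, redrawing outside the prior support; the
    weight uses the untruncated mixture density w = pi(theta)/g(theta).
    """
    if proposal is None:
        return prior.sample(rng), 1.0
    for _ in range(_MAX_SUPPORT_REJECTIONS):
        theta = proposal.sample(rng)
        prior_pdf = prior.pdf(theta)
        if prior_pdf > 0.0:
            g = proposal.pdf(theta)
            return theta, prior_pdf / g
    raise RuntimeError(
        "proposal produced 1e6 consecutive draws outside the prior support; "
        "prior/proposal mismatch"
    )


def next_epsilon(accepted_distances: np.ndarray) -> float:
    """Median of the accepted distances of the previous generation."""
    d = np.asarray(accepted_distances, dtype=float)
    if d.size == 0:
        raise ValueError("cannot derive a threshold from an empty population")
    return float(np.median(d))


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one ABC-SMC run."""

    problem: Union[str, ProblemSpec]
    n_particles: int = 1000
    budget: int = 100_000
    p: float = 1.0
    scale_kind: str = "mad"
    regression: Optional[reg_mod.RegressionSpec] = None
    sensitivity_normalize: bool = True
    seed: int = 0
    data_seed: Optional[int] = None
    max_generations: int = 50
    stagnation_patience: int = 3
    proposal_kind: str = "local"  # local (per-particle covariance) | global (2x cov)

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("population size N must be at least 2")
        if self.budget < self.n_particles:
            raise ValueError("budget must cover at least one population")

    def resolve_problem(self) -> ProblemSpec:
        if isinstance(self.problem, ProblemSpec):
            return self.problem
        return make_observed(self.problem, seed=self.data_seed or 0)


@dataclass
class RunResult:
    """Full history of one run plus the final weighted posterior sample."""

    config: RunConfig
    problem: ProblemSpec
    generations: list[Generation]
    total_simulations: int
    regressor: Optional[reg_mod.TrainedRegressor] = None
    sensitivity: Optional[sens_mod.SensitivityMatrix] = None
    messages: list[str] = field(default_factory=list)

    @property
    def final_generation(self) -> Generation:
        """Last generation that reached the full population size."""
        complete = [g for g in self.generations if not g.partial]
        return complete[-1] if complete else self.generations[-1]

    @property
    def posterior_sample(self) -> tuple[np.ndarray, np.ndarray]:
        g = self.final_generation
        return g.accepted_thetas, g.weights

    def posterior_mean(self) -> np.ndarray:
        thetas, w = self.posterior_sample
        return w @ thetas

    @property
    def epsilon_trajectory(self) -> list[float]:
        return [g.epsilon for g in self.generations]


def _simulate(problem: ProblemSpec, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    try:
        y = np.asarray(problem.simulator(theta, rng), dtype=float)
    except SimulationFailure:
        return np.full(problem.n_y, np.inf)
    if y.shape != (problem.n_y,):
        raise ValueError(
            f"simulator of {problem.name!r} returned shape {y.shape}, expected ({problem.n_y},)"
        )
    return y


def calibrate(
    problem: ProblemSpec,
    n_particles: int,
    rng: np.random.Generator,
    p: float = 1.0,
    scale_kind: str = "mad",
) -> tuple[Generation, int]:
    """Generation 0: N prior samples, initial scale weights, and epsilon_1.

    Failed simulations count against the budget and are resampled.  Returns
    the calibration generation (all particles accepted, importance weights
    1/N, own threshold inf; the derived epsilon_1 is stored in ``eps_next``)
    together with the number of simulations consumed.
    """
    thetas = np.empty((n_particles, problem.n_theta))
    data = np.empty((n_particles, problem.n_y))
    n_sims = 0
    got = 0
    while got < n_particles:
        theta = np.atleast_1d(problem.prior.sample(rng))
        y = _simulate(problem, theta, rng)
        n_sims += 1
        if np.all(np.isfinite(y)):
            thetas[got] = theta
            data[got] = y
            got += 1
        elif n_sims > 100 * n_particles:
            raise RuntimeError("calibration failed: simulator keeps failing")
    state = update_scale_weights(
        data, problem.observed, DistanceState(p=p, scale_kind=scale_kind, t=-1)
    )
    distances = np.array([state(y, problem.observed) for y in data])
    gen = Generation(
        t=0,
        epsilon=math.inf,
        distance_state=state,
        thetas=thetas,
        data=data,
        distances=distances,
        accepted=np.ones(n_particles, dtype=bool),
        weights=np.full(n_particles, 1.0 / n_particles),
        n_simulations=n_sims,
        eps_next=next_epsilon(distances),
    )
    return gen, n_sims


def run(config: RunConfig) -> RunResult:
    """Execute the full ABC-SMC analysis described by ``config``."""
    problem = config.resolve_problem()
    regspec = config.regression
    ss = np.random.SeedSequence(config.seed)
    messages: list[str] = []

    rng_cal = np.random.default_rng(ss.spawn(1)[0])
    gen0, sims_used = calibrate(
        problem, config.n_particles, rng_cal, p=config.p, scale_kind=config.scale_kind
    )
    generations = [gen0]
    logger.info(
        "t=0 (calibration): eps_1=%.6g, %d simulations", gen0.eps_next, gen0.n_simulations
    )

    trained: Optional[reg_mod.TrainedRegressor] = None
    sens_matrix: Optional[sens_mod.SensitivityMatrix] = None
    q_fixed: Optional[np.ndarray] = None
    use_stats = False
    s_obs: Optional[np.ndarray] = None
    no_progress = 0

    prev = gen0
    for t in range(1, config.max_generations + 1):
        if sims_used >= config.budget:
            break
        rng_t = np.random.default_rng(ss.spawn(1)[0])

        pool_thetas = prev.thetas
        pool_data = prev.data
        finite = np.all(np.isfinite(pool_data), axis=1)

        # -- mid-run regression training at the budget-fraction boundary
        if reg_mod.should_train(sims_used, config.budget, regspec, trained is not None):
            from .distance import mad  # plain MAD for regressor inputs, always

            sigma_train = mad(pool_data[finite])
            trained = reg_mod.fit(
                pool_thetas[finite],
                pool_data[finite],
                regspec,
                sigma_train,
                np.random.default_rng(ss.spawn(1)[0]),
                generation=t,
            )
            messages.append(f"t={t}: trained {regspec.family} regressor (mode={regspec.mode})")
            logger.info(messages[-1])
            if regspec.mode == "statistics":
                use_stats = True
                s_obs = trained(problem.observed)
            else:
                state_q, sens_matrix = sens_mod.compute_sensitivity_state(
                    trained,
                    problem.observed,
                    sigma=np.ones(problem.n_y),  # sigma refreshed below
                    scale_kind=config.scale_kind,
                    p=config.p,
                    normalize=config.sensitivity_normalize,
                )
                q_fixed = state_q.q

        # -- representation of the comparison for this generation
        if use_stats:
            rep_pool = trained(pool_data[finite])
            rep_obs = s_obs
        else:
            rep_pool = pool_data[finite]
            rep_obs = problem.observed

        # -- adaptive scale update from all previous-generation particles
        base = DistanceState(p=config.p, scale_kind=config.scale_kind, q=q_fixed, t=t - 1)
        state = update_scale_weights(rep_pool, rep_obs, base)
        logger.info("t=%d: distance weights updated (scale=%s)", t, config.scale_kind)

        # -- re-anchor epsilon: re-score previous accepted under the new d_t
        acc_rep = trained(prev.accepted_data) if use_stats else prev.accepted_data
        rescored = np.array([state(y, rep_obs) for y in acc_rep])
        eps_t = next_epsilon(rescored)

        if t == 1:
            proposal = None
        elif config.proposal_kind == "global":
            proposal = build_proposal(prev.accepted_thetas, prev.weights)
        else:
            proposal = build_local_proposal(
                prev.accepted_thetas, prev.weights, rescored, eps_t
            )

        # -- sample until N acceptances or budget exhaustion
        thetas_l, data_l, dist_l, acc_l, w_l = [], [], [], [], []
        n_acc = 0
        n_sims_gen = 0
        while n_acc < config.n_particles and sims_used < config.budget:
            theta, w_imp = propose_and_weight(proposal, problem.prior, rng_t)
            y = _simulate(problem, theta, rng_t)
            sims_used += 1
            n_sims_gen += 1
            d = state(trained(y), rep_obs) if (use_stats and np.all(np.isfinite(y))) else (
                state(y, rep_obs) if not use_stats else math.inf
            )
            ok = d <= eps_t
            thetas_l.append(theta)
            data_l.append(y)
            dist_l.append(d)
            acc_l.append(ok)
            w_l.append(w_imp if ok else 0.0)
            if ok:
                n_acc += 1

        acc_arr = np.array(acc_l, dtype=bool)
        w_acc = np.array(w_l, dtype=float)[acc_arr]
        partial = n_acc < config.n_particles
        if n_acc == 0:
            messages.append(f"t={t}: budget exhausted before any acceptance; dropped")
            logger.warning(messages[-1])
            break
        gen = Generation(
            t=t,
            epsilon=eps_t,
            distance_state=state,
            thetas=np.array(thetas_l),
            data=np.array(data_l),
            distances=np.array(dist_l),
            accepted=acc_arr,
            weights=w_acc / w_acc.sum(),
            n_simulations=n_sims_gen,
            partial=partial,
        )
        generations.append(gen)
        logger.info(
            "t=%d: eps=%.6g, accepted %d/%d (rate %.3f), simulations used %d/%d%s",
            t,
            eps_t,
            n_acc,
            n_sims_gen,
            n_acc / max(n_sims_gen, 1),
            sims_used,
            config.budget,
            " [partial]" if partial else "",
        )
        if partial:
            messages.append(f"t={t}: budget exhausted mid-generation ({n_acc} accepted)")
            break

        # -- stagnation guard
        prev_eps = generations[-2].epsilon if len(generations) > 2 else math.inf
        if prev_eps - eps_t <= 1e-12:
            no_progress += 1
            if no_progress >= config.stagnation_patience:
                messages.append(f"t={t}: epsilon stagnated for {no_progress} generations; stop")
                logger.warning(messages[-1])
                break
        else:
            no_progress = 0
        prev = gen

    return RunResult(
        config=config,
        problem=problem,
        generations=generations,
        total_simulations=sims_used,
        regressor=trained,
        sensitivity=sens_matrix,
        messages=messages,
    )
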