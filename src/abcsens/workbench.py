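"""Experiment orchestration: method names, run configs, results storage,
replicate aggregation, and the weighted-RMSE evaluation metric.

Method strings follow the naming scheme of the benchmark study, e.g.

* ``L1+Ada.+MAD`` -- L1 distance with adaptive MAD scale weights,
* ``L1+Ada.+MAD+SensiLR+P4`` -- additionally a linear model defining fixed
  sensitivity weights, with regression targets (theta^1, ..., theta^4),
* ``L1+StatLR`` -- linear summary statistics under uniform distance weights,
* a trailing ``+Init`` trains the regressor before the first generation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import smc
from .model_zoo import make_observed
from .regression import RegressionSpec

logger = logging.getLogger(__name__)

__all__ = [
    "MethodConfig",
    "parse_method",
    "weighted_rmse",
    "run_experiment",
    "load_populations",
    "replicate_runs",
    "list_methods",
]

_EXAMPLE_METHODS = [
    "L1",
    "L1+Ada.+MAD",
    "L1+Ada.+PCMAD",
    "L1+StatLR",
    "L1+StatNN",
    "L1+Ada.+MAD+StatLR",
    "L1+Ada.+MAD+StatNN",
    "L1+Ada.+MAD+StatLR+P4",
    "L1+Ada.+MAD+StatNN+P4",
    "L1+Ada.+MAD+StatLR+Init",
    "L1+Ada.+MAD+SensiLR",
    "L1+Ada.+MAD+SensiNN",
    "L1+Ada.+MAD+SensiLR+P4",
    "L1+Ada.+MAD+SensiNN+P4",
    "L1+Ada.+PCMAD+SensiLR+P4",
]


@dataclass(frozen=True)
class MethodConfig:
    """Parsed method string."""

    name: str
    p: float
    scale_kind: str  # mad | pcmad | none
    mode: Optional[str] = None  # statistics | sensitivity | None
    family: Optional[str] = None  # linear | mlp
    k: int = 1
    train_fraction: float = 0.4

    def regression_spec(self) -> Optional[RegressionSpec]:
        if self.mode is None:
            return None
        return RegressionSpec(
            family=self.family, k=self.k, train_fraction=self.train_fraction, mode=self.mode
        )


def list_methods() -> list[str]:
    """Canonical example method names (the grammar admits more combinations)."""
    return list(_EXAMPLE_METHODS)


def parse_method(name: str) -> MethodConfig:
    """Parse a method string into distance/regression configuration."""
    tokens = name.split("+")
    if not tokens or tokens[0] not in ("L1", "L2"):
        raise ValueError(f"method {name!r} must start with 'L1' or 'L2'")
    p = 1.0 if tokens[0] == "L1" else 2.0
    scale_kind = "none"
    mode = None
    family = None
    k = 1
    train_fraction = 0.4
    i = 1
    while i < len(tokens):
        tok = tokens[i]
        if tok == "Ada.":
            if i + 1 >= len(tokens) or tokens[i + 1] not in ("MAD", "PCMAD"):
                raise ValueError(f"'Ada.' must be followed by 'MAD' or 'PCMAD' in {name!r}")
            scale_kind = tokens[i + 1].lower()
            i += 2
            continue
        if tok in ("StatLR", "StatNN", "SensiLR", "SensiNN"):
            if mode is not None:
                raise ValueError(f"multiple regression tokens in {name!r}")
            mode = "statistics" if tok.startswith("Stat") else "sensitivity"
            family = "linear" if tok.endswith("LR") else "mlp"
        elif tok == "P4":
            k = 4
        elif tok == "Init":
            train_fraction = 0.0
        else:
            raise ValueError(
                f"unknown method token {tok!r} in {name!r}; valid tokens: "
                "Ada., MAD, PCMAD, StatLR, StatNN, SensiLR, SensiNN, P4, Init; "
                f"examples: {', '.join(_EXAMPLE_METHODS[:5])}, ..."
            )
        i += 1
    if mode is None and (k != 1 or train_fraction != 0.4):
        raise ValueError(f"'P4'/'Init' require a Stat or Sensi token in {name!r}")
    return MethodConfig(
        name=name,
        p=p,
        scale_kind=scale_kind,
        mode=mode,
        family=family,
        k=k,
        train_fraction=train_fraction,
    )


def weighted_rmse(
    samples: np.ndarray, weights: np.ndarray, theta_true: np.ndarray
) -> np.ndarray:
    """Per-parameter RMSE of a weighted posterior sample vs ground truth:
    sqrt(sum_i w_i (theta_ij - theta_true_j)^2)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    weights = np.asarray(weights, dtype=float)
    theta_true = np.atleast_1d(np.asarray(theta_true, dtype=float))
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError(f"weights must sum to 1, got {weights.sum()}")
    return np.sqrt(weights @ (samples - theta_true[None, :]) ** 2)


# ---------------------------------------------------------------------------
# configuration files and the results store
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "problem",
    "method",
    "n_particles",
    "budget",
    "max_generations",
    "seed",
    "data_seed",
    "theta_true",
}


def _build_run_config(cfg: dict, seed: Optional[int] = None) -> smc.RunConfig:
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys: {sorted(unknown)}; valid keys: {sorted(_CONFIG_KEYS)}"
        )
    for key in ("problem", "method"):
        if key not in cfg:
            raise ValueError(f"config is missing required key {key!r}")
    method = parse_method(cfg["method"])
    data_seed = cfg.get("data_seed", cfg.get("seed", 0))
    theta_true = cfg.get("theta_true")
    problem = make_observed(
        cfg["problem"],
        theta_true=None if theta_true is None else np.asarray(theta_true, dtype=float),
        seed=data_seed,
    )
    return smc.RunConfig(
        problem=problem,
        n_particles=int(cfg.get("n_particles", 1000)),
        budget=int(cfg.get("budget", 100_000)),
        p=method.p,
        scale_kind=method.scale_kind,
        regression=method.regression_spec(),
        seed=int(seed if seed is not None else cfg.get("seed", 0)),
        data_seed=data_seed,
        max_generations=int(cfg.get("max_generations", 50)),
    )


def _store_result(result: smc.RunResult, cfg: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for gen in result.generations:
        w = np.zeros(len(gen.thetas))
        w[gen.accepted] = gen.weights
        df = pd.DataFrame(
            {"particle": np.arange(len(gen.thetas))}
            | {
                name: gen.thetas[:, j]
                for j, name in enumerate(result.problem.parameter_names)
            }
            | {"weight": w, "distance": gen.distances, "accepted": gen.accepted}
        )
        # %.17g round-trips float64 exactly
        df.to_csv(outdir / f"population_t{gen.t}.csv", index=False, float_format="%.17g")

    meta: dict = {
        "config": cfg,
        "problem": result.problem.name,
        "n_theta": result.problem.n_theta,
        "n_y": result.problem.n_y,
        "total_simulations": result.total_simulations,
        "epsilon_trajectory": [float(e) for e in result.epsilon_trajectory],
        "messages": result.messages,
        "generations": [],
    }
    for gen in result.generations:
        st = gen.distance_state
        n_rep = gen.data.shape[1] if st.sigma is None else st.sigma.size
        meta["generations"].append(
            {
                "t": gen.t,
                "epsilon": float(gen.epsilon),
                "n_simulations": gen.n_simulations,
                "n_accepted": gen.n_accepted,
                "partial": gen.partial,
                "sigma": None if st.sigma is None else st.sigma.tolist(),
                "q": None if st.q is None else st.q.tolist(),
                "r": st.weights(n_rep).tolist(),
            }
        )
    if result.regressor is not None:
        meta["regressor"] = result.regressor.summary()
    if result.sensitivity is not None:
        A = np.abs(result.sensitivity.S)
        colsum = A.sum(axis=0)
        norm = np.divide(A, colsum, out=np.zeros_like(A), where=colsum > 0)
        meta["abs_sensitivity_normalized"] = norm.tolist()
    if result.problem.ground_truth is not None:
        thetas, w = result.posterior_sample
        meta["rmse"] = weighted_rmse(thetas, w, result.problem.ground_truth).tolist()
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def run_experiment(
    config: Union[str, Path, dict],
    seed: Optional[int] = None,
    outdir: Optional[Union[str, Path]] = None,
) -> smc.RunResult:
    """Run one configured analysis and (optionally) write its results store.

    ``config`` is a YAML file path or an equivalent dict with keys
    problem, method, n_particles, budget, max_generations, seed, data_seed,
    theta_true.  Unknown keys raise.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    run_config = _build_run_config(cfg, seed=seed)

    handler = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setLevel(logging.INFO)
        handler.setFormatter(logging.Formatter("%(message)s"))
        pkg_logger = logging.getLogger("abcsens")
        pkg_logger.addHandler(handler)
        pkg_logger.setLevel(logging.INFO)
    try:
        result = smc.run(run_config)
    finally:
        if handler is not None:
            logging.getLogger("abcsens").removeHandler(handler)
            handler.close()

    for gen in result.generations:
        print(
            f"t={gen.t} eps={gen.epsilon:.6g} "
            f"acc_rate={gen.n_accepted / max(gen.n_simulations, 1):.3f} "
            f"sims={gen.n_simulations}"
        )
    if outdir is not None:
        echo = dict(cfg)
        if seed is not None:
            echo["seed"] = seed
        _store_result(result, echo, outdir)
    return result


def load_populations(outdir: Union[str, Path]) -> dict[int, pd.DataFrame]:
    """Reload all stored populations of a run, keyed by generation index."""
    outdir = Path(outdir)
    out = {}
    for path in sorted(outdir.glob("population_t*.csv")):
        t = int(path.stem.split("population_t")[1])
        out[t] = pd.read_csv(path, float_precision="round_trip")
    if not out:
        raise FileNotFoundError(f"no stored populations under {outdir}")
    return out


def replicate_runs(
    config: Union[str, Path, dict],
    n_replicates: int,
    seeds: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Run the experiment once per seed on freshly generated observed data and
    aggregate per-parameter RMSE (median and MAD across replicates).

    Returns one row per (method, problem, parameter).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    if seeds is None:
        seeds = [int(cfg.get("seed", 0)) + i for i in range(n_replicates)]
    if len(seeds) != n_replicates:
        raise ValueError("number of seeds must match number of replicates")

    rmses = []
    for seed in seeds:
        rep_cfg = dict(cfg)
        rep_cfg["seed"] = int(seed)
        rep_cfg["data_seed"] = int(seed)  # each replicate on a fresh data set
        result = run_experiment(rep_cfg)
        if result.problem.ground_truth is None:
            raise ValueError(f"problem {result.problem.name!r} has no ground truth for RMSE")
        thetas, w = result.posterior_sample
        rmses.append(weighted_rmse(thetas, w, result.problem.ground_truth))
        names = result.problem.parameter_names
    rmses = np.array(rmses)
    med = np.median(rmses, axis=0)
    mad_rep = np.median(np.abs(rmses - med[None, :]), axis=0)
    return pd.DataFrame(
        {
            "method": cfg["method"],
            "problem": cfg["problem"],
            "parameter": list(names),
            "median_rmse": med,
            "mad_rmse": mad_rep,
            "n_replicates": n_replicates,
        }
    )
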