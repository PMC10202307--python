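"""Inverse regression models of (augmented) parameters on normalized data.

A regression model s: R^{n_y} -> R^{n_lambda} approximates posterior
expectations of parameter transforms lambda(theta) = (theta^1, ..., theta^k)
given data.  It is trained once per ABC-SMC run, by default after 40% of the
simulation budget, on all particles (accepted and rejected) of the previous
generation.  Inputs are divided by the scale vector sigma of the training
generation; targets are z-scored.  The fitted map is used either directly as
summary statistics, or differentiated at the observed data to derive
sensitivity weights.

Target augmentation (k > 1) makes symmetric/non-identifiable parameters
regressible: e.g. for y ~ N(theta^2, .) no global map y -> theta exists, but
y -> theta^2 is linear.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionSpec",
    "TrainedRegressor",
    "augment_targets",
    "should_train",
    "fit",
    "predict",
]

FAMILIES = ("linear", "mlp")
MODES = ("statistics", "sensitivity")


@dataclass(frozen=True)
class RegressionSpec:
    """What to fit, on which targets, and when.

    train_fraction=0 means training before the first generation on calibration
    (prior) samples; the default 0.4 delays training until the sampler has
    reached a high-density region where a simple model is adequate.
    """

    family: str = "linear"
    k: int = 1
    train_fraction: float = 0.4
    mode: str = "statistics"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not (isinstance(self.k, int) and self.k >= 1):
            raise ValueError(f"augmentation degree k must be an integer >= 1, got {self.k}")
        if not 0 <= self.train_fraction < 1:
            raise ValueError(f"train_fraction must lie in [0, 1), got {self.train_fraction}")


def augment_targets(thetas: np.ndarray, k: int) -> np.ndarray:
    """Componentwise powers, blocks ordered by power: (theta^1, ..., theta^k)."""
    if not (isinstance(k, int) and k >= 1):
        raise ValueError(f"augmentation degree k must be an integer >= 1, got {k}")
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    return np.hstack([thetas**j for j in range(1, k + 1)])


def should_train(
    simulations_used: int,
    budget: int,
    spec: Optional[RegressionSpec],
    already_trained: bool = False,
) -> bool:
    """True at the first generation boundary past the training fraction."""
    if spec is None or already_trained:
        return False
    if budget <= 0:
        raise ValueError("budget must be positive")
    return simulations_used >= spec.train_fraction * budget


@dataclass
class TrainedRegressor:
    """A fitted inverse map with its input/target normalizations.

    Predictions stay on the z-scored target scale: the downstream adaptive
    distance renormalizes anyway, and sensitivity weights need scale-free
    outputs.
    """

    model: object
    spec: RegressionSpec
    input_scale: np.ndarray  # full sigma of the training generation
    keep: np.ndarray  # indices of coordinates with sigma > 0
    target_mean: np.ndarray
    target_sd: np.ndarray
    n_y: int
    n_lambda: int
    generation: int = 0
    n_train: int = 0
    train_r2: Optional[np.ndarray] = field(default=None)

    def normalize_input(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape[-1] != self.n_y:
            raise ValueError(f"expected input of dimension {self.n_y}, got {y.shape[-1]}")
        return y[..., self.keep] / self.input_scale[self.keep]

    def predict_normalized(self, x: np.ndarray) -> np.ndarray:
        """Model output for already-normalized input(s)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        out = self.model.predict(np.atleast_2d(x))
        out = np.atleast_2d(out)
        if out.shape[1] != self.n_lambda:  # single-output sklearn models squeeze
            out = out.reshape(-1, self.n_lambda)
        return out[0] if single else out

    def __call__(self, y: np.ndarray) -> np.ndarray:
        return self.predict_normalized(self.normalize_input(y))

    def summary(self) -> dict:
        """Serializable description for the results store."""
        info: dict = {
            "family": self.spec.family,
            "k": self.spec.k,
            "mode": self.spec.mode,
            "generation": self.generation,
            "n_train": self.n_train,
            "n_inputs_used": int(self.keep.size),
            "n_targets": self.n_lambda,
        }
        if self.train_r2 is not None:
            info["train_r2"] = [float(v) for v in self.train_r2]
        if self.spec.family == "linear":
            info["coefficients"] = np.atleast_2d(self.model.coef_).tolist()
        else:
            info["layer_shapes"] = [list(w.shape) for w in self.model.coefs_]
        return info


def fit(
    thetas: np.ndarray,
    data: np.ndarray,
    spec: RegressionSpec,
    sigma: np.ndarray,
    rng: np.random.Generator,
    generation: int = 0,
) -> TrainedRegressor:
    """Fit one multi-output model of z-scored lambda(theta) on y/sigma.

    All particles of the training generation are used, accepted and rejected;
    rows with non-finite data (failed simulations) are dropped with a warning.
    Coordinates with sigma = 0 are excluded from the regressor input.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    data = np.atleast_2d(np.asarray(data, dtype=float))
    sigma = np.asarray(sigma, dtype=float)
    if thetas.shape[0] != data.shape[0]:
        raise ValueError("parameter and data sample counts differ")
    ok = np.all(np.isfinite(data), axis=1) & np.all(np.isfinite(thetas), axis=1)
    if not np.all(ok):
        logger.warning("dropping %d non-finite training row(s)", int(np.sum(~ok)))
        thetas, data = thetas[ok], data[ok]
    if thetas.shape[0] < 2:
        raise ValueError("need at least two finite training samples")

    keep = np.flatnonzero(sigma > 0)
    if keep.size == 0:
        raise ValueError("all data coordinates have zero scale; nothing to regress on")
    if keep.size < sigma.size:
        logger.warning(
            "regressor drops %d zero-scale input coordinate(s)", sigma.size - keep.size
        )
    X = data[:, keep] / sigma[keep]

    targets = augment_targets(thetas, spec.k)
    t_mean = targets.mean(axis=0)
    t_sd = targets.std(axis=0)
    degenerate = t_sd == 0
    if np.any(degenerate):
        t_sd = np.where(degenerate, 1.0, t_sd)  # degenerate target contributes nothing
    Z = (targets - t_mean) / t_sd
    n_lambda = Z.shape[1]

    if spec.family == "linear":
        model = LinearRegression()
        model.fit(X, Z)
    else:
        width = math.ceil((keep.size + n_lambda) / 2)
        model = MLPRegressor(
            hidden_layer_sizes=(width,),
            activation="relu",
            solver="adam",
            max_iter=500,
            early_stopping=True,
            validation_fraction=0.1,
            n_iter_no_change=10,
            random_state=int(rng.integers(2**31 - 1)),
        )
        model.fit(X, Z if n_lambda > 1 else Z.ravel())

    pred = np.atleast_2d(model.predict(X)).reshape(len(X), n_lambda)
    ss_res = np.sum((Z - pred) ** 2, axis=0)
    ss_tot = np.sum(Z**2, axis=0)  # targets are centered
    r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), 0.0)

    return TrainedRegressor(
        model=model,
        spec=spec,
        input_scale=sigma.copy(),
        keep=keep,
        target_mean=t_mean,
        target_sd=t_sd,
        n_y=sigma.size,
        n_lambda=n_lambda,
        generation=generation,
        n_train=thetas.shape[0],
        train_r2=r2,
    )


def predict(reg: TrainedRegressor, y: np.ndarray) -> np.ndarray:
    """Summary statistics s(y) on the z-scored target scale."""
    return reg(y)
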