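# abcsens

Likelihood-free Bayesian inference for stochastic simulators via ABC-SMC
(approximate Bayesian computation with sequential Monte Carlo), with three
ingredients that make the data comparison *informative*:

1. **Adaptive scale-normalized distances.** Simulations and observations are
   compared with a weighted Minkowski distance
   `d_t(y, y_obs) = (Σ_i |r_i (y_i − y_obs,i)|^p)^(1/p)`, whose per-coordinate
   weights `r_i = q_i/σ_i` use a robust scale σ (MAD, or the outlier-aware
   PCMAD) recomputed every generation from all simulations of the previous
   generation.
2. **Regression-based summary statistics.** Mid-run (by default after 40% of
   the simulation budget), an inverse regression model `s: y ↦ λ(θ)` is
   trained on all particles of the previous generation; from then on the
   sampler compares `s(y)` with `s(y_obs)` under a freshly scale-normalized
   adaptive distance.
3. **Sensitivity weights.** Alternatively, the trained model is differentiated
   at the observed data (central finite differences with automatic step-size
   control) and the per-target-normalized absolute Jacobian yields fixed
   weights `q_i = Σ_l |S_il| / Σ_j |S_jl|` quantifying how informative each
   data coordinate is — data are weighted, not transformed, so no information
   is discarded.

For structurally non-identifiable parameters (e.g. a parameter entering the
model only through its square), regression targets are augmented with powers,
`λ(θ) = (θ¹, …, θᵏ)` ("P4" for k = 4), so that an identifiable transform can
be learned even when θ itself cannot.

The package ships a model zoo of benchmark problems — a four-parameter
demonstration problem with heterogeneous scales and an uninformative data
block, a non-identifiable quadratic toy, a conversion-reaction ODE, g-and-k
order statistics, and Lotka–Volterra Markov jump processes simulated exactly
with a numba-accelerated Gillespie algorithm — plus a workbench for method
configuration, results storage, and weighted-RMSE evaluation over replicates.

## Worked example

Infer the parameter of the quadratic toy model `y ~ N(θ², 0.1²)` with prior
θ ~ U[−1, 1] and observed value 0.7. The posterior is symmetric-bimodal with
modes at ±√0.7 ≈ ±0.84; its exact mean is 0 and its exact second moment is
0.692.

```python
import numpy as np
from abcsens import RunConfig, run

cfg = RunConfig(problem="quadratic", n_particles=1000, budget=20_000,
                scale_kind="mad", seed=1, max_generations=8)
res = run(cfg)
theta, w = res.posterior_sample
print("generations:", len(res.generations), "simulations:", res.total_simulations)
print("E[theta]   =", round(float(w @ theta[:, 0]), 4))
print("E[theta^2] =", round(float(w @ theta[:, 0] ** 2), 4))
```

prints

```
generations: 5 simulations: 20000
E[theta]   = 0.0207
E[theta^2] = 0.6921
```

i.e. the sampler spends its 20,000-simulation budget over four adaptive
generations (plus calibration), keeps both posterior modes (mean ≈ 0), and
recovers the conditioned observation through the second moment (≈ 0.69).

The same analysis from the shell, with a results store:

```sh
abcsens run --config examples/quadratic.yaml --outdir runs/quadratic
abcsens list-problems
abcsens list-methods
```

Method strings compose as in the benchmark study: `L1+Ada.+MAD` is the
scale-normalized adaptive L1 distance; `L1+Ada.+MAD+SensiLR+P4` adds linear-
regression sensitivity weights with targets (θ¹, …, θ⁴); `L1+StatLR` uses
linear-regression summary statistics under uniform weights; `+Init` trains
before the first generation instead of after 40% of the budget.

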