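# nonsteady

**Biomarker-based toxicant exposure estimation without steady-state
assumptions.**

Risk assessors routinely convert a blood or hair mercury concentration into
an intake rate by multiplying it by the steady-state ratio *b = kv/f*. Real
exposures, however, are intermittent — people eat fish on some days and not
others — and under intermittent exposure the steady-state conversion is
badly biased and imprecise for individual intake rates. `nonsteady`
implements a formal statistical alternative for epidemiologists and exposure
scientists: it models the biomarker as a discrete-time convolution of daily
intakes with one-compartment elimination weights, puts a zero-inflated gamma
distribution on the daily intakes, and estimates the intake-magnitude
parameters by alternating quasi-likelihood estimating equations.

## Model

For individual *i* measured on day *t*,

```
y_it = Σ_{j=1..t} W_ijt · I_ij + ε_it ,     W_ijt = (f/v) · e^{−k(t−j)}
```

where `I_ij` is the day-*j* intake (µg/d), `f` the absorbed fraction, `v`
the blood volume (L), `k` the elimination rate (1/d), and `ε` a measurement
error with known variance σε². Daily intakes are i.i.d. zero-inflated gamma:
zero with probability 1 − ω (ω, the exposure frequency, is measured, e.g. by
food-frequency questionnaire) and otherwise gamma with mean µ = e^β and
variance σg² = e^α. The estimating equations

```
D' V⁻¹ (Y − EY) = 0          (for β)
D*' V**⁻¹ (s − diag V) = 0   (for α,  s_i = (Y_i − EY_i)²)
```

are solved by alternating damped Fisher-scoring updates; model-based
variances `(D'V⁻¹D)⁻¹` and `(D*'V**⁻¹D*)⁻¹` give plug-in confidence
intervals on the log scale, exponentiated to µ and σg². Closed-form moments
use the geometric sums S1 = Σ e^{−k(t−j)} and S2 (with 2k), so no
explicit convolution is ever required. A steady-state comparator
(`b·y`, the frequency-corrected `b·y/ω`, and their closed-form bias and
standard error) is included, as is a Monte-Carlo harness reproducing the
estimator's bias/MSE/coverage behavior over a grid of frequencies and
sample sizes.

## Worked example

Simulate 64 individuals with exposure frequency ω = 0.5 under the default
methylmercury constants (f = 0.0475, v = 5 L, k = 0.014/d, t = 1000 d,
µ = 10, σg² = 5), then fit:

```bash
nonsteady simulate --n 64 --omega 0.5 --seed 11 --out obs.csv
nonsteady fit obs.csv --sigma-eps2 0.0009 --out fit.json
```

which prints

```
mu_hat = 10.0622  sigma_g2_hat = 15.2997  (converged in 4 iterations)
```

with `fit.json` recording the 95% intervals µ ∈ (9.83, 10.30) and
σg² ∈ (0.16, 1473). The mean intake magnitude is recovered tightly — the
interval spans ~±2% around the true value 10 µg/d — while the
intake-variance estimate is, as expected at this sample size, noisy with a
deliberately conservative interval (between-person biomarker spread carries
little information about day-to-day intake variance when each person is
measured once; see `docs/methods.md`). The same functionality is available
as a library:

```python
from nonsteady import SimulationScenario, simulate_dataset, fit, confidence_interval
data = simulate_dataset(SimulationScenario(n=64, omega=0.5, seed=11), 0)
result = fit(data)
print(result.mu_hat, result.sigma_g2_hat, confidence_interval(result)["mu"])
```

`nonsteady grid --out grid.csv` runs the full Monte-Carlo study grid
(ω ∈ {0.1,…,0.9} × n ∈ {2,…,1024}) and writes one tidy row of
bias/MSE/coverage/convergence summaries per cell.

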