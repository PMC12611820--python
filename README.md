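# entroflow

Entropy and expectation gradient flows on probability densities, with a
directed inter-regional time-series predictor and a full significance stack.

## The problem

Continuous neural recordings (e.g. ΔF/F two-photon calcium signals from
retinotopically defined visual areas) can be described by the probability
distributions of their amplitudes. How does the activity distribution of one
cortical region transform into that of another? `entroflow` models such
transformations as gradient flows on the manifold of smooth, positive,
unit-mass densities ("information space"), decomposed into two interpretable
basis components:

- the **entropic flow** v_S = log q − ⟨log q⟩, whose integral curves are
  power-law renormalizations q → q^λ / ∫ q^λ dx (it reshapes the *spread*
  of a density), and
- the **expectation flow** v_E = x − ⟨x⟩, whose integral curves are
  exponential tilts q → q e^{λx} / Z (it shifts the *mean*; a Gaussian's
  mean moves by λσ² with variance unchanged).

For a density symmetric about its mean the two fields are orthogonal
(Cov_q(log q, x) = 0), so they act as independent basis flows. The **mixed
flow**

    ∂ log q / ∂λ = α (log q − ⟨log q⟩) + β (x − ⟨x⟩)

weighs the two contributions; its coefficients (α, β) summarize how one
distribution is reweighted and tilted into another.

Applied to time series, the same operator gives a directed predictor from a
source region A to a target region B:

    x_B^est = x_A + α [log q_A(x_A) − ⟨log q_A⟩] + β [x_A − ⟨x_A⟩],

where q_A is the Gaussian-KDE density of the source (Silverman bandwidth).
(α, β) are fitted by minimizing the L2 prediction error; directionality is
real — A→B and B→A are independent fits. Significance of each directed R² is
assessed with circular-shift surrogates (1,000 random rotations of the
source, full refit each time), corrected across all ordered region pairs by
Benjamini–Hochberg FDR (q = 0.01) with a Bonferroni cross-check; hold-out
(80/20) and 20-fold randomized cross-validation quantify generalization.

## Worked example

Construct a target series from an autocorrelated source with known
coefficients, refit them, and test significance:

```python
import numpy as np
from entroflow import (FlowParams, FitConfig, generate_pair_from_flow,
                       fit_pair, holdout_validate, circular_permutation_test)

rng = np.random.default_rng(0)
x = np.empty(2000); x[0] = rng.normal()
eps = rng.normal(0, 1, 2000)
for i in range(1, 2000):
    x[i] = 0.8 * x[i-1] + eps[i]                    # AR(1) source

y = generate_pair_from_flow(x, FlowParams(alpha=0.02, beta=0.7),
                            noise_sd=0.1 * np.std(x), seed=1)

raw = FitConfig(standardize=False)
res = fit_pair(x, y, raw)
print(f"alpha = {res.alpha:.5f}, beta = {res.beta:.5f}, R2 = {res.r2:.4f}")
rep = holdout_validate(x, y, config=raw)
print(f"train R2 = {rep.train_r2[0]:.4f}, test R2 = {rep.test_r2[0]:.4f}")
perm = circular_permutation_test(x, y, n_perm=1000, seed=0, config=raw)
print(f"permutation p = {perm.p_value}, max surrogate R2 = {perm.surrogate_r2.max():.4f}")
```

Output:

```
alpha = 0.02335, beta = 0.70004, R2 = 0.9965
train R2 = 0.9960, test R2 = 0.9957
permutation p = 0.0, max surrogate R2 = 0.6350
```

The fit recovers the generating coefficients (α is noisier than β because
the log-density regressor has less leverage at 10% observation noise), the
held-out R² matches the training R² (no overfitting — the model has two free
parameters), and no circular-shift surrogate comes close to the empirical
R², so the directed coupling is significant at p < 0.001.

The same pipeline runs from the shell: `entroflow simulate`, `entroflow fit`,
`entroflow pairwise` (full directional matrix with permutation + FDR, written
as CSV matrices plus a JSON manifest), `entroflow recover` (benchmarks below).
Multi-region recordings are read from CSV (one column per region) or HDF5;
pixel × time stacks are reduced per region with `first_pc`.

## Benchmarks and the acceptance script

Two forward-generative experiments validate that (α, β) can be recovered
from data generated with known coefficients (α = 0.05, β = 0.5):

1. **Diffusing Gaussian** (density space): samples of N(0, 1 + 2·0.25·t) at
   t = 0 are KDE-smoothed, pushed through the mixed flow, and the
   coefficients refitted by density-space L2 minimization; recovered and
   ground-truth target densities are compared by squared 2-Wasserstein,
   total variation, and L2 metrics.
2. **Langevin with sinusoidal drift** (time domain): a source trajectory of
   dx = (sin(πt) − x) dt + 0.3 dW is mapped through the series predictor,
   5% observation noise is added, and the coefficients refitted by
   time-domain least squares.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the benchmark figures from scratch (20 seeds per experiment,
medians reported): relative recovery errors of α and β and the
total-variation distance for the density experiment (t1, t2, t3), and the
same three figures for the Langevin experiment (t5, t6, t7). Runtime is
about a minute on one CPU.
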