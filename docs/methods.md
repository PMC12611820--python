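# Methods

## Model

All computations take place on gridded 1-D densities: a `DensityGrid` is a
strictly positive function on a uniform grid (default 1,024 points spanning
mean ± 8 SD of the data that induced it) with unit trapezoidal mass. For
smooth, rapidly decaying densities on wide grids the trapezoid rule is
spectrally accurate (the Euler–Maclaurin boundary terms vanish), which is
why closed-form Gaussian identities hold to 1e-6 or better on these grids.
Densities are floored at 1e-300 before any logarithm; positivity is part of
the manifold definition and log q appears in every flow field.

Two functionals generate the flows. Entropy S[q] = −∫ q log q dx has
functional gradient 1 + log q; subtracting its q-mean projects it onto the
unit-mass manifold, giving the entropic field v_S = log q − ⟨log q⟩, whose
integral curves are power-law renormalizations q^λ/∫q^λ. Expectation
E[q] = ∫ x q dx analogously yields v_E = x − ⟨x⟩ with exponential tilts
q e^{λx}/Z as integral curves. Both fields have zero mean under q by
construction (∫ v q dx = 0), and Cov_q(log q, x) = 0 for any density
symmetric about its mean — the orthogonality that justifies treating the
two flows as an independent basis in the centered symmetric case.

**Sign convention.** The literature this implements introduces the field as
the gradient of *negative* entropy yet prints v_S = log q − ⟨log q⟩; the two
statements differ by a sign (δS/δq = −(1 + log q) for S = −∫ q log q). We
implement the printed field exactly. Consequently the forward (α > 0)
entropic direction *sharpens* a density: the β = 0 mixed flow solves to
q ∝ q0^{e^{αλ}}, i.e. a power-law map with exponent e^{αλ} > 1, and entropy
decreases. The ambiguity is a relabeling of the flow direction, not of the
family of reachable transformations; we record it rather than resolve it.

## Numerics

The mixed flow ∂ log q/∂λ = α v_S + β v_E is integrated by explicit Euler on
log q with renormalization after every step, so unit mass holds exactly along
the trajectory. Defaults: λ from 0 to 1 in 100 steps (Δλ = 0.01). Two exact
checks calibrate the integrator:

- β = 0 converges first-order in Δλ to `power_law_transform(q0, exp(αλ))`
  (the error halves when the step halves);
- α = 0 reproduces `exponential_tilt(q0, βλ)` to machine precision at *any*
  step count, because a log-space Euler step with renormalization is itself
  an exact tilt and tilts compose. The O(Δλ) bound quoted for this branch in
  desk references is therefore loose, and the step-refinement test is only
  informative on the entropic branch.

The power-law generator identity is checked by comparing q^{1+ε}/Z with the
linearized update q(1 + ε v_S): the gap is O(ε²) and quarters when ε halves.
Tilts that push more than 1% of the mass into a boundary grid cell raise a
warning (the finite support is truncating the tilted density).

KDE uses a Gaussian kernel with the robust Silverman bandwidth
0.9 min(SD, IQR/1.34) n^{−1/5}; the normal-optimal variant (4/(3n))^{1/5} SD
is available by configuration (`rule="normal"`). The robust form was chosen
for heavy-tailed ΔF/F-like amplitude distributions; the two differ only by a
constant factor. Log-densities are evaluated by a chunked log-sum-exp and
floored at log(1e-300), so they are never −∞.

Density metrics: squared 2-Wasserstein distance by inverse-CDF quadrature at
4,096 midpoint quantile levels (exact for 1-D transport up to
discretization; supports may differ), total variation ½∫|p − q| and
function-space L2 on a shared grid. "L2 error" is reported as the
function-space norm for densities and as RMSE for time series, labeled
distinctly, since the phrase is ambiguous between the two.

## Fitting

The time-series predictor x_B^est = x_A + α f_S + β f_E with
f_S = log q_A(x_A) − ⟨log q_A⟩ and f_E = x_A − ⟨x_A⟩ is *linear* in (α, β),
so the L2-optimal coefficients are obtained in closed form by least squares
(the exact minimizer of the stated objective); a Nelder-Mead + L-BFGS-B
polish route (`method="simplex"`, box |α|, |β| ≤ 10³, objective tolerance
1e-10, start at the identity (0, 0)) is provided and agrees with the exact
solution, with a monotone objective trace. ⟨log q_A⟩ is the sample mean of
the KDE log-density over the training samples (not a grid integral),
matching fitting on observed time points. Signals are z-scored with
training-segment statistics by default (`standardize=False` fits on the raw
scale, which is what the recovery benchmarks use — z-scoring rescales the
coefficients). Density-space fitting (recovery benchmark 1) minimizes the L2
distance between the flowed and target densities; this objective is
nonlinear in (α, β) and uses Nelder-Mead from (0, 0) with a restart polish.

Constant series are rejected at fit time; in batch (pairwise) mode a
constant region produces a logged skip record instead of an error.

## Validation and significance

Hold-out fits on the first 80% of both series and evaluates R² on the rest,
with the KDE, feature means, and z-scoring statistics all training-derived.
Randomized CV draws 20 contiguous circular 20% test blocks (respecting
temporal autocorrelation; a pointwise mode exists but is not the default)
and reports the mean ± SD train − test R² gap. Note an exactness subtlety:
a noiseless pair generated from the *full-series* KDE is not exactly inside
the model family refit on a training subset (the refit KDE differs
slightly), so "perfect generalization" holds to ~1e-4 rather than machine
precision unless the pair is generated from the training-segment density or
is the identity pair.

Circular-shift surrogates rotate the source series by a uniform offset in
[1, T−1] — per session, never across declared session boundaries — and refit
(α, β) completely. Because a circular shift leaves the source's sample set
(hence its KDE, z-scoring statistics, and per-sample feature values)
invariant, the implementation rotates the precomputed features with the
series and re-runs only the coefficient solve; this is algebraically
identical to a from-scratch refit. p = #{surrogate R² ≥ empirical}/n_perm
(the plain proportion); the conservative (k+1)/(n+1) variant is available.
Only the source is shifted (the transformation's input); shifting the
target instead would be an equivalent choice under the null.

BH-FDR (q = 0.01) is applied jointly across all off-diagonal ordered pairs,
pooled over every recording passed in one invocation, with a Bonferroni mask
as cross-check; Bonferroni rejections are always a subset of BH rejections
at the same level.

## Synthetic benchmarks

The generators state a fixed world; none of their parameters were tuned to
test outcomes. Diffusing Gaussian: initial N(0, 1), D = 0.25, t1 = 0,
t2 = 1 (variance σ² + 2Dt), n = 20,000 samples. Langevin: γ = 1, drift
a sin(ωt) with a = 1 and ω = 2π·0.5, σ = 0.3, dt = 0.01 (Euler–Maruyama,
stable for γ dt < 1), duration 50 → 5,000 samples. True flow coefficients
α = 0.05, β = 0.5 for both experiments (the source reference states them
only for the density test; the series test reuses the same pair).
Observation noise in the series test: SD = 5% of the noiseless target SD.

The density experiment fits flow(KDE(samples), α, β) to the flow of the same
KDE estimate under the true coefficients, and reports metrics against the
flow of the *analytic* source law — so parameter errors reflect optimizer
accuracy (near zero) while the density metrics reflect KDE estimation error
and shrink as n grows. `exact=True` substitutes the analytic law for the
KDE, the exact-arithmetic limit in which every figure is ~0. The series
experiment is identifiable: least squares on 5,000 points with 5% noise
recovers both coefficients to well under 1%.

What a green benchmark does and does not establish: the generators produce
smooth unimodal marginals, strong autocorrelation, and targets exactly
constructible by the predictor — they validate recovery machinery, not the
model's adequacy for real cortical data, which may violate the
centered-symmetry assumption behind flow orthogonality and contains shared
noise the pairwise model does not represent.

## Limitations

- Densities are 1-D; the general n-dimensional formulation is out of scope.
- Only entropy and expectation functionals are implemented (the generalized
  projected-gradient machinery is an extension hook).
- No lag/delay optimization in the pairwise predictor; zero-lag mapping only.
- Permutation p-values have resolution 1/n_perm; with the default plain
  proportion estimator p = 0 is reportable and should be read as p < 1/n_perm.
- The pixel-stack path drops NaN pixel rows before PCA and performs no
  motion correction, ΔF/F computation, or retinotopic parcellation — those
  are upstream preprocessing.
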