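# Methods

This note records the statistical model, the numerical conventions and the
design decisions behind `penregsim`, at the level of detail a maintainer or
reviewer needs to interpret its output.

## Generative model

Each simulated dataset draws predictor rows `x_i ~ N(0, Σ)` with unit
variances (so Σ is a correlation matrix) and a response

    y_i = β₀ + x_iᵀ β + ε_i,   ε_i ~ N(0, σ²),

with β₀ = 1.45 in all built-in scenarios. Predictor marginals are standard
normal by construction: the motivating clinical variables are analysed
after log/sqrt transforms, so the generator works on the transformed scale
directly and does not model skewed raw concentrations. Both X and y are
regenerated for every Monte-Carlo replicate (random-X design); the
distribution of cross-validated tuning parameters across replicates is only
meaningful under this choice.

## Correlation calibration

The scenarios are specified by *variance inflation factor* targets rather
than by an explicit Σ. `VIF_j = 1/(1 − R²_j)` equals the j-th diagonal
entry of Σ⁻¹; calibration searches a structured family of
positive-definite correlation matrices for one whose VIF vector matches the
targets:

* **banded-serial** (scenarios B/C, a glucose curve over nine time points):
  a non-stationary first-order Markov chain, `corr(i, j) = Π r_l` over the
  neighbour correlations between i and j. PD for |r_l| < 1. Its precision
  matrix is tridiagonal, giving the chain identity
  `VIF_j = 1/(1−r_{j−1}²) + 1/(1−r_j²) − 1` used as the analytic starting
  point. Eight free parameters face nine targets, so the system is
  overdetermined; trust-region least squares reaches max |achieved −
  target| ≈ 0.03 against the targets (3.06, 3.94, 4.99, 6.57, 7.61, 7.06,
  4.36, 4.51, 2.76), well inside the 0.5 calibration tolerance.
* **grouped-block** (scenario A, a panel of assays with fasting/post-load/
  AUC summaries per analyte): a two-level factor model
  `corr(i, j) = a_i a_j + 1{same group} c_i c_j` with per-variable shared
  and group loadings, parameterized in polar form (total loading u ≤
  √0.995 and a mixing angle) so unique variance stays positive and the
  matrix is PD by construction. With two parameters per variable the 19
  targets (range 1.4–33.3) are met essentially exactly. Variables with
  target VIF exactly 1 are held orthogonal (zero row/column).

Calibration is deterministic: an analytic initial guess, then
`scipy.optimize.least_squares`, with seeded random restarts only on
failure. An `explicit` escape hatch accepts a user matrix and verifies its
VIFs. Because the original study's correlation matrices are published only
as a heatmap, quantities that depend on the full Σ (prediction RMSE
magnitudes, tuning-parameter magnitudes, per-variable wrong-sign rates) are
reproduced *qualitatively* — same orderings and same scale — rather than
digit-for-digit; quantities forced structurally (ridge/OLS never excluding
a variable, VIF of an orthogonal system) are exact.

## Penalized estimation

The objective is the *unscaled* residual sum of squares plus separate
penalty weights,

    Σ_i (y_i − β₀ − x_iᵀβ)² + λ₁ Σ_j |β_j| + λ₂ Σ_j β_j²,

with the intercept unpenalized. There is no 1/n or ½ factor; tuning
parameter magnitudes (e.g. the medians reported by the study runner) are
only comparable under this convention. The equivalent mixed form uses
λ = λ₁ + λ₂ and mixing weight α = λ₂/(λ₁+λ₂); the constraint-form
parameters (s, t) are in 1:1 correspondence with λ₂ and λ₁ and are not
separately implemented.

Predictors are centered and scaled to unit SD before fitting (penalties
then weigh all variables equally); the response is centered only, which
solves the unpenalized intercept exactly. Coefficients are reported on the
original scale.

* λ₁ = 0 (ridge/OLS): closed-form solve of `(XᵀX + λ₂I)β = Xᵀy` on the
  standardized data; inside cross-validation an eigendecomposition of each
  fold's Gram matrix is reused across all λ₂ values.
* λ₁ > 0: cyclic coordinate descent with soft-thresholding on the Gram
  form, `β_j ← S(c_j − Σ_{l≠j} G_{jl} β_l, λ₁/2) / (G_{jj} + λ₂)`.
  Convergence when the largest absolute coefficient change in a sweep
  drops below 1e-8; sweep cap 1e5 (exceeding it raises a convergence
  error). The inner loop is numba-compiled. The objective is convex, so
  the fixed point is the global minimum; coefficients are exactly zero
  where thresholding truncates, and "selected" means exactly nonzero (no
  epsilon).

Correctness anchors (all in the test suite): closed-form ridge to 1e-8,
the orthonormal-design soft-threshold solution, and scikit-learn's
`ElasticNet` configured to the same objective (α = λ₁/2n + λ₂/n,
l1_ratio = (λ₁/2n)/α) to 1e-6.

## Stepwise selection

`AIC = n·ln(RSS/n) + 2·k_params` and `BIC = n·ln(RSS/n) + k_params·ln(n)`,
where `k_params` counts slopes plus intercept (additive constants cancel in
comparisons). The search starts from the full OLS model and greedily
applies the best single drop, or re-entry of a previously dropped variable,
until no move lowers the criterion; ties break toward the lowest variable
index and the intercept is never a candidate. Greedy-best with re-entry is
the common production behaviour of stepwise-backward implementations; pure
backward elimination is available via `allow_reentry=False`. Subset RSS
values come from the centered Gram matrix, so a step costs O(k³) rather
than a fresh regression per candidate.

For a single predictor the procedure reduces to one likelihood-ratio
comparison: the variable is kept iff `n·ln(RSS₀/RSS₁) > penalty`,
asymptotically `P(χ²₁ > 2) = 0.157` for AIC and `P(χ²₁ > ln n)` for BIC —
both verified by simulation in the suite. BIC's per-parameter penalty
exceeds AIC's once ln(n) > 2, i.e. from n = 8.

## Cross-validation tuning

`kfold_cv_error` partitions indices by a seeded shuffle into K near-equal
folds and returns the per-observation mean squared prediction error (total
held-out squared error divided by n), so K = n reproduces classic
leave-one-out. Folds must be nonempty and each training complement must
retain at least two observations. K = 10 throughout the study runner; fold
assignment is re-randomized per replicate from the replicate's derived
seed, and all strategies within one replicate share the same folds.

One-dimensional searches evaluate zero plus a 25-point log-spaced grid on
[1e-3, 1e3] (the observed optima sit one to two decades inside these
bounds) and refine around an interior grid minimum by golden section to a
relative tolerance of 1% on λ. The joint Enet 3 search evaluates a 15×15
log grid plus both axes and (0,0), then refines an interior minimum by
Nelder-Mead in log-coordinates; every evaluated point is recorded and the
chosen penalty is the arg-min over the evaluated set. The reported CV error
is recomputed cold-start at the chosen penalty, so it is bit-identical to
an independent `kfold_cv_error` call with the same folds (warm-started
search evaluations can differ at the coordinate-descent tolerance,
~1e-9).

Sequential strategies inherit their structure from this machinery: Enet 1's
first stage is exactly the LASSO search (identical folds give identical
λ₁); its second stage includes λ₂ = 0 and therefore never worsens the CV
error; symmetrically for Enet 2.

## Metrics

Per method × variable, over m replicates: bias = mean(β̂_j) − β_j and
RMSE include non-selected (zero) estimates; the wrong-sign percentage
counts nonzero estimates opposing the sign of a nonzero true coefficient,
as a share of all m replicates, so wrong-sign + correct-sign + excluded
shares total 100%. For true-zero variables wrong-sign is undefined and the
selection probability is the type-1 error. Model complexity is the mean
nonzero count, with a separate mean over the designated nuisance
variables. Prediction RMSE is the root of the mean per-replicate MSE on an
*independent* evaluation set of 1000 fresh draws per replicate (the
training-sample MSE is recorded alongside for transparency; the convention
is stated in the run metadata).

## Determinism and problem sizes

Replicate seeds derive from `SeedSequence(master_seed, spawn_key=(cell,
n, replicate))`, so any replicate reproduces in isolation, parallel or
reordered aggregation cannot change results, and two runs with one master
seed are bit-identical. All derived seeds stay below 2³¹.

Shipped configurations default to m = 500 replicates — the package's
desk-scale choice, sufficient for the qualitative orderings the suite
asserts (Monte-Carlo SE of a selection share at m = 500 is ≈ 2 points) —
with the original-scale m = 5000 available in `configs/full_study.yaml`.
The structural checks (ridge/OLS never excluding) hold at any m and use
m = 50; the large-sample recovery check uses n = 5000 with m = 500.

## Known limitations

* The calibrated Σ matrices match the published VIFs, not the unpublished
  full correlation structure; Σ-dependent magnitudes are qualitative
  reproductions (see "Correlation calibration").
* The generator does not emulate non-normal marginals, measurement error,
  missing data, or the fixed-X design of a single observed cohort, so
  passing tests demonstrate method behaviour under the idealized
  generative model, not performance guarantees on real cohorts.
* Cross-validated ridge is *not* an unbiased recovery device even at
  n = 5000: CV keeps λ₂/n ≈ 0.1, leaving a shrinkage bias of several
  percent of |β| on the boundary time points, which exceeds Monte-Carlo
  noise at m = 500. The suite's large-sample recovery check documents this
  deliberately (OLS passes; ridge fails by design of ridge, not by defect
  of the solver).
* Stepwise selection is greedy; on adversarial instances its criterion
  value can exceed the all-subsets optimum (the suite checks it never
  *beats* the exhaustive oracle and coincides with it on strong-signal
  designs).
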