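# Methods

## Model

`threetrees` fits the additive mixed-effects model

    Y_ij = X_ij' β + Z_j' γ + Σ_{t=1..3} T_t(h_t) + u_j + ε_ij,

where `h_1 = X_ij` (level-1 covariates), `h_2 = Z_j` (cluster-constant
level-2 covariates), `h_3 = (X_ij, Z_j)`, `u_j ~ N(0, σ_u²)` iid across
clusters, `ε_ij ~ N(0, σ_ε²)` iid, independent of each other. Each `T_t`
is a binary regression tree; equivalently a sum of region indicators
`Σ_m μ_tm · 1{h ∈ R_tm}` over the tree's terminal partition. Assumptions:
two-level nesting only, Gaussian response, random intercepts only (no
random slopes, no crossed effects), no missing data.

## Mixed-model estimation

The random-intercept structure admits one-dimensional profiling. With
`θ = σ_u²/σ_ε²`, the marginal covariance is `σ_ε²(I + θ Z Z')` whose
inverse acts per cluster in closed form (`(I + θJ)⁻¹ = I − θ/(1+n_jθ)·J`).
Fixed effects are profiled out by GLS and `σ_ε²` by its closed form,
leaving a scalar (restricted) likelihood in `log θ`, maximised by bounded
scalar search on `log θ ∈ [−12, 12]` (tolerance 1e-9). A candidate at the
lower bound, or beaten by `θ = 0`, is reported as `σ_u² = 0` with a
warning. Cluster intercepts are BLUPs — shrunken cluster-mean residuals
`u_j = n_jθ/(1 + n_jθ) · ē_j`. Standard errors come from the GLS
information matrix; p-values use the normal approximation (no
degrees-of-freedom correction). REML is the default (ML available); the
implementation matches the balanced one-way ANOVA closed form to ~1e-8 and
an independent mixed-model implementation to ~1e-4.

Rank-deficient fixed-effect designs are rejected up front with the names
of the collinear columns — the characteristic failure mode when
cluster-constant tree regions duplicate each other.

## Tree engines

All engines share one tree structure (binary splits `x ≤ s`, 0/1
covariates split at 0.5) and one gain definition: node risk
`R(t) = Σ_t (y − ȳ_t)²/N` normalised by the *total* sample size N, so
risks are additive and the split gain is `R(t) − R(t_L) − R(t_R)`.
Defaults used throughout the simulation protocol: `maxdepth = 3`,
`nmin = 10` (minimum rows per node).

**CART.** Exhaustive scan over midpoints of consecutive distinct values;
ties break to the lowest variable index, then the lowest threshold. A
split is kept only if its gain is at least `cp` times the root risk
(`cp = 0` accepts any positive gain). Cost-complexity pruning
(`R(T) + α|T|`) is solved exactly by a bottom-up collapse/keep dynamic
program; ties prefer the collapsed tree, which makes the pruned sequence
nested in α. Pruning is exposed but not used inside the 3Trees pipeline,
which relies on the cp gate (mirroring the tuning the simulation protocol
prescribes).

**CTree.** At each node every candidate covariate is tested for
association with the node target by the two-sided t-test of the
simple-regression slope; p-values are Bonferroni-adjusted for the number
of candidates at the node. The node splits only if the minimum adjusted
p-value is below `alpha` (default 0.05), and then on that variable, with
the split point chosen by the shared gain criterion restricted to it.
Design choice: the richer permutation-statistic framework of the original
conditional-inference literature is deliberately not used — the package
realises the plain partial-test-plus-Bonferroni procedure. A consequence
worth knowing: inside backfitting, residual structure that is *linearly*
uncorrelated with every covariate (a centred step in X after its linear
projection is removed, or X² terms) is invisible to the slope test, so
the ctree engine can leave all trees at the root on strongly nonlinear
data and the fit degenerates to the plain mixed model.

**EvTree.** A population (default 100) of random depth-1 trees is evolved:
each iteration every member spawns an offspring through one of five
operators (grow a random leaf, prune a random internal node, redraw a
random split rule, move a threshold to an adjacent candidate, or exchange
subtrees between two parents — equal probabilities), offspring violating
depth/size limits are repaired by pruning, and an offspring replaces its
parent only with strictly lower loss. The loss is BIC-flavoured:
`n·log(max(MSE, 1e-10)) + λ·M_t·log(n)` with `λ = 2`. Stopping: 2000
iterations or 100 without improvement of the best loss. All randomness
flows from one generator seeded per call. Replicated studies use a
reduced budget (population 20, 120 iterations, stagnation 25, exposed as
`evaluate.STUDY_EVOLUTION`); spot checks against the full budget moved the
M2 clusMSE cell by well under its Monte-Carlo error, and on small XOR
instances the reduced search still attains the exhaustively enumerated
optimal depth-2 loss in ≥95% of seeded runs.

## Backfitting selection and joint estimation

Selection initialises all tree contributions to zero and iterates:

1. REML fit of `[1 | X | Z]` on the response minus the current tree
   contributions; compute the linear prediction and BLUPs.
2. For T1, T2, T3 in order: refit the tree on the partial residual
   excluding it; centre its fitted contribution (the mean is re-absorbed
   by the next intercept fit). A refit is **kept only if it lowers the
   combined training MSE**; an iteration that ends no better than the
   previous recorded state is reverted and the loop stops. This guard is
   a deliberate design choice: unguarded refits of greedy trees churn on
   noise and make the MSE trajectory wobble at the 1e-3 level, defeating
   the relative-MSE convergence rule; with the guard the trajectory is
   non-increasing and the loop typically converges in 3–6 iterations.
3. Stop when the relative MSE change falls below `mse_tolerance`
   (default 1e-4) or after `max_backfit_iterations` (default 50).

T2 is fitted on all rows (using only the cluster-constant columns), not on
one row per cluster, so every tree sees the same row weighting. Variance
components are re-estimated at every iteration (a full mixed fit). Trees
are refit from scratch each iteration, not warm-started.

Estimation then builds `[1 | X | Z | D1 | D2 | D3]`, where `D_t`
reference-codes tree t's terminal regions (first region dropped), removes
exactly collinear columns by a greedy left-to-right rank scan (recorded in
`dropped_columns`), and refits jointly by REML. Predictions add the
tree-region coefficients via the same encoding; unseen clusters get a
zero BLUP.

## Synthetic-data generator

The generator emulates the two-level designs of the simulation protocol:
balanced J clusters × n_j rows (standard design 70 × 50 = 3500 rows; size
grid 750 (50×15), 1500 (50×30), 3500 (70×50), 5000 (100×50),
10000 (200×50)). Covariates: X1–X3 equicorrelated normal per row and
Z1–Z2 correlated normal per cluster, with ρ ∈ {0.8, 0.2}; X4 and Z3
Bernoulli(0.5) at their respective levels. Noise:
(σ_u², σ_ε²) ∈ {(3, 1), (0.3, 0.5)} giving ICC 0.75 / 0.375. Scenarios:

* M1 — linear: β = (5,2,0,3,1), γ = (3,0,1);
* M2 — semilinear: γ = (2,0,1) plus 3·1{X1>0} + 2·Z3 − 2·1{X1>0}·Z3;
* M3 — nonlinear: β = (5,2,0,2,2), γ = (3,0,2) plus 2·X1² + 1·Z2·ln|X3|
  (|X3| clamped at 1e-12 against the probability-zero event X3 = 0).

β2 = γ2 = 0 in every scenario, so irrelevant predictors are present by
construction. Per-replication seeds derive from a master seed and the
replication index through a seed sequence, so any single replication can
be regenerated in isolation.

What the generator does *not* emulate: unbalanced clusters, heavy-tailed
or heteroscedastic noise, measurement error in covariates, informative
cluster sizes, more than two levels. Passing tests therefore demonstrate
correctness of the estimators under the stated Gaussian random-intercept
conditions, not robustness to real-data violations of them.

## Evaluation protocol

Each replication generates a dataset, splits every cluster's rows 50/50
(each cluster contributes at least one row to both halves, so test-set
predictions can reuse the estimated intercepts), fits each method on the
training half and computes four criteria: MSE / PMSE (fixed part only,
train / test) and clusMSE / clusPMSE (adding BLUPs). Each criterion
divides by its own set's row count. Summaries report "mean (SD)" at three
decimals; raw per-replication arrays are always retained so no check
depends on rounding. Replicated cells in tests and the acceptance script
use 30 replications for LMM and CART cells and 10 for EvTree cells — sizes
chosen to put the Monte-Carlo standard error of every compared cell well
below its comparison tolerance.

## Numerical choices and degenerate inputs

* Split ties: lowest variable index, then lowest threshold (deterministic).
* Constant covariate at a node: association statistic 0, p = 1, never
  selected; no admissible split in CART.
* Constant target: no positive gain, node becomes terminal.
* MSE floor 1e-10 inside the evolutionary loss (perfect fits).
* Exact-collinearity drop tolerance: residual norm < 1e-8 of column norm.
* `maxdepth = 0` is legal everywhere and yields a global-mean tree.

## Known limitations

* Gaussian responses and random intercepts only.
* The ctree engine's slope test is blind to linearly-uncorrelated
  nonlinearity (see above); it shines on data that are linear or nearly
  so, and as an honest stopping rule on noise.
* The evolutionary engine is the slowest by two orders of magnitude; the
  backfitting loop multiplies its cost by three trees × iterations.
* No parallelism; replicated studies are embarrassingly parallel but run
  serially.
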