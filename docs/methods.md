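# Methods

`panelnet` implements a longitudinal symptom-network analysis for panel data
with nine symptom domains (depression DEP, somatic and subjective anxiety
SOM/ANX, sleep quantity/quality SQQ, daytime insomnia symptoms DIS, passive
and active sleepiness Pas/AcS, suicidal ideation and tendency SuI/SuT),
measured at up to three waves with four baseline covariates (age, gender,
education, illness duration).  This note records the models, the defaults
and why, the numerical conventions, and what the synthetic-data tests do and
do not demonstrate.

## Synthetic cohort generator

The generator provides ground truth for every estimator in the package.

* **Contemporaneous structure.** The residual precision matrix starts from
  the identity; each requested partial correlation ρ_ij is inserted as −ρ_ij
  off-diagonal.  If the smallest eigenvalue drops below 0.05, a minimal
  diagonal ridge restores it (slightly shrinking the implied partials, which
  are recomputed and exposed via `GroundTruth.implied_partials`); a request
  with a non-positive eigenvalue is rejected outright.  With unit diagonal
  and no ridge, implied partials equal the requested values exactly.
* **Dynamics.** Scores follow a VAR(1): `y_t = Bᵀ y_{t−1} + Cᵀ x + ε_t`,
  with the autoregressive effects on B's diagonal, cross-lagged effects off
  it, covariate effects C (zero by default), and residual precision
  `noise_scale × K`.  B must have spectral radius < 1.  Wave 0 is drawn from
  N(0, K⁻¹) by default; with `stationary_init=True` it is drawn from the
  VAR's stationary covariance (discrete Lyapunov solution), which makes the
  marginal — hence cross-sectional network — structure identical across
  waves.  The stationary start is used whenever the study conditions call
  for cross-wave invariance.
* **Attrition.** Dropout at each follow-up is Bernoulli with logit
  `a_t + b_t · DEP_0`; once dropped, a participant stays missing (monotone).
  Defaults a = (−0.88, −0.43), b = (0.3, 0.3) reproduce roughly 650 → 460 →
  280 completers from n0 = 650 with completers less severe at baseline —
  missing-at-random given the observed baseline.  The dropout uniforms come
  from a dedicated substream so attrition parameters can be varied against a
  fixed randomness stream.  Note a subtlety verified by simulation: a
  steeper severity slope reduces *first*-follow-up completers in
  expectation, but can *increase* second-follow-up completers, because
  severity-selective dropout at T1 leaves a low-severity pool with higher T2
  retention (the two survival events are positively correlated).
* **Covariates.** age ~ U[15, 24] (the cohort's inclusion range), gender ~
  Bernoulli(0.5), education uniform on {1..4}, duration ~ Exponential(mean
  2.2 years).  Scores are continuous normals, not integer scale totals: the
  analysis mean-centres totals and treats them as continuous, so
  discretization would only add a layer the estimators ignore.
* **Default truth** (`default_ground_truth`): nine contemporaneous edges
  with |ρ| in 0.15–0.40, strongest for SuI–SuT, SOM–ANX and Pas–AcS; lagged
  paths AcS→SOM 0.40, AcS→DEP 0.35, SuI→SuT 0.40 over an autoregressive
  diagonal of 0.3.  These are the study conditions for all recovery and
  stability simulations.

What the generator does **not** emulate: item-level questionnaire structure,
floor/ceiling effects and skew of real scale totals, non-monotone
missingness, time-varying covariates, or treatment effects.  Passing tests
therefore demonstrate correctness of the estimators under a well-specified
Gaussian VAR world, not robustness to the full messiness of clinical data.

## Cross-sectional networks (EBIC-glasso)

Per wave: listwise-complete cases (≥ max(10, p+1) required), mean-centring
of each domain within the wave, Pearson correlations, then the graphical
lasso maximizing `log det K − tr(SK) − λ Σ_{i≠j}|K_ij|`.  The solver is the
classic block coordinate-descent ("glasso") algorithm with unpenalized
diagonal, written in-package and numba-compiled: the permutation and
case-dropping procedures below need on the order of 10⁵–10⁶ small solves,
and the λ = 0 limit doubles as an exact inversion oracle in the tests
(partials match direct inversion to 1e−6; sklearn's implementation is kept
as an independent cross-check).  Convergence is declared on the duality gap
(default tol 1e−4, 200 sweeps; non-convergence raises, carrying the gap).

λ is selected by the Extended BIC, `−2L + E log n + 4γE log p` with
`L = (n/2)(log det K − tr(SK))` and E the retained edge count, over a
100-point logarithmic grid from λ_max = max off-diagonal |S| down to
λ_max/100; γ = 0.5.  These are the established defaults of the EBIC-glasso
method; ties favour the sparser model.  Edges are reported as partial
correlations `w_ij = −K_ij/√(K_ii K_jj)`.  The display filter |w| > 0.1
applies only to exported "display" edge lists, never to analysis matrices.

## Centrality

Strength `Σ_j |w_ij|`, expected influence `Σ_j w_ij`, closeness
`1/Σ_{j≠i} d(i,j)` and betweenness `Σ_{s<t} σ_st(i)/σ_st`, with shortest
paths computed over edge lengths 1/|w| (negative edges enter by absolute
value) by Dijkstra with exact path counting.  Conventions the definitions
leave open, fixed here and covered by tests:

* closeness uses 1/Σd rather than (N−1)/Σd — the two differ by a constant
  factor, so rankings and z-scores (what is actually compared) are
  identical;
* a node with any unreachable partner has closeness 0; pairs with σ_st = 0
  contribute 0 to betweenness;
* path-length ties are detected with relative tolerance 1e−10, so σ counting
  is deterministic under floating point;
* z-scores use denominator N−1; constant columns map to all-zero z.

Closeness and betweenness are validated exactly against exhaustive
simple-path enumeration on networks of up to 7 nodes.

## Network invariance tests

Two permutation statistics comparing waves A and B: structure
`M = max_ij |w^A_ij − w^B_ij|` and global strength
`S = |Σ|w^A| − Σ|w^B||` (sums over the upper triangle).  Participants are
pooled, reassigned to groups of the original sizes, and both networks
re-estimated per permutation with the same γ; p-values use the add-one
estimator `(1 + #{perm ≥ obs})/(1 + n_perm)` (resolution 1/(n_perm+1), never
exactly 0).  Default 1,000 permutations in production, 100 at test scale.
The three pairwise wave comparisons are Bonferroni-adjusted with m = 3.

Two deliberate conventions: (1) the pooled rows are sorted into a canonical
order before the permutation stream is drawn, and the split is taken at the
smaller group size, which makes swapping the group labels leave the
p-values *exactly* unchanged; (2) waves are permuted as independent groups
even though participants overlap across waves — the standard usage of this
test on panel data; the report carries the caveat, and type-I calibration is
verified by simulation on genuinely independent groups (rejection rate at
α = 0.05 within the binomial band around nominal over 200 replicates).

## Cross-lagged panel networks

For each outcome symptom at wave t, a lasso regression on all nine symptoms
at t−1 (wave-centred) plus the four covariates.  Covariates are
penalty-free — adjustment is unconditional — implemented by exact
partialling-out: when only the symptom block is penalized, the joint
solution equals the lasso of covariate-residualized y on
covariate-residualized standardized predictors (Frisch–Waugh extends to the
lasso in this configuration), after which covariate coefficients are
recovered by least squares.  Symptom predictors are standardized internally
for the penalty; coefficients are returned on the centred-score scale.

The penalty is chosen per outcome by 10-fold cross-validation with the
Gaussian deviance (held-out MSE): `cv_se` is the standard deviation of
per-fold deviances over √n_folds, and λ.1se is the largest grid value whose
mean deviance is within one standard error of the minimum.  The λ grid has
100 log-spaced points from the smallest all-zero λ down to ratio 0.001.
Folds are drawn from seeds derived from the master seed and the outcome
index, keyed to the sorted participant ordering, so the fitted matrix is
invariant to input row order and bit-reproducible.  Complete cases are
taken per wave-pair (not per outcome), keeping the nine regressions on one
common sample.  A fold whose training outcome is constant triggers a logged
reshuffle.  No significance filtering is applied at estimation: the network
is the λ.1se coefficient matrix; bootstrap CIs qualify edges afterwards.

Directed centrality: in-EI_i `= Σ_{j≠i} A_ji`, out-EI_i `= Σ_{j≠i} A_ij`
(diagonal excluded, k = 8 other nodes), z-scored across the nine nodes.

Under the default truth at n = 500, the three largest cross-lagged
coefficients identify exactly the three true ordered paths in ≥ 90% of
seeds.  Lasso shrinkage biases the recovered magnitudes toward zero, so
coefficient values are interpreted as ranked evidence, not unbiased effects.

## Bootstrap accuracy and stability

Nonparametric n-out-of-n bootstrap (default B = 1,000 in production, 20–200
at test scale) with percentile — not BCa — intervals, matching the
convention of the standard validation tooling and keeping every quantile
directly checkable.  Difference tests declare a pair distinct when the
percentile CI of the replicate-wise difference excludes zero.  Failed
replicates are dropped and counted; more than 5% failures raises a warning
in the report.

Case-dropping stability: for each drop proportion p in {0.05, …, 0.75}
(100 subsamples each in production, 50 in tests), subsamples of
round((1−p)·n) cases are re-estimated and each index vector is
Pearson-correlated with its full-sample counterpart (identical vectors —
including constant ones — count as correlation 1).  The CS coefficient is
the largest *tested* proportion with P(r ≥ 0.70) ≥ 0.95 — reported with its
grid, never interpolated — with interpretation bands > 0.50 excellent,
0.25–0.50 moderate, < 0.25 insufficient.  The stored subsample correlations
are retained so the coefficient can be re-derived from the report.

## Multiple-imputation sensitivity

Chained equations with predictive mean matching (each incomplete symptom
column regressed on all other columns of the wide all-waves layout; donor
pool 5; 10 iterations; statsmodels' MICE machinery), m = 20 independent
chains from derived seeds.  Observed cells are preserved bit-exactly; a
column more than 80% missing is refused; covariates must be complete.
Completed datasets are re-analysed in full and edge/coefficient matrices
pooled by their entrywise mean (the Rubin's-rules point estimate; variance
pooling is out of scope).  Pooled centralities are recomputed from the
pooled matrices.  For the cross-sectional networks a stacked-data mode
(`pooled_ggm(..., mode="stacked")`) is available as well: it averages the m
correlation matrices and runs a single EBIC fit at the original n, which
keeps the pooled network exactly sparse.  Agreement with the complete-case analysis is summarized
by Spearman correlations over nodes (centralities), upper-triangle edges
(GGM) and all 81 directed entries (CLPN); a constant vector yields
"not applicable" rather than a number.

A known property of mean-pooling, documented rather than hidden: averaging
across imputations turns the exact zeros of sparse fits into tiny nonzero
values.  Pooled networks therefore track a full-data estimate well in
Frobenius distance, while *rank*-based agreement over all edges can favour
a complete-case estimate, whose exact-zero ties coincide with the
full-data fit's.  Rank comparisons are most meaningful over edges that are
nonzero in at least one of the compared networks.

## Pipeline, determinism and problem sizes

`run_full_pipeline` executes all stages, isolates failures per stage, and
stamps every artifact with the config hash and master seed; per-stage seeds
derive from the master seed, so reruns are byte-identical apart from
wall-clock timers in the manifest.  The acceptance script runs the full
sequence on the default n0 = 650 cohort (stationary start) with B = 100
bootstrap replicates, 200 permutations, 50 subsamples per drop level on a
5-level grid, and m = 20 imputations — sizes chosen so the whole analysis
completes on a laptop-class single core while leaving every Monte Carlo
summary stable to the precision reported.

## Known limitations

Pearson (not polychoric) input moments; no FIML or Ising/mixed models; no
graphical-VAR or multilevel extensions; independent-group permutation for
overlapping waves; point-estimate (not variance) pooling under imputation;
continuous synthetic scores.  These are documented scope boundaries, not
configuration options.
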