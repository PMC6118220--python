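# Methods

`profilenet` implements a three-stage analysis of multi-wave cohort data on
cognitive, social and emotional functioning, together with a synthetic
cohort generator that makes every stage testable against known ground
truth. This note documents the statistical model behind each stage, the
tunable parameters and their defaults, the numerical choices, and what the
synthetic benchmark does and does not establish about real data.

## Data model

The unit of analysis is a complete-case cohort: every participant measured
at two waves (T1, T2) on 24 variables spanning three domains — cognitive
(13 variables: three task-derived ratios, the cold Columbia Card Task, the
seven BRIEF executive-function scales, two SDQ problem scales), social
(7: four social-support scales, resistance to peer influence, two SDQ
scales) and emotional (4: need for arousal, hot Columbia Card Task, SDQ
emotional symptoms, BRIEF emotional control). Group membership (on-track
vs. delayed school progression) is constant within participant. Validation
rejects, rather than imputes, any missingness, duplicate participant×wave
rows, or group switches; higher-is-worse instruments keep their native
direction throughout (no sign flipping), so "problem" factors read as
problems in every output.

## Covariate adjustment

Each variable is regressed on age and IQ (OLS with intercept) separately
per wave, pooled over both groups, and replaced by its residuals.
Pooled fitting is the default because the downstream penalty selection is
also pooled; per-group residualization is available via `by_group=True`.
Residual columns are exactly mean-zero and orthogonal to both covariates
(checked to 1e-8 in tests). Z-scoring uses the n−1 sample standard
deviation. Both the network and the community analyses consume
residualized-then-standardized matrices by default; the ANOVA offers a
raw (`adjust=False`) mode.

## Network stage

The conditional-independence structure of the 24 residualized variables is
estimated per group and wave as a Gaussian graphical model: the graphical
lasso maximizes `log det Θ − tr(SΘ) − λ Σ_{i≠j}|Θ_ij|` (diagonal
unpenalized; solved by scikit-learn's coordinate descent, with the exact
inverse used at λ = 0). Edge weights are partial correlations
`ρ_ij = −Θ_ij/√(Θ_ii Θ_jj)`.

The penalty λ is selected by minimizing the extended BIC,
`−2·loglik + E·log n + 4γ·E·log p`, over a descending log-spaced grid of
100 values from λ_max (the largest off-diagonal |S|, above which the graph
is empty) down to 0.01·λ_max. Defaults: γ = 0.5 (the conventional
conservative choice; 0 reduces to BIC), ties broken toward the sparser
model. Selection runs on the pooled sample of both groups within a wave;
each group's network is then fit at the shared λ so group differences in
sparsity reflect the data, not separate penalties.

Node importance is strength centrality (sum of absolute partial
correlations; unweighted degree available via `kind="degree"`).
Confidence intervals come from a group-stratified nonparametric bootstrap:
each iteration resamples participants with replacement within each group
(sizes preserved), reselects λ on the pooled resample, refits both
networks and records centralities; the 95% interval is the 2.5/97.5
percentile across iterations and the point estimate is the non-resampled
fit. A full analysis uses B = 1000; tests and the acceptance script use
smaller B and coarser grids, which widens Monte-Carlo error but changes no
logic.

Numerical notes: solver tolerance 1e-4 (duality gap, absolute units) with
max 500 iterations; iterations that stop at the cap with the gap still
open return `converged=False` rather than failing (strict mode raises),
because such estimates are accurate to ~1e-4 and discarding them would
bias the bootstrap; edges are counted at |Θ_ij| > 1e-10. Edge counts along
the λ path are non-increasing on the pipeline's own data (asserted in
tests); this is not a theorem for coordinate-descent solutions in general.

## Factor stage

To make participant profiles interpretable, the 24 z-scored variables
collapse onto 12 profile factors. Each multi-indicator cluster (EF Task:
3 indicators; Reg Prob: 2; EF Daily: 7; Soc Supp: 4) gets its own
one-factor model — unit factor variance, free loadings, diagonal residual
covariance — estimated by minimizing the Wishart ML discrepancy
`log|Σ| + tr(SΣ⁻¹) − log|S| − p` on the cluster correlation matrix
(L-BFGS-B; loadings initialized at 0.5, residual variances at 0.5 and
bounded below at 1e-4, which also caps Heywood cases with a warning; the
first loading's sign is fixed positive). Two-indicator clusters are fit
with equal-magnitude loadings (closed form λ² = |r|) because the
free-loading two-indicator model is unidentified. Per-cluster fitting
(rather than one joint 12-factor model) keeps single-indicator factors
trivial and estimation stable; a joint model is a possible extension.

Participants are scored by the regression (Thurstone) method,
`f̂ = λᵀΣ⁻¹z` (Bartlett scoring available); the eight single-indicator
factors pass the indicator's z-score through unchanged. Scores are linear
in the data and deterministic given the data.

## Community stage

Each participant's 12-factor profile is Pearson-correlated with every
other participant's profile. Negative similarities are truncated to zero
by default (`absolute` and `shift` policies available) since modularity
assumes nonnegative weights and truncation preserves the "similar profiles
attract" reading; the diagonal is zero.

Louvain modularity maximization partitions the similarity graph:
seeded-random node visit order, max-gain local moving, graph aggregation,
repeated until Q stops improving (Q is asserted non-decreasing across
passes). The multi-restart driver (default 200 restarts) starts the first
restart from singletons and later restarts from seeded random partitions —
random starts reach local optima the greedy singleton start essentially
never finds (measured on an adversarial 7-node graph: hit probability
~2e-4 vs ~0.11 per restart) — and returns the highest-Q partition, ties
broken toward fewer communities, then lexicographically. Communities are
renumbered by descending size. The local-moving sweep is numba-compiled
(a numpy fallback keeps the package importable without numba) because the
permutation null runs Louvain tens of thousands of times.

Significance of the observed Q uses a permutation null: each of 200
(default) permutations shuffles every factor column independently across
participants — destroying within-person profile coherence while exactly
preserving each factor's marginal distribution — and reruns the full
similarity → adjacency → multi-restart-Louvain pipeline with the same
restart effort as the observed analysis (avoiding optimization-effort bias
in the comparison). The statistic is `z = (Q_obs − mean(Q_null))/sd(Q_null)`
with the n−1 sd. Column-wise (rather than within-row) shuffling is the
default reading of "randomizing the factor scores"; a row-wise variant
would preserve each participant's score distribution instead and is
deliberately not the default because it leaves profile *levels* intact.

Summaries report per-community mean factor profiles and, per group, the
percentage of that group's members in each community (columns sum to 100).

## ANOVA stage

Per variable, the Group × Time interaction of the classical mixed-design
ANOVA is computed via an exact reduction: with two time points, the
interaction F equals the one-way between-group F on per-participant
T2 − T1 difference scores, with df (1, N−2). Tests verify exact agreement
with both a closed-form cell-means decomposition and pingouin's
`mixed_anova`. Covariates are handled by running the test on residualized
variables (the shared preprocessing pathway); `adjust=False` reproduces
the raw analysis. No sphericity correction is needed with two levels, and
no multiple-testing correction is applied (per-variable reporting is
deliberate; users screening 24 variables should bear the family size in
mind).

## Synthetic cohort generator

The generator emulates the study design the pipeline targets, with
defaults fixed at the design stage:

- **Groups and waves**: 320 on-track / 69 delayed participants, two waves
  0.89 years apart. Ages at T1: on-track 13.19 ± 0.72, delayed
  13.81 ± 0.79 years; IQ 25.4 ± 3.6 in both groups — so age, but not IQ,
  is confounded with group and residualization is consequential.
- **Profile communities**: each participant draws one of K = 3 planted
  prototypes (a regulation-problems profile, a high-risk-taking profile,
  and a balanced profile) with group-specific mixing proportions
  (on-track 0.40/0.25/0.35, delayed 0.33/0.16/0.51). Factor scores are
  prototype + N(0, 1) noise per factor.
- **Separation**: prototypes are scaled by `separation` = 2.0 SD by
  default. This value was chosen analytically so that planted membership
  is recoverable essentially at the Bayes optimum (the closest prototype
  pair then sits ~5.6 SD apart, per-pair misassignment < 2%): the
  generator's job in recovery benchmarks is to plant structure that a
  correct implementation can find. At 2.0 SD the observed modularity is
  Q ≈ 0.48–0.53; a separation near 1.5 reproduces the Q ≈ 0.42–0.45 range
  typical of real cohorts of this kind, at the price of genuinely
  ambiguous boundary participants (Bayes error ~5–10%, ARI ceiling ~0.87).
- **Measurement model**: multi-indicator loadings 0.55–0.8 by cluster;
  single-indicator loadings 0.9; residuals drawn from a planted sparse
  GGM (30 edges among 24 variables, partial correlations 0.2–0.4 in
  magnitude, constructed with unit-diagonal precision so planted partials
  are exact, minimum eigenvalue ≥ 0.05) and scaled to √(1−λ²) so variables
  are approximately unit-variance.
- **Waves**: T2 factor scores are T1 + a common drift (0.1) + N(0, 0.3)
  innovation — no Group × Time interaction is planted, matching the null
  ANOVA expectation; `generate_anova_fixture` plants explicit 2×2 cell
  effects for calibration and power testing.
- **Covariates**: every variable gains `0.2·(age − mean age) +
  0.05·(IQ − mean IQ)`.

All randomness descends from one seed via counter-indexed child seeds, so
every output is bit-reproducible.

**What the benchmark does not show.** The generator produces Gaussian,
linear, complete-case data with communities that are exactly exchangeable
within prototype. Real questionnaire data are ordinal, skewed, and
missing-prone; real profile heterogeneity is rarely a clean finite
mixture; and real age effects need not be linear. Passing recovery and
calibration tests therefore demonstrates that the estimators are correct
and well calibrated under their own assumptions — not that those
assumptions hold in any particular cohort.

## Problem sizes used in tests and the acceptance script

Simulation-heavy checks run scaled versions of the full analysis: the
acceptance script uses 200 Louvain restarts with 50 permutations (a full
analysis would use 200), 400 ANOVA null replicates, and a 500-observation
sample for network recovery; the test suite uses cohorts of 110–389
participants and bootstrap B ≤ 5 with coarsened λ grids. These sizes are
the package's own choice of benchmark scale; every scaled quantity's
Monte-Carlo error is covered by the asserted tolerances.

## Known limitations

- EBIC γ, the λ grid, and percentile (rather than BCa) bootstrap intervals
  are conventions, configurable but not data-driven.
- The community stage's negative-weight policy and permutation scheme are
  analysis choices exposed in the API; results can depend on them.
- The CFA stage fits clusters independently; cross-factor correlations are
  absorbed into profile correlations rather than modeled.
- Louvain is a heuristic: the exhaustive-optimality guarantee is verified
  only for graphs with ≤ 8 nodes.
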