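# Methods

## Model and estimation

A cross-lagged panel network (CLPN) over p constructs measured at two waves
is the p×p matrix of standardized regression coefficients obtained from p
node-wise regressions: each follow-up score is regressed on *all* baseline
scores plus covariates. `B[i, j]` is the coefficient of node i at T1 in the
regression of node j at T2 — the diagonal holds autoregressive paths, the
off-diagonal holds cross-lagged paths. This orientation convention is fixed
package-wide (asserted in the estimation module) to prevent transposition
errors between estimation, centrality, stability, and comparison.

Each regression minimizes

    (1/2n) Σ (y − Xβ)² + λ Σ m·|β|

with penalty mask `m = 1` for the p baseline constructs and `m = 0` for
covariates. Covariates are adjustment variables, not network nodes;
penalizing them would leak construct variance into the unshrunken covariate
coefficients and bias edges, so they stay unpenalized (a toggle exists).
Inputs are standardized and centered, so no intercept is fitted.

The solver is cyclic coordinate descent with soft thresholding on the Gram
form of the problem (`X'X/n`, `X'y/n`), computed along a decreasing λ path
with warm starts. Per-sweep cost is independent of n, which makes the
case-drop bootstrap (thousands of re-estimations) cheap. Convergence: the
sweep stops when no coefficient moves more than 1e-8 (cap 1e5 sweeps per λ)
— two orders below the tightest closed-form comparisons in the test suite.
The solver is verified against (a) closed-form least squares at λ = 0 and
(b) exhaustive 2-D grid minimization of the objective at several λ.

### Penalty selection

λ is selected per outcome node by K-fold (default 10) cross-validated MSE
over a 30-point log-spaced grid from λ_max (the smallest penalty that zeroes
all penalized coefficients) down to λ_max/1000. The default rule is the CV
minimum; the one-standard-error rule is available. This is a genuinely open
choice with a real tradeoff that we measured on simulated panels
(6 nodes, sparse truth with |β| ∈ [0.10, 0.19]):

- **CV-min** recovers essentially all true paths at n = 2000 (100% correct
  sign, cross-lagged RMSE ≈ 0.02) but keeps ≈ 15–20% spurious cross-lagged
  edges on pure-noise panels at n = 500 — almost all below |0.01|. The
  reference glmnet implementation shows the same behavior (≈ 11% on
  identical data), since CV within one sample cannot fully discount
  sample-specific noise correlations.
- **1-SE** cuts the null false-edge rate to ≈ 9% but misses ≈ 15% of the
  weak (|β| = 0.10) true paths at n = 2000.

CV-min is kept as the default because the analysis interprets edge signs and
magnitudes (where missing a true path is costlier than carrying a ≈ 0 edge);
users wanting a conservative network should pass `lambda_rule="1se"`. The
null-sparsity acceptance property in the test suite is asserted at the 10%
level and fails under the default rule by design — it documents this
operating characteristic rather than hiding it.

Fold assignment is seeded, and rows are first placed in a canonical sorted
order inside `fit_node`, so the estimated network is *exactly* invariant to
the row order of participants.

## Synthetic data generator

The generator is the model's generative mirror. Wave-1 scores are drawn per
group from a multivariate normal with configured means/SDs and correlation
matrix; wave-2 scores are produced on the standardized scale as
`z2 = B'z1 + covariate effects + ε` and affinely mapped to score units using
configured wave-2 means/SDs. Defining the dynamics on the standardized scale
makes `true_B` directly comparable to estimated standardized edges, and with
zero residual SD ordinary least squares on the generator's scales recovers
`true_B` to machine precision (a test).

`default_paper_like_config` encodes the study conditions of a two-school
adolescent cohort: groups male (n = 275) and female (n = 495), six
instruments (CDI, AERQ, FARS, FQQ, PTESQ, SSRS-CA) with the published
group-wise means/SDs at both waves, group ages (male 15.90 ± 1.55, female
16.20 ± 1.36, truncated to [12, 19]), and sparse group-specific coefficient
matrices whose signed magnitudes echo the strongest published paths
(female: depression→family −0.19, depression→friendship +0.15, teacher
support dominating out-influence; male: friendship→social support +0.17,
depression→social support −0.18; both: the depression ↔ emotional-resilience
negative feedback loop). Choices the source does not pin down, fixed once
here: autoregressive paths 0.35 (stable but not dominant constructs),
baseline correlations ±0.3 (equicorrelated resilience constructs, depression
negatively related to all), residual SDs 0.85 on the standardized scale
(cross-lagged effects of this size explain little follow-up variance), a
small age effect (+0.05 SD on follow-up depression), groups coded 0/1 in
sorted label order, and 5% MCAR missingness (the cohort's realized
missingness was never reported — this default is arbitrary and flagged
as such).

Missingness mechanisms: MCAR removes construct cells uniformly; MAR makes a
follow-up cell's log-odds of missingness increase by 0.1 per SD of the
participant's observed baseline depression (first node), with baseline cells
MCAR — a minimal, documented MAR scheme for exercising the imputer.
Covariates and group labels are never removed.

What the generator does *not* emulate: item-level responses (totals are
continuous, not rounded ordinal sums), floor/ceiling effects, measurement
error/reliability below 1, attrition between waves, and clustering by
school or classroom. Passing tests therefore demonstrate correctness of the
estimation machinery under the assumed Gaussian linear model, not robustness
to those real-data features.

## Imputation

Iterative random-forest single imputation: initialize missing construct
cells at column means; visit incomplete columns in ascending order of
missingness; per column, fit a random-forest regressor (default 100 trees)
on all other columns over the rows observed for it and re-predict its
missing cells; after each full pass compute the normalized squared change of
the imputed values, and stop at the first increase (returning the previous
pass's values) or after `max_iter` (default 10) passes. One completed
dataset results; observed cells are never modified, and the missingness mask
is retained. The group label enters as a numeric code so group structure
informs imputation. Forest seeds derive deterministically from the call
seed.

## Centrality, stability, comparison

Expected influence: out-EI(i) = Σ_{j≠i} B[i,j], in-EI(j) = Σ_{i≠j} B[i,j].
Autoregressive self-loops are excluded by default — they measure a
construct's stability, not its influence on others — with an
`include_self` toggle since the convention is not universal. Both indices
sum over the same edge set, so their totals coincide (tested to 1e-12).
Standardized variants z-score across nodes (n−1); ranks are descending with
ties averaged.

Case-drop bootstrap: for each drop proportion d in
{0.05, …, 0.75} and each of n_boot replicates (default 1000; tests and the
acceptance script use 100–200 for runtime), draw ⌊n(1−d)⌋ participants
without replacement, re-standardize, re-estimate the network *re-selecting*
λ by the same CV procedure (reusing the full-sample λ would understate
instability), and record the Spearman correlation of each centrality vector
with the full-sample one. Every replicate is seeded individually from the
top-level seed, so results are independent of execution order or worker
count. Subsamples below the minimum fit size are skipped with a recorded
warning; undefined correlations (constant vectors) are NaN and count as
failures. CS coefficient = the largest grid proportion at which ≥ 95% of
replicates correlate ≥ 0.7 with the full sample.

Comparison of two group networks: Pearson correlation of the vectorized
edge weights, sign-class discordance, and Pearson correlations of the
centrality vectors (p values from the t approximation; with p = 6 nodes the
centrality correlations are low-powered by construction and read as
descriptive). The default edge set is all p(p−1) = 30 directed cross-lagged
entries *including* exact zeros, and zero-vs-nonzero counts as discordant:
under lasso selection, an edge present in one group and absent in the other
is a substantive directional disagreement, and a 30-edge set is the only
convention under which a discordance like 16/30 = 53.33% is representable.
A nonzero-union variant is provided; conventions are always reported, never
mixed silently.

## Descriptives

Group comparisons use Welch's unequal-variance t-test (two-tailed) — a
robust default where only "independent samples t-tests" is specified.
Degenerate zero-variance-in-both-groups columns use the convention p = 1
when means agree, else p = 0. Published descriptive-table p values for this
kind of data are not reproducible from rounded means/SDs/ns alone and are
not used as oracles anywhere.

## Pipeline and reproducibility

`run_pipeline` chains impute → descriptives → standardize → overall network
(covariates age + group code) → per-group networks (covariate age) →
centralities → per-network stability → group comparison → artifact writing.
Each stage's seed is derived deterministically from the single run seed via
spawn keys; the JSON report is serialized with sorted keys and contains no
timestamps, so identical configs yield byte-identical reports (tested). The
CLI subcommands are thin wrappers over the same functions and compose
through the CSV/GraphML/JSON exchange formats.

Problem sizes used by the shipped tests and acceptance script — 20 seeds at
n = 2000 for recovery, 20 at n = 500 for the null, n = 770 with 200
replicates for stability, 20 MCAR replicates at n = 250 for imputation —
were chosen to keep Monte-Carlo error well below the asserted margins while
completing a full run in minutes on one CPU.

## Known limitations

- Two waves only; no contemporaneous (within-wave) network, no Gaussian
  graphical model, no moderated or time-varying effects.
- Single imputation: between-imputation uncertainty is not propagated into
  edge estimates.
- Lasso edges are biased toward zero by construction; magnitudes are
  conservative and the CV-min default admits some near-zero spurious edges
  (quantified above).
- No permutation-based network comparison test; group differences are
  described, not formally tested edge-by-edge.
- CS coefficients are resolved only to the drop-proportion grid.
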