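# Methods

`blcasig` implements a biomarker-discovery workflow for bulk expression
cohorts with binary clinical endpoints and right-censored follow-up, of
the kind produced by normalized single-channel microarray profiling of
bladder-cancer (BLCA) patients treated with neoadjuvant chemotherapy
(NAC). This note records the statistical model behind each stage, the
parameters that matter, the synthetic-data model the tests rely on, and
the numerical choices made where the design was genuinely open.

## Endpoint derivation

Therapy response arrives as four codes (0 = partial response, 1 =
complete response, 2 = stable disease, 3 = progressive disease) and is
dichotomized to response (0,1 -> 0) versus disease (2,3 -> 1). Histology
arrives as a predominant label (urothelial or neuroendocrine) plus an
optional set of secondary codes 1–8; it is reduced to five groups with
the secondary codes as the main discriminator, resolved by the fixed
precedence **neuroendocrine (code 3 or predominant NE) > squamous (2) >
micropapillary (6) > other (4,5,7,8) > urothelial (1 or no secondary)**.
The published rule set is only available as a figure; this precedence is
a documented package choice. Two consequences worth flagging: secondary
*papillary* (7) and *plasmacytoid* (4) are binned as "other", keeping the
rule purely code-driven rather than interpreting papillary as a variant
of urothelial. AJCC T-stage labels (Ta…T4b) map to stage groups 0–IV
(Ta,Tis -> 0; T1 -> I; T2* -> II; T3*,T4,T4a -> III; T4b -> IV) and to a
muscle-invasion dichotomy at T2 (`<T2` = {Ta,Tis,T1}). The bare label
T4 is grouped with T4a into stage III rather than IV, the conservative
reading of a table that only assigns T4a and T4b explicitly.

Samples whose diagnostic TURBT pathology ID lacks the literal,
case-sensitive `SR-` prefix are excluded at ingest, as are samples
missing from either the expression or the clinical table. Samples with
no usable time-to-event fall back to the follow-up time as a censoring
time; samples missing both are excluded from survival analyses only.

## Differential expression (mean filter + Wilcoxon)

Genes with mean expression below 0.7 (inclusive boundary: mean >= 0.7 is
kept) across the analyzed samples are dropped as near-zero uninformative
mass. Each surviving gene is tested with the Wilcoxon rank-sum
(Mann–Whitney U) test in both one-sided directions against the binary
endpoint, with group 1 (the event-positive class) defining "over". A
gene is selected when **either** one-sided p-value is <= alpha (0.01 in
the strict phases, 0.05 in the max-overlap pool phase). The exact null
distribution is used when both groups have at most 25 observations and
the pooled data are untied; otherwise the normal approximation with
midranks, tie-corrected variance and a 0.5 continuity correction. No
multiple-testing correction is applied — deliberately, since selection
feeds a regularized model rather than standing as an inference; the
false-selection rate among null genes is therefore about 2·alpha.

## Elastic-net logistic regression

The classifier minimizes
`(1/n)·deviance + lambda·[m·||b||_1 + (1−m)/2·||b||_2^2]` with mixing
m = 0.5. Predictors are standardized internally and coefficients
reported on the input scale. The penalty grid holds 100 log-spaced
values from lambda_max (the smallest penalty zeroing all coefficients,
`max_j |x_j'(y − ȳ)| / (n·m)` on standardized data) down to
lambda_max·1e-4; grid points at or above lambda_max are filled with the
exact null solution (zero coefficients, intercept at the empirical
log-odds) from the KKT conditions. lambda_min minimizes the mean
held-out binomial deviance over stratified 10-fold CV (folds reduced
with a warning when a class is smaller than k; ties break toward the
larger penalty). Per-lambda fits use the saga solver with warm starts
down the path, a fixed shuffling seed for determinism, tolerance 1e-3
and at most 2000 epochs — accurate to well under the CV noise that
drives penalty selection, at a fraction of the cost of a tighter
tolerance.

Train/test splits are stratified at a 70/30 ratio: each class
contributes round(class_size × 0.7) training samples, with the rounding
remainder reconciled against round(n × 0.7) on the largest classes
first (so a 102-sample cohort always yields a 31-sample test set).
Classification at the default boundary uses strict `P > 0.5`; the
accuracy-maximizing cutpoint search scans midpoints between adjacent
distinct scores plus ±inf sentinels and calls `score >= cutpoint`
positive, breaking ties toward the lowest cutpoint. AUC uses the rank
(Mann–Whitney) formulation with ties counting 1/2. Accuracy confidence
intervals are exact binomial (Clopper–Pearson) from beta quantiles —
the method that reproduces the printed intervals 0.589–0.9041 (24/31)
and 0.7862–0.9834 (35/38) exactly.

## Resampling gene selection

**Consensus frequency selection** repeats, for 100 cycles by default:
stratified 70/30 split; DE on the *training* samples at alpha = 0.01;
CV'd elastic-net fit on the DE genes; increment a counter for every
nonzero-coefficient gene. Genes are then ranked by count (descending,
gene ID ascending as the deterministic tie-break), the top 100 are
refit with a fresh stratified split, and the final model's nonzero set
is the signature. Running the per-cycle DE step on training samples
only (rather than the full cohort) is a package choice that also avoids
test-set leakage; the max-overlap phase 1 below is the deliberately
"better informed" full-cohort variant.

**Maximum-overlap selection** fixes the patients instead of the genes.
Phase 1 collects a gene pool: DE on the full cohort at alpha = 0.05,
then repeated CV'd elastic-net fits on the full cohort (cycle-to-cycle
variation from CV fold randomization only); any gene selected even once
enters the pool. Phase 2 builds candidate models exactly like consensus
cycles (alpha = 0.01, 70/30 splits, test accuracy at the 0.5 boundary).
The `find_overlap` scan initializes the incumbent with the first
candidate and replaces it only when a later candidate's overlap with
the pool is **strictly larger and** its accuracy is **not worse**; the
scan is order-dependent by construction and is property-tested against
an independent brute-force restatement. The winning split is frozen,
the final model refit on its training set, and overlap size, test
accuracy with exact CI, and AUC are reported. The phase-1 cycle count
is not pinned by the procedure's description; it defaults to the same
100 as every other loop and is configurable.

Per-cycle seeds derive from the master seed via `SeedSequence.spawn`,
so both procedures are bit-reproducible and the pool is monotone in the
cycle count under a fixed seed.

## Signature scores, risk groups, survival

The final model's predicted event probability is the per-sample
signature score, computed for all cohort samples (train and test) with
the frozen model. Risk groups come from the linear-interpolation sample
quartiles (the convention interpolating at index 1 + (n−1)q): the
2-group mode splits at the median (score <= Q2 -> low), the only
quartile-derived two-way split; the 4-group mode uses lower-inclusive
bins at Q1/Q2/Q3. Survival per group uses the Kaplan–Meier
product-limit estimator with the standard tie convention (deaths
processed before censorings); group differences use the log-rank
chi-square test with groups − 1 degrees of freedom. Both are computed
through lifelines behind this module's interface and verified against
hand-computed product-limit tables in the tests.

## Clustering

The exploratory track standardizes variables (sample SD, n−1 — chosen
for consistency with the statistics elsewhere; the population-SD
convention of the usual scaler differs in the third decimal at these
n), takes principal components from the covariance eigendecomposition
(descending eigenvalues; sign fixed so each component's largest
loading is positive), and runs K-means (10 restarts per K) over a K
range, reporting the mean silhouette per K, the silhouette argmax as
k_best, and the inertia elbow by the maximum distance-to-chord rule; a
`no_structure` flag is raised when no K reaches silhouette 0.25.

The main track clusters patients with PAM over the Spearman distance
d = 1 − rho_s between sample profiles across genes (constant profiles
get distance 1 with a warning). PAM is implemented directly — greedy
BUILD initialization, then best-improvement single-swap moves until
none reduces the total dissimilarity; the objective is non-increasing
and the search is deterministic. Consensus clustering wraps PAM:
80% subsampling without replacement, 250 repetitions by default (tests
use far fewer), M_ij = co-clustering fraction among co-sampled reps,
final partition by average-linkage hierarchical clustering of 1 − M cut
at K, consensus CDFs reported per K. The resampling parameters are
package defaults, not published values. Heatmap export orders samples
by cluster then within-cluster average-linkage leaf order, genes by
hierarchical clustering of gene–gene Spearman distances, and attaches
per-sample annotation tracks.

## Synthetic cohorts

The generator produces data with exactly the structure the pipeline
assumes, so every stage is testable without the private 102-patient
cohort:

- **Expression**: a two-component mixture — "low" genes with mean
  ~U(0.01, 0.5), "expressed" genes ~U(0.7, 2.0) — with per-sample values
  gamma-distributed around the gene mean (shape 4, so SD = mean/2) and
  0.5% of entries inflated 3–8x to mimic normalization outliers. This
  reproduces the filterable near-zero mass, the non-negativity, and the
  right skew that motivates the rank test; it is a stand-in, not a
  claim about the real data's distribution.
- **Signal**: event labels are drawn first (fixed class sizes at the
  configured prevalence); planted genes (means redrawn in U(1.2, 2.0)
  so both directions stay feasible) get a location shift of
  `effect_size` expression units in the event class with a random sign
  per gene, making both truth directions testable. At the default
  effect of 1.0 units the shift is at least one pooled SD for every
  planted gene.
- **Survival**: exponential event times with the hazard multiplied by
  `hazard_ratio_event` (default 3) in the event-positive class;
  administrative censoring at the (1 − censor_rate) quantile of the
  drawn times, the simplest mechanism producing right-censored data
  and hitting the target rate by construction.
- **Clinical fields**: therapy-response codes consistent with the
  latent event; 4% neuroendocrine predominant histology; 40% missing
  secondary histology; T-stage drawn over the 12 labels with weights
  favouring muscle-invasive stages; `SR-` prefixed pathology IDs.

Defaults (120 samples, 2,000 genes, 20 informative, prevalence 0.4,
half the genes low-expressed, 30% censoring) are the conditions the
test suite and the acceptance script exercise; 2,000 genes is a
scaled-down surrogate for a 46,050-gene array chosen so the full
resampling loop runs on a single CPU in minutes. All randomness flows
from one master seed through numpy's `SeedSequence` spawning (PCG64),
giving bit-identical cohorts across platforms.

What the generator does **not** emulate: probe-level effects, batch
effects, gene–gene correlation beyond what the shared endpoint induces,
informative censoring, and the real cohort's missing-data patterns.
Passing recovery tests therefore demonstrates that the procedures
recover independent planted location shifts under skewed noise — not
that they would recover correlated biological programs in real data.

## Problem sizes and tolerances

The test suite and the acceptance script run the resampling procedures
at 25 cycles per phase on the 120 x 2,000 cohort — the package's
standard reduced-scale configuration — and smaller unit fixtures
elsewhere. Planted-signal recovery is asserted at >= 80% of planted
genes in the consensus top-100 and >= 70% in the max-overlap signature;
null cohorts must show no gene frequency above half the cycles and a
test AUC within [0.2, 0.8]. Oracle agreements (exact Wilcoxon
enumeration, product-limit tables, all-pairs AUC, brute-force
`find_overlap`) are exact to numerical precision; the unpenalized-MLE
comparison at lambda = 1e-6 is within 5%; the continuity-corrected
normal approximation to the rank-sum null is within 0.006 of the exact
distribution at n = m = 8.

A behaviour worth understanding before interpreting consensus
frequencies: because every cycle resamples overlapping 70% subsets of
the *same* cohort, a gene that is spuriously extreme in the full cohort
(expected at rate ~2·alpha among the filtered genes) stays
DE-selected in most cycles, and the fold-held-out deviance that picks
the penalty is computed on training samples that already participated
in the DE selection, so such genes keep nonzero coefficients
cycle after cycle. On pure-noise cohorts the occurrence counter
therefore concentrates on a few null genes (the acceptance script
reports the observed maximum frequency fraction on a null cohort), even
though the frozen model's *held-out* test AUC remains at chance level.
Consensus frequencies measure stability of selection under resampling,
not evidence against the null; the held-out accuracy, CI and AUC are
the quantities with inferential meaning.

## Known limitations

- The histology precedence and the stage-III placement of bare T4 are
  documented choices where the published grouping is ambiguous.
- The procedures inherit the instability of accuracy-driven selection
  on small test sets; `find_overlap` is order-dependent by design, so
  signatures depend on the master seed (reproducibly so).
- PAM uses full objective re-evaluation per candidate swap (O(n^2) per
  candidate); adequate for cohort-scale n, not for thousands of
  samples.
- No external-cohort validation is modelled; the package validates
  internally by construction.
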