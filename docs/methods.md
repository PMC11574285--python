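# Methods

## Detection model and prevalence

All statistics derive from a boolean detection mask: a gene is detected in
a cell when its expression value strictly exceeds the detection threshold.
The strict inequality matters at the boundary — a value exactly equal to
the threshold is *not* detected — and an inclusive variant is available via
`Thresholds(strict_detection=False)`.  Defaults:

| parameter | default | units / scale | meaning |
|---|---|---|---|
| `detection_scrna` | 3.5 | log(CPM) | scRNA-seq detection threshold |
| `detection_spatial` | 0.3 | spatial panel units | spatial detection threshold |
| `enrichment_fraction` | 70 | percent | in-cluster prevalence needed for a cluster to count as enriched |

Prevalence is computed as `100 * count / n` with the integral count formed
first, so results are bit-identical to a naive counting loop; groups with
zero members are omitted rather than reported as 0 (the ratio is
undefined).  Denominators are always all cells of the group, except the
co-transcription distribution, which is reported on two explicitly labeled
bases (all cells, and cells detecting at least one family gene).

The enrichment comparison is inclusive (≥ 70%) by default, with
`strict_enrichment=True` switching to strict >; the two differ only for
clusters sitting exactly on the boundary, which the boundary tests pin
down.

The spatial detection threshold is applied to the spatial expression
values as stored.  Whether such values are raw or log-scale depends on the
upstream platform; the synthetic generator emits values on a compressed
log-like scale consistent with the 0.3 default.

## Multi-membership neighborhoods

A cell may belong to several neighborhoods.  `expand_memberships` builds a
separate, row-duplicated table used *only* for neighborhood-grouped
statistics; every other grouping uses the unduplicated table, so no cell is
double-counted at taxonomy levels.  Cells absent from the membership table
keep their single neighborhood label.

## Decoding

Features are the boolean detection profiles (column order = configured
gene order); the target is any metadata column.  The decoder is a random
forest with 200 trees, maximum depth 10 and balanced class weights,
evaluated by stratified 5-fold cross-validation with shuffling under a
fixed seed.  One CV pass produces both the per-fold balanced accuracies
and the out-of-fold predictions that feed the true-label-normalized
confusion matrix and per-class precision/recall/F1 report — predictions
for each cell always come from a model that never saw it.  Classes with
fewer members than folds are dropped with a warning, never merged.  The
chance level is the analytic `100/K` percent for `K` classes.  Linear
baselines (logistic regression, LDA) run under the identical CV protocol;
the LDA uses the `lsqr` solver with Ledoit–Wolf shrinkage because boolean
profiles with deterministic genes make the within-class scatter singular,
where the default SVD solver is undefined.

### Attribution

The class × gene attribution matrix contains mean absolute Shapley values
of the forest's predicted class probabilities, estimated by Monte Carlo
permutation sampling: for each sampled feature ordering, the features of a
background row are switched one at a time to the explained row's values,
and the marginal change in the background-averaged class probability is
credited to the switched feature.  Averaging signed contributions over
orderings estimates the Shapley value; the reported matrix is the mean of
absolute values over explained rows, per class.  Explained rows are a
class-weight-balanced sample (probability inversely proportional to class
frequency, capped at class size) of at most `attribution_sample` rows
(default 10,000).  Estimator settings: `attribution_background` (default
50 background rows) and `attribution_permutations` (default 8 orderings).
The model explained is a single forest refit on the full table — accuracy
comes from the CV loop, attribution from the full fit.  Two exact
properties hold regardless of the Monte Carlo error: a feature constant
across the data receives attribution exactly 0, and all entries are
non-negative.  The estimate is noisy at few permutations; the defaults
favor the rank structure (which gene drives which class) over precise
magnitudes.

## Effector families

Family sums add *raw* expression values (no thresholding) over the fixed
partition Htr1/5 = {Htr1a, Htr1b, Htr1d, Htr1f, Htr5a, Htr5b},
Htr2 = {Htr2a, Htr2b, Htr2c}, Htr4/6/7 = {Htr4, Htr6, Htr7},
Htr3 = {Htr3a, Htr3b}.  The primary family is the per-cell argmax;
all-zero cells are labeled `unassigned` and reported separately rather
than forced into a family; exact ties break deterministically toward the
earlier family in the order above, with the tie count logged (ties are
measure-zero on continuous data but common on sparse fixtures).
Assignment is invariant to positive rescaling of a cell's expression.

## Cross-modal spatial mapping

Enriched clusters are identified in the scRNA-seq dataset only; the
spatial subset is a pure label filter (`cluster ∈ enriched set`), which is
what lets the method localize genes missing from the spatial panel.  The
`enriched_fraction` statistic — percent of all gene-detecting cells that
belong to enriched clusters — quantifies how much of the gene's signal the
projection carries; when it is small, the `direct` mode (thresholding the
spatial panel values themselves) is the honest alternative, and both modes
are first-class.  Regional prevalence normalizes by the total cell count
per division/structure, so the count-weighted mean of a division's
structure prevalences equals the division prevalence exactly — an identity
the tests assert.

Per-class concordance between modalities is an ordinary least-squares
regression of spatial on scRNA-seq prevalence over shared classes (slope,
intercept, R²).  A sub-unity slope is the expected signature of the
spatial platform's lower per-gene sensitivity.

Anteroposterior profiles are per-section subset prevalences ordered by
mean AP coordinate.  Top-section selection takes local maxima (plateau
edges count; profile ends compare against their single neighbor), ranks
them by prevalence with ties toward the anterior, and greedily keeps peaks
at pairwise AP distance ≥ `min_spacing` (default 10% of the profile's AP
range — "adequately spaced" is inherently a display choice, so the default
is configurable).  If fewer than `k` (default 4) peaks survive, the
highest remaining sections respecting the spacing rule fill the list and
the result is flagged as filled.

## Synthetic data: what it emulates and what it does not

The generator plants a Bernoulli detection probability per (cluster, gene).
Detected amounts are drawn from a per-gene normal truncated strictly above
the detection threshold; undetected values are exactly 0.  This guarantees
the planted Bernoulli structure survives thresholding exactly, making
every downstream statistic checkable against closed-form expectations —
the design goal.  The cost in realism: real log(CPM) distributions are
zero-inflated continuous mixtures whose mass *straddles* the threshold, so
on real data the detection call is genuinely lossy in a way the synthetic
data never is.  Passing tests therefore validate the bookkeeping and the
statistics, not the biological adequacy of any threshold.

Default desk-scale conditions, chosen once: a 10-class / 20-subclass /
20-supertype / 40-cluster taxonomy with 20,000 cells per modality (runs in
seconds); per-gene base prevalences log-spaced over 0.1%–35%, matching the
dynamic range a whole-brain receptor family spans; per-cluster logit noise
(sd 1.5) creating both depleted and enriched clusters; per-gene detected-
amount means increasing with base prevalence (widespread genes run hotter
within cells, as observed in whole-brain data) plus gene-level scatter;
a 9-of-14 spatial gene panel; 20 sections over a unit-free AP range of
(0, 10); a deterministic 5 × 4 grid parcellation (division from x,
structure from y, structures nested in divisions by construction) standing
in for atlas registration; and a spatial prevalence scale (default 1.0)
that multiplies detection probabilities to emulate the systematic
cross-platform sensitivity offset.  Everything derives from one root seed
through fixed named streams, so generation is bit-reproducible and
taxonomy, expression and spatial draws are independently reproducible.

Not emulated: transcriptome-wide structure (only the family is modeled),
realistic spatial autocorrelation of cell types (clusters are uniform over
space, so parcellation prevalences are flat in expectation unless planted
otherwise), doublets/ambient contamination, and cluster-size skew (uniform
by default; `cluster_weights` plants skew when needed).

## Problem sizes and numerical choices

Tests run at 140–5,000 cells (50,000 for the concordance check), sizes at
which every counting statistic is verified *exactly* against brute-force
loops, and stochastic checks use 3–4 binomial SDs so seed-fixed runs are
stable.  The enrichment-recovery experiment uses the planted probability
ladder {0.9, 0.8, 0.5, 0.1} at 200 cells/cluster over 100 replicates:
0.8 sits 3.5 binomial SDs above the 70% threshold and 0.5 about 4 SDs
below, so recovering exactly the two high clusters is expected in ≫95% of
replicates.  Prevalence recovery is asserted at the full generated n
(pooled over replicates), where the 4-SD band is a sound simultaneous
bound; per-replicate 4-SD checks over hundreds of binomial draws would
fail a percent of the time by construction.  Pearson correlations of
constant vectors are reported as missing (NaN), never 0.  The ± convention
on mean profile correlations is the standard error of the mean, and both
the per-group mean over other groups and the overall mean over unordered
pairs are exposed.

## Known limitations

- The attribution matrix is a sampling estimate; magnitudes stabilize only
  as background size and permutation count grow.
- The HDF5 expression reader loads the full matrix into memory; the
  multi-million-cell source datasets need chunked adapters that are out of
  scope here.
- The static report renders whatever serialized results it finds; it does
  not recompute anything, so stale result folders produce stale figures
  (the manifest hash is the guard).
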