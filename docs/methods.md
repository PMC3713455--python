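# Methods

This note documents the models, defaults and numerical choices behind
`kdsig`. The pipeline re-implements a perturbation-based study design from
myeloid-malignancy transcriptomics: an shRNA series of graded potency knocks
a candidate driver gene down to a ladder of residual expression levels; the
genes whose expression tracks that ladder form a "driver-low" signature; the
signature is then scored in patient cohorts by enrichment analysis and by a
k-nearest-neighbor classifier trained on the knockdown profiles.

## Expression model and the synthetic generators

All matrices are log2-scale intensities, genes × samples. The generators
exist so that every downstream stage can be scored against a known truth;
their defaults encode the study conditions the pipeline targets.

**Knockdown series.** 13 samples by default: 1 unperturbed, 4 control-shRNA
and 8 driver-shRNA samples. Per-gene baselines are drawn N(7, 2) on the log2
scale (lognormal intensities on the linear scale, a standard microarray
caricature); the driver's baseline is fixed at 9.0 log2 units because the
anchor gene of such a study is by construction well expressed. The driver's
log2 value in driver-shRNA sample *j* is `baseline + log2(f_j)` with residual
fractions `f_j = linspace(0.05, 0.30, 8)` — a 5–30% ladder. Planted targets
follow `baseline_t + slope_t * log2(f_j)` with slope +1 (80 positive targets)
or −1 (10 negative targets) by default; all genes receive additive Gaussian
log2 noise, `noise_sd = 0.3`. The noise magnitude of the original arrays is
not documented anywhere we could anchor it; 0.3 log2 units is a typical
residual SD for replicate bulk microarrays and is an explicit assumption.
With `noise_sd = 0` every planted relationship is exact (correlations ±1,
shifts equal to log2 of the residual fraction), which the tests exploit.

**Patient cohort.** 17 "driver-low" cases, 9 normal-like cases and 4 normal
controls by default. Low cases draw a per-case residual fraction *f* uniform
on [0.20, 0.45] and shift the driver and every signature gene by
`direction * log2(f)`; other samples share the control distribution. Cohort
noise is 0.5 log2 units — patients are more heterogeneous than a cell-line
series. An optional platform distortion applies a per-gene affine map
(`scale ~ N(1, 0.1)`, `offset ~ N(0, 0.5)` by default) and drops a fraction
of genes entirely, emulating cross-platform transfer.

What the generators deliberately do **not** model: probe-level effects,
batch structure beyond the per-gene affine map, correlated noise between
genes outside the planted programs, and any biology of the non-signature
transcriptome (null genes are independent). Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
assumed signal model, not robustness to every failure mode of real arrays.

## Preprocessing

Probe matrices collapse to one row per gene by the max-mean rule (the probe
with the highest mean across samples represents the gene; ties break to the
lexicographically smallest probe id). Non-expressed genes are removed when
they fail to exceed an expression floor in at least 25% of samples; the floor
defaults to the 20th percentile of all matrix values. Both knobs are
explicit configuration because no universal threshold exists; gene counts
after filtering depend on the annotation and floor and are not comparable
across platforms.

Relative expression of a gene is reported per sample as a percentage of the
**linear-scale** mean of a reference group (percentages of intensities, not
of log values); a sample 2 log2 units below the reference mean reads 25%.
Samples at or below a threshold (default 45%) are flagged "low". The report
is invariant to adding a constant to the gene's log2 row, since numerator
and denominator scale together.

## Marker selection

The two-class statistic is the signal-to-noise ratio
`(μ_A − μ_B) / (σ_A + σ_B)` with each class σ floored at
`max(0.2·|μ|, 0.2)` — the convention of the comparative-marker tools used
for microarray class comparison. Significance comes from two-sided label
permutations: p = (1 + #{|score_perm| ≥ |score_obs|}) / (n_perm + 1), with
exhaustive enumeration of all label assignments whenever their number does
not exceed `n_perm` (then p is an exact rank among all assignments). FDR is
Benjamini–Hochberg across genes. Fold change is the ratio of linear-scale
class means, folded to ≥ 1 with a direction flag. Default selection:
q ≤ 0.006 and fold change ≥ 2.

A granularity note: with sampled permutations p cannot fall below
1/(n_perm + 1), so the smallest reachable q over *m* genes is roughly
`m / (k·(n_perm+1))` at rank *k*. Tight q thresholds therefore require
permutation counts commensurate with the gene count — the reason the default
is 10,000 permutations.

## Signature derivation and refinement

Every gene is scored by the Pearson correlation of its profile with the
driver's profile across all series samples, including the unperturbed one
(it extends the expression gradient). The unrefined signature takes genes
with r strictly beyond ±0.8. Refinement mirrors the two curation steps such
studies apply:

1. **Co-clustering with the negative program.** All signature genes are
   hierarchically clustered on their profiles (distance 1 − Pearson, average
   linkage; both configurable). The negatives' cluster is the smallest
   dendrogram node containing every negative gene; positive genes inside it
   are removed. If the negatives only reunite at the root the step is
   skipped with a warning rather than deleting the whole signature.
2. **Low expression in controls.** Positive genes below the expression floor
   in at least ⌈0.75 · n_controls⌉ control samples are removed (the
   "3 out of 4 controls" rule generalized to any control count).

The refined signature keeps only positive members; every removal, including
the dropped negative members themselves, is logged with its reason, so the
log accounts exactly for the size change and refinement is idempotent.

## Enrichment scoring

The enrichment score walks the ranked gene list (two-class SNR scores,
descending, ties broken by gene id): hits add `|score|^w / Σ_hits |score|^w`,
misses subtract `1/(N − N_hits)`; the ES is the running sum's signed maximum
deviation and the leading edge contains the set members at or before the
extremum (at or after it for negative ES). The weight exponent defaults to 1
(classic weighted form); weight 0 reduces to the unweighted Kolmogorov–
Smirnov walk, under which the ES is invariant to monotone score transforms
and negates when the ranking reverses.

Significance uses phenotype permutation by default (labels permuted, ranking
recomputed each time); with fewer than 7 samples in either class the engine
falls back to gene-set permutation (random sets of the same size on the
fixed ranking) with a warning. The nominal p compares the observed ES
against the *same-signed* portion of the permutation null with the +1
correction — the definition under which the p-value is uniform for random
sets under a global null, which the acceptance suite verifies by KS test.
NES divides the ES by the mean |null ES| of matching sign. Degenerate cases:
a set covering the whole list has no miss steps (ES = 1 at the end); an
all-zero-score hit set under positive weight falls back to uniform hit
weights.

## KNN classification

Training profiles are the knockdown series restricted to the refined
signature: driver-shRNA samples are `driver-low`, control-shRNA and
unperturbed samples are `control` (8 vs 5 by default). Zero-variance
training genes are excluded with a warning. Cross-platform harmonization is
deliberately minimal: restrict to shared genes, then z-score each gene
within its own dataset (training with training parameters, test with
test-cohort parameters), which cancels per-gene affine platform differences
exactly. Coverage of the signature on the test platform below 80% records a
warning; below 50% classification refuses to run.

Each test sample takes the majority vote of its k = 3 nearest training
samples by Euclidean distance; a distance tie at the k-th position admits
all tied neighbors (k expands for that sample, logged). Confidence is the
vote fraction — exactly 2/3 or 1.0 for binary k = 3 — and the signed score
is −confidence when the signature is called present, +confidence otherwise.
One caveat of per-dataset z-scoring: a test cohort containing *only*
signature-low samples loses its own reference point; cohorts should include
normal samples, as real designs do.

## qPCR quantification

Per (sample, gene), replicate Ct values (triplicates expected; missing wells
tolerated as NaN, never sentinel cycles) average to a mean Ct, and the input
quantity is `Q = E^(−mean Ct)` with E the primer pair's mean amplification
efficiency (fold per cycle, validated in (1, 2.2]). Each sample is
normalized by the geometric mean of its reference-gene quantities (three
housekeeping genes by default, the PAPOLA/UBQLN1/VPS39 convention), then
each gene is scaled so the control-sample mean equals 1. Aggregation is mean
Ct rather than mean quantity (the standard choice); a sample missing a
reference is flagged, normalized by the references it has, and excluded from
the control-scaling denominator. Noise-free, the round trip through the
plate simulator recovers planted quantities to 1e−10; at 0.1-cycle noise a
planted 0.3 comes back within ±0.05.

## Pipeline and determinism

`run_pipeline` validates the complete configuration before any stage runs
(odd k, permutation counts ≥ 100, cutoff and threshold ranges, design
invariants), then executes simulate → filter → signature → differential
expression → enrichment → classification → relative expression, writing each
stage's artifact (GCT/CLS/TSV/GMT/JSON) plus a line-structured run log and
the resolved configuration. Stages communicate only through serialized
artifacts. A single seed is split per stage via `numpy.random.SeedSequence`;
identical configuration and seed reproduce every artifact byte-for-byte (the
run log's wall-clock timestamps are the documented exception). On stage
failure all partial outputs are removed and the error names the stage.

## Problem sizes used in the test and acceptance suites

Simulations run at the design scale described above (2,000 genes, 13-sample
series, 30-sample cohorts), with 10 replicate seeds for averaged recovery
metrics, 1,000–10,000 label permutations for marker selection, and 199–999
permutations for enrichment — sizes chosen so the planted effects operate in
the same regime as the motivating study while the full suite stays fast.

## Known limitations

- The non-expressed filter and collapse rules are parameterized policies;
  absolute gene counts after filtering are not meaningful across platforms.
- Permutation p-values are floored at 1/(n_perm+1); very small q targets
  need correspondingly many permutations (see the granularity note).
- Harmonization assumes per-gene affine platform differences; nonlinear
  probe effects and absent-gene imputation are out of scope.
- Efficiencies are inputs to the qPCR math; estimating them from dilution
  series or amplification curves is not implemented.
- The synthetic null transcriptome is independent across genes, so
  correlation-based false-positive rates on real data (with co-expression
  structure) will exceed those measured here.
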