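# Methods

This note documents the models, defaults and numerical choices behind
`oasubtypes`, and what the synthetic-cohort experiments do and do not
establish about real data.

## Synthetic cohort model

The generator emulates a multi-center knee-OA bulk 3'-counting RNA-seq
cohort with three tissues (cartilage for every patient plus a few non-OA
amputation controls; synovium and subchondral bone each present per patient
with probability 1 − `tissue_missing_rate`, default 0.5, mirroring the
unequal tissue availability of such cohorts).

**Counts.** Gene base means are log-normal (meanlog 3, sdlog 1.2), giving
heavy-tailed bulk-like abundance distributions. For each sample the mean
vector is scaled so its sum equals a target library size drawn uniformly
from `library_size_range` (default 600 000–1 800 000 — safely inside the
depth-QC window; widening the range to 400 000–2 100 000 produces samples
the depth filter removes). Counts are negative binomial with dispersion
`nb_dispersion` (default 0.2). Realized totals therefore fluctuate around
the target by roughly ±1 %; tests on library sizes allow a 5 % margin.
Controls are drawn from the base means at a quarter of the OA dispersion —
the variance structure of non-OA control tissue is not constrained by any
external reference, so "transcriptionally quieter than end-stage disease"
is this package's own modeling choice.

**Subtypes.** Four subtypes at configurable proportions (default
0.618/0.183/0.076/0.122; the defaults are rounded percentages summing to
0.999, so validation tolerates 1 % slack and renormalizes). Patients are
apportioned by largest-remainder rounding — deterministic, and at n = 131
it yields sizes 81/24/10/16. Each subtype owns a disjoint block of
`n_markers_per_subtype` (default 60) marker genes whose cartilage means are
multiplied by 2^`marker_log2fc` (default 2.0) in that subtype's patients.

**Crosstalk.** Each subtype owns `n_planted_crosstalk_per_subtype` (default
20) ligand-receptor pairs assigned to one directed tissue pair. Planted
ligand/receptor genes sit at a low baseline mean (0.05, i.e. CPM ≈ 0.2,
below the 1-CPM expression threshold with high probability) and are boosted
64-fold in the planted (tissue, subtype), which puts them at ≈ 13 CPM — so
the per-patient co-expression rule fires for the planted direction and
subtype and essentially nowhere else. The emitted ligand-receptor table
contains every planted pair plus random filler pairs over the remaining
genes.

**Clinical scores.** Osteophyte ~ Binomial(12, p_s) with p elevated in C2
(0.62 vs 0.35), JSN ~ Binomial(6, q_s) with q elevated in C4 (0.68 vs
0.35), age ~ Normal(μ_s, 6) with the C3 mean lowered by 10 years, KL
uniform on {3, 4}. `clinical_effect_scale` scales all shifts; 0 gives the
null cohort used for type-I-error checks.

**Seeds.** All randomness flows from `seed`; identical configs give
bit-identical output. `biology_seed` (default: `seed`) separately seeds the
gene-level plan — marker blocks, crosstalk pairs, base means, the LR table
and gene sets — so an external validation cohort generated with a fresh
`seed` but the discovery run's `biology_seed` shares its planted biology
while resampling patients, noise and clinical scores. This is what makes
external-classification transfer measurable in simulation.

**What the simulation does not capture.** Real cohorts carry batch/center
effects, correlated gene modules, compositional (cell-mixture) variation,
gradual rather than block-structured subtype differences, and
platform-specific noise. Passing the recovery tests shows the pipeline's
machinery is correct and well-calibrated on its stated generative model; it
does not certify discovery power on real tissue.

## QC and normalization

Filters follow fixed, documented boundary semantics: the depth window is
inclusive at both ends ("lower/higher than" exclusions in prose imply the
bounds themselves are kept); the minimum-expression rule is strict
(CPM > 5, so exactly 5.0 fails); variances use the n−1 denominator on
log2(CPM+1). The scale of the control-variance threshold (3) is not
externally fixed; this package computes it on log2(CPM+1), where 3 is a
meaningful cutoff for a log-scale variance. CPM is computed once, before
gene filtering, and not re-normalized afterwards. Highly variable genes are
the top-n by log2(CPM+1) standard deviation with lexicographic tie-breaks.

## Consensus clustering

Base solutions: {Euclidean, Pearson (1−r), Spearman (1−rank-r)} sample
distances × {PCA of the distance matrix, symmetric normalized graph
Laplacian of A = exp(−D/max D)} × embedding dimensions d from ⌈0.04·N⌉ to
⌊0.07·N⌋ (at least one value), k-means with 10 restarts and 300 iterations,
seeded per combination. The Laplacian embedding drops the trivial
(constant) eigenvector and keeps the d next-smallest — at very small N the
d-range collapses to d = 1, where the trivial vector carries no partition
information and would otherwise randomize the base solutions. Embedding
column signs are fixed (largest-magnitude entry positive) for determinism.

The consensus matrix of co-clustering fractions (diagonal exactly 1) is cut
with complete linkage on 1 − consensus; clusters are renumbered by
decreasing size with lexicographic tie-breaks. Model selection maximizes
the mean silhouette width under the 1 − consensus distance across the
(n_hvg, k) grid; ties resolve toward smaller k then smaller n. A
single-cluster degenerate cut scores silhouette −1. `force_k` restricts
the argmax to one k, for when the cluster count is chosen on grounds other
than the silhouette (e.g. clinical interpretability).

## Markers and differential expression

Marker AUROC uses the Mann–Whitney identity (ranks; ties at half weight);
an exhaustive pair-enumeration oracle checks it in the tests. P-values are
two-sided Wilcoxon rank-sum (asymptotic, tie-corrected), BH-adjusted across
genes within each cluster; the adjustment scope (per cluster) and the
AUROC floor (0.6) are this package's defaults and are configurable. A gene
is reported only for its argmax-AUROC cluster, so marker sets are disjoint.

Differential expression substitutes a self-contained Welch t-test on
log2(CPM+1) with pseudocount-1 CPM fold changes for a negative-binomial
GLM; the retained set uses |FC| > 4 at BH FDR < 0.05. Genes with zero
variance in both groups are assigned p = 1 (equal means) or p = 0 (exact
separation) explicitly. The result is antisymmetric under swapping the two
groups.

## Crosstalk

The per-patient co-expression rule (ligand ≥ 1 CPM in the source tissue AND
receptor ≥ 1 CPM in the target tissue), the expressed-pair cutoff
(occurrence ratio ≥ 0.5) and the highly-expressed cutoff (≥ 0.9) are
explicit, configurable defaults chosen to mirror common bulk
ligand-receptor practice. Patients missing either tissue are excluded
pair-wise (evaluable-set semantics); a direction with no evaluable patients
is flagged, never scored 0. "High" implies "expressed" regardless of the
two thresholds' relative order, so per-direction counts always satisfy
0 ≤ high ≤ expressed ≤ database size. Enrichment of crosstalk genes is a
one-sided hypergeometric tail over a caller-supplied background with BH
correction across sets.

## Clinical statistics

The Cochran–Armitage trend statistic uses the closed form
T = Σ t_i (r_i − n_i p̄), Var = p̄(1−p̄)[Σ t_i² n_i − (Σ t_i n_i)²/N],
Z = T/√Var with a two-sided normal p; Z² equals the standard χ² trend
statistic (checked numerically). Scores are the native clinical values
(observed osteophyte/JSN/KL categories; age binned at 55/65/75 years —
the bin edges are this package's choice). Tests are two-sided; each
clinical score's pairwise tests form one BH family. The rank-sum test uses
exact enumeration over all C(n, n_x) group labelings (midranks, valid under
ties) for n ≤ 12 and the tie-corrected continuity-corrected normal
approximation otherwise. Fisher's exact test covers 2×2 tables exactly and
r×k tables by seeded Monte Carlo over fixed-margin tables.

## Classifier

Features are within-sample fractional ranks over the marker genes
(monotone-transform invariant, hence robust to TPM/FPKM/CPM scale
differences between platforms); genes missing from an external matrix are
imputed at rank 0 and reported. The forest uses 500 trees, √p features per
split, out-of-bag scoring, and is fully seeded. Absent classes appear in
composition tables as zero-count rows; percentages are count/total×100 at
one decimal.

## Problem sizes

The test suite and acceptance script run on simulated cohorts of 40–200
patients with 400–6 000 genes and grids of 1–10 (n_hvg, k) points — sizes at
which every stage's behavior (recovery, negative controls, boundary
semantics) is measurable while the full suite stays fast. The acceptance
script uses the 131-patient default cohort with the full 6 000-gene
universe.

## Known limitations

- The DE test is a log-scale Welch t, not a count-model GLM; dispersion
  shrinkage and low-count behavior differ from negative-binomial methods.
- Consensus clustering recomputes all base solutions per grid point; for
  cohorts far larger than a few hundred samples the grid search cost grows
  quadratically in samples.
- The crosstalk statistic treats patients as exchangeable within subtype
  and ignores within-patient correlation across pairs sharing a gene.
- No batch/center correction is applied; center is carried in the metadata
  only.
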