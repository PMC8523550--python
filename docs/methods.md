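# Methods

This note documents the models, parameter choices and known limitations of
`ptcatlas`. The package implements the computational core of a combined
single-cell + bulk transcriptomic analysis of papillary thyroid carcinoma
(PTC): signature scoring, bulk-referenced malignancy classification of single
cells, tissue-preference statistics, trajectory gene screens and PAG-based
molecular subtyping, together with the synthetic cohorts used to exercise
them.

## The synthetic cohorts

Real PTC cohorts of this design (tumor/paratumor bulk RNA-seq with mutation
calls; droplet scRNA-seq of thyrocytes across paratumor, tumor, lymph-node
and distant-metastatic tissue) are controlled-access and far beyond desk
scale, so the generator plants the *structure* the methods assume and the
tests measure recovery of that structure. What the generator emulates, and
what it deliberately does not, determines what a green test suite can and
cannot say about real data.

### Shared gene-effect model

A single latent coordinate t ∈ [0, 1] drives both data types: pseudotime for
cells, a per-sample "malignancy coordinate" for bulk tumors. Per gene, the
log2 mean shift at coordinate t is a line through the origin with slope:

| gene set                 | size (default) | slope            |
|--------------------------|----------------|------------------|
| TDS panel                | 13             | −effect_size     |
| BRAF signature stand-in  | 36             | +effect_size     |
| RAS signature stand-in   | 35             | −effect_size     |
| planted PAGs             | 60             | ±effect_size (alternating) |
| mitochondrial (`MT-…`)   | 20             | 0                |
| null genes               | remainder of 1000 | 0             |

`effect_size` defaults to 2 log2 units across the full coordinate range — a
4-fold change, chosen as a strong but realistic bulk-level separation; the
underlying study reports no effect magnitudes, so this is a free modeling
choice, fixed once. The BRAF+RAS stand-ins together form the 71-gene BRS
signature (the real 71-gene list is user-supplied in production use; it is
referenced but not printed in public sources).

Gene baselines sit on a log-normal grid (null genes N(0, 1.5²) in log2);
signature and PAG genes draw from a tighter high band (N(2.5, 0.6²)),
reflecting that the real panels (TG, TPO, …) are among the most abundant
thyrocyte transcripts — and, practically, that genes averaging ~1 count per
cell cannot carry a correlation signal through shot noise.

### Bulk cohort

Paratumors draw t ~ U(0, 0.25); tumors draw t by planted subtype — RAS-like
U(0.45, 0.6), BRAF-like-A U(0.6, 0.8), BRAF-like-B U(0.8, 1.0) — so TDS
ordering (RAS-like > A > B) and the BRAF-score gradient emerge from the
model rather than being painted per group. Mutation labels align with
subtype (RAS-mut → RAS-like, BRAF-mut split between A and B). Subtypes are
additionally separated by a fingerprint on the planted PAG block (A perturbs
the first half, B the second, each ± half the single-cell effect,
mass-balanced so TPM renormalization does not distort ranks of unrelated
genes). Expression adds per-gene N(0, 0.5²) log2 noise and is column-scaled
to TPM (sums to 10⁶ exactly). A validation cohort can be drawn over the
*same* gene universe through an independent sample stream
(`generate_reference_cohort(cfg, stream="bulk_validation")`), mirroring how
a real validation cohort shares the transcriptome with the reference.

### Single-cell dataset

Five states with pseudotime intervals: normal U(0, 0.2), premalignant
U(0.15, 0.32), follicular-like U(0.48, 0.75), pEMT-like and dediff-like
U(0.65, 1.0). The trajectory bifurcates at t = 0.4: cells beyond it carry a
branch label (pEMT-like → A, dediff-like → B, follicular-like split at
random), cells before it sit on the shared root. The gap between
premalignant (≤ 0.32) and malignant (≥ 0.48) states mirrors the bulk
paratumor/tumor gap, which is what gives the malignancy classifier a margin;
the mean ordering normal < premalignant < malignant is a generator
invariant.

Counts are negative binomial with inverse-size `dispersion` (default 0.12;
variance = μ + 0.12 μ², the overdispersion of a typical UMI protocol;
dispersion → 0 recovers Poisson, which a test verifies under constant
library sizes). Library sizes are log-normal (median 2200, σ = 0.6) so a
few percent of cells fall outside the 500–5000 UMI QC window in both
directions. Mitochondrial genes take a per-cell Beta(2, 28) mass fraction
(mean ≈ 6.7%), putting a realistic tail of cells above the 10% QC cap.

At these defaults the planted PAGs correlate with pseudotime at |r| ≳ 0.3
(the documented floor); at deeper sequencing (median ~6000 UMIs) the
correlations exceed 0.5, and a test pins each regime.

### What the generator does not model

No immune or stromal compartments, ambient RNA, doublets, batch effects, or
patient-level structure; bulk noise is i.i.d. per gene rather than
correlated across pathways; cells within a state are exchangeable. Passing
tests therefore demonstrate correctness of the statistics and recoverability
under the planted model — not robustness to the full messiness of real
cohorts.

## Method implementations and choices

**QC** (`preprocess.qc_filter`): retain cells with 500 ≤ UMI ≤ 5000 and
mitochondrial fraction ≤ 10% (boundaries inclusive); the report records each
cell's metrics and failure reason. Filtering is idempotent.

**Normalization**: ln(1 + count/total × 10⁴) per cell; zero-total cells are
an error naming the cell.

**HVG selection**: default is a variance-stabilizing statistic (lowess trend
of log10 variance on log10 mean over raw counts; per-gene standardized
values clipped at √n; genes ranked by the variance of the standardized
values). A simpler mean-binned normalized-dispersion ranking is available
via `method="dispersion"`. Ties break by gene name for determinism. The
production default of n = 2000 scales to 500 on the 1000-gene synthetic
universe (same ~minority fraction of the transcriptome).

**DEG screen**: a gene passes iff expressed in > 20% of cells in at least
one group ("either or both" read as OR), |log2FC| > 0.5 with
log2FC = log2((mean expm1 + 1)/(mean expm1 + 1)) (pseudocount avoids
division by zero; the FC estimator is otherwise unspecified upstream), and
Bonferroni-adjusted Wilcoxon rank-sum p < 0.01. The Wilcoxon p is exact for
groups ≤ 20 without ties, else the tie-corrected normal approximation.

**Module score**: genes are cut into 24 equal-frequency bins by average
expression; per signature gene, 100 controls are sampled without replacement
from its bin (with replacement plus a warning when the bin is smaller — on
the 1000-gene universe the analysis drivers use n_ctrl = 30, matching the
~41-gene bins); the score is mean(signature) − mean(union of controls).
Signature genes are not excluded from control pools, so a signature spanning
the whole universe scores ≈ 0. All sampling derives from a named child
stream of the master seed.

**BRS**: "normalized Euclidean distance" is implemented as Euclidean
distance on per-gene z-scored expression across the scored cohort, which
makes the 71 genes commensurate. BRS = 0 maps to RAS-like (negative BRS is
the BRAF-like criterion). Zero-variance genes are excluded with a warning;
`normalize=False` exposes the raw arithmetic for closed-form checks.

**TDS**: bulk TDS sums the 13 median-centered log2(TPM+1) terms; whether the
original statistic sums or averages is not fully pinned in public
descriptions, so `reduce="mean"` is exposed (sum is the default, making
"sum of log2 fold change" literal). Base 2 is used throughout.

**Malignancy KNN**: bulk reference stored as per-sample average ranks over
the HVG ∩ bulk gene intersection; cells ranked per cell on log-normalized
values (Spearman renders the bulk-TPM vs cell-log scale question moot).
Top-k (k = 9, odd so a binary vote cannot tie) by correlation descending;
boundary ties break lexicographically by sample id. Cells' genes missing
from the reference are zero-filled (10x matrices are dense over the gene
dimension; absence means unmeasured) and flagged; zero-variance cells are
returned "unclassifiable" rather than silently assigned.

**Ro/e**: observed/expected with chi-square expected counts; reported
descriptively, with the whole-table chi-square p as an auxiliary column.
Zero-count tissues are dropped (their expectation would be 0).

**Trajectory screens**: Pearson correlation for both screens (the TDS screen
names Pearson explicitly; the PAG screen's flavor is unspecified, and
Spearman is available behind `method="spearman"`). PAG selection applies BH
at 0.05 *before* the top-N cut as a principled default even though no
correction is described upstream; n_top defaults to 480. Cells with NA
pseudotime are dropped, not imputed. Zero-variance genes get r = 0, p = 1.

**Subtyping**: Ward linkage on Euclidean distance of per-gene z-scored
log2(TPM+1) over the PAG list, cut at exactly 3 clusters (the figure-level
convention), with complete/average linkage configurable. Clusters map to
labels by decreasing mean TDS (mean BRS breaks ties): highest → RAS-like,
then BRAF-like-A, lowest → BRAF-like-B. Joint clustering of all samples is
the default; a split mode (binary BRS call first, then subcluster the
BRAF-like samples into two) covers the alternative reading of the original
design. A degenerate cohort (no informative PAG genes) is centered rather
than z-scored and flagged, keeping the assignment total.

## Problem sizes

All shipped analyses and tests run on 1000-gene universes: 100-sample
reference cohorts + 500-cell datasets for classification, 150-tumor cohorts
for subtyping, 30 planted PAGs for the recovery screen, ten seeds per
recovery claim. These sizes keep every property measurable (≥ 200 null genes
for error-rate checks, ≥ 3 SE resolution on proportions) while the full
suite runs in seconds.

## Known limitations

The PAG-recovery test screens the non-signature gene space, because the
TDS/BRAF/RAS panels are themselves monotone along pseudotime by construction
and would otherwise compete with the 30 planted PAGs for the top-30 cut —
recovery there measures the screen's ability to separate monotone from null
genes, not to distinguish overlapping planted signals. Validation
sensitivity of the bulk classifier runs a few points below its single-cell
accuracy: RAS-like tumors sit closest to the paratumor boundary and
occasionally fall to majority-paratumor neighborhoods at this reference
size. Exact Wilcoxon p-values fall back to the tie-corrected normal
approximation when ties occur in small groups. The module-score expectation
identity (score ≈ mean(signature) − mean(bin means)) holds only
approximately under the union-of-controls convention when control draws
overlap.
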