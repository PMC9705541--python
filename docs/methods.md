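# Methods

`il2tome` implements the statistical analysis of a longitudinal single-cell
multiomics study of interval low-dose IL-2 (iLD-IL-2) immunotherapy: 13
participants with type 1 diabetes, treated on a 3-day dosing interval with
0.2–0.47 × 10⁶ IU/m² aldesleukin, sampled at Day 0 (baseline), Day 27 (end of
dosing) and Day 55 (one month after the last dose). Five flow-sorted
populations (CD4⁺ CD127^low CD25^hi Treg, CD4⁺ CD25^−/low Tconv, CD8⁺ T,
CD56^br NK, CD56^dim NK) were pooled at designated proportions
(30/25/25/12/8 %) and profiled on a targeted panel (~565 mRNA probes + 65
surface proteins), with and without in vitro stimulation. Because the
deposited count matrices are not bundled, a synthetic-cohort generator with a
full ground-truth record stands in for the raw data; every downstream stage
is exercised and validated against that truth.

## Synthetic cohort generator (`synthetic_data`)

The generator reproduces the *statistical structure the analysis assumes*,
not any estimate from the deposited data — the study provides no generative
model, so all distributional choices below are documented stand-ins.

- **Counts.** mRNA and protein counts are negative binomial with mean μ and
  dispersion α (variance μ + αμ²), the same family the differential
  expression model fits. Cell-level gene dispersions are drawn uniformly from
  0.2–0.8; protein dispersions 0.1–0.4; a per-cell lognormal size factor
  (σ = 0.3) induces realistic library-size variation.
- **Clusters.** Each sorting gate carries a fixed baseline composition of
  named clusters (naive/memory FOXP3⁺HELIOS⁺ Tregs, CD25⁺ FOXP3⁻HELIOS⁻
  Teffs, CD25⁺ T_FH, CXCR5⁺ T_CM, CXCR5^low IL-21⁺ cells, MAIT, Vγ9Vδ2,
  CD56^br/CD56^dim NK subsets, plus small B-cell and CD4⁻CD8⁻ contamination
  clusters). Clusters differ through canonical markers (FOXP3, IKZF2, CD45RA,
  CD25, CXCR5, SLC4A10, TRDV2, CD56/CD16, …) and ~30 incidental filler genes
  each; signature and cell-cycle genes are excluded from those incidental
  profiles so composition shifts cannot masquerade as expression effects.
- **Planted composition effects** are *frequency multipliers*: a cluster with
  multiplier m at a visit has exactly m × its baseline within-gate frequency
  (remaining clusters rescaled to close the simplex), so the planted log2
  fold change is log2(m) by construction. Defaults mirror the study's
  direction of effect: naive Tregs ×2 at Day 27, CD25⁺ Teffs and T_FH down,
  MAIT/Vγ9Vδ2 down at Day 27 persisting at Day 55, activated CD56^br up.
- **Day-55 signature.** Ten up-genes (CISH, TNFSF14, TNFSF10, STAT1, SGK1, …)
  and ten down-genes (AREG, NFKBIZ, NFKBIA, RGS1, TNFAIP3, …) are shifted by
  ±0.6 log2 units in **all** clusters at Day 55. At Day 27 the shift is
  (dose − 0.32) × κ with concordance coefficient κ = 4 log2FC per 10⁶ IU/m²:
  high-dose participants change concordantly with Day 55, low-dose
  participants discordantly. The pivot 0.32 is the middle dose; the study
  reports the dose association without a functional form.
- **Tags.** Each cell's sample tag encodes (visit, gate pool); Treg+CD56^dim
  and Tconv+CD56^br share tags as in the wet-lab pooling. Signal tags are
  NB(150, 0.15), background Poisson(0.3); multiplets (3 %) receive a second
  signal tag; dropout cells receive background only, at 30 % in the CD56^br
  gate (whose barcoding was unreliable) and 2 % elsewhere.
- **Cycling cells** are 0.7 % of unstimulated cells (mirroring the reported
  0.72 %), with the 11 cell-cycle panel genes at mean 4; none are generated
  under stimulation. IL-21 is expressed only in stimulated T_FH-like
  clusters, with the IL-21⁺ fraction reduced ×0.6 at Day 27.
- **FACS counts** are lognormal around baseline × planted visit multipliers
  (Treg ×1.4 at Day 27; CD56^br ×1.8), σ = 0.10 — noise chosen so the mean
  recovered ratio stays within ~1 % of the multiplier (lognormal ratio bias
  e^{σ²} ≈ 1.01).
- **Suppression assay:** 12 participants × 3 visits × ratios 0:1/1:4/1:2/1:1
  × 5 replicates; Teff-alone CPM ~20,000 with multiplicative noise
  (σ = 0.15); suppression fractions 0.35/0.55/0.70; two planted low-CPM
  samples (Teff-alone ≈ 800) exercise the 1,000-CPM exclusion, mirroring the
  two samples the study excluded.
- **Pseudo-bulk-level simulator.** Calibration and power studies
  (null LRT rate, signature recovery, dose-response power) use
  `generate_pseudobulk_counts`, which draws sample-level NB counts around the
  composition-weighted cluster means directly (per-gene dispersion lognormal
  with mean 0.02, participant effects σ = 0.1, library effects σ = 0.2).
  Aggregating thousands of cells makes this an accurate and much cheaper
  surrogate for summing simulated cells. The 0.02 dispersion corresponds to
  a residual within-participant CV of ~15 % for a sorted, longitudinally
  resampled cell population — the regime in which a 0.6 log2FC effect is
  reliably detectable at 13 participants, which is what the study's own gene
  lists imply.

What the generator does **not** emulate: ambient RNA, UMI collisions and
sequencing error correction, batch chemistry, doublet expression profiles for
tag multiplets (their tags are doubled, their transcriptomes are not), and
any real correlation structure between genes beyond cluster membership.
Tests passing on this cohort therefore validate the analysis logic and its
statistical calibration, not robustness to those artifacts.

## Demultiplexing, doublets, QC (`demux_qc`)

Tag calling uses a two-condition presence rule (count ≥ 10 and ≥ 0.3 × the
cell's top tag): 0 present tags → "tag N/A", 1 → singlet, ≥2 → multiplet.
The vendor pipeline's exact rule is not public; this surrogate is the
simplest that yields all three labels and achieves >99 % accuracy at the
simulated signal/background separation.

Doublet scoring follows the simulated-doublet principle: synthetic doublets
are raw-count sums of random pairs of cells, sampled only from non-multiplet
cells, while every observed cell (multiplets included) is scored as the
fraction of simulated doublets among its k = 30 nearest neighbours in a
30-component joint PCA of the log-/CLR-normalized concatenated modalities,
fitted on observed + simulated profiles together. The pipeline scores each
participant's cells separately, matching the per-sample processing of the
assay.

QC removes cells by the first matching criterion: (1) tag multiplets and
clusters whose median doublet score exceeds the 95th percentile of all cell
scores; (2) tag N/A cells except in CD56^br NK clusters; (3) clusters with
median mRNA totals below 10 % of the global median *and* protein totals
outside [10 %, 1000 %] of the global median; (4) clusters annotated as B-cell
or monocyte contamination; (5) CD4⁻CD8⁻ T cells. Thresholds (the percentile,
the 10 % bounds) are configurable; the study names the criteria without
values. Samples whose retained unstimulated cells fall below a cutoff are
excluded from all downstream analyses but kept through clustering; the
study-scale cutoff is 1,000 cells (~8 % of a typical sample's yield), and
the pipeline scales the cutoff by that same fraction at reduced simulation
scale so the planted low-yield sample remains the one excluded.

## Normalization and clustering (`normalize_cluster`)

mRNA: x̃ = ln(1 + 10⁴·c/total). Protein: centred log-ratio with pseudo-count
1 (the common convention for counts; unspecified in the source). Both
matrices are regressed feature-wise on detected-feature counts and the
participant of origin; residuals are z-scored. Clustering takes the top 10
PCs per assay, variance-normalizes each assay block, concatenates, builds a
k = 30 shared-nearest-neighbour graph (Jaccard weights, pruned at 1/15) and
runs Leiden community detection under the RB configuration (modularity)
objective at the configured resolution, seeded. This concatenated-PC SNN
graph replaces the weighted-nearest-neighbour construction of the original
workflow: it keeps "both assays contribute" while remaining simple and
deterministic; it is a documented deviation, as is covariate regression in
place of CCA/MNN anchor integration (adequate at this scale because the
generator has no batch effects beyond participant). Clusters under 10 cells
are dissolved and their cells reassigned to the nearest surviving centroid —
the original removed such cells; reassignment conserves frequency
denominators and is logged. NK partitions cluster on RNA alone (their
protein staining is unreliable). Final per-partition resolutions: Treg 0.6,
Tconv 0.5, CD8 0.5, NK 0.3, cycling 0.5 unstimulated; 0.5/0.4/0.5/0.5
stimulated.

Annotation is a first-match marker rule table: positivity means >50 % of the
cluster's cells have ≥1 raw count of the marker. The rules encode the
published definitions (naive Treg = CD45RA⁺FOXP3⁺HELIOS⁺, memory Treg =
CD45RA⁻FOXP3⁺HELIOS⁺, CD25⁺ Teff = FOXP3⁻HELIOS⁻, etc.); the original
annotation was manual, so the table is a surrogate that makes annotation
testable — labels on real data may differ. Clusters whose mean proliferation
score (11 cell-cycle genes minus 50 random control genes, seeded) exceeds
0.5 are labelled cycling before any marker rule.

## Differential abundance (`diff_abundance`)

Frequencies are computed within (participant, visit, stimulation, sorting
gate), excluding low-yield samples and cells that clustered away from their
sorting gate — gates are the only valid denominators because the pooling
proportions are arbitrary. Contrasts (Day 27 vs 0, Day 55 vs 0) use a
two-sided paired Wilcoxon signed-rank test: zero differences discarded,
exact p by the distribution of W⁺ over all 2ⁿ sign assignments (computed by
convolution over the doubled ranks, so tied ranks are handled exactly) for
n ≤ 25 — all cohort-scale tests are exact at n = 13 — and a tie- and
continuity-corrected normal approximation beyond. Benjamini–Hochberg
correction is applied after pooling all p-values of a run. Per-participant
log2 fold changes use half the table's smallest nonzero frequency as an
additive pseudo-frequency when one side is zero.

## Pseudo-bulk differential expression (`pseudobulk_de`)

Raw counts are summed per (participant × visit × cell group × stimulation);
size factors are median-of-ratios normalized to geometric mean 1. Per gene,
an NB GLM (log link, size-factor offsets) is fitted for visit (2-df factor)
+ participant and for participant alone; Λ = 2(ℓ_full − ℓ_reduced) is
referred to χ²₂. The LRT therefore tests *any* visit effect; fold changes
per contrast come from the visit coefficients. The gene-wise dispersion is
the maximizer of the Cox–Reid-adjusted profile likelihood (method-of-moments
start, floor 10⁻⁸, two mean-refit cycles), held fixed across both models.
The CR adjustment matters: with 15 mean parameters estimated from 39
samples, unadjusted ML dispersion is biased low and inflates the null
rejection rate several-fold; with it, the measured type-I error at α = 0.05
is ≈ 0.065–0.07. Genes that fail to converge are flagged and excluded from
FDR. BH adjustment is per cell population by default (configurable to
global pooling; the source is not fully explicit — per-population matches
"in at least one cell population" selection).

Fold-change shrinkage is a MAP estimate under a zero-centred Cauchy prior,
with a normal approximation N(β̂, se²) for the likelihood and the prior
scale estimated as √max(mean β̂² − mean se², 10⁻⁴) — the excess spread of
the raw estimates over their sampling noise. This is an analog of
heavy-tailed effect-size shrinkage for small targeted panels, not a
reimplementation of any package. Selection thresholds (|log2FC| ≥ 0.4 with
FDR < 0.01, or FDR < 10⁻¹⁰; the stricter ≥1.2 single-tier variant for
within-cluster IL-21⁺ contrasts) are applied to the maximum-likelihood fold
change; shrunken values determine reported effect sizes and direction calls,
with cross-population direction conflicts resolved by majority and ties
dropped with a warning.

## Signature scores and dose response (`signature_dose`)

Normalized pseudo-bulk expression is ln(1 + count/size factor). Within each
cell-group × stimulation dataset, each signature gene is z-scored across all
samples jointly (sample sd, n−1; z-scoring within visit is a configurable
alternative) and the score is Σz(up) − Σz(down). Δ-scores subtract the
participant's Day-0 score; their mean over the cell groups present is
regressed on dose by OLS with a two-sided t-test on the slope, unadjusted.
Paired two-tailed t-tests compare each visit with Day 0 per cell group.
Participant-specific Day-27 fold-change profiles of the signature genes
(ln-scale differences / ln 2 of normalized pseudo-bulk, averaged over cell
groups) are summarized by PC1 of a centred PCA, sign-oriented to correlate
positively with the Day-55 direction — the concordant–discordant axis.

## Absolute counts and suppression (`counts_suppression`)

Absolute subset counts multiply the whole-blood FACS count of the parent
population (cells/µl) by the within-gate single-cell frequency; when the
frequencies partition the gate they sum exactly to the parent count. The
suppression assay averages the five replicate CPMs per condition, excludes
any participant-visit whose Teff-alone mean is below 1,000 CPM (the unit of
the published exclusion rule), and reports
100 − (CPM_with/CPM_without) × 100 per ratio; negative values (enhancement)
are allowed and flagged.

## Scale, determinism, numerical notes

- The default "desk scale" is 5,000 cells per visit (~15,000 cells per
  dataset, ~385 per participant-visit); a full pipeline run takes about a
  minute on one CPU. Calibration studies use the pseudo-bulk-level
  simulator at 2,000 cells/sample. These sizes are the package's default
  study conditions for all reported numbers.
- All randomness flows from one integer seed (child seeds via a seeded
  generator); PCA uses a seeded randomized solver with a fixed sign
  convention, Leiden is seeded, and result tables are written with 12
  significant digits, so identical seed + configuration reproduce
  byte-identical outputs.
- Degenerate inputs: zero-total cells are a hard error at normalization
  (QC removes them first); constant features z-score to zero; collinear
  covariates are dropped with a warning; cell groups whose usable samples
  cannot support the visit+participant design are skipped in DE with a
  warning; paired tests with zero-variance differences are flagged
  degenerate rather than given a p-value.

## Known limitations

- Annotation rules and QC thresholds are surrogates for manual choices in
  the original workflow; on real data the labels would need review.
- The joint-graph construction and the shrinkage prior are analogs, not
  re-implementations, of the cited methods; numerical agreement with those
  packages is not claimed.
- The exact Wilcoxon p-value is discrete at n = 13: uniformity checks must
  account for its atoms (the tests use a randomized probability integral
  transform).
- The NB LRT retains a mild anticonservative tendency (~0.065 at nominal
  0.05) inherited from χ² asymptotics at 39 samples; this is measured and
  within the tolerance the calibration tests assert.
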