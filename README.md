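# il2tome

Analysis pipeline for longitudinal single-cell multiomics of **interval
low-dose IL-2 (iLD-IL-2) immunotherapy**, with a synthetic-cohort generator
so every stage is testable without access to patient data.

Low-dose IL-2 selectively expands regulatory T cells (Tregs) and CD56^bright
NK cells in autoimmune disease. In the study design this package implements,
13 participants with type 1 diabetes received aldesleukin (0.2–0.47 × 10⁶
IU/m²) every three days for four weeks; blood was sampled at Day 0, Day 27
(end of dosing) and Day 55 (one month after). Five flow-sorted populations
(30 % CD4⁺ CD127^low CD25^hi Treg, 25 % CD4⁺ Tconv, 25 % CD8⁺ T, 12 %
CD56^br NK, 8 % CD56^dim NK) were pooled and profiled on a targeted panel
(~565 mRNAs + 65 surface proteins), with sample tags encoding each cell's
visit and sorting-gate pool. The package covers the full analysis chain:

- **`synthetic_data`** — negative-binomial cohort generator with ground
  truth: planted composition effects (e.g. a 2× Day-27 increase in naive
  FOXP3⁺HELIOS⁺ Tregs), a dose-dependent Day-55 expression signature
  (*CISH* up, *AREG* down, …), tag multiplets/dropout, rare cycling cells.
- **`demux_qc`** — sample-tag calling, simulated-doublet scoring, the
  five-criterion QC filter, low-yield sample exclusion, partitioning.
- **`normalize_cluster`** — log / centred-log-ratio normalization,
  latent-variable regression and scaling, joint two-assay SNN-graph Leiden
  clustering, marker-rule annotation, proliferation module scores.
- **`diff_abundance`** — gate-stratified frequencies, exact paired Wilcoxon
  signed-rank tests (enumeration for n ≤ 25), pooled Benjamini–Hochberg FDR,
  per-participant log2 fold changes, IL-21⁺ stratification.
- **`pseudobulk_de`** — pseudo-bulk aggregation, median-of-ratios size
  factors, per-gene negative-binomial likelihood-ratio tests
  (visit + participant vs participant; Cox–Reid-adjusted ML dispersion),
  heavy-tailed MAP fold-change shrinkage, two-tier signature-gene selection.
- **`signature_dose`** — Day-55 signature z-score sums, Δ-scores,
  paired t-tests, dose-response regression, the concordant–discordant PC1.
- **`counts_suppression`** — absolute counts (FACS parent × single-cell
  frequency) and the Treg suppression-assay statistic with its 1,000-CPM
  exclusion rule.

The model at the core of the expression analysis: pseudo-bulk counts
K_gj ~ NB(s_j μ_gj, α_g) with log μ_gj = β₀ + β_visit + β_participant, tested
by Λ_g = 2(ℓ_full − ℓ_reduced) ~ χ²₂; the Day-55 signature score of a sample
is S_j = Σ_{g∈up} z_gj − Σ_{g∈down} z_gj over z-scored normalized expression,
and ΔS = S_t − S_0 is regressed on dose.

## Worked example

```python
from il2tome import pipeline, PipelineConfig

results = pipeline.run_all(PipelineConfig(), seed=1, outdir="out")
tests = results["abundance_tests"]
print(tests[(tests.cell_type == "naive Treg") & (tests.stimulation == "unstim")]
      [["contrast", "median_log2fc", "pvalue", "padj"]])
```

prints (seed 1, default 5,000 cells/visit):

```
     contrast  median_log2fc    pvalue      padj
    d27_vs_d0       1.020541  0.000244  0.002637
    d55_vs_d0      -0.096027  0.497314  0.789852
```

i.e. the generator's planted 2× Day-27 enrichment of naive Tregs is
recovered as a median per-participant log2 fold change of ≈1.0, significant
after pooled FDR correction, and correctly absent at Day 55. The same run's
`results["dose_regression"]` shows a strongly positive Day-27 dose slope for
the mean Δ signature score (p ≈ 2 × 10⁻⁹) and no Day-55 dose dependence —
the planted concordance structure.

The same pipeline is available from a shell:

```bash
il2tome all --seed 1 --outdir out          # full run, deterministic per seed
il2tome simulate --seed 1 --outdir cohort  # just the synthetic cohort
```

## Layout

```
src/il2tome/        library (one module per pipeline stage + config, CLI)
tests/              pytest suite, incl. tests/test_acceptance.py
scripts/acceptance.py
docs/methods.md     model, parameter and design documentation
```
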