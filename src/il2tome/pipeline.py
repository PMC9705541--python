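"""End-to-end orchestration: simulate -> demux -> QC -> cluster -> analyse.

``run_all`` chains every stage on a synthetic cohort and writes all result
tables as TSV.  All randomness derives from the single run seed; two runs
with the same seed and configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import (
    counts_suppression,
    demux_qc,
    diff_abundance,
    normalize_cluster,
    pseudobulk_de,
    signature_dose,
    synthetic_data,
)
from .config import PipelineConfig
from .datamodel_io import MultiomicsDataset, write_dataset, write_tables

logger = logging.getLogger(__name__)

CELL_GROUP_GATES = ["Treg", "Tconv", "CD8", "CD56br", "CD56dim"]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _cell_covariates(dataset: MultiomicsDataset) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "n_genes": np.asarray((dataset.rna_counts > 0).sum(axis=1)).ravel(),
            "n_proteins": np.asarray((dataset.protein_counts > 0).sum(axis=1)).ravel(),
            "participant": dataset.cell_meta["participant"].astype(str).to_numpy(),
        }
    )


def normalize_dataset(dataset: MultiomicsDataset, regress: bool = True):
    """Log-normalize RNA, CLR-normalize protein and z-scale residuals."""
    rna_lognorm = normalize_cluster.lognormalize_rna(dataset.rna_counts)
    protein_clr = normalize_cluster.clr_normalize_protein(dataset.protein_counts)
    covariates = _cell_covariates(dataset) if regress else None
    rna_scaled = normalize_cluster.scale_regress(rna_lognorm, covariates)
    protein_scaled = normalize_cluster.scale_regress(protein_clr, covariates)
    return rna_lognorm, protein_clr, rna_scaled, protein_scaled


def cluster_and_annotate(
    dataset: MultiomicsDataset,
    config: PipelineConfig,
    seed: int,
    resolution: float | None = None,
    rna_only: bool = False,
    with_cycling: bool = True,
):
    """One clustering round: normalize, embed, cluster, annotate.

    Returns (labels, annotation table, module scores or None).
    """
    rna_lognorm, _, rna_scaled, protein_scaled = normalize_dataset(dataset)
    assignment = normalize_cluster.embed_and_cluster(
        rna_scaled,
        None if rna_only else protein_scaled,
        n_pcs=config.cluster.n_pcs,
        k=config.cluster.k,
        resolution=resolution if resolution is not None else config.cluster.resolution,
        seed=seed,
        min_cluster_size=config.cluster.min_cluster_size,
    )
    scores = None
    unstim = (dataset.cell_meta["stimulation"] == "unstim").all()
    if with_cycling and unstim:
        scores = normalize_cluster.score_cell_modules(
            rna_lognorm,
            dataset.gene_names,
            n_control=config.cluster.n_control_genes,
            seed=seed,
        )
    annotation = normalize_cluster.annotate_clusters(
        dataset, assignment.labels, config=config.cluster, module_scores=scores
    )
    return assignment.labels, annotation, scores


def demux_qc_stage(
    dataset: MultiomicsDataset, config: PipelineConfig, seed: int, tag_map: dict
):
    """Tag calling, joint clustering, per-participant doublet scoring, the
    five-criterion filter and low-yield exclusion, then partitioning."""
    calls = demux_qc.call_sample_tags(
        dataset.tag_counts,
        dataset.tag_names,
        min_count=config.demux.min_count,
        min_ratio=config.demux.min_ratio,
    )
    demux_qc.apply_tag_calls(dataset, calls, tag_map)

    labels, annotation, scores = cluster_and_annotate(dataset, config, seed)

    doublet_scores = np.zeros(dataset.n_cells)
    seeds = _spawn_seeds(seed + 1, dataset.cell_meta["participant"].nunique())
    for si, (participant, idx) in enumerate(
        dataset.cell_meta.groupby("participant").groups.items()
    ):
        idx = np.asarray(idx)
        result = demux_qc.score_doublets(
            dataset.subset(idx),
            k=config.doublet.k,
            seed=seeds[si],
            n_pcs=config.doublet.n_pcs,
        )
        doublet_scores[idx] = result.scores

    # The study-scale low-yield cutoff (1000 cells) is ~8% of a typical
    # sample's yield; at reduced simulation scale the cutoff shrinks in
    # proportion so the planted low-yield sample is still the one excluded.
    per_sample = dataset.cell_meta.groupby(
        [dataset.cell_meta["participant"], dataset.cell_meta["visit"]]
    ).size()
    min_cells = int(min(config.qc.min_cells, max(10, round(0.08 * per_sample.median()))))
    filtered, report = demux_qc.apply_qc_filters(
        dataset, labels, annotation, doublet_scores,
        config=config.qc, min_cells=min_cells,
    )
    demux_qc.partition_cells(filtered, annotation=annotation)
    return filtered, report, annotation


def refine_partitions(
    dataset: MultiomicsDataset, config: PipelineConfig, seed: int
) -> MultiomicsDataset:
    """Re-cluster each partition at its configured resolution and refresh the
    per-cell cluster labels and annotations."""
    meta = dataset.cell_meta
    stim = (meta["stimulation"] == "stim").any()
    resolutions = (
        config.cluster.partition_resolutions_stim
        if stim
        else config.cluster.partition_resolutions_unstim
    )
    labels_out = meta["cluster_label"].to_numpy(dtype=object).copy()
    seeds = _spawn_seeds(seed + 2, len(resolutions) + 1)
    for pi, (partition, resolution) in enumerate(sorted(resolutions.items())):
        idx = np.flatnonzero(meta["partition"].to_numpy() == partition)
        if idx.size < max(30, config.cluster.n_pcs + 1):
            continue
        sub = dataset.subset(idx)
        labels, annotation, _ = cluster_and_annotate(
            sub,
            config,
            seeds[pi],
            resolution=resolution,
            rna_only=(partition == "NK" and config.cluster.nk_rna_only),
            with_cycling=False,
        )
        labels_out[idx] = annotation["label"].reindex(labels).to_numpy()
    meta["cluster_label"] = labels_out
    return dataset


def run_all(config: PipelineConfig | None = None, seed: int = 0,
            outdir: str | None = None, refine: bool = True) -> dict:
    """Run the full pipeline on a synthetic cohort; returns all result tables."""
    config = config or PipelineConfig()
    seeds = _spawn_seeds(seed, 12)
    sim = config.simulation
    truth = synthetic_data.build_truth(sim)
    results: dict = {}

    unstim, _ = synthetic_data.generate_dataset(truth, sim, seed=seeds[0])
    stim, _ = synthetic_data.generate_dataset(truth, sim, seed=seeds[1], stimulated=True)
    facs = synthetic_data.generate_facs_counts(truth, sim, seed=seeds[2])
    assay = synthetic_data.generate_suppression_assay(truth, seed=seeds[3])

    datasets = {}
    for name, dataset, ds_seed in (("unstim", unstim, seeds[4]), ("stim", stim, seeds[5])):
        filtered, report, _ = demux_qc_stage(dataset, config, ds_seed, truth.gate_design.tag_map)
        if refine:
            filtered = refine_partitions(filtered, config, ds_seed)
        datasets[name] = filtered
        results[f"qc_report_{name}"] = report.to_frame()

    # Differential abundance (gate-stratified frequencies, paired Wilcoxon).
    freq_frames = []
    for name, dataset in datasets.items():
        ann = dataset.cell_meta.rename(columns={"cluster_label": "cell_type"})
        freq_frames.append(diff_abundance.compute_frequencies(ann))
    frequencies = pd.concat(freq_frames, ignore_index=True)
    results["frequencies"] = frequencies
    results["abundance_tests"] = diff_abundance.abundance_tests(
        frequencies, exact_max_n=config.abundance.exact_max_n
    )

    il21 = diff_abundance.stratify_il21(
        datasets["stim"], threshold=config.abundance.il21_threshold
    )
    results["il21_fractions"] = il21
    results["il21_tests"] = diff_abundance.il21_tests(il21)

    # Pseudo-bulk DE per unstimulated cell group (RNA panel).
    counts, sample_meta = pseudobulk_de.aggregate_pseudobulk(
        datasets["unstim"], modality="rna", min_cells=config.de.min_cells_per_sample
    )
    de_results: dict[str, pd.DataFrame] = {}
    norm_by_group: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for group in CELL_GROUP_GATES:
        mask = (sample_meta["cell_group"] == group).to_numpy()
        if mask.sum() < 6:
            continue
        grp_counts = counts.loc[mask].reset_index(drop=True)
        grp_meta = sample_meta.loc[mask].reset_index(drop=True)
        usable = (
            grp_meta[~grp_meta["low_cell_flag"]]
            if "low_cell_flag" in grp_meta
            else grp_meta
        )
        X_full, _, _ = pseudobulk_de._design_matrices(usable.reset_index(drop=True))
        if len(usable) <= X_full.shape[1] or np.linalg.matrix_rank(X_full) < X_full.shape[1]:
            logger.warning("skipping DE for %s: %d usable samples cannot support "
                           "the visit+participant design", group, len(usable))
            continue
        sf = pseudobulk_de.estimate_size_factors(grp_counts)
        de = pseudobulk_de.fit_nb_lrt(grp_counts, grp_meta, sf, config.de)
        de.insert(0, "cell_group", group)
        de_results[group] = de
        norm_by_group[group] = (
            signature_dose.normalize_pseudobulk(grp_counts, sf), grp_meta
        )
    results["de_results"] = (
        pd.concat(de_results.values(), ignore_index=True)
        if de_results
        else pd.DataFrame()
    )

    up, down = pseudobulk_de.select_signature_genes(
        de_results, contrast="d55_vs_d0",
        fc_cut=config.de.fc_cut, fdr_cut=config.de.fdr_cut, p_cut=config.de.p_cut,
    )
    results["signature_genes"] = pd.DataFrame(
        [{"gene": g, "direction": "up"} for g in up]
        + [{"gene": g, "direction": "down"} for g in down]
    )

    # Day-55 signature scores, Δ-scores, paired t-tests, dose regression.
    score_rows = []
    fc_profiles = []
    for group, (norm, meta) in norm_by_group.items():
        scores = signature_dose.signature_score(norm, up, down)
        frame = meta[["participant", "visit", "cell_group"]].copy()
        if "dose" in meta:
            frame["dose"] = meta["dose"]
        frame["score"] = scores.to_numpy()
        score_rows.append(frame)
        if up or down:
            fc = signature_dose.participant_fold_changes(
                norm, meta, [g for g in up + down if g in norm.columns]
            )
            fc_profiles.append(fc)
    scores_table = pd.concat(score_rows, ignore_index=True) if score_rows else pd.DataFrame()
    results["signature_scores"] = scores_table

    if len(scores_table):
        deltas, mean_delta = signature_dose.delta_scores(scores_table)
        results["delta_scores"] = deltas
        results["mean_delta_scores"] = mean_delta
        ttest_rows = []
        for (group, visit), sub in scores_table.groupby(["cell_group", "visit"]):
            if visit == 0:
                continue
            wide = scores_table[scores_table["cell_group"] == group].pivot_table(
                index="participant", columns="visit", values="score", aggfunc="first"
            )
            if 0 not in wide.columns or visit not in wide.columns:
                continue
            paired = wide[[visit, 0]].dropna()
            if len(paired) < 2:
                continue
            res = signature_dose.paired_t_test(paired[visit], paired[0])
            ttest_rows.append(
                {"cell_group": group, "contrast": f"d{visit}_vs_d0",
                 "t": res.statistic, "pvalue": res.pvalue,
                 "degenerate": res.degenerate, "n": len(paired)}
            )
        results["signature_t_tests"] = pd.DataFrame(ttest_rows)

        dose_rows = []
        for contrast, sub in mean_delta.groupby("contrast"):
            if "dose" not in sub or sub["dose"].nunique() < 2 or len(sub) < 3:
                continue
            fit = signature_dose.dose_regression(sub["mean_delta"], sub["dose"])
            dose_rows.append(
                {"contrast": contrast, "slope": fit.slope, "intercept": fit.intercept,
                 "pvalue": fit.pvalue, "n": fit.n}
            )
        results["dose_regression"] = pd.DataFrame(dose_rows)

        if fc_profiles:
            mean_fc = (
                pd.concat(fc_profiles).groupby(level=0).mean().dropna(how="any")
            )
            if len(mean_fc) >= 2:
                pca = signature_dose.participant_pca(mean_fc, up, down)
                results["participant_pc1"] = (
                    pca.scores.rename_axis("participant").reset_index(name="pc1")
                )

    # Absolute counts: FACS Treg parent x Treg-gate subset frequencies.
    unstim_freq = frequencies[
        (frequencies["stimulation"] == "unstim") & (frequencies["gate"] == "Treg")
    ]
    results["absolute_counts"] = counts_suppression.absolute_subset_counts(
        facs, unstim_freq, parent_gates={"Treg": "Treg"}
    )

    results["suppression_summary"] = counts_suppression.summarize_suppression(assay)
    results["facs_counts"] = facs
    results["suppression_assay"] = assay

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        config.to_yaml(os.path.join(outdir, "config_used.yaml"))
        with open(os.path.join(outdir, "run_info.json"), "w") as fh:
            json.dump({"seed": seed, "config_hash": config.hash()}, fh, indent=2, sort_keys=True)
        for name, table in results.items():
            if isinstance(table, pd.DataFrame):
                write_tables(table, os.path.join(outdir, f"{name}.tsv"))
        write_dataset(datasets["unstim"], os.path.join(outdir, "dataset_unstim"))
    logger.info("pipeline complete: %d result tables", len(results))
    return results
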