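import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from il2tome import demux_qc, synthetic_data as syn
from il2tome.config import QCConfig, SimulationConfig
from il2tome.datamodel_io import MultiomicsDataset
from conftest import make_toy_dataset


class TestTagCalling:
    def test_single_dominant_tag_is_singlet(self):
        calls = demux_qc.call_sample_tags(np.array([[50, 0, 0]]), ["A", "B", "C"],
                                          min_count=10)
        assert calls.loc[0, "call"] == "singlet"
        assert calls.loc[0, "tag"] == "A"

    def test_two_present_tags_is_multiplet(self):
        calls = demux_qc.call_sample_tags(np.array([[40, 35, 0]]), ["A", "B", "C"],
                                          min_count=10, min_ratio=0.5)
        assert calls.loc[0, "call"] == "multiplet"

    def test_all_zero_counts_is_tag_na(self):
        calls = demux_qc.call_sample_tags(np.zeros((3, 4)), list("ABCD"))
        assert (calls["call"] == "tag_na").all()

    def test_subthreshold_second_tag_stays_singlet(self):
        calls = demux_qc.call_sample_tags(np.array([[100, 20, 0]]), ["A", "B", "C"],
                                          min_count=10, min_ratio=0.3)
        assert calls.loc[0, "call"] == "singlet"

    def test_accuracy_on_well_separated_tags(self, dataset_small):
        """Signal tags are >20x background; calls must match truth >= 99%."""
        calls = demux_qc.call_sample_tags(dataset_small.tag_counts,
                                          dataset_small.tag_names)
        meta = dataset_small.cell_meta
        expected = np.where(
            meta["true_multiplet"], "multiplet",
            np.where(meta["true_dropout"], "tag_na", "singlet"),
        )
        correct = (calls["call"].to_numpy() == expected) & (
            (calls["call"] != "singlet")
            | (calls["tag"].to_numpy() == meta["true_tag"].to_numpy())
        )
        assert correct.mean() >= 0.99


class TestDoubletScoring:
    def test_identical_cells_get_identical_scores(self):
        ds = make_toy_dataset(n_cells=30, n_genes=5)
        ds.rna_counts = sp.csr_matrix(np.tile([5, 3, 2, 1, 4], (30, 1)))
        ds.protein_counts = sp.csr_matrix(np.tile([10, 5, 8], (30, 1)))
        out = demux_qc.score_doublets(ds, n_sim=30, k=5, seed=0)
        assert len(set(np.round(out.scores, 12))) == 1

    def test_multiplets_excluded_from_simulation_but_scored(self, dataset_small):
        sub = dataset_small.subset(np.arange(400))
        calls = demux_qc.call_sample_tags(sub.tag_counts, sub.tag_names)
        demux_qc.apply_tag_calls(sub, calls)
        out = demux_qc.score_doublets(sub, n_sim=200, k=10, seed=0)
        assert len(out.scores) == sub.n_cells  # multiplet-tagged cells scored too
        assert np.isfinite(out.scores).all()
        assert ((out.scores >= 0) & (out.scores <= 1)).all()

    def test_too_few_eligible_cells_is_error(self):
        ds = make_toy_dataset(n_cells=3)
        ds.cell_meta["tag_call"] = ["multiplet", "multiplet", "singlet"]
        with pytest.raises(ValueError, match="non-multiplet"):
            demux_qc.score_doublets(ds, n_sim=5, k=2, seed=0)

    def test_planted_cross_population_doublets_score_high(self):
        sim = SimulationConfig(cells_per_visit=500, n_participants=1)
        truth = syn.five_population_truth(sim)
        ds, _ = syn.generate_dataset(truth, sim, seed=2)
        rng = np.random.default_rng(3)
        n, nd = ds.n_cells, 40
        gates = ds.cell_meta["gate"].to_numpy()
        a = rng.integers(0, n, nd)
        b = rng.integers(0, n, nd)
        redo = gates[a] == gates[b]
        while redo.any():
            b[redo] = rng.integers(0, n, int(redo.sum()))
            redo = gates[a] == gates[b]
        full = MultiomicsDataset(
            rna_counts=sp.vstack([ds.rna_counts, ds.rna_counts[a] + ds.rna_counts[b]]),
            protein_counts=sp.vstack(
                [ds.protein_counts, ds.protein_counts[a] + ds.protein_counts[b]]
            ),
            tag_counts=np.vstack([ds.tag_counts, ds.tag_counts[a]]),
            cell_meta=pd.concat([ds.cell_meta, ds.cell_meta.iloc[a]],
                                ignore_index=True),
            rna_features=ds.rna_features,
            protein_features=ds.protein_features,
            tag_names=ds.tag_names,
        )
        out = demux_qc.score_doublets(full, seed=0)
        labels = np.r_[np.zeros(n), np.ones(nd)]
        assert roc_auc_score(labels, out.scores) >= 0.9
        doublet_scores = out.scores[n:]
        assert np.median(doublet_scores) > np.percentile(out.scores[:n], 95)


def _qc_setup(dataset):
    """Ground-truth clusters as labels + a matching annotation table."""
    truth_clusters = dataset.cell_meta["true_cluster"].to_numpy()
    names = sorted(set(truth_clusters))
    labels = np.array([names.index(c) for c in truth_clusters])
    label_map = {
        "naive_treg": ("naive Treg", "Treg"), "memory_treg": ("memory Treg", "Treg"),
        "teff_cd25": ("CD25+ Teff", "Treg"), "tfh_cd25": ("CD25+ TFH", "Treg"),
        "naive_tconv": ("naive Tconv", "Tconv"), "memory_tconv": ("memory Tconv", "Tconv"),
        "tcm_cxcr5": ("CXCR5+ Tcm", "Tconv"), "tph_il21": ("CXCR5low IL21+", "Tconv"),
        "bcell_contam": ("B cell contamination", "contamination"),
        "naive_cd8": ("naive CD8", "CD8"), "memory_cd8": ("memory CD8", "CD8"),
        "mait": ("MAIT", "CD8"), "vd2": ("Vg9Vd2", "CD8"), "dn_t": ("DN T", "contamination"),
        "cd56br": ("CD56br", "NK"), "cd56br_hladr": ("CD56br HLA-DR+", "NK"),
        "cd56dim": ("CD56dim", "NK"), "cd56dim_cyto": ("CD56dim cytotoxic", "NK"),
        "cycling": ("cycling", "cycling"),
    }
    annotation = pd.DataFrame(
        {
            "label": [label_map[n][0] for n in names],
            "group": [label_map[n][1] for n in names],
        },
        index=pd.Index(range(len(names)), name="cluster"),
    )
    return labels, annotation


@pytest.fixture(scope="module")
def qc_run(dataset_small):
    ds = dataset_small.subset(np.arange(dataset_small.n_cells))
    calls = demux_qc.call_sample_tags(ds.tag_counts, ds.tag_names)
    demux_qc.apply_tag_calls(ds, calls)
    labels, annotation = _qc_setup(ds)
    scores = np.zeros(ds.n_cells)
    filtered, report = demux_qc.apply_qc_filters(
        ds, labels, annotation, scores, QCConfig(), min_cells=25
    )
    return ds, filtered, report


class TestQCFilters:
    def test_cells_are_conserved(self, qc_run):
        _, filtered, report = qc_run
        assert sum(report.removed.values()) + report.n_retained == report.n_input
        assert filtered.n_cells == report.n_retained

    def test_multiplets_removed_under_criterion_1(self, qc_run):
        ds, filtered, report = qc_run
        n_multiplet = int((ds.cell_meta["tag_call"] == "multiplet").sum())
        assert report.removed["1_multiplet_or_doublet_cluster"] >= n_multiplet
        assert (filtered.cell_meta["tag_call"] != "multiplet").all()

    def test_tag_na_spared_only_in_cd56br_clusters(self, qc_run):
        _, filtered, _ = qc_run
        na = filtered.cell_meta["tag_call"] == "tag_na"
        assert na.any()  # CD56br dropout cells survive
        assert filtered.cell_meta.loc[na, "cluster_label"].str.startswith("CD56br").all()

    def test_contamination_and_dn_removed(self, qc_run):
        _, filtered, report = qc_run
        assert report.removed["4_contamination"] > 0
        assert report.removed["5_dn_t"] > 0
        labels = filtered.cell_meta["cluster_label"]
        assert not labels.isin(["B cell contamination", "DN T"]).any()

    def test_criterion_counts_invariant_to_cell_order(self, dataset_small):
        ds = dataset_small.subset(np.arange(2000))
        calls = demux_qc.call_sample_tags(ds.tag_counts, ds.tag_names)
        demux_qc.apply_tag_calls(ds, calls)
        labels, annotation = _qc_setup(ds)
        scores = np.linspace(0, 1, ds.n_cells)
        _, r1 = demux_qc.apply_qc_filters(ds, labels, annotation, scores,
                                          QCConfig(), min_cells=1)
        perm = np.random.default_rng(0).permutation(ds.n_cells)
        ds2 = ds.subset(perm)
        _, r2 = demux_qc.apply_qc_filters(ds2, labels[perm], annotation, scores[perm],
                                          QCConfig(), min_cells=1)
        assert r1.removed == r2.removed

    def test_high_doublet_score_cluster_removed(self, dataset_small):
        ds = dataset_small.subset(np.arange(3000))
        calls = demux_qc.call_sample_tags(ds.tag_counts, ds.tag_names)
        demux_qc.apply_tag_calls(ds, calls)
        labels, annotation = _qc_setup(ds)
        scores = np.zeros(ds.n_cells)
        ids, counts = np.unique(labels, return_counts=True)
        small_cluster = ids[counts.argmin()]  # < 5% of cells, so the 95th
        target = labels == small_cluster      # percentile stays at 0
        scores[target] = 1.0
        filtered, report = demux_qc.apply_qc_filters(ds, labels, annotation, scores,
                                                     QCConfig(), min_cells=1)
        assert report.removed["1_multiplet_or_doublet_cluster"] >= int(target.sum())
        assert not np.isin(filtered.cell_meta["cluster"], small_cluster).any()

    def test_low_yield_sample_flagged_excluded(self):
        """A 603-cell sample is excluded at the 1,000-cell threshold while a
        1,200-cell sample survives."""
        rng = np.random.default_rng(0)
        n1, n2 = 603, 1200
        meta = pd.DataFrame(
            {
                "participant": ["P08"] * n1 + ["P01"] * n2,
                "dose": 0.32,
                "visit": [55] * n1 + [0] * n2,
                "stimulation": "unstim",
                "gate": "Treg",
                "tag_call": "singlet",
            }
        )
        n = n1 + n2
        ds = MultiomicsDataset(
            rna_counts=sp.csr_matrix(rng.integers(1, 5, size=(n, 6))),
            protein_counts=sp.csr_matrix(rng.integers(1, 20, size=(n, 3))),
            tag_counts=np.full((n, 2), 50),
            cell_meta=meta,
            rna_features=pd.DataFrame({"name": [f"G{i}" for i in range(6)]}),
            protein_features=pd.DataFrame({"name": [f"P{i}" for i in range(3)]}),
            tag_names=["t1", "t2"],
        )
        annotation = pd.DataFrame({"label": ["memory Treg"], "group": ["Treg"]},
                                  index=pd.Index([0], name="cluster"))
        filtered, report = demux_qc.apply_qc_filters(
            ds, np.zeros(n, int), annotation, np.zeros(n), min_cells=1000
        )
        assert report.samples_excluded == ["P08_d55"]
        excluded = filtered.cell_meta["sample_excluded"]
        assert excluded.sum() == n1
        assert (filtered.cell_meta.loc[excluded, "participant"] == "P08").all()


class TestPartitioning:
    def _partitioned(self, dataset):
        ds = dataset.subset(np.arange(dataset.n_cells))
        labels, annotation = _qc_setup(ds)
        ds.cell_meta["cluster"] = labels
        ds.cell_meta["cluster_label"] = annotation["label"].reindex(labels).to_numpy()
        return demux_qc.partition_cells(ds, labels, annotation)

    def test_groups_follow_cluster_annotation(self, dataset_small):
        meta = self._partitioned(dataset_small)
        treg = meta["cluster_label"] == "naive Treg"
        assert (meta.loc[treg, "partition"] == "Treg").all()
        nk = meta["cluster_label"] == "CD56dim"
        assert (meta.loc[nk, "partition"] == "NK").all()

    def test_cycling_partition_overrides_gate_for_unstim(self, dataset_small):
        meta = self._partitioned(dataset_small)
        cyc = meta["cluster_label"] == "cycling"
        assert cyc.any()
        assert (meta.loc[cyc, "partition"] == "cycling").all()
        assert not meta.loc[cyc, "gate_mismatch"].any()

    def test_no_cycling_partition_for_stimulated_cells(self, stim_dataset_small):
        meta = self._partitioned(stim_dataset_small)
        assert "cycling" not in set(meta["partition"])

    def test_unknown_gate_is_error(self, dataset_small):
        ds = dataset_small.subset(np.arange(50))
        labels, annotation = _qc_setup(ds)
        ds.cell_meta["gate"] = "mystery"
        with pytest.raises(KeyError, match="gate"):
            demux_qc.partition_cells(ds, labels, annotation)
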