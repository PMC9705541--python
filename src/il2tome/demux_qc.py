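"""Sample-tag demultiplexing, doublet scoring, QC filtering and partitioning.

Tag calling uses a two-condition presence rule (absolute count and ratio to
the top tag): zero present tags is "tag N/A", one is a singlet, two or more a
multiplet.  Doublet scoring simulates synthetic doublets by summing random
pairs of non-multiplet cells and scores every cell (including multiplets) by
the fraction of simulated doublets among its nearest neighbours in a joint
PCA space.  The five-criterion QC filter and the low-yield sample exclusion
then remove suspect cells, and the survivors are partitioned into the four
major groups (Treg / Tconv / CD8 / NK) plus cycling cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .config import DemuxConfig, DoubletConfig, QCConfig
from .datamodel_io import MultiomicsDataset
from .normalize_cluster import clr_normalize_protein, lognormalize_rna

logger = logging.getLogger(__name__)

TAG_SINGLET = "singlet"
TAG_MULTIPLET = "multiplet"
TAG_NA = "tag_na"

#: Sorting gate -> major analysis group.
GATE_GROUPS = {"Treg": "Treg", "Tconv": "Tconv", "CD8": "CD8",
               "CD56br": "NK", "CD56dim": "NK"}


# ---------------------------------------------------------------------------
# Tag calling
# ---------------------------------------------------------------------------

def call_sample_tags(
    tag_counts: np.ndarray,
    tag_names: list[str],
    min_count: int = 10,
    min_ratio: float = 0.3,
) -> pd.DataFrame:
    """Call each cell singlet / multiplet / tag N/A from its tag counts.

    A tag is *present* when its count is >= ``min_count`` and >= ``min_ratio``
    times the cell's top tag count.  Returns a frame with columns ``call``,
    ``tag`` (winning tag for singlets, empty otherwise), ``top_count`` and
    ``second_count``.
    """
    counts = np.asarray(tag_counts)
    if np.any(counts < 0):
        raise ValueError("tag counts must be non-negative")
    order = np.argsort(counts, axis=1)
    top_idx = order[:, -1]
    top = counts[np.arange(len(counts)), top_idx]
    second = counts[np.arange(len(counts)), order[:, -2]] if counts.shape[1] > 1 else np.zeros(len(counts))
    present = (counts >= min_count) & (counts >= min_ratio * top[:, None])
    n_present = present.sum(axis=1)
    call = np.where(n_present == 0, TAG_NA,
                    np.where(n_present == 1, TAG_SINGLET, TAG_MULTIPLET))
    tag = np.where(call == TAG_SINGLET, np.array(tag_names)[top_idx], "")
    return pd.DataFrame(
        {"call": call, "tag": tag, "top_count": top, "second_count": second}
    )


def apply_tag_calls(dataset: MultiomicsDataset, calls: pd.DataFrame,
                    tag_map: dict | None = None) -> MultiomicsDataset:
    """Attach tag calls (and the decoded visit/pool, if a map is given) to
    the cell metadata in place; returns the dataset for chaining."""
    meta = dataset.cell_meta
    meta["tag_call"] = calls["call"].to_numpy()
    meta["tag"] = calls["tag"].to_numpy()
    if tag_map is not None:
        meta["tag_visit"] = [
            tag_map[t][0] if t in tag_map else -1 for t in calls["tag"]
        ]
    return dataset


# ---------------------------------------------------------------------------
# Doublet scoring
# ---------------------------------------------------------------------------

class DoubletScores(NamedTuple):
    scores: np.ndarray          # per observed cell, in [0, 1]
    cluster_medians: pd.Series | None


def score_doublets(
    dataset: MultiomicsDataset,
    n_sim: int | None = None,
    k: int = 30,
    seed: int = 0,
    n_pcs: int = 30,
    labels: np.ndarray | None = None,
) -> DoubletScores:
    """Score cells by similarity to simulated doublets.

    Synthetic doublets are raw count sums of random cell pairs, sampled only
    from cells *not* tagged as multiplets, while every observed cell
    (multiplets included) receives a score.  Observed and simulated profiles
    are log-/CLR-normalized, concatenated across modalities and embedded by a
    joint PCA; the score is the fraction of simulated doublets among each
    observed cell's ``k`` nearest neighbours.
    """
    rng = np.random.default_rng(seed)
    n_obs = dataset.n_cells
    if n_sim is None:
        n_sim = 2 * n_obs
    multiplet = (
        dataset.cell_meta["tag_call"].to_numpy() == TAG_MULTIPLET
        if "tag_call" in dataset.cell_meta
        else np.zeros(n_obs, dtype=bool)
    )
    eligible = np.flatnonzero(~multiplet)
    if eligible.size < 2:
        raise ValueError("need at least 2 non-multiplet cells to simulate doublets")

    pair_a = rng.choice(eligible, size=n_sim)
    pair_b = rng.choice(eligible, size=n_sim)
    resample = pair_a == pair_b
    while resample.any():
        pair_b[resample] = rng.choice(eligible, size=int(resample.sum()))
        resample = pair_a == pair_b

    rna = dataset.rna_counts
    prot = dataset.protein_counts
    rna_all = sp.vstack([rna, rna[pair_a] + rna[pair_b]])
    prot_all = sp.vstack([prot, prot[pair_a] + prot[pair_b]])
    joint = np.hstack([lognormalize_rna(rna_all), clr_normalize_protein(prot_all)])

    n_comp = min(n_pcs, joint.shape[1], joint.shape[0] - 1)
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
    coords = pca.fit_transform(joint)

    k_eff = min(k, coords.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(coords)
    _, idx = nn.kneighbors(coords[:n_obs])
    neighbor_idx = idx[:, 1:]  # drop self
    scores = (neighbor_idx >= n_obs).mean(axis=1)

    medians = None
    if labels is not None:
        medians = pd.Series(scores).groupby(np.asarray(labels)).median()
    return DoubletScores(scores=scores, cluster_medians=medians)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input: int
    removed: dict = field(default_factory=dict)     # criterion -> cell count
    n_retained: int = 0
    samples_excluded: list = field(default_factory=list)
    retained_per_sample: dict = field(default_factory=dict)

    def validate(self) -> None:
        if sum(self.removed.values()) + self.n_retained != self.n_input:
            raise AssertionError("QC report does not conserve cells")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"criterion": crit, "cells_removed": n} for crit, n in self.removed.items()
        ]
        rows.append({"criterion": "retained", "cells_removed": self.n_retained})
        return pd.DataFrame(rows)


CRITERIA = (
    "1_multiplet_or_doublet_cluster",
    "2_tag_na",
    "3_low_rna_extreme_protein",
    "4_contamination",
    "5_dn_t",
)


def apply_qc_filters(
    dataset: MultiomicsDataset,
    labels: np.ndarray,
    annotation: pd.DataFrame,
    doublet_scores: np.ndarray,
    config: QCConfig | None = None,
    min_cells: int | None = None,
) -> tuple[MultiomicsDataset, QCReport]:
    """Apply the five-criterion cell filter and the low-yield sample rule.

    Cells are removed by the *first* matching criterion: (1) tag multiplets
    and members of clusters with high median doublet score; (2) tag N/A cells,
    except in CD56br NK clusters (their tagging was unreliable but the mRNA
    library was sound); (3) clusters with very low RNA totals and very low or
    very high protein totals; (4) clusters annotated as monocyte / B cell
    contamination; (5) DN (CD4-CD8-) T cells.  Samples whose retained
    unstimulated cell count falls below ``min_cells`` are flagged excluded
    from downstream analyses (they stay in the dataset for clustering/QC).
    """
    config = config or QCConfig()
    if min_cells is None:
        min_cells = config.min_cells
    labels = np.asarray(labels)
    n = dataset.n_cells
    if len(labels) != n or len(doublet_scores) != n:
        raise ValueError("labels / doublet scores do not match dataset cells")
    if "label" not in annotation.columns:
        raise KeyError("cluster annotation (label column) required by criteria 2, 4 and 5")
    meta = dataset.cell_meta
    calls = meta["tag_call"].to_numpy() if "tag_call" in meta else np.full(n, TAG_SINGLET)

    cluster_label = annotation["label"]
    cell_label = cluster_label.reindex(labels).to_numpy()

    # Criterion 1: multiplets + high-doublet-score clusters.
    threshold = np.percentile(doublet_scores, config.doublet_score_percentile)
    cluster_median = pd.Series(doublet_scores).groupby(labels).median()
    high_doublet = cluster_median > threshold
    c1 = (calls == TAG_MULTIPLET) | high_doublet.reindex(labels).to_numpy()

    # Criterion 2: tag N/A, sparing CD56br NK clusters.
    cd56br = pd.Series(cell_label).str.startswith("CD56br").to_numpy()
    c2 = (calls == TAG_NA) & ~cd56br

    # Criterion 3: cluster-level low RNA with extreme protein totals.
    rna_totals = np.asarray(dataset.rna_counts.sum(axis=1)).ravel()
    prot_totals = np.asarray(dataset.protein_counts.sum(axis=1)).ravel()
    rna_med = pd.Series(rna_totals).groupby(labels).median()
    prot_med = pd.Series(prot_totals).groupby(labels).median()
    g_rna, g_prot = np.median(rna_totals), np.median(prot_totals)
    bad_cluster = (rna_med < config.low_rna_fraction * g_rna) & (
        (prot_med < config.protein_low_fraction * g_prot)
        | (prot_med > config.protein_high_fraction * g_prot)
    )
    c3 = bad_cluster.reindex(labels).to_numpy()

    # Criteria 4 and 5 come from the annotation rule table.
    c4 = pd.Series(cell_label).isin(
        ["B cell contamination", "Monocyte contamination"]
    ).to_numpy()
    c5 = cell_label == "DN T"

    removed = {}
    unmatched = np.ones(n, dtype=bool)
    for crit, mask in zip(CRITERIA, (c1, c2, c3, c4, c5)):
        hit = mask & unmatched
        removed[crit] = int(hit.sum())
        unmatched &= ~hit

    retained = unmatched
    filtered = dataset.subset(retained)
    filtered.cell_meta["cluster"] = labels[retained]
    filtered.cell_meta["cluster_label"] = cell_label[retained]

    # Low-yield sample exclusion (unstimulated cell count per sample).
    fmeta = filtered.cell_meta
    sample_ids = fmeta["participant"].astype(str) + "_d" + fmeta["visit"].astype(str)
    unstim = (
        fmeta["stimulation"].to_numpy() == "unstim"
        if "stimulation" in fmeta
        else np.ones(len(fmeta), dtype=bool)
    )
    if not unstim.any():  # stim-only dataset: judge yield on all its cells
        unstim = np.ones(len(fmeta), dtype=bool)
    per_sample = pd.Series(sample_ids[unstim]).value_counts().to_dict()
    excluded = sorted(s for s, c in per_sample.items() if c < min_cells)
    fmeta["sample_excluded"] = sample_ids.isin(excluded).to_numpy()
    for s in excluded:
        logger.warning("sample %s excluded: %d retained cells < %d",
                       s, per_sample[s], min_cells)

    report = QCReport(
        n_input=n,
        removed=removed,
        n_retained=int(retained.sum()),
        samples_excluded=excluded,
        retained_per_sample=per_sample,
    )
    report.validate()
    return filtered, report


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def partition_cells(
    dataset: MultiomicsDataset,
    labels: np.ndarray | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Partition retained cells into Treg / Tconv / CD8 / NK (+ cycling).

    The partition comes from the cell's cluster annotation group; unstimulated
    cells in cycling clusters go to the cycling partition regardless of gate
    (no cycling partition exists for stimulated cells).  Cells whose sorting
    gate does not correspond to their partition are flagged ``gate_mismatch``
    and excluded from frequency denominators downstream.
    """
    meta = dataset.cell_meta
    if labels is None:
        labels = meta["cluster"].to_numpy()
    if annotation is not None:
        groups = annotation["group"].reindex(np.asarray(labels)).to_numpy()
    elif "cluster_label" in meta:
        raise KeyError("annotation table required to derive partition groups")
    else:
        raise KeyError("no cluster annotation available for partitioning")

    unknown = set(meta["gate"]) - set(GATE_GROUPS)
    if unknown:
        raise KeyError(f"unknown gate labels: {sorted(unknown)}")
    gate_group = meta["gate"].map(GATE_GROUPS).to_numpy()
    stim = meta["stimulation"].to_numpy() == "stim" if "stimulation" in meta else np.zeros(len(meta), bool)

    partition = np.asarray(groups, dtype=object).copy()
    cycling = partition == "cycling"
    # Stimulated datasets have no cycling partition: fall back to the gate group.
    partition[cycling & stim] = gate_group[cycling & stim]
    mismatch = (partition != gate_group) & ~(cycling & ~stim)
    # Cells annotated "other"/contamination count with their gate group but
    # keep their annotation label for frequency numerators.
    fallback = ~np.isin(partition, ["Treg", "Tconv", "CD8", "NK", "cycling"])
    partition[fallback] = gate_group[fallback]
    mismatch[fallback] = False

    meta["partition"] = partition
    meta["gate_mismatch"] = mismatch
    return meta
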