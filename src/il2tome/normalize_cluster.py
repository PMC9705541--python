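"""Dual-modality normalization, scaling, joint graph clustering and annotation.

mRNA counts are log-normalized (``ln(1 + 1e4 * c / total)``); protein counts
are treated as compositional and centred-log-ratio transformed.  Normalized
features are then regressed against latent covariates (detected-feature counts
and participant of origin) and the residuals z-scored.  Clustering builds a
shared-nearest-neighbour graph on concatenated, variance-normalized per-assay
principal components and applies modularity community detection (Leiden, RB
configuration model) at a configurable resolution; clusters under ten cells
are dissolved onto the nearest surviving centroid.  Cluster annotation is a
first-match marker rule table (FOXP3/HELIOS/CD45RA Treg groups and friends),
and the per-cell proliferation score is an 11-gene cell-cycle module score
against 50 random control genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .config import ClusterConfig
from .datamodel_io import MultiomicsDataset

logger = logging.getLogger(__name__)

PROLIFERATION_GENES = [
    "AURKB", "HMGB2", "HMMR", "MCM4", "MKI67", "PCLAF",
    "PCNA", "TK1", "TOP2A", "TYMS", "UBE2C",
]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def lognormalize_rna(counts) -> np.ndarray:
    """x = ln(1 + 1e4 * c / cell_total); scale-invariant within each cell."""
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=float)
    totals = dense.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError(
            f"{int((totals <= 0).sum())} cells have zero total RNA counts; "
            "remove them before normalization"
        )
    return np.log1p(1e4 * dense / totals[:, None])


def clr_normalize_protein(counts, pseudo: float = 1.0) -> np.ndarray:
    """Centred log ratio per cell: ln(c+pseudo) minus its within-cell mean."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be > 0")
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=float)
    if np.any(dense < 0):
        raise ValueError("protein counts must be non-negative")
    logged = np.log(dense + pseudo)
    return logged - logged.mean(axis=1, keepdims=True)


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Greedily drop columns that do not increase the design rank."""
    keep, kept_cols = [], []
    for j in range(X.shape[1]):
        candidate = X[:, keep + [j]]
        if np.linalg.matrix_rank(candidate) > len(keep):
            keep.append(j)
            kept_cols.append(names[j])
        else:
            logger.warning("dropping collinear covariate column %r", names[j])
    return X[:, keep], kept_cols


def scale_regress(normalized: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    """Regress each feature on the covariates; return z-scored residuals.

    Categorical covariate columns (e.g. participant) are dummy-encoded.
    Constant features come back as all-zero columns.
    """
    Y = np.asarray(normalized, dtype=float)
    n = Y.shape[0]
    if covariates is None or covariates.shape[1] == 0:
        resid = Y - Y.mean(axis=0, keepdims=True)
    else:
        enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
        X = np.column_stack([np.ones(n), enc.to_numpy()])
        X, _ = _drop_collinear(X, ["intercept"] + list(enc.columns))
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        resid = resid - resid.mean(axis=0, keepdims=True)
    sd = resid.std(axis=0, ddof=1)
    out = np.zeros_like(resid)
    nz = sd > 1e-12
    out[:, nz] = resid[:, nz] / sd[nz]
    return out


# ---------------------------------------------------------------------------
# Embedding + clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Per-cell cluster labels plus the embedding they were derived in."""

    labels: np.ndarray            # integer cluster id per cell
    embedding: np.ndarray         # cells x (concatenated per-assay PCs)
    cluster_sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids, counts = np.unique(self.labels, return_counts=True)
        self.cluster_sizes = {int(i): int(c) for i, c in zip(ids, counts)}


def _assay_pcs(scaled: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    if scaled.shape[0] <= n_pcs:
        raise ValueError(
            f"need more cells ({scaled.shape[0]}) than components ({n_pcs})"
        )
    n_comp = min(n_pcs, scaled.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
    coords = pca.fit_transform(scaled)
    # Deterministic sign convention: largest-magnitude loading positive.
    signs = np.sign(pca.components_[np.arange(n_comp),
                                    np.abs(pca.components_).argmax(axis=1)])
    signs[signs == 0] = 1.0
    coords = coords * signs
    # Normalize the block so each assay contributes unit total variance.
    total_var = coords.var(axis=0, ddof=1).sum()
    return coords / np.sqrt(max(total_var, 1e-12))


def snn_graph(embedding: np.ndarray, k: int, prune: float = 1.0 / 15.0) -> igraph.Graph:
    """Shared-nearest-neighbour graph with Jaccard edge weights."""
    n = embedding.shape[0]
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), k_eff + 1)
    adj = sp.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n, n)
    )
    shared = adj @ adj.T
    shared = sp.triu(shared.tocoo(), k=1)
    denom = 2.0 * (k_eff + 1) - shared.data
    jaccard = shared.data / denom
    keep = jaccard >= prune
    edges = np.column_stack([shared.row[keep], shared.col[keep]])
    graph = igraph.Graph(n=n, edges=edges.tolist())
    graph.es["weight"] = jaccard[keep].tolist()
    return graph


def embed_and_cluster(
    rna_scaled: np.ndarray,
    protein_scaled: np.ndarray | None,
    n_pcs: int = 10,
    k: int = 30,
    resolution: float = 0.5,
    seed: int = 0,
    min_cluster_size: int = 10,
) -> ClusterAssignment:
    """Joint SNN-graph clustering on concatenated per-assay PCs.

    ``protein_scaled=None`` runs RNA-only mode (used for NK cells, whose
    protein staining is unreliable).  Deterministic given the seed.
    """
    blocks = [_assay_pcs(rna_scaled, n_pcs, seed)]
    if protein_scaled is not None:
        blocks.append(_assay_pcs(protein_scaled, n_pcs, seed))
    embedding = np.hstack(blocks)
    graph = snn_graph(embedding, k=k)
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(partition.membership)
    labels = _dissolve_small_clusters(labels, embedding, min_cluster_size)
    return ClusterAssignment(labels=labels, embedding=embedding)


def _dissolve_small_clusters(
    labels: np.ndarray, embedding: np.ndarray, min_size: int
) -> np.ndarray:
    """Clusters under ``min_size`` cells are dissolved and their cells
    reassigned to the nearest surviving cluster centroid (keeps frequency
    denominators intact)."""
    ids, counts = np.unique(labels, return_counts=True)
    small = set(ids[counts < min_size].tolist())
    survivors = [i for i in ids if i not in small]
    if not small:
        return labels
    if not survivors:
        logger.warning("all clusters below min size %d; keeping labels", min_size)
        return labels
    centroids = np.stack([embedding[labels == i].mean(axis=0) for i in survivors])
    out = labels.copy()
    for cell in np.flatnonzero(np.isin(labels, list(small))):
        d = np.linalg.norm(centroids - embedding[cell], axis=1)
        out[cell] = survivors[int(d.argmin())]
    # Relabel to consecutive ids for stable downstream tables.
    remap = {old: new for new, old in enumerate(sorted(set(out.tolist())))}
    return np.array([remap[v] for v in out])


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationRule:
    """First-match marker rule: '+' markers must exceed the positivity cut,
    '-' markers must stay below it; optionally scoped to majority gates."""

    label: str
    group: str
    markers: dict
    gates: tuple | None = None


#: Default rule table mirroring the manual annotation logic: FOXP3/HELIOS
#: (IKZF2) and CD45RA define the Treg-gate groups; CXCR5/PD-1 the T_FH-like
#: subsets; SLC4A10 and TRDV2 the innate-like CD8 subsets; CD56/CD16 the NK
#: subsets; CD19/CD14 flag contamination.
DEFAULT_RULES = [
    AnnotationRule("B cell contamination", "contamination", {"CD19": "+"}),
    AnnotationRule("Monocyte contamination", "contamination", {"CD14": "+"}),
    AnnotationRule("DN T", "contamination", {"CD4": "-", "CD8": "-", "CD3": "+"},
                   gates=("Treg", "Tconv", "CD8")),
    AnnotationRule("naive Treg", "Treg",
                   {"FOXP3": "+", "IKZF2": "+", "CD45RA": "+"}, gates=("Treg",)),
    AnnotationRule("memory Treg", "Treg",
                   {"FOXP3": "+", "IKZF2": "+", "CD45RA": "-"}, gates=("Treg",)),
    AnnotationRule("CD25+ TFH", "Treg", {"FOXP3": "-", "CXCR5": "+"}, gates=("Treg",)),
    AnnotationRule("CD25+ Teff", "Treg", {"FOXP3": "-", "IKZF2": "-"}, gates=("Treg",)),
    AnnotationRule("CXCR5+ Tcm", "Tconv", {"CXCR5": "+"}, gates=("Tconv",)),
    AnnotationRule("CXCR5low IL21+", "Tconv", {"PD-1": "+", "CXCR5": "-"},
                   gates=("Tconv",)),
    AnnotationRule("MAIT", "CD8", {"SLC4A10": "+"}),
    AnnotationRule("Vg9Vd2", "CD8", {"TRDV2": "+"}),
    AnnotationRule("naive CD8", "CD8", {"CD8": "+", "CD4": "-", "CD45RA": "+"}),
    AnnotationRule("memory CD8", "CD8", {"CD8": "+", "CD4": "-"}),
    AnnotationRule("naive Tconv", "Tconv",
                   {"CD4": "+", "CD45RA": "+", "FOXP3": "-"}, gates=("Tconv",)),
    AnnotationRule("memory Tconv", "Tconv", {"CD4": "+"}, gates=("Tconv",)),
    AnnotationRule("CD56br HLA-DR+", "NK", {"CD56": "+", "CD16": "-", "HLA-DR": "+"}),
    AnnotationRule("CD56br", "NK", {"CD56": "+", "CD16": "-"}),
    AnnotationRule("CD56dim cytotoxic", "NK", {"CD16": "+", "PRF1": "+"}),
    AnnotationRule("CD56dim", "NK", {"CD16": "+"}),
]


def marker_positive_fractions(
    dataset: MultiomicsDataset,
    labels: np.ndarray,
    features: list[str],
    positive_count: int = 1,
) -> pd.DataFrame:
    """Per cluster, the fraction of cells with raw count >= positive_count."""
    cols = {}
    for feat in features:
        try:
            vec = dataset.rna_counts[:, dataset.gene_index(feat)].toarray().ravel()
        except KeyError:
            vec = dataset.protein_counts[:, dataset.protein_index(feat)].toarray().ravel()
        cols[feat] = vec >= positive_count
    frame = pd.DataFrame(cols)
    frame["cluster"] = labels
    return frame.groupby("cluster").mean()


def annotate_clusters(
    dataset: MultiomicsDataset,
    labels: np.ndarray,
    rules: list[AnnotationRule] | None = None,
    config: ClusterConfig | None = None,
    module_scores: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign each cluster the first matching rule label (else "other").

    Clusters whose mean proliferation score exceeds the configured threshold
    are labelled cycling before any marker rule is evaluated.  Raises if a
    rule references a feature absent from both panels.
    """
    rules = rules if rules is not None else DEFAULT_RULES
    config = config or ClusterConfig()
    features = sorted({m for rule in rules for m in rule.markers})
    known = set(dataset.gene_names) | set(dataset.protein_names)
    missing = [f for f in features if f not in known]
    if missing:
        raise KeyError(f"annotation rules reference absent features: {missing}")

    fractions = marker_positive_fractions(
        dataset, labels, features, positive_count=config.positive_count
    )
    gate_mode = (
        pd.DataFrame({"cluster": labels, "gate": dataset.cell_meta["gate"].to_numpy()})
        .groupby("cluster")["gate"]
        .agg(lambda s: s.mode().iloc[0])
    )
    mean_scores = None
    if module_scores is not None:
        mean_scores = (
            pd.Series(module_scores).groupby(labels).mean()
        )

    rows = []
    for cluster in fractions.index:
        label, group = "other", "other"
        if mean_scores is not None and mean_scores.loc[cluster] > config.cycling_score_threshold:
            label = group = "cycling"
        else:
            for rule in rules:
                if rule.gates is not None and gate_mode.loc[cluster] not in rule.gates:
                    continue
                ok = True
                for feat, sign in rule.markers.items():
                    frac = fractions.loc[cluster, feat]
                    if sign == "+" and frac <= config.positive_fraction:
                        ok = False
                    if sign == "-" and frac > config.positive_fraction:
                        ok = False
                if ok:
                    label, group = rule.label, rule.group
                    break
        rows.append(
            {
                "cluster": int(cluster),
                "label": label,
                "group": group,
                "n_cells": int((labels == cluster).sum()),
                "majority_gate": gate_mode.loc[cluster],
            }
        )
    annotation = pd.DataFrame(rows).set_index("cluster")
    logger.info("annotated %d clusters: %s", len(annotation),
                dict(annotation["label"].value_counts()))
    return annotation


# ---------------------------------------------------------------------------
# Module scores and marker classifiers
# ---------------------------------------------------------------------------

def score_cell_modules(
    rna_lognorm: np.ndarray,
    gene_names: list[str],
    module_genes: list[str] | None = None,
    n_control: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Proliferation (module) score: mean normalized expression over the
    module genes minus the mean over ``n_control`` random non-module genes."""
    module_genes = module_genes if module_genes is not None else PROLIFERATION_GENES
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    missing = [g for g in module_genes if g not in name_to_idx]
    if missing:
        raise KeyError(f"module genes missing from panel: {missing}")
    module_idx = [name_to_idx[g] for g in module_genes]
    pool = [i for g, i in name_to_idx.items() if g not in set(module_genes)]
    if n_control > len(pool):
        raise ValueError(
            f"n_control={n_control} exceeds available non-module genes ({len(pool)})"
        )
    rng = np.random.default_rng(seed)
    control_idx = rng.choice(pool, size=n_control, replace=False)
    X = np.asarray(rna_lognorm)
    return X[:, module_idx].mean(axis=1) - X[:, control_idx].mean(axis=1)


def classify_foxp3_positive(dataset: MultiomicsDataset) -> pd.Series:
    """CD25-/low FOXP3+ T cells: >=1 raw FOXP3 copy, evaluated only within the
    Tconv sorting gate (pd.NA outside it)."""
    foxp3 = dataset.rna_counts[:, dataset.gene_index("FOXP3")].toarray().ravel()
    in_gate = dataset.cell_meta["gate"].to_numpy() == "Tconv"
    out = pd.Series(pd.NA, index=dataset.cell_meta.index, dtype="boolean")
    out[in_gate] = foxp3[in_gate] >= 1
    return out
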