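"""Core data model and file I/O for the iLD-IL-2 multiomics pipeline.

The central container is :class:`MultiomicsDataset`: per-cell UMI counts for a
targeted mRNA panel and an oligo-tagged surface-protein (AbSeq-style) panel,
plus per-cell sample-tag counts and cell-level metadata (participant, IL-2
dose, visit day, stimulation status, sorting gate).  Matrices are stored
sparse (CSR) with cells as rows.

On-disk layout is plain text: MatrixMarket coordinate files with companion
``features.tsv`` / ``barcodes.tsv`` tables per modality, and tab-separated
metadata tables.  MTX indices are 1-based on disk per the MatrixMarket
standard; everything in memory is 0-based.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Sorted-gate pooling proportions used when the five populations were mixed
#: before single-cell capture (Treg 30%, Tconv 25%, CD8 25%, CD56br 12%,
#: CD56dim 8%).
DEFAULT_GATE_PROPORTIONS = {
    "Treg": 0.30,
    "Tconv": 0.25,
    "CD8": 0.25,
    "CD56br": 0.12,
    "CD56dim": 0.08,
}

#: Gate pools sharing one sample tag.  Treg was pooled with CD56dim and Tconv
#: with CD56br; the pooled subsets are transcriptionally distant enough to be
#: separated at analysis time.
DEFAULT_GATE_POOLS = {
    "Treg+CD56dim": ("Treg", "CD56dim"),
    "Tconv+CD56br": ("Tconv", "CD56br"),
    "CD8": ("CD8",),
}

VISITS = (0, 27, 55)


class DataValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


@dataclass
class GateDesign:
    """Sorting-gate pooling design: gate proportions and the tag map.

    ``tag_map`` maps each sample-tag name to a ``(visit, pool_name)`` pair and
    ``pools`` maps pool names to the tuple of gates sharing that tag.
    """

    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GATE_PROPORTIONS)
    )
    pools: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GATE_POOLS)
    )
    tag_map: dict[str, tuple[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tag_map:
            self.tag_map = {
                f"tag_d{visit}_{pool}": (visit, pool)
                for visit in VISITS
                for pool in self.pools
            }
        self.validate()

    def validate(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise DataValidationError(
                f"gate proportions sum to {total!r}, expected 1 (±1e-9)"
            )
        pooled = [g for gates in self.pools.values() for g in gates]
        if sorted(pooled) != sorted(self.proportions):
            raise DataValidationError("pools must cover each gate exactly once")
        seen = {}
        for tag, (visit, pool) in self.tag_map.items():
            if pool not in self.pools:
                raise DataValidationError(f"tag {tag!r} maps to unknown pool {pool!r}")
            key = (visit, pool)
            if key in seen:
                raise DataValidationError(
                    f"tags {seen[key]!r} and {tag!r} both map to {key!r}"
                )
            seen[key] = tag

    @property
    def tags(self) -> list[str]:
        return list(self.tag_map)

    def tag_for(self, visit: int, gate: str) -> str:
        """Return the sample tag a cell from ``gate`` at ``visit`` receives."""
        for tag, (v, pool) in self.tag_map.items():
            if v == visit and gate in self.pools[pool]:
                return tag
        raise KeyError(f"no tag for visit {visit}, gate {gate}")


# Columns expected (and written) for cell-level metadata.
CELL_META_COLUMNS = [
    "participant",
    "dose",
    "visit",
    "stimulation",
    "gate",
    "tag_call",
]


@dataclass
class MultiomicsDataset:
    """Cell x feature counts for both modalities plus tags and metadata."""

    rna_counts: sp.csr_matrix
    protein_counts: sp.csr_matrix
    tag_counts: np.ndarray
    cell_meta: pd.DataFrame
    rna_features: pd.DataFrame
    protein_features: pd.DataFrame
    tag_names: list[str]

    def __post_init__(self) -> None:
        self.rna_counts = sp.csr_matrix(self.rna_counts)
        self.protein_counts = sp.csr_matrix(self.protein_counts)
        self.tag_counts = np.asarray(self.tag_counts)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        n = self.n_cells
        for name, mat in (("rna", self.rna_counts), ("protein", self.protein_counts)):
            if mat.shape[0] != n:
                raise DataValidationError(
                    f"{name} matrix has {mat.shape[0]} rows but cell_meta has {n}"
                )
            data = mat.data
            if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
                raise DataValidationError(f"{name} counts must be non-negative integers")
        if self.tag_counts.shape != (n, len(self.tag_names)):
            raise DataValidationError(
                f"tag matrix shape {self.tag_counts.shape} != ({n}, {len(self.tag_names)})"
            )
        if np.any(self.tag_counts < 0):
            raise DataValidationError("tag counts must be non-negative")
        if self.rna_counts.shape[1] != len(self.rna_features):
            raise DataValidationError("rna feature table does not match matrix columns")
        if self.protein_counts.shape[1] != len(self.protein_features):
            raise DataValidationError(
                "protein feature table does not match matrix columns"
            )
        genes = set(self.rna_features["name"])
        prots = set(self.protein_features["name"])
        if len(genes) != len(self.rna_features) or len(prots) != len(self.protein_features):
            raise DataValidationError("feature names must be unique within a modality")
        if genes & prots:
            raise DataValidationError(
                f"gene/protein identifier sets overlap: {sorted(genes & prots)[:5]}"
            )
        missing = [c for c in ("participant", "visit", "gate") if c not in self.cell_meta]
        if missing:
            raise DataValidationError(f"cell_meta missing columns: {missing}")

    # -- convenience ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_meta)

    @property
    def gene_names(self) -> list[str]:
        return list(self.rna_features["name"])

    @property
    def protein_names(self) -> list[str]:
        return list(self.protein_features["name"])

    def gene_index(self, name: str) -> int:
        idx = self.rna_features.index[self.rna_features["name"] == name]
        if len(idx) == 0:
            raise KeyError(f"gene {name!r} not in panel")
        return int(idx[0])

    def protein_index(self, name: str) -> int:
        idx = self.protein_features.index[self.protein_features["name"] == name]
        if len(idx) == 0:
            raise KeyError(f"protein {name!r} not in panel")
        return int(idx[0])

    def subset(self, mask: np.ndarray) -> "MultiomicsDataset":
        """Return a new dataset restricted to the boolean/integer cell mask."""
        mask = np.asarray(mask)
        return MultiomicsDataset(
            rna_counts=self.rna_counts[mask],
            protein_counts=self.protein_counts[mask],
            tag_counts=self.tag_counts[mask],
            cell_meta=self.cell_meta.iloc[mask].reset_index(drop=True)
            if mask.dtype != bool
            else self.cell_meta.loc[mask].reset_index(drop=True),
            rna_features=self.rna_features,
            protein_features=self.protein_features,
            tag_names=self.tag_names,
        )


def _write_mtx(path: str, matrix: sp.spmatrix) -> None:
    # mmwrite stores integer matrices losslessly in coordinate format
    scipy.io.mmwrite(path, sp.coo_matrix(matrix))


def _read_mtx(path: str) -> sp.csr_matrix:
    mat = scipy.io.mmread(path)
    arr = sp.csr_matrix(mat)
    if arr.data.size and np.any(arr.data != np.round(arr.data)):
        raise DataValidationError(f"non-integer counts in {path}")
    return arr


def write_dataset(dataset: MultiomicsDataset, outdir: str) -> None:
    """Write a dataset as MTX + feature/barcode tables + metadata TSVs."""
    os.makedirs(outdir, exist_ok=True)
    barcodes = pd.DataFrame(
        {"barcode": [f"cell{i:07d}" for i in range(dataset.n_cells)]}
    )
    for modality, mat, feats in (
        ("rna", dataset.rna_counts, dataset.rna_features),
        ("protein", dataset.protein_counts, dataset.protein_features),
    ):
        _write_mtx(os.path.join(outdir, f"{modality}_counts.mtx"), mat)
        feats.to_csv(os.path.join(outdir, f"{modality}_features.tsv"), sep="\t", index=False)
    barcodes.to_csv(os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False)
    tags = pd.DataFrame(dataset.tag_counts, columns=dataset.tag_names)
    tags.to_csv(os.path.join(outdir, "tag_counts.tsv"), sep="\t", index=False)
    write_tables(dataset.cell_meta, os.path.join(outdir, "cell_meta.tsv"))


def read_dataset(indir: str) -> MultiomicsDataset:
    """Read a dataset written by :func:`write_dataset`, validating alignment."""
    def _path(name: str) -> str:
        p = os.path.join(indir, name)
        if not os.path.exists(p):
            raise DataValidationError(f"missing input file: {p}")
        return p

    barcodes = pd.read_csv(_path("barcodes.tsv"), sep="\t")
    mats, feats = {}, {}
    for modality in ("rna", "protein"):
        mats[modality] = _read_mtx(_path(f"{modality}_counts.mtx"))
        feats[modality] = pd.read_csv(_path(f"{modality}_features.tsv"), sep="\t")
        if mats[modality].shape[0] != len(barcodes):
            raise DataValidationError(
                f"{modality}_counts.mtx has {mats[modality].shape[0]} rows but "
                f"barcodes.tsv has {len(barcodes)}"
            )
        if mats[modality].shape[1] != len(feats[modality]):
            raise DataValidationError(
                f"{modality}_counts.mtx has {mats[modality].shape[1]} columns but "
                f"{modality}_features.tsv has {len(feats[modality])} rows"
            )
    tags = pd.read_csv(_path("tag_counts.tsv"), sep="\t")
    if len(tags) != len(barcodes):
        raise DataValidationError(
            f"tag_counts.tsv has {len(tags)} rows but barcodes.tsv has {len(barcodes)}"
        )
    cell_meta = pd.read_csv(_path("cell_meta.tsv"), sep="\t")
    if len(cell_meta) != len(barcodes):
        raise DataValidationError(
            f"cell_meta.tsv has {len(cell_meta)} rows but barcodes.tsv has {len(barcodes)}"
        )
    return MultiomicsDataset(
        rna_counts=mats["rna"],
        protein_counts=mats["protein"],
        tag_counts=tags.to_numpy(),
        cell_meta=cell_meta,
        rna_features=feats["rna"],
        protein_features=feats["protein"],
        tag_names=list(tags.columns),
    )


def write_tables(df: pd.DataFrame, path: str) -> None:
    """Write a result table as TSV with stable column order and >=10 significant
    digits for floats (so write/read round-trips are exact to <1e-9 relative)."""
    directory = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(directory):
        raise OSError(f"unwritable path (directory missing): {directory}")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def validate_facs_counts(facs: pd.DataFrame) -> pd.DataFrame:
    """Validate a FACS absolute-count table (cells/ul of whole blood)."""
    required = {"participant", "visit", "subset", "count"}
    missing = required - set(facs.columns)
    if missing:
        raise DataValidationError(f"facs table missing columns: {sorted(missing)}")
    if (facs["count"] < 0).any():
        raise DataValidationError("facs counts must be >= 0")
    dup = facs.duplicated(["participant", "visit", "subset"])
    if dup.any():
        raise DataValidationError("facs table must have one record per participant x visit x subset")
    return facs
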