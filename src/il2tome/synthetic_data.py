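"""Synthetic cohort generator with the statistical structure the analysis assumes.

The generator emulates the study design: 13 participants treated with interval
low-dose IL-2 (doses 0.2-0.47 x 1e6 IU/m^2), sampled at Days 0, 27 and 55;
five flow-sorted populations pooled at designated proportions (30% Treg, 25%
Tconv, 25% CD8, 12% CD56br, 8% CD56dim); a ~565-gene targeted mRNA panel plus
65 surface proteins; sample-tag multiplets and tag dropout (elevated in the
CD56br pool); a rare cycling-cell fraction; planted compositional effects
(e.g. a 2x Day-27 increase in naive FOXP3+HELIOS+ Tregs); and a Day-55
expression signature (CISH up, AREG down, ...) shifted in all clusters at Day
55 and shifted at Day 27 in proportion to (dose - pivot) x a concordance
coefficient.

Counts are negative binomial with mean mu and dispersion alpha (variance
mu + alpha * mu^2) — matching the downstream model family; the real study
provides no generative description, so every distributional choice here is a
documented stand-in, not an estimate from the deposited data.

The returned :class:`SimulationTruth` suffices to recompute every expectation
used in tests, and the generated ``cell_meta`` carries ``true_*`` ground-truth
columns (cluster, gate, tag, multiplet/dropout/cycling flags).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import SimulationConfig
from .datamodel_io import GateDesign, MultiomicsDataset, DataValidationError

logger = logging.getLogger(__name__)

CYCLING_GENES = [
    "AURKB", "HMGB2", "HMMR", "MCM4", "MKI67", "PCLAF",
    "PCNA", "TK1", "TOP2A", "TYMS", "UBE2C",
]

SIGNATURE_UP = [
    "CISH", "TNFSF14", "TNFSF10", "STAT1", "SGK1",
    "DUSP4", "DUSP5", "SOCS1", "BCL2", "FOXO1",
]
SIGNATURE_DOWN = [
    "AREG", "NFKBIZ", "NFKBIA", "RGS1", "TNFAIP3",
    "OSM", "DUSP2", "EGR1", "FOSB", "NR4A1",
]

# Marker genes with cluster-specific means; reserved names in the panel.
MARKER_GENES = [
    "FOXP3", "IKZF2", "IL21", "IL2RA", "CCR7", "SELL", "S100A4", "MAF",
    "CD8A", "GZMK", "SLC4A10", "KLRB1", "TRDV2", "TRGV9", "NCAM1",
    "FCGR3A", "GZMB", "PRF1", "HLA-DRA", "MS4A1", "CD79A", "CD3E",
    "KIT", "SOX4", "LYZ", "CD14G",
]

MARKER_PROTEINS = [
    "CD25", "CD127", "CD45RA", "CD4", "CD8", "CD56", "CD16", "CXCR5",
    "PD-1", "ICOS", "HLA-DR", "CD39", "CD19", "CD14", "CD3",
]

#: Baseline cluster composition within each sorting gate (simplex per gate).
DEFAULT_COMPOSITIONS = {
    "Treg": {"naive_treg": 0.25, "memory_treg": 0.40, "teff_cd25": 0.20, "tfh_cd25": 0.15},
    "Tconv": {"naive_tconv": 0.39, "memory_tconv": 0.38, "tcm_cxcr5": 0.14,
              "tph_il21": 0.08, "bcell_contam": 0.01},
    "CD8": {"naive_cd8": 0.345, "memory_cd8": 0.45, "mait": 0.12, "vd2": 0.08,
            "dn_t": 0.005},
    "CD56br": {"cd56br": 0.85, "cd56br_hladr": 0.15},
    "CD56dim": {"cd56dim": 0.80, "cd56dim_cyto": 0.20},
}

#: Planted frequency multipliers per (cluster, visit day).  A multiplier m
#: fixes the cluster's expected within-gate frequency at m x baseline; the
#: remaining clusters of the gate are rescaled to close the simplex, so the
#: planted log2 fold change of a targeted cluster is exactly log2(m).
DEFAULT_COMPOSITION_MULTIPLIERS = {
    ("naive_treg", 27): 2.0,            # >2-fold naive Treg enrichment during dosing
    ("teff_cd25", 27): 2.0 ** -0.6,
    ("tfh_cd25", 27): 2.0 ** -0.4,
    ("mait", 27): 2.0 ** -0.6,
    ("mait", 55): 2.0 ** -0.5,          # innate-like reductions persist at Day 55
    ("vd2", 27): 2.0 ** -0.6,
    ("vd2", 55): 2.0 ** -0.5,
    ("cd56br_hladr", 27): 1.74,
}

#: Gene-expression markers per cluster: marker gene -> mean UMI count.
CLUSTER_GENE_MARKERS = {
    "naive_treg": {"FOXP3": 3.0, "IKZF2": 3.0, "IL2RA": 4.0, "CCR7": 4.0, "SELL": 4.0},
    "memory_treg": {"FOXP3": 3.0, "IKZF2": 3.0, "IL2RA": 4.0, "S100A4": 4.0},
    "teff_cd25": {"IL2RA": 3.0, "S100A4": 4.0},
    "tfh_cd25": {"IL2RA": 3.0, "MAF": 4.0},
    "naive_tconv": {"CCR7": 4.0, "SELL": 4.0},
    "memory_tconv": {"S100A4": 4.0},
    "tcm_cxcr5": {"MAF": 4.0, "S100A4": 3.0},
    "tph_il21": {"S100A4": 3.0},
    "naive_cd8": {"CD8A": 5.0, "CCR7": 4.0, "SELL": 4.0},
    "memory_cd8": {"CD8A": 5.0, "GZMK": 4.0},
    "mait": {"CD8A": 4.0, "SLC4A10": 5.0, "KLRB1": 5.0},
    "vd2": {"TRDV2": 5.0, "TRGV9": 5.0},
    "cd56br": {"NCAM1": 6.0, "SELL": 3.0, "KIT": 3.0},
    "cd56br_hladr": {"NCAM1": 6.0, "HLA-DRA": 5.0},
    "cd56dim": {"FCGR3A": 5.0, "GZMB": 5.0},
    "cd56dim_cyto": {"FCGR3A": 5.0, "GZMB": 5.0, "PRF1": 5.0},
    "bcell_contam": {"MS4A1": 6.0, "CD79A": 5.0},
    "dn_t": {"CD3E": 4.0},
    "cycling": {},  # cycling genes boosted separately
}

_T_PROTEIN_BASE = {"CD3": 150.0, "CD19": 0.2, "CD14": 0.2, "CD56": 0.5, "CD16": 0.5}

#: Surface-protein means per cluster (unlisted proteins keep panel baseline).
CLUSTER_PROTEIN_MARKERS = {
    "naive_treg": {**_T_PROTEIN_BASE, "CD4": 150.0, "CD8": 0.3, "CD25": 120.0,
                   "CD127": 2.0, "CD45RA": 150.0, "CXCR5": 0.3, "PD-1": 0.5},
    "memory_treg": {**_T_PROTEIN_BASE, "CD4": 150.0, "CD8": 0.3, "CD25": 120.0,
                    "CD127": 2.0, "CD45RA": 0.5, "CXCR5": 0.3, "CD39": 60.0},
    "teff_cd25": {**_T_PROTEIN_BASE, "CD4": 150.0, "CD8": 0.3, "CD25": 60.0,
                  "CD127": 20.0, "CD45RA": 0.5, "CXCR5": 0.3, "PD-1": 1.0},
    "tfh_cd25": {**_T_PROTEIN_BASE, "CD4": 150.0, "CD8": 0.3, "CD25": 60.0,
                 "CD45RA": 0.5, "CXCR5": 60.0, "PD-1": 40.0, "ICOS": 40.0},
    "naive_tconv": {**_T_PROTEIN_BASE, "CD4": 150.0, "CD8": 0.3, "CD25": 0.5,
                    "CD127": 40.0, "CD45RA": 150.0, "CXCR5": 0.3, "PD-1": 0.5},
    "memory_tconv": {**_T_PROTEIN_BASE, "CD4": 150.0, "CD8": 0.3, "CD25": 0.5,
                     "CD127": 40.0, "CD45RA": 0.5, "CXCR5": 0.3, "PD-1": 2.0},
    "tcm_cxcr5": {**_T_PROTEIN_BASE, "CD4": 150.0, "CD8": 0.3, "CD25": 0.5,
                  "CD45RA": 0.5, "CXCR5": 60.0, "PD-1": 10.0},
    "tph_il21": {**_T_PROTEIN_BASE, "CD4": 150.0, "CD8": 0.3, "CD25": 0.5,
                 "CD45RA": 0.5, "CXCR5": 1.0, "PD-1": 80.0},
    "naive_cd8": {**_T_PROTEIN_BASE, "CD4": 0.3, "CD8": 150.0, "CD45RA": 150.0,
                  "CXCR5": 0.3, "PD-1": 0.5},
    "memory_cd8": {**_T_PROTEIN_BASE, "CD4": 0.3, "CD8": 150.0, "CD45RA": 0.5,
                   "CXCR5": 0.3, "PD-1": 2.0},
    "mait": {**_T_PROTEIN_BASE, "CD4": 0.3, "CD8": 100.0, "CD45RA": 0.5,
             "CXCR5": 0.3},
    "vd2": {**_T_PROTEIN_BASE, "CD4": 0.3, "CD8": 20.0, "CD45RA": 0.5,
            "CXCR5": 0.3},
    "cd56br": {"CD3": 0.3, "CD4": 0.3, "CD8": 0.3, "CD19": 0.2, "CD14": 0.2,
               "CD56": 200.0, "CD16": 0.3, "CD45RA": 80.0},
    "cd56br_hladr": {"CD3": 0.3, "CD4": 0.3, "CD8": 0.3, "CD19": 0.2, "CD14": 0.2,
                     "CD56": 200.0, "CD16": 0.3, "HLA-DR": 80.0},
    "cd56dim": {"CD3": 0.3, "CD4": 0.3, "CD8": 0.3, "CD19": 0.2, "CD14": 0.2,
                "CD56": 20.0, "CD16": 150.0},
    "cd56dim_cyto": {"CD3": 0.3, "CD4": 0.3, "CD8": 0.3, "CD19": 0.2, "CD14": 0.2,
                     "CD56": 20.0, "CD16": 150.0},
    "bcell_contam": {"CD3": 0.3, "CD4": 0.5, "CD8": 0.3, "CD19": 150.0,
                     "CD14": 0.3, "CD45RA": 80.0},
    "dn_t": {**_T_PROTEIN_BASE, "CD4": 0.3, "CD8": 0.3, "CD45RA": 2.0},
    "cycling": {**_T_PROTEIN_BASE, "CD4": 80.0, "CD8": 20.0, "CD25": 20.0},
}

#: Clusters whose cells express IL-21 after in vitro stimulation, with the
#: baseline fraction of IL-21+ cells per cluster.
IL21_CLUSTERS = {"tph_il21": 0.45, "tfh_cd25": 0.35, "tcm_cxcr5": 0.15}


@dataclass
class SuppressionTruth:
    """Ground truth for the in vitro Treg suppression assay."""

    teff_cpm_mean: float = 20000.0
    # Fraction of Teff proliferation suppressed at each Treg:Teff ratio.
    suppression_fractions: dict = field(
        default_factory=lambda: {"1:4": 0.35, "1:2": 0.55, "1:1": 0.70}
    )
    noise_sigma: float = 0.15
    n_replicates: int = 5
    n_participants: int = 12
    # (participant index, visit) pairs given a sub-threshold Teff-alone CPM,
    # mirroring the two excluded low-proliferation samples.
    low_cpm_samples: tuple = ((10, 0), (11, 27))
    low_cpm_mean: float = 800.0


@dataclass
class FacsTruth:
    """Ground truth for whole-blood FACS absolute counts (cells/ul)."""

    baselines: dict = field(default_factory=lambda: {"Treg": 40.0, "CD56br": 25.0})
    multipliers: dict = field(
        default_factory=lambda: {
            ("Treg", 27): 1.4, ("Treg", 55): 1.05,
            ("CD56br", 27): 1.8, ("CD56br", 55): 1.1,
        }
    )
    noise_sigma: float = 0.15


@dataclass
class SimulationTruth:
    """Everything needed to recompute the expectations behind a simulation."""

    gate_design: GateDesign
    compositions: dict
    composition_multipliers: dict
    gene_names: list
    protein_names: list
    rna_means: pd.DataFrame          # clusters x genes
    rna_dispersions: np.ndarray      # per gene
    protein_means: pd.DataFrame      # clusters x proteins
    protein_dispersions: np.ndarray  # per protein
    signature_up: list = field(default_factory=lambda: list(SIGNATURE_UP))
    signature_down: list = field(default_factory=lambda: list(SIGNATURE_DOWN))
    signature_lfc: float = 0.6
    concordance_coef: float = 4.0    # log2FC per (1e6 IU/m^2) at Day 27
    dose_pivot: float = 0.32
    multiplet_rate: float = 0.03
    tag_dropout: dict = field(
        default_factory=lambda: {"Treg": 0.02, "Tconv": 0.02, "CD8": 0.02,
                                 "CD56br": 0.30, "CD56dim": 0.02}
    )
    tag_signal_mean: float = 150.0
    tag_signal_dispersion: float = 0.15
    tag_background_mean: float = 0.3
    cycling_fraction: float = 0.007
    cycling_boost: float = 12.0
    cell_size_sigma: float = 0.3
    il21_fractions: dict = field(default_factory=lambda: dict(IL21_CLUSTERS))
    il21_day27_multiplier: float = 0.6
    il21_positive_mean: float = 6.0
    il21_negative_mean: float = 0.02
    facs: FacsTruth = field(default_factory=FacsTruth)
    suppression: SuppressionTruth = field(default_factory=SuppressionTruth)
    # (participant index, visit, cell fraction) of the planted low-yield sample.
    low_yield_sample: tuple = (7, 55, 0.15)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for gate, comp in self.compositions.items():
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise DataValidationError(
                    f"composition for gate {gate!r} sums to {total}, expected 1"
                )
            if any(v < 0 for v in comp.values()):
                raise DataValidationError(f"negative composition in gate {gate!r}")
        if np.any(self.rna_dispersions <= 0) or np.any(self.protein_dispersions <= 0):
            raise DataValidationError("dispersions must be > 0")
        for name, rate in [
            ("multiplet_rate", self.multiplet_rate),
            ("cycling_fraction", self.cycling_fraction),
            *[(f"tag_dropout[{g}]", r) for g, r in self.tag_dropout.items()],
        ]:
            if not 0.0 <= rate <= 1.0:
                raise DataValidationError(f"{name} = {rate} outside [0, 1]")
        for ratio, frac in self.suppression.suppression_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise DataValidationError(
                    f"suppression fraction for {ratio} = {frac} outside [0, 1]"
                )
        for subset, baseline in self.facs.baselines.items():
            if baseline < 0:
                raise DataValidationError(f"negative FACS baseline for {subset}")

    @property
    def clusters(self) -> list:
        return list(self.rna_means.index)

    def visit_composition(self, gate: str, visit: int) -> dict:
        """Within-gate composition at a visit after applying planted multipliers.

        Targeted clusters take frequency multiplier x baseline; untargeted
        clusters are rescaled to keep the gate composition on the simplex.
        """
        base = self.compositions[gate]
        targeted = {
            c: base[c] * self.composition_multipliers[(c, visit)]
            for c in base
            if (c, visit) in self.composition_multipliers
        }
        t_new = sum(targeted.values())
        t_old = sum(base[c] for c in targeted)
        if t_new >= 1.0:
            raise DataValidationError(
                f"planted multipliers push gate {gate!r} composition off the simplex"
            )
        scale = (1.0 - t_new) / (1.0 - t_old) if t_old < 1.0 else 0.0
        return {
            c: targeted.get(c, base[c] * scale) for c in base
        }

    def signature_shift(self, visit: int, dose: float) -> tuple[float, float]:
        """(log2 shift of up-genes, log2 shift of down-genes) for a sample."""
        if visit == 55:
            return self.signature_lfc, -self.signature_lfc
        if visit == 27:
            shift = (dose - self.dose_pivot) * self.concordance_coef
            return shift, -shift
        return 0.0, 0.0


def _build_panel(n_genes: int, n_proteins: int) -> tuple[list, list]:
    reserved = list(dict.fromkeys(MARKER_GENES + CYCLING_GENES + SIGNATURE_UP + SIGNATURE_DOWN))
    if n_genes < len(reserved):
        raise DataValidationError(
            f"panel needs at least {len(reserved)} genes for reserved markers"
        )
    genes = reserved + [f"GENE{i:04d}" for i in range(n_genes - len(reserved))]
    if n_proteins < len(MARKER_PROTEINS):
        raise DataValidationError(
            f"panel needs at least {len(MARKER_PROTEINS)} proteins"
        )
    proteins = list(MARKER_PROTEINS) + [
        f"PROT{i:03d}" for i in range(n_proteins - len(MARKER_PROTEINS))
    ]
    return genes, proteins


def build_truth(sim: SimulationConfig | None = None, panel_seed: int = 0) -> SimulationTruth:
    """Construct the default ground truth (panel, cluster means, effects).

    ``panel_seed`` only controls the incidental per-cluster expression profiles
    of filler genes; the planted effects are fixed by the defaults above.
    """
    sim = sim or SimulationConfig()
    rng = np.random.default_rng(panel_seed)
    genes, proteins = _build_panel(sim.n_genes, sim.n_proteins)
    clusters = list(CLUSTER_GENE_MARKERS)

    base = np.clip(rng.lognormal(np.log(0.5), 0.8, size=len(genes)), 0.05, 20.0)
    rna_means = pd.DataFrame(
        np.tile(base, (len(clusters), 1)), index=clusters, columns=genes
    )
    # Marker genes: high in their clusters, near-absent elsewhere.
    marker_set = {g for mk in CLUSTER_GENE_MARKERS.values() for g in mk}
    for g in marker_set | set(CYCLING_GENES) | {"IL21"}:
        rna_means[g] = 0.02
    for cluster, markers in CLUSTER_GENE_MARKERS.items():
        for g, mu in markers.items():
            rna_means.loc[cluster, g] = mu
    # FOXP3 keeps a trace level outside Treg clusters so the >=1-copy rule in
    # the Tconv gate has a non-degenerate rare positive population.
    for cluster in clusters:
        if rna_means.loc[cluster, "FOXP3"] <= 0.02:
            rna_means.loc[cluster, "FOXP3"] = 0.02
    # Cycling cells: T-cell baseline with the cell-cycle module boosted.
    cycling_row = rna_means.loc["memory_tconv"].copy()
    cycling_row[CYCLING_GENES] = base[[genes.index(g) for g in CYCLING_GENES]] * 0 + 4.0
    rna_means.loc["cycling"] = cycling_row
    rna_means.loc["cycling", CYCLING_GENES] = 4.0

    # Incidental per-cluster profiles on filler genes (keeps clusters separable
    # beyond the handful of markers); signature and cycling genes excluded so
    # composition shifts cannot masquerade as Day-55 expression effects.
    protected = set(SIGNATURE_UP) | set(SIGNATURE_DOWN) | set(CYCLING_GENES) | marker_set | {"IL21"}
    fillers = [g for g in genes if g not in protected]
    for cluster in clusters:
        chosen = rng.choice(len(fillers), size=min(30, len(fillers)), replace=False)
        factors = rng.uniform(2.0, 4.0, size=len(chosen))
        cols = [fillers[i] for i in chosen]
        rna_means.loc[cluster, cols] = rna_means.loc[cluster, cols].to_numpy() * factors

    rna_disp = rng.uniform(0.2, 0.8, size=len(genes))

    prot_base = np.clip(rng.lognormal(np.log(30.0), 0.5, size=len(proteins)), 2.0, 300.0)
    protein_means = pd.DataFrame(
        np.tile(prot_base, (len(clusters), 1)), index=clusters, columns=proteins
    )
    for cluster, markers in CLUSTER_PROTEIN_MARKERS.items():
        for p, mu in markers.items():
            protein_means.loc[cluster, p] = mu
    prot_disp = rng.uniform(0.1, 0.4, size=len(proteins))

    return SimulationTruth(
        gate_design=GateDesign(),
        compositions={g: dict(c) for g, c in DEFAULT_COMPOSITIONS.items()},
        composition_multipliers=dict(DEFAULT_COMPOSITION_MULTIPLIERS),
        gene_names=genes,
        protein_names=proteins,
        rna_means=rna_means,
        rna_dispersions=rna_disp,
        protein_means=protein_means,
        protein_dispersions=prot_disp,
    )


def five_population_truth(sim: SimulationConfig | None = None) -> SimulationTruth:
    """Truth variant with one cluster per gate (five well-separated populations)."""
    truth = build_truth(sim)
    return dataclasses.replace(
        truth,
        compositions={
            "Treg": {"memory_treg": 1.0},
            "Tconv": {"memory_tconv": 1.0},
            "CD8": {"memory_cd8": 1.0},
            "CD56br": {"cd56br": 1.0},
            "CD56dim": {"cd56dim": 1.0},
        },
        composition_multipliers={},
        cycling_fraction=0.0,
        multiplet_rate=0.0,
        tag_dropout={g: 0.0 for g in truth.tag_dropout},
    )


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Negative binomial with variance mu + alpha mu^2 via gamma-Poisson."""
    mean = np.asarray(mean, dtype=float)
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * np.maximum(mean, 1e-12))
    return rng.poisson(lam)


def _participant_ids(sim: SimulationConfig) -> tuple[list, dict]:
    participants = [f"P{i + 1:02d}" for i in range(sim.n_participants)]
    doses = {p: sim.doses[i % len(sim.doses)] for i, p in enumerate(participants)}
    return participants, doses


def generate_dataset(
    truth: SimulationTruth,
    sim: SimulationConfig | None = None,
    seed: int = 0,
    stimulated: bool = False,
) -> tuple[MultiomicsDataset, SimulationTruth]:
    """Generate one dataset (unstimulated or stimulated) for the full cohort."""
    sim = sim or SimulationConfig()
    rng = np.random.default_rng(seed)
    participants, doses = _participant_ids(sim)
    gate_names = list(truth.gate_design.proportions)
    props = np.array([truth.gate_design.proportions[g] for g in gate_names])
    n_per_sample = max(1, sim.cells_per_visit // sim.n_participants)

    rows = []
    for visit in (0, 27, 55):
        for pi, participant in enumerate(participants):
            n = n_per_sample
            if truth.low_yield_sample is not None:
                ly_pi, ly_visit, ly_frac = truth.low_yield_sample
                if pi == ly_pi and visit == ly_visit:
                    n = max(1, int(round(n * ly_frac)))
            gates = rng.choice(gate_names, size=n, p=props)
            clusters = np.empty(n, dtype=object)
            for gate in gate_names:
                mask = gates == gate
                if not mask.any():
                    continue
                comp = truth.visit_composition(gate, visit)
                names = list(comp)
                clusters[mask] = rng.choice(
                    names, size=int(mask.sum()), p=np.array([comp[c] for c in names])
                )
            cycling = np.zeros(n, dtype=bool)
            if not stimulated and truth.cycling_fraction > 0:
                cycling = rng.random(n) < truth.cycling_fraction
                clusters[cycling] = "cycling"
            for gate, cluster, cyc in zip(gates, clusters, cycling):
                rows.append((participant, doses[participant], visit, gate, cluster, cyc))

    meta = pd.DataFrame(
        rows,
        columns=["participant", "dose", "visit", "true_gate", "true_cluster", "true_cycling"],
    )
    meta["stimulation"] = "stim" if stimulated else "unstim"
    meta["gate"] = meta["true_gate"]
    meta["sample_id"] = meta["participant"] + "_d" + meta["visit"].astype(str)
    n_cells = len(meta)

    size_factors = rng.lognormal(0.0, truth.cell_size_sigma, size=n_cells)
    genes, proteins = truth.gene_names, truth.protein_names
    up_idx = [genes.index(g) for g in truth.signature_up]
    down_idx = [genes.index(g) for g in truth.signature_down]

    # Per-cell log2 shifts of the Day-55 signature genes (all clusters).
    up_shift = np.zeros(n_cells)
    down_shift = np.zeros(n_cells)
    for (visit, dose), idx in meta.groupby(["visit", "dose"]).groups.items():
        u, d = truth.signature_shift(int(visit), float(dose))
        up_shift[np.asarray(idx)] = u
        down_shift[np.asarray(idx)] = d

    rna = np.zeros((n_cells, len(genes)), dtype=np.int64)
    prot = np.zeros((n_cells, len(proteins)), dtype=np.int64)
    for cluster, idx in meta.groupby("true_cluster").groups.items():
        idx = np.asarray(idx)
        mu = np.outer(size_factors[idx], truth.rna_means.loc[cluster].to_numpy())
        mu[:, up_idx] *= 2.0 ** up_shift[idx][:, None]
        mu[:, down_idx] *= 2.0 ** down_shift[idx][:, None]
        rna[idx] = _nb_draws(rng, mu, truth.rna_dispersions[None, :])
        mu_p = np.outer(size_factors[idx], truth.protein_means.loc[cluster].to_numpy())
        prot[idx] = _nb_draws(rng, mu_p, truth.protein_dispersions[None, :])

    # IL-21 is elicited only by in vitro stimulation, in T_FH-like clusters.
    il21_col = genes.index("IL21")
    meta["true_il21_pos"] = False
    if stimulated:
        for cluster, base_frac in truth.il21_fractions.items():
            idx = np.flatnonzero(meta["true_cluster"].to_numpy() == cluster)
            if idx.size == 0:
                continue
            frac = np.full(idx.size, base_frac)
            frac[meta["visit"].to_numpy()[idx] == 27] = base_frac * truth.il21_day27_multiplier
            pos = rng.random(idx.size) < frac
            meta.loc[idx, "true_il21_pos"] = pos
            counts = np.where(
                pos,
                _nb_draws(rng, np.full(idx.size, truth.il21_positive_mean), 0.3),
                rng.poisson(truth.il21_negative_mean, size=idx.size),
            )
            rna[idx, il21_col] = counts

    # Sample tags: high-count signal tag for the (visit, pool) of origin,
    # Poisson background elsewhere; multiplets gain a second signal tag and
    # dropout cells (CD56br-enriched) lose theirs.
    tags = list(truth.gate_design.tags)
    tag_counts = rng.poisson(truth.tag_background_mean, size=(n_cells, len(tags)))
    true_tags = [
        truth.gate_design.tag_for(int(v), g)
        for v, g in zip(meta["visit"], meta["true_gate"])
    ]
    tag_idx = np.array([tags.index(t) for t in true_tags])
    dropout_rate = meta["true_gate"].map(truth.tag_dropout).to_numpy(dtype=float)
    dropout = rng.random(n_cells) < dropout_rate
    multiplet = (~dropout) & (rng.random(n_cells) < truth.multiplet_rate)
    signal = _nb_draws(
        rng,
        np.full(n_cells, truth.tag_signal_mean),
        truth.tag_signal_dispersion,
    )
    keep = ~dropout
    tag_counts[np.flatnonzero(keep), tag_idx[keep]] += signal[keep]
    second_idx = (tag_idx + rng.integers(1, len(tags), size=n_cells)) % len(tags)
    second_signal = _nb_draws(
        rng, np.full(n_cells, truth.tag_signal_mean), truth.tag_signal_dispersion
    )
    tag_counts[np.flatnonzero(multiplet), second_idx[multiplet]] += second_signal[multiplet]

    meta["true_tag"] = true_tags
    meta["true_dropout"] = dropout
    meta["true_multiplet"] = multiplet

    dataset = MultiomicsDataset(
        rna_counts=sp.csr_matrix(rna),
        protein_counts=sp.csr_matrix(prot),
        tag_counts=tag_counts,
        cell_meta=meta,
        rna_features=pd.DataFrame({"name": genes, "modality": "rna"}),
        protein_features=pd.DataFrame({"name": proteins, "modality": "protein"}),
        tag_names=tags,
    )
    logger.info(
        "simulated %s dataset: %d cells, %d genes, %d proteins",
        "stimulated" if stimulated else "unstimulated",
        n_cells, len(genes), len(proteins),
    )
    return dataset, truth


def generate_facs_counts(
    truth: SimulationTruth, sim: SimulationConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Whole-blood absolute counts per participant x visit x subset."""
    sim = sim or SimulationConfig()
    rng = np.random.default_rng(seed)
    participants, _ = _participant_ids(sim)
    rows = []
    for subset, baseline in truth.facs.baselines.items():
        if baseline < 0:
            raise DataValidationError(f"negative FACS baseline for {subset}")
        for participant in participants:
            level = baseline * rng.lognormal(0.0, truth.facs.noise_sigma)
            for visit in (0, 27, 55):
                mult = truth.facs.multipliers.get((subset, visit), 1.0)
                noise = (
                    rng.lognormal(0.0, truth.facs.noise_sigma)
                    if truth.facs.noise_sigma > 0
                    else 1.0
                )
                rows.append((participant, visit, subset, level * mult * noise))
    return pd.DataFrame(rows, columns=["participant", "visit", "subset", "count"])


def generate_suppression_assay(truth: SimulationTruth, seed: int = 0) -> pd.DataFrame:
    """Replicate-level CPM table for the Treg suppression assay.

    Long format: participant, visit, ratio, replicate, cpm — five replicates
    per condition at Treg:Teff ratios 0:1, 1:4, 1:2 and 1:1.
    """
    sup = truth.suppression
    rng = np.random.default_rng(seed)
    participants = [f"S{i + 1:02d}" for i in range(sup.n_participants)]
    low = {(pi, visit) for pi, visit in sup.low_cpm_samples}
    rows = []
    for pi, participant in enumerate(participants):
        for visit in (0, 27, 55):
            teff_mean = sup.low_cpm_mean if (pi, visit) in low else sup.teff_cpm_mean
            teff_mean = teff_mean * (
                rng.lognormal(0.0, sup.noise_sigma) if sup.noise_sigma > 0 else 1.0
            )
            for ratio in ("0:1", "1:4", "1:2", "1:1"):
                frac = 0.0 if ratio == "0:1" else sup.suppression_fractions[ratio]
                cond_mean = teff_mean * (1.0 - frac)
                for rep in range(sup.n_replicates):
                    noise = (
                        rng.lognormal(0.0, sup.noise_sigma)
                        if sup.noise_sigma > 0
                        else 1.0
                    )
                    rows.append((participant, visit, ratio, rep + 1, cond_mean * noise))
    return pd.DataFrame(
        rows, columns=["participant", "visit", "ratio", "replicate", "cpm"]
    )


def generate_pseudobulk_counts(
    truth: SimulationTruth,
    sim: SimulationConfig | None = None,
    seed: int = 0,
    cell_group: str = "Treg",
    n_cells_per_sample: int = 2000,
    null: bool = False,
    pseudobulk_dispersion_mean: float = 0.02,
    participant_sigma: float = 0.1,
    library_sigma: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directly simulate a pseudo-bulk count table for one cell group.

    Aggregating thousands of cells per sample makes pseudo-bulk counts well
    approximated by a negative binomial around the composition-weighted cluster
    means; simulating at that level keeps calibration and power studies (null
    LRT rates, signature-gene recovery, dose-response power) cheap.  Returns
    (counts: samples x genes, sample_meta).
    """
    sim = sim or SimulationConfig()
    rng = np.random.default_rng(seed)
    participants, doses = _participant_ids(sim)
    genes = truth.gene_names
    up_idx = [genes.index(g) for g in truth.signature_up]
    down_idx = [genes.index(g) for g in truth.signature_down]

    alpha = rng.lognormal(np.log(pseudobulk_dispersion_mean), 0.3, size=len(genes))
    part_effect = rng.lognormal(0.0, participant_sigma, size=(len(participants), len(genes)))

    rows, meta_rows = [], []
    for visit in (0, 27, 55):
        comp = {
            g: truth.visit_composition(g, 0 if null else visit)
            for g in truth.compositions
        }
        gate_comp = comp[cell_group] if cell_group in comp else comp["Treg"]
        mean_g = np.zeros(len(genes))
        for cluster, w in gate_comp.items():
            mean_g += w * truth.rna_means.loc[cluster].to_numpy()
        for pi, participant in enumerate(participants):
            mu = n_cells_per_sample * mean_g * part_effect[pi]
            mu = mu * rng.lognormal(0.0, library_sigma)
            if not null:
                u, d = truth.signature_shift(visit, doses[participant])
                mu = mu.copy()
                mu[up_idx] *= 2.0 ** u
                mu[down_idx] *= 2.0 ** d
            rows.append(_nb_draws(rng, mu, alpha))
            meta_rows.append((participant, doses[participant], visit, cell_group))

    counts = pd.DataFrame(np.array(rows), columns=genes)
    meta = pd.DataFrame(
        meta_rows, columns=["participant", "dose", "visit", "cell_group"]
    )
    return counts, meta
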