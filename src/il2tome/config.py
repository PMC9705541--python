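"""Pipeline configuration.

Every threshold, resolution and rate used by the pipeline lives in one nested
dataclass tree so a full run is reproducible from a single YAML artifact plus
a seed.  ``PipelineConfig.from_yaml`` accepts a partial file: unspecified keys
keep their defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class DemuxConfig:
    # A tag is "present" when count >= min_count and >= min_ratio * top count.
    min_count: int = 10
    min_ratio: float = 0.3


@dataclass
class DoubletConfig:
    sim_ratio: float = 2.0      # simulated doublets per observed cell
    n_pcs: int = 30
    k: int = 30


@dataclass
class QCConfig:
    # Cluster-level doublet criterion: median score above this percentile of
    # all cell scores.
    doublet_score_percentile: float = 95.0
    # "Very low RNA" = cluster median total below this fraction of the global
    # median; protein medians must lie inside [low, high] x global median.
    low_rna_fraction: float = 0.10
    protein_low_fraction: float = 0.10
    protein_high_fraction: float = 10.0
    # Samples (participant x visit) with fewer retained unstimulated cells are
    # excluded from downstream analyses.  The study-scale default is 1000; the
    # desk-scale pipeline overrides it in proportion to cells per sample.
    min_cells: int = 1000


@dataclass
class ClusterConfig:
    n_pcs: int = 10
    k: int = 30
    resolution: float = 0.5
    min_cluster_size: int = 10
    # Final per-partition resolutions (unstimulated / stimulated).
    partition_resolutions_unstim: dict = field(
        default_factory=lambda: {
            "Treg": 0.6, "Tconv": 0.5, "CD8": 0.5, "NK": 0.3, "cycling": 0.5,
        }
    )
    partition_resolutions_stim: dict = field(
        default_factory=lambda: {"Treg": 0.5, "Tconv": 0.4, "CD8": 0.5, "NK": 0.5}
    )
    # Protein data is unusable in CD56br NK cells (compromised staining), so
    # NK partitions cluster on RNA alone.
    nk_rna_only: bool = True
    # Marker positivity: fraction of cells with raw count >= positive_count
    # must exceed positive_fraction.
    positive_count: int = 1
    positive_fraction: float = 0.5
    # Clusters whose mean proliferation score exceeds this are cycling.
    cycling_score_threshold: float = 0.5
    n_control_genes: int = 50


@dataclass
class AbundanceConfig:
    exact_max_n: int = 25
    il21_threshold: int = 1


@dataclass
class DEConfig:
    fc_cut: float = 0.4
    fdr_cut: float = 0.01
    p_cut: float = 1e-10
    fig3_fc_cut: float = 1.2
    min_cells_per_sample: int = 10
    dispersion_floor: float = 1e-8
    shrink: bool = True
    # BH scope: "population" adjusts within each cell group, "global" pools.
    fdr_scope: str = "population"


@dataclass
class SimulationConfig:
    """Cohort and scale for the synthetic generator (see synthetic_data)."""

    n_participants: int = 13
    cells_per_visit: int = 5000
    # Doses in 1e6 IU/m^2, assigned cyclically from this ordered pool.
    doses: tuple = (0.2, 0.32, 0.32, 0.32, 0.32, 0.47, 0.2, 0.32, 0.32, 0.32, 0.47, 0.2, 0.32)
    n_genes: int = 565
    n_proteins: int = 65


@dataclass
class PipelineConfig:
    demux: DemuxConfig = field(default_factory=DemuxConfig)
    doublet: DoubletConfig = field(default_factory=DoubletConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    abundance: AbundanceConfig = field(default_factory=AbundanceConfig)
    de: DEConfig = field(default_factory=DEConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | None) -> "PipelineConfig":
        cfg = cls()
        if path is None:
            return cfg
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for section, values in data.items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section {section!r}")
            sub = getattr(cfg, section)
            for key, value in (values or {}).items():
                if not hasattr(sub, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                if isinstance(getattr(sub, key), tuple) and isinstance(value, list):
                    value = tuple(value)
                setattr(sub, key, value)
        return cfg

    def hash(self) -> str:
        """Stable hash of the full configuration, logged with every run."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
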