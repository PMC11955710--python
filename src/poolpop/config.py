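"""Configuration objects for the simulation and pipeline stages."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


@dataclass
class TraitConfig:
    """Variance components and design sizes for one simulated trait.

    ``sigma2_*`` are variances of the random terms of the plot-level model:
    population (``p``), population x location (``pl``), population x season
    (``ps``), population x year (``py``), season x year (``sy``), replicate
    (``b``), row (``r``), column (``c``) and residual (``e``).  Fixed-effect
    magnitudes for year / location / season are generated as evenly spaced
    offsets of size ``fixed_effect_scale``.
    """

    sigma2_p: float = 1.0
    sigma2_pl: float = 0.0
    sigma2_ps: float = 0.0
    sigma2_py: float = 0.0
    sigma2_sy: float = 0.0
    sigma2_b: float = 0.0
    sigma2_r: float = 0.0
    sigma2_c: float = 0.0
    sigma2_e: float = 1.0
    n_locations: int = 2
    n_years: int = 3
    n_seasons: int = 3
    n_reps: int = 2
    n_rows: int = 10
    n_cols: int = 10
    fixed_effect_scale: float = 1.0
    mean: float = 5.0

    def variances(self) -> dict[str, float]:
        return {
            k.replace("sigma2_", ""): v
            for k, v in asdict(self).items()
            if k.startswith("sigma2_")
        }

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if name.startswith("sigma2_") and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be a finite non-negative real, got {v}")
        for name in ("n_locations", "n_years", "n_seasons", "n_reps", "n_rows", "n_cols"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_rows * self.n_cols < 1:
            raise ValueError("row-column grid is empty")


def _default_pops_per_cluster() -> list[int]:
    # 7 clusters summing to 92 populations
    return [14, 13, 13, 13, 13, 13, 13]


def _default_traits() -> dict[str, TraitConfig]:
    return {"biomass": TraitConfig(sigma2_p=1.12, sigma2_ps=0.24, sigma2_py=0.19, sigma2_e=1.8)}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic pooled-GBS germplasm study.

    Defaults mirror the scale the downstream pipeline assumes: 92
    populations in 7 drift-structured clusters, 4,509 biallelic loci,
    30-individual bulks sequenced as 4 technical replicates.
    """

    seed: int = 0
    n_clusters: int = 7
    pops_per_cluster: list[int] = field(default_factory=_default_pops_per_cluster)
    n_loci: int = 4509
    cluster_fst: float | list[float] = 0.06
    within_cluster_sd: float = 0.02
    pool_size: int = 30
    n_tech_reps: int = 4
    mean_depth: float = 20.0
    missing_rate: float = 0.02
    n_bioclim: int = 19
    n_adaptive: int = 60
    adaptive_slope: float = 1.5
    n_chromosomes: int = 7
    trait_config: dict[str, TraitConfig] = field(default_factory=_default_traits)

    @property
    def n_populations(self) -> int:
        return int(sum(self.pops_per_cluster))

    def fst_per_cluster(self) -> list[float]:
        if isinstance(self.cluster_fst, (int, float)):
            return [float(self.cluster_fst)] * self.n_clusters
        return [float(f) for f in self.cluster_fst]

    def validate(self) -> None:
        if len(self.pops_per_cluster) != self.n_clusters:
            raise ValueError(
                f"pops_per_cluster has {len(self.pops_per_cluster)} entries "
                f"for n_clusters={self.n_clusters}"
            )
        if any(n < 1 for n in self.pops_per_cluster):
            raise ValueError("every cluster needs at least one population")
        fsts = self.fst_per_cluster()
        if len(fsts) != self.n_clusters:
            raise ValueError("cluster_fst list length must equal n_clusters")
        for f in fsts:
            if not math.isfinite(f) or not (0.0 < f < 1.0):
                raise ValueError(f"cluster_fst must lie in (0,1), got {f}")
        if not math.isfinite(self.mean_depth) or self.mean_depth <= 0:
            raise ValueError(f"mean_depth must be positive, got {self.mean_depth}")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.n_tech_reps < 1:
            raise ValueError("n_tech_reps must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0,1)")
        if self.n_adaptive > self.n_loci:
            raise ValueError("n_adaptive exceeds n_loci")
        if self.n_adaptive < 0:
            raise ValueError("n_adaptive must be >= 0")
        if not math.isfinite(self.within_cluster_sd) or self.within_cluster_sd < 0:
            raise ValueError("within_cluster_sd must be non-negative")
        if not math.isfinite(self.adaptive_slope):
            raise ValueError("adaptive_slope must be finite")
        for name, tc in self.trait_config.items():
            tc.validate()
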