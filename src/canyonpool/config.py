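"""Simulation configuration for two-slope pooled-sequencing cohorts.

The default configuration emulates the study design this package targets:
two microclimatically contrasted populations ("NFS" = north-facing slope,
"SFS" = south-facing slope), each represented by 9 pooled isofemale lines
of 40 haploid genomes, sequenced to ~73x mean depth, with selective sweeps
prevalent on the SFS side and an interslope structure in the F_ST ~ 0.17
regime after calibration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

NFS = "NFS"
SFS = "SFS"
SLOPES = (NFS, SFS)


@dataclass(frozen=True)
class SweepInterval:
    """A planted sweep: reduced site density and extreme-shifted spectra.

    ``diversity_reduction`` is the retained fraction of diversity in (0, 1]:
    1.0 means no effect; 0.3 means 30% of sites keep segregating (with
    frequencies pushed toward 0 or 1), the rest are fixed in the swept slope.
    ``slope`` is "NFS", "SFS" or "both".
    """

    chrom: str
    start: int
    end: int
    diversity_reduction: float = 0.3
    slope: str = "both"

    def affected_slopes(self) -> tuple[str, ...]:
        return SLOPES if self.slope == "both" else (self.slope,)


@dataclass(frozen=True)
class TEFamily:
    """A transposable-element family: number of insertion sites genome-wide
    and the probability that a site has carriers on both slopes."""

    name: str
    n_sites: int
    sharing_prob: float


def _default_sweeps() -> list[SweepInterval]:
    return [
        SweepInterval("2R", 300_001, 400_000, 0.3, SFS),
        SweepInterval("2R", 650_001, 750_000, 0.3, SFS),
    ]


def _default_te_families() -> list[TEFamily]:
    # Family sizes and sharing rates in the range observed for Drosophila
    # pool-seq TE surveys: one old, nearly fixed family (INE-1-like, ~88%
    # shared), recently invading families with very low sharing (P-element,
    # 412, mariner-like), and intermediate LTR families.
    return [
        TEFamily("INE-1", 1030, 0.88),
        TEFamily("P-element", 584, 0.06),
        TEFamily("412", 309, 0.06),
        TEFamily("mariner", 85, 0.07),
        TEFamily("G-element", 120, 0.07),
        TEFamily("roo", 590, 0.55),
        TEFamily("Cr1a", 300, 0.50),
        TEFamily("Helena", 200, 0.45),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-slope cohort generator.

    Frequencies come from the standard neutral site-frequency spectrum
    (xi_i proportional to 1/i); with probability ``migration_mix`` a site's
    population frequency is shared between slopes, otherwise each slope
    receives an independent draw.  Pools of ``haploids_per_pool`` haplotypes
    are sampled per line, then reads binomially at Poisson(``mean_depth``)
    coverage.
    """

    n_lines_per_slope: int = 9
    haploids_per_pool: int = 40
    mean_depth: float = 73.0
    genome_length: int = 1_000_000
    chrom: str = "2R"
    theta_per_site: float = 0.01
    migration_mix: float = 0.5
    sweep_intervals: list[SweepInterval] = field(default_factory=_default_sweeps)
    te_families: list[TEFamily] = field(default_factory=_default_te_families)
    te_carrier_prob: float = 0.7
    shared_species_fraction: float = 0.01
    # Second-species structure (see docs/methods.md): probability that the
    # major allele coincides between species at shared sites, the fraction of
    # shared sites with a convergent interslope difference, and the reference
    # orientation of the second species' private sites.
    species_cooccurrence: float = 0.85
    species_convergent_fraction: float = 0.3
    species_background_coincidence: float = 0.34
    gene_spacing: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if self.n_lines_per_slope <= 0:
            raise ValueError("n_lines_per_slope must be positive")
        if self.haploids_per_pool < 4:
            raise ValueError("haploids_per_pool must be at least 4")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.theta_per_site <= 0:
            raise ValueError("theta_per_site must be positive")
        if self.gene_spacing <= 0:
            raise ValueError("gene_spacing must be positive")
        for name, frac in [
            ("migration_mix", self.migration_mix),
            ("shared_species_fraction", self.shared_species_fraction),
            ("species_cooccurrence", self.species_cooccurrence),
            ("species_convergent_fraction", self.species_convergent_fraction),
            ("species_background_coincidence", self.species_background_coincidence),
            ("te_carrier_prob", self.te_carrier_prob),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        self.sweep_intervals = [
            sw if isinstance(sw, SweepInterval) else SweepInterval(*sw)
            for sw in self.sweep_intervals
        ]
        for sw in self.sweep_intervals:
            if not 0.0 < sw.diversity_reduction <= 1.0:
                raise ValueError("diversity_reduction must lie in (0, 1]")
            if sw.slope not in (NFS, SFS, "both"):
                raise ValueError(f"unknown sweep slope {sw.slope!r}")
            if sw.start < 1 or sw.end > self.genome_length or sw.end < sw.start:
                raise ValueError(
                    f"sweep interval {sw.chrom}:{sw.start}-{sw.end} outside "
                    f"the simulated genome (1-{self.genome_length})"
                )
            if sw.chrom != self.chrom:
                raise ValueError(f"sweep interval on unknown chromosome {sw.chrom}")
        ordered = sorted(self.sweep_intervals, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValueError("sweep intervals must not overlap")
        self.te_families = [
            te if isinstance(te, TEFamily) else TEFamily(*te)
            for te in self.te_families
        ]
        for te in self.te_families:
            if te.n_sites <= 0:
                raise ValueError("TE family n_sites must be positive")
            if not 0.0 <= te.sharing_prob <= 1.0:
                raise ValueError("TE sharing_prob must lie in [0, 1]")

    # -- identifiers ------------------------------------------------------

    def line_ids(self) -> list[str]:
        return [
            f"{slope}_{i + 1}"
            for slope in SLOPES
            for i in range(self.n_lines_per_slope)
        ]

    def slope_of(self) -> dict[str, str]:
        return {lid: lid.split("_")[0] for lid in self.line_ids()}

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep_intervals"] = [dataclasses.asdict(s) for s in self.sweep_intervals]
        d["te_families"] = [dataclasses.asdict(t) for t in self.te_families]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["sweep_intervals"] = [
            SweepInterval(**s) if isinstance(s, dict) else SweepInterval(*s)
            for s in d.get("sweep_intervals", [])
        ]
        d["te_families"] = [
            TEFamily(**t) if isinstance(t, dict) else TEFamily(*t)
            for t in d.get("te_families", _default_te_families())
        ]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)
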