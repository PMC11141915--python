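"""Abstract genome model: autosomes, arms, SNP densities, gene catalog.

Coordinates are 0-based half-open throughout the package; lengths are in
abstract units (defaults are roughly megabase-scale, mirroring the relative
sizes of the human autosomes so that length-weighted statistics such as the
whole-genome-doubling fraction behave realistically).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Gene",
    "Chromosome",
    "GenomeModel",
    "default_genome",
    "CLASSIC_MONOSOMY_CHROMS",
]

# Chromosomes recurrently lost in classic chromophobe RCC.
CLASSIC_MONOSOMY_CHROMS = ("1", "2", "6", "10", "13", "17", "21")

# (name, length in abstract Mb-like units, p-arm fraction).  Lengths and
# centromere splits are rounded from the human assembly; only ratios matter.
_AUTOSOMES = [
    ("1", 249, 0.50), ("2", 242, 0.38), ("3", 198, 0.46), ("4", 190, 0.26),
    ("5", 182, 0.27), ("6", 171, 0.36), ("7", 159, 0.38), ("8", 145, 0.31),
    ("9", 138, 0.31), ("10", 134, 0.30), ("11", 135, 0.40), ("12", 133, 0.27),
    ("13", 114, 0.16), ("14", 107, 0.16), ("15", 102, 0.19), ("16", 90, 0.41),
    ("17", 83, 0.30), ("18", 80, 0.23), ("19", 59, 0.44), ("20", 64, 0.44),
    ("21", 47, 0.26), ("22", 51, 0.29),
]


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: str
    start: int
    end: int
    driver: bool = False

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    p_arm_fraction: float
    n_snp_sites: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if not 0.0 < self.p_arm_fraction < 1.0:
            raise ValueError(
                f"chromosome {self.name}: p-arm fraction must lie in (0, 1)"
            )
        if self.n_snp_sites < 0:
            raise ValueError(f"chromosome {self.name}: SNP count must be >= 0")

    @property
    def centromere(self) -> int:
        return int(round(self.length * self.p_arm_fraction))

    def arm_of(self, position: float) -> str:
        return "p" if position < self.centromere else "q"

    def arm_bounds(self, arm: str) -> tuple[int, int]:
        if arm == "p":
            return 0, self.centromere
        if arm == "q":
            return self.centromere, self.length
        raise ValueError(f"unknown arm {arm!r}")


@dataclass(frozen=True)
class GenomeModel:
    """Autosome set with arm structure, SNP densities and a gene catalog."""

    chromosomes: tuple[Chromosome, ...]
    genes: tuple[Gene, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        by_name = {c.name: c for c in self.chromosomes}
        for g in self.genes:
            c = by_name.get(g.chrom)
            if c is None:
                raise ValueError(f"gene {g.name}: unknown chromosome {g.chrom}")
            if not (0 <= g.start < g.end <= c.length):
                raise ValueError(
                    f"gene {g.name}: interval [{g.start}, {g.end}) outside "
                    f"chromosome {g.chrom} of length {c.length}"
                )

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def arm_table(self) -> list[tuple[str, str, int, int]]:
        """(chrom, arm, start, end) rows tiling every chromosome."""
        rows = []
        for c in self.chromosomes:
            rows.append((c.name, "p", 0, c.centromere))
            rows.append((c.name, "q", c.centromere, c.length))
        return rows

    def gene(self, name: str) -> Gene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)


def default_genome(snp_sites_per_chrom: int = 500) -> GenomeModel:
    """Compact synthetic genome: 22 autosomes, ~500 het SNP sites each.

    The gene catalog places a TP53-like driver on 17p and a PTEN-like driver
    on 10q (the loci whose zygosity the timing module reasons about), plus a
    TSC1-like driver on 9q and passenger genes used by gene-level CN calls.
    """
    chroms = tuple(
        Chromosome(name, length, frac, snp_sites_per_chrom)
        for name, length, frac in _AUTOSOMES
    )
    genes = (
        Gene("TP53L", "17", 7, 8, driver=True),
        Gene("PTENL", "10", 88, 89, driver=True),
        Gene("TSC1L", "9", 132, 133, driver=True),
        Gene("GENE_A", "3", 50, 52),
        Gene("GENE_B", "5", 100, 103),
        Gene("GENE_C", "12", 20, 21),
    )
    return GenomeModel(chromosomes=chroms, genes=genes)
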