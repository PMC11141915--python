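"""Forward simulator of chromophobe-RCC-like clonal evolution.

Generates multiregion tumor/normal sequencing-style observations (germline
het-SNP allelic depths and somatic variant read counts) from an explicit
clone tree, together with the full generating truth, so every inference
stage in this package can be scored against a known answer.

The default scenario encodes the canonical progression of aggressive
chromophobe RCC: a hypodiploid *classic* clone carrying monosomies of
chromosomes 1, 2, 6, 10, 13, 17 and 21 with a hemizygous TP53-like driver
on the single remaining chromosome 17, and a *dedifferentiated* descendant
that acquires a PTEN-like driver on monosomic chromosome 10 and then
undergoes whole-genome doubling (WGD), turning both drivers homozygous on
copy-number (2, 0) chromosomes.

Read-count emission: tumor site depth is Poisson with mean proportional to
the purity-mixed local copy number (normalized to a diploid average), the
normal is Poisson at the nominal coverage, and allele counts are binomial.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import CLASSIC_MONOSOMY_CHROMS, GenomeModel, default_genome

__all__ = [
    "Mutation",
    "CloneGenotype",
    "BranchEvents",
    "RegionSpec",
    "EvolutionScenario",
    "SimulatedDataset",
    "expected_vaf",
    "expected_baf",
    "expected_logr",
    "build_genotypes",
    "simulate_scenario",
    "default_scenario",
    "write_dataset",
]

ROOT_CLONE = "root"

ANNOTATION_CLASSES = ("nonsynonymous", "synonymous", "other")


# ---------------------------------------------------------------------------
# expected-value primitives (the emission model in closed form)
# ---------------------------------------------------------------------------

def expected_vaf(purity: float, tumor_total_cn: float, multiplicity: float,
                 clone_fraction: float = 1.0) -> float:
    """Expected somatic variant allele frequency in a purity-diluted sample.

    A mutation on ``multiplicity`` of ``tumor_total_cn`` tumor copies, carried
    by a fraction ``clone_fraction`` of tumor cells, diluted by normal cells
    contributing two reference copies.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if not 0.0 <= clone_fraction <= 1.0:
        raise ValueError(f"clone_fraction must be in [0, 1], got {clone_fraction}")
    if multiplicity < 0 or multiplicity > tumor_total_cn:
        raise ValueError("multiplicity must satisfy 0 <= m <= tumor_total_cn")
    denom = purity * tumor_total_cn + (1.0 - purity) * 2.0
    if denom == 0.0:
        raise ZeroDivisionError(
            "homozygous-deletion site in a pure sample has no sequenceable copies"
        )
    return purity * clone_fraction * multiplicity / denom


def expected_baf(purity: float, cn_major: float, cn_minor: float) -> float:
    """Expected major-allele fraction at a germline-heterozygous SNP."""
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if cn_major < cn_minor or cn_minor < 0:
        raise ValueError("require cn_major >= cn_minor >= 0")
    denom = purity * (cn_major + cn_minor) + (1.0 - purity) * 2.0
    if denom == 0.0:
        raise ZeroDivisionError(
            "homozygous-deletion site in a pure sample has no sequenceable copies"
        )
    return (purity * cn_major + (1.0 - purity) * 1.0) / denom


def expected_logr(purity: float, tumor_total_cn: float,
                  sample_ploidy: float) -> float:
    """Expected log2 tumor/normal depth ratio after library-size normalization."""
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if sample_ploidy <= 0:
        raise ValueError(f"sample_ploidy must be > 0, got {sample_ploidy}")
    num = purity * tumor_total_cn + (1.0 - purity) * 2.0
    den = purity * sample_ploidy + (1.0 - purity) * 2.0
    return float(np.log2(num / den))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mutation:
    mutation_id: str
    chrom: str
    position: float
    multiplicity: int
    annotation: str
    gene: str | None = None
    driver: str | None = None

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError(f"{self.mutation_id}: multiplicity must be >= 1")
        if self.annotation not in ANNOTATION_CLASSES:
            raise ValueError(f"{self.mutation_id}: unknown annotation "
                             f"{self.annotation!r}")


@dataclass
class CloneGenotype:
    """Per-arm parental copy numbers plus the clone's mutation set."""

    clone_id: str
    parent_id: str | None
    arm_cn: dict[tuple[str, str], tuple[int, int]]  # (chrom, arm) -> (mat, pat)
    mutations: dict[str, Mutation] = field(default_factory=dict)
    wgd: bool = False

    def total_cn(self, chrom: str, arm: str) -> int:
        mat, pat = self.arm_cn[(chrom, arm)]
        return mat + pat

    def chrom_total_cn(self, chrom: str, genome: GenomeModel,
                       position: float | None = None) -> int:
        if position is None:
            # use p arm (monosomies here are whole-chromosome)
            return self.total_cn(chrom, "p")
        arm = genome.chromosome(chrom).arm_of(position)
        return self.total_cn(chrom, arm)

    def ploidy(self, genome: GenomeModel) -> float:
        tot = 0.0
        for c in genome.chromosomes:
            for arm in ("p", "q"):
                lo, hi = c.arm_bounds(arm)
                tot += (hi - lo) * self.total_cn(c.name, arm)
        return tot / genome.total_length

    def validate(self, genome: GenomeModel) -> None:
        for (chrom, arm), (mat, pat) in self.arm_cn.items():
            if mat < 0 or pat < 0:
                raise ValueError(f"{self.clone_id}: negative CN on {chrom}{arm}")
        for mut in self.mutations.values():
            cn = self.chrom_total_cn(mut.chrom, genome, mut.position)
            if mut.multiplicity > cn:
                raise ValueError(
                    f"{self.clone_id}: mutation {mut.mutation_id} multiplicity "
                    f"{mut.multiplicity} exceeds total CN {cn}"
                )


@dataclass(frozen=True)
class BranchEvents:
    """Ordered events on one clone-tree edge.

    Monosomies and driver point mutations happen before a WGD on the same
    edge; passenger mutations are drawn at uniform times along the edge and
    those predating the WGD (time < ``wgd_time``) are doubled by it.
    """

    monosomies: tuple[str, ...] = ()
    drivers: tuple[str, ...] = ()          # gene names from the genome catalog
    wgd: bool = False
    arm_gains: tuple[tuple[str, str], ...] = ()  # (chrom, arm), applied post-WGD
    passenger_rate: float = 0.0            # Poisson mean, nonsynonymous
    synonymous_rate: float = 0.0           # Poisson mean, synonymous passengers
    wgd_time: float = 0.5                  # position of WGD along the branch

    def __post_init__(self) -> None:
        if self.passenger_rate < 0 or self.synonymous_rate < 0:
            raise ValueError("passenger rates must be >= 0")
        if not 0.0 <= self.wgd_time <= 1.0:
            raise ValueError("wgd_time must be in [0, 1]")


@dataclass(frozen=True)
class RegionSpec:
    region_id: str
    clone_fractions: dict[str, float]
    purity: float
    coverage: float = 100.0
    metastasis: bool = False
    subcategory: str = "classic"           # classic | atyp | dediff

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"{self.region_id}: purity must be in (0, 1]")
        s = sum(self.clone_fractions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"{self.region_id}: clone fractions sum to {s}, not 1")
        if self.subcategory not in ("classic", "atyp", "dediff"):
            raise ValueError(f"{self.region_id}: unknown subcategory")


@dataclass(frozen=True)
class EvolutionScenario:
    """Clone tree (edges carry BranchEvents) plus multiregion sampling plan."""

    branches: tuple[tuple[str, str, BranchEvents], ...]  # (clone, parent, events)
    regions: tuple[RegionSpec, ...]
    error_rate: float = 0.0                # symmetric per-read error

    def __post_init__(self) -> None:
        clone_ids = {ROOT_CLONE} | {c for c, _, _ in self.branches}
        for clone, parent, _ in self.branches:
            if parent not in clone_ids:
                raise ValueError(f"clone {clone}: unknown parent {parent}")
        for r in self.regions:
            for cid in r.clone_fractions:
                if cid not in clone_ids or cid == ROOT_CLONE:
                    raise ValueError(
                        f"region {r.region_id} references undefined clone {cid!r}"
                    )

    def clone_order(self) -> list[str]:
        """Clones in parent-before-child order."""
        parent_of = {c: p for c, p, _ in self.branches}
        order: list[str] = []
        remaining = dict(parent_of)
        while remaining:
            progressed = False
            for c, p in list(remaining.items()):
                if p == ROOT_CLONE or p in order:
                    order.append(c)
                    del remaining[c]
                    progressed = True
            if not progressed:
                raise ValueError("clone tree contains a cycle")
        return order


@dataclass
class SimulatedDataset:
    snp_table: pd.DataFrame
    variant_table: pd.DataFrame
    truth: dict
    master_seed: int
    genome: GenomeModel
    scenario: EvolutionScenario


# ---------------------------------------------------------------------------
# genotype construction
# ---------------------------------------------------------------------------

def _substream(master_seed: int, *tags: str) -> np.random.Generator:
    """Independent stream per (seed, tag...) — stable under region addition."""
    keys = tuple(zlib.crc32(t.encode()) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=keys))


def build_genotypes(scenario: EvolutionScenario, genome: GenomeModel,
                    seed: int) -> dict[str, CloneGenotype]:
    """Walk the clone tree applying each edge's events to the parent genotype."""
    genotypes: dict[str, CloneGenotype] = {
        ROOT_CLONE: CloneGenotype(
            clone_id=ROOT_CLONE, parent_id=None,
            arm_cn={(c.name, arm): (1, 1)
                    for c in genome.chromosomes for arm in ("p", "q")},
        )
    }
    events_of = {c: ev for c, _, ev in scenario.branches}
    parent_of = {c: p for c, p, _ in scenario.branches}
    mut_counter = 0
    for clone in scenario.clone_order():
        parent = genotypes[parent_of[clone]]
        ev = events_of[clone]
        rng = _substream(seed, "branch", clone)
        arm_cn = dict(parent.arm_cn)
        muts = dict(parent.mutations)

        # monosomies: lose the paternal homolog of the whole chromosome
        for chrom in ev.monosomies:
            for arm in ("p", "q"):
                mat, pat = arm_cn[(chrom, arm)]
                if pat > 0:
                    arm_cn[(chrom, arm)] = (mat, pat - 1)
                elif mat > 0:
                    arm_cn[(chrom, arm)] = (mat - 1, pat)
                else:
                    raise ValueError(f"monosomy of nullisomic {chrom} in {clone}")

        new_pre_wgd: list[str] = []

        for gene_name in ev.drivers:
            g = genome.gene(gene_name)
            mut_counter += 1
            mid = f"m{mut_counter:05d}_{gene_name}"
            arm = genome.chromosome(g.chrom).arm_of(g.midpoint)
            if sum(arm_cn[(g.chrom, arm)]) < 1:
                raise ValueError(f"driver {gene_name} on nullisomic {g.chrom}")
            muts[mid] = Mutation(mid, g.chrom, g.midpoint, 1, "nonsynonymous",
                                 gene=gene_name, driver=gene_name)
            new_pre_wgd.append(mid)

        # passengers: chromosome weighted by length x current copies,
        # uniform position, uniform time along the branch
        weights = np.array(
            [c.length * sum(arm_cn[(c.name, "p")]) for c in genome.chromosomes],
            dtype=float)
        # arm-level weighting uses p-arm copies; monosomies here are
        # whole-chromosome so p and q copies agree in practice
        for ann, rate in (("nonsynonymous", ev.passenger_rate),
                          ("synonymous", ev.synonymous_rate)):
            n = int(rng.poisson(rate)) if rate > 0 else 0
            if n == 0:
                continue
            probs = weights / weights.sum()
            chrom_idx = rng.choice(len(genome.chromosomes), size=n, p=probs)
            times = rng.random(n)
            for i in range(n):
                c = genome.chromosomes[int(chrom_idx[i])]
                pos = round(float(rng.random() * c.length), 6)
                mut_counter += 1
                mid = f"m{mut_counter:05d}"
                muts[mid] = Mutation(mid, c.name, pos, 1, ann)
                if ev.wgd and times[i] < ev.wgd_time:
                    new_pre_wgd.append(mid)

        wgd_flag = parent.wgd
        if ev.wgd:
            # WGD doubles every arm copy number; inherited mutations and
            # this branch's pre-WGD mutations double in multiplicity
            arm_cn = {k: (2 * m, 2 * p) for k, (m, p) in arm_cn.items()}
            doubled = set(parent.mutations) | set(new_pre_wgd)
            muts = {
                mid: (replace(m, multiplicity=2 * m.multiplicity)
                      if mid in doubled else m)
                for mid, m in muts.items()
            }
            wgd_flag = True

        # post-WGD arm gains (+1 copy of the retained/major haplotype) —
        # the odd-copy aneuploidy that accompanies WGD in real tumors
        for chrom, arm in ev.arm_gains:
            mat, pat = arm_cn[(chrom, arm)]
            if mat >= pat:
                arm_cn[(chrom, arm)] = (mat + 1, pat)
            else:
                arm_cn[(chrom, arm)] = (mat, pat + 1)

        gt = CloneGenotype(clone, parent_of[clone], arm_cn, muts, wgd_flag)
        gt.validate(genome)
        genotypes[clone] = gt
    return genotypes


# ---------------------------------------------------------------------------
# observation emission
# ---------------------------------------------------------------------------

def _snp_sites(genome: GenomeModel) -> pd.DataFrame:
    rows = []
    for c in genome.chromosomes:
        n = c.n_snp_sites
        positions = np.round((np.arange(n) + 0.5) * c.length / n, 6)
        for p in positions:
            rows.append((c.name, float(p)))
    df = pd.DataFrame(rows, columns=["chrom", "position"])
    df.insert(0, "site_id", [f"s{i:06d}" for i in range(len(df))])
    return df


def _mixture_cn(genotypes: dict[str, CloneGenotype], fractions: dict[str, float],
                chrom: str, arm: str) -> tuple[float, float, float]:
    """(maternal, paternal, total) copy number averaged over the clone mixture."""
    mat = pat = 0.0
    for cid, f in fractions.items():
        m, p = genotypes[cid].arm_cn[(chrom, arm)]
        mat += f * m
        pat += f * p
    return mat, pat, mat + pat


def _truth_segments(genome: GenomeModel, genotypes: dict[str, CloneGenotype],
                    region: RegionSpec) -> tuple[list[dict], float]:
    """Merge adjacent arms with identical mixed CN into truth segments."""
    p = region.purity
    # tumor ploidy of the mixture (length-weighted total CN)
    tot = 0.0
    for c in genome.chromosomes:
        for arm in ("p", "q"):
            lo, hi = c.arm_bounds(arm)
            _, _, t = _mixture_cn(genotypes, region.clone_fractions, c.name, arm)
            tot += (hi - lo) * t
    ploidy = tot / genome.total_length
    segs: list[dict] = []
    for c in genome.chromosomes:
        for arm in ("p", "q"):
            lo, hi = c.arm_bounds(arm)
            mat, pat, t = _mixture_cn(genotypes, region.clone_fractions,
                                      c.name, arm)
            major, minor = max(mat, pat), min(mat, pat)
            row = {
                "chrom": c.name, "start": lo, "end": hi,
                "cn_total": t, "cn_major": major, "cn_minor": minor,
                "expected_logr": expected_logr(p, t, ploidy),
                "expected_baf": expected_baf(p, major, minor),
            }
            if (segs and segs[-1]["chrom"] == c.name
                    and segs[-1]["cn_major"] == major
                    and segs[-1]["cn_minor"] == minor):
                segs[-1]["end"] = hi
            else:
                segs.append(row)
    return segs, ploidy


def simulate_scenario(scenario: EvolutionScenario, genome: GenomeModel | None = None,
                      seed: int = 0) -> SimulatedDataset:
    """Run the forward simulation; deterministic given ``seed``."""
    if genome is None:
        genome = default_genome()
    genotypes = build_genotypes(scenario, genome, seed)
    sites = _snp_sites(genome)

    # B-allele parental origin fixed per site for the whole patient
    hap_rng = _substream(seed, "haplotypes")
    b_is_maternal = hap_rng.random(len(sites)) < 0.5

    arm_of_site = np.array([
        genome.chromosome(c).arm_of(p)
        for c, p in zip(sites["chrom"], sites["position"])
    ])

    all_muts: dict[str, Mutation] = {}
    for cid in scenario.clone_order():
        for mid, m in genotypes[cid].mutations.items():
            all_muts.setdefault(mid, m)
    mut_ids = sorted(all_muts)

    snp_frames = []
    var_frames = []
    truth_regions = {}
    for region in scenario.regions:
        rng = _substream(seed, "region", region.region_id)
        p = region.purity
        segs, ploidy = _truth_segments(genome, genotypes, region)

        # --- SNP sites ---
        mat = np.empty(len(sites))
        pat = np.empty(len(sites))
        for c in genome.chromosomes:
            for arm in ("p", "q"):
                mask = (sites["chrom"].values == c.name) & (arm_of_site == arm)
                m_, p_, _ = _mixture_cn(genotypes, region.clone_fractions,
                                        c.name, arm)
                mat[mask] = m_
                pat[mask] = p_
        total = mat + pat
        b_copies = np.where(b_is_maternal, mat, pat)
        denom = p * total + (1 - p) * 2.0
        exp_b = (p * b_copies + (1 - p) * 1.0) / denom
        eps = scenario.error_rate
        if eps:
            exp_b = exp_b * (1 - 2 * eps) + eps
        t_depth = rng.poisson(region.coverage * denom / 2.0)
        n_depth = rng.poisson(region.coverage, size=len(sites))
        t_alt = rng.binomial(t_depth, exp_b)
        n_alt = rng.binomial(n_depth, 0.5)
        snp = sites.copy()
        snp["region"] = region.region_id
        snp["t_alt"] = t_alt
        snp["t_ref"] = t_depth - t_alt
        snp["n_alt"] = n_alt
        snp["n_ref"] = n_depth - n_alt
        snp_frames.append(snp)

        # --- somatic variants ---
        vrows = []
        mut_truth = {}
        for mid in mut_ids:
            m = all_muts[mid]
            arm = genome.chromosome(m.chrom).arm_of(m.position)
            mmix = sum(
                f * genotypes[cid].mutations[mid].multiplicity
                for cid, f in region.clone_fractions.items()
                if mid in genotypes[cid].mutations
            )
            _, _, tcn = _mixture_cn(genotypes, region.clone_fractions,
                                    m.chrom, arm)
            site_denom = p * tcn + (1 - p) * 2.0
            vaf = p * mmix / site_denom if site_denom > 0 else 0.0
            if eps:
                vaf = vaf * (1 - 2 * eps) + eps
            depth = int(rng.poisson(region.coverage * site_denom / 2.0))
            alt = int(rng.binomial(depth, vaf)) if depth > 0 else 0
            vrows.append((mid, m.gene or "", m.chrom, m.position,
                          region.region_id, alt, depth - alt, m.annotation,
                          m.driver or ""))
            mut_truth[mid] = {
                "expected_vaf": vaf, "tumor_total_cn": tcn,
                "mixed_multiplicity": mmix,
            }
        var_frames.append(pd.DataFrame(
            vrows, columns=["mutation_id", "gene", "chrom", "position",
                            "region", "alt", "ref", "annotation", "driver"]))

        truth_regions[region.region_id] = {
            "purity": p,
            "coverage": region.coverage,
            "tumor_ploidy": ploidy,
            "metastasis": region.metastasis,
            "subcategory": region.subcategory,
            "clone_fractions": dict(region.clone_fractions),
            "wgd": any(genotypes[c].wgd and f > 0.5
                       for c, f in region.clone_fractions.items()),
            "segments": segs,
            "mutations": mut_truth,
        }

    truth = {
        "schema_version": 1,
        "master_seed": seed,
        "clones": {
            cid: {
                "parent": gt.parent_id,
                "wgd": gt.wgd,
                "ploidy": gt.ploidy(genome),
                "arm_cn": {f"{c}{a}": list(cn)
                           for (c, a), cn in sorted(gt.arm_cn.items())},
                "mutations": {
                    mid: {"chrom": m.chrom, "position": m.position,
                          "multiplicity": m.multiplicity,
                          "annotation": m.annotation, "gene": m.gene,
                          "driver": m.driver}
                    for mid, m in sorted(gt.mutations.items())
                },
            }
            for cid, gt in genotypes.items() if cid != ROOT_CLONE
        },
        "regions": truth_regions,
    }
    return SimulatedDataset(
        snp_table=pd.concat(snp_frames, ignore_index=True),
        variant_table=pd.concat(var_frames, ignore_index=True),
        truth=truth,
        master_seed=seed,
        genome=genome,
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# default scenario
# ---------------------------------------------------------------------------

def default_scenario(purity: float = 0.7, coverage: float = 100.0,
                     classic_rate: float = 28.0, dediff_extra_rate: float = 12.0,
                     synonymous_fraction: float = 0.5,
                     monosomies: tuple[str, ...] = CLASSIC_MONOSOMY_CHROMS,
                     with_metastasis: bool = False,
                     dediff_purity: float | None = None,
                     arm_gains: tuple[tuple[str, str], ...] = (
                         ("1", "q"), ("7", "p"), ("7", "q")),
                     error_rate: float = 0.0) -> EvolutionScenario:
    """Two-clone progression: hypodiploid classic -> WGD dedifferentiated.

    The trunk rate defaults to 28 nonsynonymous mutations (the typical
    burden of a classic sample) and the dedifferentiation branch adds ~12
    more, so dedifferentiated samples carry ~40.  The dedifferentiated
    clone carries a post-WGD 1q gain by default (copy-number gains beyond
    two copies, e.g. of 1q, accompany WGD in these tumors); an odd-copy
    segment also keeps the purity/ploidy fit identifiable, since a genome
    whose copy numbers are all even is indistinguishable from its halved
    version at higher purity.
    """
    branches = (
        ("classic", ROOT_CLONE, BranchEvents(
            monosomies=tuple(monosomies), drivers=("TP53L",),
            passenger_rate=classic_rate,
            synonymous_rate=classic_rate * synonymous_fraction)),
        ("dediff", "classic", BranchEvents(
            drivers=("PTENL",), wgd=True, arm_gains=tuple(arm_gains),
            passenger_rate=dediff_extra_rate,
            synonymous_rate=dediff_extra_rate * synonymous_fraction)),
    )
    regions = [
        RegionSpec("R1_classic", {"classic": 1.0}, purity, coverage,
                   metastasis=False, subcategory="classic"),
        RegionSpec("R2_dediff", {"dediff": 1.0},
                   dediff_purity if dediff_purity is not None else purity,
                   coverage, metastasis=False, subcategory="dediff"),
    ]
    if with_metastasis:
        regions.append(
            RegionSpec("R3_met", {"dediff": 1.0},
                       dediff_purity if dediff_purity is not None else purity,
                       coverage, metastasis=True, subcategory="dediff"))
    return EvolutionScenario(branches=branches, regions=tuple(regions),
                             error_rate=error_rate)


def write_dataset(dataset: SimulatedDataset, directory) -> dict[str, str]:
    """Write the dataset's tables; see :mod:`chromoevo.io` for formats."""
    from . import io as cio
    return cio.write_dataset(dataset, directory)
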