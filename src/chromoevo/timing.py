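"""Mutation filtering, burden, multiplicity and event timing vs WGD.

The ordering logic exploits zygosity: a mutation present on every copy of
a chromosome that has undergone duplication (multiplicity = total CN with
minor CN 0) must have been acquired *before* the duplication, because a
post-duplication mutation can only sit on one of the copies.  In the
chromophobe-RCC progression this is the signature by which TP53 and PTEN
mutations — hemizygous on monosomic chromosomes 17 and 10 in the classic
clone — are shown to precede whole-genome doubling when they appear
homozygous on (2, 0) chromosomes in the dedifferentiated clone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ascn import SegmentProfile, WgdCall

__all__ = [
    "ZYGOSITY_LABELS",
    "TimingCall",
    "filter_variants",
    "tmb",
    "mutation_logor",
    "estimate_multiplicity",
    "classify_zygosity",
    "annotate_variants",
    "order_events",
    "VAF_THRESHOLD",
    "SUBCLONAL_M",
]

logger = logging.getLogger(__name__)

VAF_THRESHOLD = 0.15      # somatic call threshold on tumor VAF
SUBCLONAL_M = 0.75        # below this multiplicity a variant is subclonal
PURITY_EXCLUDE = 0.3      # samples below this purity are excluded from timing

ZYGOSITY_LABELS = ("hemizygous_loh", "homozygous", "heterozygous",
                   "subclonal", "indeterminate")

VERDICTS = ("mutation_before_duplication", "mutation_after_duplication",
            "unordered")


@dataclass(frozen=True)
class TimingCall:
    patient: str
    gene: str
    mutation_id: str
    verdict: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


# ---------------------------------------------------------------------------
# filtering and burden
# ---------------------------------------------------------------------------

def filter_variants(variants: pd.DataFrame,
                    vaf_threshold: float = VAF_THRESHOLD) -> pd.DataFrame:
    """Somatic-call filter: VAF >= threshold (boundary retained) and
    nonsynonymous annotation.  Variants without an annotation are excluded
    and counted in the log."""
    df = variants.copy()
    depth = df["alt"] + df["ref"]
    df["vaf"] = np.where(depth > 0, df["alt"] / depth.replace(0, np.nan), 0.0)
    df["vaf"] = df["vaf"].fillna(0.0)
    missing = df["annotation"].isna() | (df["annotation"] == "")
    if missing.any():
        logger.warning("%d variants lack annotation class; excluded",
                       int(missing.sum()))
    keep = (~missing) & (df["annotation"] == "nonsynonymous") \
        & (df["vaf"] >= vaf_threshold)
    return df[keep].reset_index(drop=True)


def tmb(filtered_variants: pd.DataFrame) -> int:
    """Total mutation burden: the count of retained nonsynonymous variants."""
    return int(len(filtered_variants))


def tmb_by_sample(filtered_variants: pd.DataFrame) -> pd.Series:
    if len(filtered_variants) == 0:
        return pd.Series(dtype=int)
    return filtered_variants.groupby("region").size()


# ---------------------------------------------------------------------------
# multiplicity and zygosity
# ---------------------------------------------------------------------------

def mutation_logor(alt: float, ref: float) -> float:
    """Natural-log allele odds of a somatic mutation, Haldane-corrected.

    Under the assumption that the mutation lies on the major allele, this is
    directly comparable to the segment-level het-site |logOR| and can be
    overlaid on B-allele plots.
    """
    if alt + ref <= 0:
        raise ValueError("alt + ref must be > 0")
    return float(np.log((alt + 0.5) / (ref + 0.5)))


def estimate_multiplicity(vaf: float, purity: float,
                          tumor_total_cn: int) -> tuple[float, int, bool]:
    """Invert the purity-mixed VAF model for the mutation multiplicity.

    Returns (m_hat, m_rounded clamped to [1, total CN], subclonal_flag);
    the subclonal flag is raised when m_hat < 0.75.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if tumor_total_cn < 1:
        raise ValueError("tumor_total_cn must be >= 1")
    m_hat = vaf * (purity * tumor_total_cn + (1.0 - purity) * 2.0) / purity
    m = int(np.clip(round(m_hat), 1, tumor_total_cn))
    return float(m_hat), m, m_hat < SUBCLONAL_M


def classify_zygosity(m: int, cn_total: int | None, cn_minor: int | None,
                      subclonal: bool = False) -> str:
    """Zygosity of a somatic mutation given its multiplicity and local CN.

    hemizygous_loh: single remaining copy carries the mutation (total CN 1);
    homozygous: every copy mutated with the other parental allele lost;
    heterozygous: fewer copies mutated than present; subclonal overrides;
    indeterminate when copy number is unavailable.
    """
    if cn_total is None or cn_minor is None:
        return "indeterminate"
    if m > cn_total:
        raise ValueError(f"multiplicity {m} exceeds total CN {cn_total}")
    if subclonal:
        return "subclonal"
    if cn_total == 1:
        return "hemizygous_loh"
    if cn_minor == 0 and m == cn_total and cn_total >= 2:
        return "homozygous"
    return "heterozygous"


def _segment_at(profile: SegmentProfile, chrom: str,
                position: float) -> pd.Series | None:
    sub = profile.segments
    hit = sub[(sub["chrom"] == chrom) & (sub["start"] <= position)
              & (position < sub["end"])]
    if len(hit) == 0:
        return None
    return hit.iloc[0]


def annotate_variants(filtered: pd.DataFrame, profile: SegmentProfile
                      ) -> pd.DataFrame:
    """Attach multiplicity, zygosity and mutation logOR to filtered variants
    of one sample using its fitted segment profile."""
    rows = []
    for _, v in filtered.iterrows():
        seg = _segment_at(profile, v["chrom"], v["position"])
        rec = dict(v)
        rec["mutation_logor"] = mutation_logor(v["alt"], v["ref"])
        if seg is None:
            rec.update(m_hat=np.nan, multiplicity=np.nan,
                       cn_total=np.nan, cn_minor=np.nan,
                       zygosity="indeterminate")
        else:
            m_hat, m, sub = estimate_multiplicity(
                v["vaf"], profile.purity, max(int(seg["cn_total"]), 1))
            rec.update(
                m_hat=m_hat, multiplicity=m,
                cn_total=int(seg["cn_total"]), cn_minor=int(seg["cn_minor"]),
                zygosity=classify_zygosity(m, int(seg["cn_total"]),
                                           int(seg["cn_minor"]), sub))
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# event ordering
# ---------------------------------------------------------------------------

def _verdict_for_sample(zyg: str, m: int | float, cn_total: int | float,
                        cn_minor: int | float, wgd: bool) -> str:
    """Single-sample ordering rule; combined across samples by order_events."""
    if not wgd:
        return "unordered"
    if zyg == "homozygous" and cn_minor == 0 and cn_total >= 2:
        return "mutation_before_duplication"
    if m == 1 and cn_total >= 2:
        return "mutation_after_duplication"
    return "unordered"


def order_events(patient: str, annotated_by_sample: dict[str, pd.DataFrame],
                 wgd_by_sample: dict[str, WgdCall],
                 purity_by_sample: dict[str, float] | None = None,
                 drivers_only: bool = True) -> list[TimingCall]:
    """Order driver mutations relative to genome duplication per patient.

    A mutation is called before the duplication when it is homozygous on a
    minor-CN-0 chromosome in a WGD-positive sample — whether or not it is
    also seen hemizygous in a non-WGD sample — and after the duplication
    when it sits on a single copy of a duplicated chromosome.  Mutations are
    matched across samples by (chromosome, position); contradictory verdicts
    collapse to unordered with a conflict note.  Samples below the purity
    exclusion threshold do not contribute evidence.
    """
    evidence: dict[tuple, dict] = {}
    for sample, df in annotated_by_sample.items():
        if purity_by_sample is not None and \
                purity_by_sample.get(sample, 1.0) < PURITY_EXCLUDE:
            logger.info("sample %s excluded from timing (purity < %s)",
                        sample, PURITY_EXCLUDE)
            continue
        wgd = wgd_by_sample[sample].wgd
        for _, v in df.iterrows():
            if drivers_only and not v.get("driver"):
                continue
            key = (v["chrom"], v["position"])
            ev = evidence.setdefault(key, {
                "gene": v.get("gene") or v.get("driver") or "",
                "mutation_id": v["mutation_id"], "samples": {}})
            ev["samples"][sample] = {
                "zygosity": v["zygosity"],
                "multiplicity": v.get("multiplicity"),
                "cn_total": v.get("cn_total"),
                "cn_minor": v.get("cn_minor"),
                "wgd": wgd,
            }
    calls = []
    for key in sorted(evidence):
        ev = evidence[key]
        verdicts = set()
        for s, rec in ev["samples"].items():
            if rec["zygosity"] in ("indeterminate", "subclonal"):
                continue
            v = _verdict_for_sample(rec["zygosity"], rec["multiplicity"],
                                    rec["cn_total"], rec["cn_minor"],
                                    rec["wgd"])
            if v != "unordered":
                verdicts.add(v)
        if len(verdicts) == 1:
            verdict = verdicts.pop()
        elif len(verdicts) > 1:
            verdict = "unordered"
            ev["conflict"] = sorted(verdicts)
            logger.warning("patient %s %s: contradictory timing verdicts %s",
                           patient, ev["gene"], ev.get("conflict"))
        else:
            verdict = "unordered"
        extrapolated = any(
            rec["cn_total"] is not None and not pd.isna(rec["cn_total"])
            and rec["cn_total"] > 2 and rec["zygosity"] == "homozygous"
            for rec in ev["samples"].values())
        if extrapolated:
            ev["extrapolated_above_cn2"] = True
        calls.append(TimingCall(patient=patient, gene=ev["gene"],
                                mutation_id=ev["mutation_id"],
                                verdict=verdict, evidence=ev))
    return calls
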