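"""End-to-end report: simulate -> fit CN -> time events -> build tree.

`run_report` chains every stage on a simulated patient (or on supplied
tables), writes the standard outputs (SEG table, arm-call matrix, timing
TSV, Newick tree + sidecar, summary JSON) and returns the bundle in memory.
All randomness derives from the config seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ascn, io as cio, phylo, timing
from .config import RunConfig
from .genome import default_genome
from .karyosim import default_scenario, simulate_scenario

__all__ = ["run_report", "fit_all_regions"]

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1
_SUMMARY_REQUIRED = ("schema_version", "seed", "samples", "timing",
                     "tmb", "exclusions")


def fit_all_regions(snp_table: pd.DataFrame, config: RunConfig,
                    chrom_lengths: dict[str, float] | None = None
                    ) -> dict[str, ascn.SegmentProfile]:
    profiles = {}
    for region, grp in snp_table.groupby("region", sort=True):
        profiles[region] = ascn.fit_cn(
            grp, critical_coarse=config.critical_coarse,
            critical_fine=config.critical_fine,
            chrom_lengths=chrom_lengths, sample_id=region,
            cn_max=config.cn_max,
            purity_exclude=config.purity_exclude)
        logger.info("fit %s: purity=%.2f ploidy=%.2f residual=%.4f",
                    region, profiles[region].purity, profiles[region].ploidy,
                    profiles[region].residual)
    return profiles


def _validate_summary(summary: dict) -> None:
    missing = [k for k in _SUMMARY_REQUIRED if k not in summary]
    if missing:
        raise ValueError(f"summary schema violation: missing {missing}")


def run_report(config: RunConfig, out_dir, patient: str = "P1") -> dict:
    """Run the full pipeline on the configured simulated patient."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = default_genome(config.snp_sites_per_chrom)
    scenario = default_scenario(
        purity=config.purity, coverage=config.coverage,
        classic_rate=config.classic_rate,
        dediff_extra_rate=config.dediff_extra_rate,
        synonymous_fraction=config.synonymous_fraction,
        monosomies=config.monosomies,
        with_metastasis=config.with_metastasis,
        error_rate=config.error_rate)
    dataset = simulate_scenario(scenario, genome, seed=config.seed)
    paths = cio.write_dataset(dataset, out / "dataset")
    chrom_lengths = {c.name: float(c.length) for c in genome.chromosomes}

    # --- copy number ---
    profiles = fit_all_regions(dataset.snp_table, config, chrom_lengths)
    excluded = [r for r, p in profiles.items() if p.excluded]
    included = {r: p for r, p in profiles.items() if not p.excluded}
    for r in excluded:
        logger.warning("sample %s excluded: purity %.2f < %.2f", r,
                       profiles[r].purity, config.purity_exclude)
    cio.write_seg(profiles.values(), out / "segments.seg")
    wgd = {r: ascn.call_wgd(p) for r, p in profiles.items()}
    arm_table = [(c, a, float(s), float(e)) for c, a, s, e in genome.arm_table()]
    arm_calls = {r: ascn.call_arms(p, arm_table) for r, p in included.items()}
    arm_matrix = pd.DataFrame(
        {r: {ac.arm: ac.call for ac in calls}
         for r, calls in arm_calls.items()})
    arm_matrix.to_csv(out / "arm_calls.tsv", sep="\t")

    # --- variants, burden, timing ---
    filtered_by_region = {}
    annotated = {}
    for region, grp in dataset.variant_table.groupby("region"):
        filt = timing.filter_variants(grp, config.vaf_threshold)
        filtered_by_region[region] = filt
        logger.info("filter %s: %d/%d variants retained", region,
                    len(filt), len(grp))
        if region in included:
            annotated[region] = timing.annotate_variants(
                filt, profiles[region])
    tmb_by_region = {r: timing.tmb(f) for r, f in filtered_by_region.items()}
    subcat = {r.region_id: r.subcategory for r in scenario.regions}
    tmb_by_subcat = {}
    for cat in sorted(set(subcat.values())):
        vals = [tmb_by_region[r] for r in tmb_by_region
                if subcat.get(r) == cat and r not in excluded]
        if vals:
            tmb_by_subcat[cat] = {"median": float(np.median(vals)),
                                  "range": [min(vals), max(vals)]}
    purity_by_sample = {r: p.purity for r, p in profiles.items()}
    calls = timing.order_events(patient, annotated, wgd, purity_by_sample)
    timing_rows = [{"patient": c.patient, "gene": c.gene,
                    "mutation_id": c.mutation_id, "verdict": c.verdict,
                    "evidence": json.dumps(c.evidence, default=str)}
                   for c in calls]
    pd.DataFrame(timing_rows).to_csv(out / "timing.tsv", sep="\t", index=False)

    # --- phylogeny ---
    tree = None
    if len(included) >= 2:
        filt_all = pd.concat([filtered_by_region[r] for r in included],
                             ignore_index=True)
        patterns = phylo.build_pattern_matrix(filt_all)
        meta = {r.region_id: {
            "subcategory": r.subcategory,
            "metastasis": r.metastasis,
            "ploidy": round(profiles[r.region_id].ploidy, 3),
        } for r in scenario.regions if r.region_id in included}
        tree = phylo.build_tree(patterns, meta)
        phylo.annotate_tree(tree, calls, arm_calls, wgd)
        phylo.write_tree(tree, out / "tree.nwk", out / "tree.json")

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "samples": {
            r: {"purity": p.purity, "ploidy": round(p.ploidy, 3),
                "wgd": wgd[r].wgd, "wgd_fraction": round(wgd[r].fraction, 4),
                "subcategory": subcat.get(r), "excluded": p.excluded,
                "low_confidence": p.low_confidence}
            for r, p in profiles.items()},
        "timing": {c.gene or c.mutation_id: c.verdict for c in calls},
        "tmb": {"by_sample": tmb_by_region, "by_subcategory": tmb_by_subcat},
        "exclusions": excluded,
    }
    _validate_summary(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=cio._json_default)
    return {"summary": summary, "profiles": profiles, "wgd": wgd,
            "arm_calls": arm_calls, "timing_calls": calls, "tree": tree,
            "dataset": dataset, "paths": paths}
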