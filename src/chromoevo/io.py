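"""Readers and writers for the formats the pipeline touches.

Conventions: internal coordinates are 0-based half-open floats in abstract
megabase-like units, quantized to 1e-6; VCF output converts to 1-based
integer base pairs (1 abstract unit = 1e6 bp) and conversion is inverted
exactly on read.  TSV tables are tab-delimited with a header row; the truth
schema is versioned JSON.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "write_dataset",
    "read_vcf_minimal",
    "write_vcf_minimal",
    "read_snp_tsv",
    "read_variant_tsv",
    "read_truth",
    "write_seg",
    "read_seg",
]

_BP = 1_000_000  # abstract unit -> base pairs

VARIANT_COLUMNS = ["mutation_id", "gene", "chrom", "position", "region",
                   "alt", "ref", "annotation", "driver"]
SNP_COLUMNS = ["site_id", "chrom", "position", "region",
               "t_alt", "t_ref", "n_alt", "n_ref"]
SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_sites", "mean_logr",
               "lor", "cn_total", "cn_major", "cn_minor"]


def _pos_to_bp(position: float) -> int:
    return int(round(position * _BP)) + 1  # 1-based


def _bp_to_pos(pos_bp: int) -> float:
    return round((pos_bp - 1) / _BP, 6)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf_minimal(variants: pd.DataFrame, path,
                      chrom_lengths: dict[str, float]) -> None:
    """Minimal multi-sample VCF 4.2: one sample column per region, AD-style
    allelic depths, mutation metadata in ID/INFO."""
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=int(round(length * _BP)) + 1)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("ANN", 1, "String", "Annotation class")
    header.info.add("DRIVER", 1, "String", "Driver label")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    regions = sorted(variants["region"].unique()) if len(variants) else []
    for r in regions:
        header.add_sample(str(r))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        if len(variants) == 0:
            return
        key = ["mutation_id", "gene", "chrom", "position", "annotation",
               "driver"]
        grouped = variants.groupby(key, sort=False, dropna=False)
        recs = []
        for (mid, gene, chrom, pos, ann, driver), grp in grouped:
            recs.append((chrom, pos, mid, gene, ann, driver, grp))
        recs.sort(key=lambda r: (r[0], r[1], r[2]))
        for chrom, pos, mid, gene, ann, driver, grp in recs:
            rec = vcf.new_record(contig=str(chrom),
                                 start=_pos_to_bp(pos) - 1,
                                 alleles=("A", "T"), id=str(mid))
            if gene:
                rec.info["GENE"] = str(gene)
            rec.info["ANN"] = str(ann)
            if driver:
                rec.info["DRIVER"] = str(driver)
            by_region = {row["region"]: row for _, row in grp.iterrows()}
            for r in regions:
                if r in by_region:
                    row = by_region[r]
                    rec.samples[str(r)]["AD"] = (int(row["ref"]),
                                                 int(row["alt"]))
                else:
                    rec.samples[str(r)]["AD"] = (0, 0)
            vcf.write(rec)


def read_vcf_minimal(path) -> pd.DataFrame:
    """Read a minimal VCF back to the long variant table (one row per
    mutation x region).  Records lacking allelic depths are fatal, with the
    record number and locus in the message."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for i, rec in enumerate(vcf, start=1):
            for sample in samples:
                ad = rec.samples[sample].get("AD")
                if ad is None or ad[0] is None:
                    raise ValueError(
                        f"record {i} at {rec.chrom}:{rec.pos} sample "
                        f"{sample}: missing AD depths")
                rows.append({
                    "mutation_id": rec.id or f"rec{i}",
                    "gene": rec.info.get("GENE", ""),
                    "chrom": rec.chrom,
                    "position": _bp_to_pos(rec.pos),
                    "region": sample,
                    "alt": int(ad[1]),
                    "ref": int(ad[0]),
                    "annotation": rec.info.get("ANN", ""),
                    "driver": rec.info.get("DRIVER", ""),
                })
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_snp_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "region": str})
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_variant_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "region": str},
                     keep_default_na=False)
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_seg(profiles, path) -> None:
    """SEG-like TSV across samples from SegmentProfile objects."""
    frames = []
    for prof in profiles:
        seg = prof.segments.copy()
        seg.insert(0, "sample", prof.sample_id or "sample")
        frames.append(seg[["sample", "chrom", "start", "end", "n_sites",
                           "mean_logr", "lor", "cn_total", "cn_major",
                           "cn_minor"]])
    _write_tsv(pd.concat(frames, ignore_index=True), path)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# dataset bundle
# ---------------------------------------------------------------------------

def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def write_dataset(dataset, directory) -> dict[str, str]:
    """Write a SimulatedDataset: VCF + TSV mirror, SNP TSV, truth JSON and
    BED-like arm/gene tables.  Returns the path map."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": str(d / "variants.vcf"),
            "variants_tsv": str(d / "variants.tsv"),
            "snps_tsv": str(d / "snps.tsv"),
            "truth_json": str(d / "truth.json"),
            "arms_tsv": str(d / "arms.tsv"),
            "genes_tsv": str(d / "genes.tsv"),
        }
        genome = dataset.genome
        chrom_lengths = {c.name: float(c.length) for c in genome.chromosomes}
        write_vcf_minimal(dataset.variant_table, paths["vcf"], chrom_lengths)
        _write_tsv(dataset.variant_table[VARIANT_COLUMNS], paths["variants_tsv"])
        _write_tsv(dataset.snp_table[SNP_COLUMNS], paths["snps_tsv"])
        with open(paths["truth_json"], "w") as fh:
            json.dump(dataset.truth, fh, indent=1, default=_json_default)
        arms = pd.DataFrame(genome.arm_table(),
                            columns=["chrom", "arm", "start", "end"])
        _write_tsv(arms, paths["arms_tsv"])
        genes = pd.DataFrame(
            [(g.chrom, g.start, g.end, g.name, int(g.driver))
             for g in genome.genes],
            columns=["chrom", "start", "end", "name", "driver"])
        _write_tsv(genes, paths["genes_tsv"])
        return paths
    except OSError as exc:
        raise OSError(f"failed writing dataset under {d}: {exc}") from exc
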