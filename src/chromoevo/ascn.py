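"""Allele-specific somatic copy number from tumor/normal allelic depths.

The pipeline mirrors the classical two-pass design of exome CNV callers:

1. per-SNP statistics — logR (library-size-normalized log2 depth ratio,
   total copy number) and logOR (allelic log odds at germline-het sites,
   allelic imbalance);
2. recursive binary segmentation of the bivariate (logR, |logOR|) series,
   run twice: a coarse pass whose segments feed the purity/ploidy fit, and
   a fine pass with a lower critical value for focal events;
3. a joint purity / diploid-logR-offset grid search assigning every segment
   an integer (major, minor) copy-number pair;
4. threshold calls: whole-genome doubling (major CN >= 2 over >= 50% of the
   autosomal genome), chromosome-arm gain/loss (> 50% of the arm), and
   gene-level copy numbers inherited from fine-pass segments.

Because allele phase is unobserved, allelic imbalance is summarized per
segment by a variance-debiased magnitude of the per-site logOR — folding
|logOR| directly is upward-biased at balanced states, so the segment
summary subtracts the delta-method read-count variance before comparison
with the model's |log-odds| for each candidate copy-number pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .karyosim import expected_baf

__all__ = [
    "SegmentProfile",
    "ArmCall",
    "WgdCall",
    "site_stats",
    "segment_genome",
    "PurityPloidyModel",
    "fit_purity_ploidy",
    "fit_cn",
    "call_wgd",
    "call_arms",
    "gene_copy_number",
    "differential_gene_cn",
    "DEFAULT_CRITICAL_COARSE",
    "DEFAULT_CRITICAL_FINE",
]

# Calibrated on flat-noise simulations to a <=5% whole-genome false-split
# rate (the coarse pass is stricter by design, mirroring the two-pass
# coarse->fine convention of FACETS-style callers).
DEFAULT_CRITICAL_COARSE = 60.0
DEFAULT_CRITICAL_FINE = 35.0

_LOR_CAP = 4.0  # expected |logOR| cap; read-count corrections bound observation


@dataclass
class SegmentProfile:
    """Fitted segments plus sample-level purity/ploidy.

    ``segments`` columns: chrom, start, end, n_sites, mean_logr, lor
    (debiased allelic-imbalance magnitude), cn_total, cn_major, cn_minor.
    """

    segments: pd.DataFrame
    purity: float
    ploidy: float
    dip_offset: float          # fitted logR of a (1,1) diploid segment
    residual: float
    low_confidence: bool = False
    excluded: bool = False     # purity below the exclusion threshold
    sample_id: str | None = None

    def __post_init__(self) -> None:
        seg = self.segments
        if not (seg["cn_major"] >= seg["cn_minor"]).all():
            raise ValueError("major CN must be >= minor CN")
        if not (seg["cn_minor"] >= 0).all():
            raise ValueError("minor CN must be >= 0")


@dataclass(frozen=True)
class ArmCall:
    arm: str                   # e.g. "17p"
    call: str                  # gain | loss | neutral
    fraction: float            # fraction of the arm supporting the call

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


@dataclass(frozen=True)
class WgdCall:
    wgd: bool
    fraction: float            # autosomal length share with major CN >= 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.wgd != (self.fraction >= 0.5):
            raise ValueError("flag must equal (fraction >= 0.5)")


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------

def site_stats(snp_table: pd.DataFrame, min_normal_depth: int = 10) -> pd.DataFrame:
    """Per-site logR and logOR from paired tumor/normal allelic depths.

    logR is library-size normalized: log2[(t/n) * (sum n / sum t)].  logOR is
    the natural-log allelic odds ratio with Haldane's 0.5 correction.  Sites
    with normal depth below ``min_normal_depth`` are dropped before the
    library-size factor is computed.
    """
    if len(snp_table) == 0:
        raise ValueError("empty SNP table")
    df = snp_table.copy()
    t_tot = df["t_alt"].to_numpy(float) + df["t_ref"].to_numpy(float)
    n_tot = df["n_alt"].to_numpy(float) + df["n_ref"].to_numpy(float)
    keep = n_tot >= min_normal_depth
    df, t_tot, n_tot = df[keep].copy(), t_tot[keep], n_tot[keep]
    if len(df) == 0:
        raise ValueError("no sites pass the normal-depth filter")
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["position"].to_numpy()
        bad = np.nonzero(np.diff(pos) <= 0)[0]
        if bad.size:
            raise ValueError(
                f"positions not strictly increasing on chromosome {chrom} "
                f"at site index {bad[0] + 1} (position {pos[bad[0] + 1]})"
            )
    libnorm = n_tot.sum() / t_tot.sum()
    out = pd.DataFrame({
        "chrom": df["chrom"].to_numpy(),
        "position": df["position"].to_numpy(),
        "logr": np.log2(np.maximum(t_tot, 0.5) / n_tot * libnorm),
        "logor": (np.log((df["t_alt"] + 0.5) / (df["t_ref"] + 0.5))
                  - np.log((df["n_alt"] + 0.5) / (df["n_ref"] + 0.5))),
        "t_depth": t_tot.astype(int),
        "n_depth": n_tot.astype(int),
        # per-site logOR noise variance (delta-method with Haldane counts)
        "logor_var": (1.0 / (df["t_alt"] + 0.5) + 1.0 / (df["t_ref"] + 0.5)
                      + 1.0 / (df["n_alt"] + 0.5) + 1.0 / (df["n_ref"] + 0.5)),
    })
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _split_stats(x: np.ndarray, min_seg: int) -> np.ndarray:
    """Pooled two-sample t^2 at every admissible split of one series."""
    n = len(x)
    ks = np.arange(min_seg, n - min_seg + 1)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    n1 = ks.astype(float)
    n2 = n - n1
    s1, s2 = cs[ks], cs[-1] - cs[ks]
    q1, q2 = cs2[ks], cs2[-1] - cs2[ks]
    m1, m2 = s1 / n1, s2 / n2
    ss = (q1 - n1 * m1 ** 2) + (q2 - n2 * m2 ** 2)
    sp2 = np.maximum(ss / np.maximum(n - 2, 1), 1e-8)
    return (m1 - m2) ** 2 / (sp2 * (1.0 / n1 + 1.0 / n2))


def _segment_one(logr: np.ndarray, alor: np.ndarray, critical: float,
                 min_seg: int, offset: int, out: list[int]) -> None:
    n = len(logr)
    if n < 2 * min_seg:
        return
    stat = _split_stats(logr, min_seg) + _split_stats(alor, min_seg)
    k = int(np.argmax(stat))
    if stat[k] <= critical:
        return
    split = k + min_seg
    out.append(offset + split)
    _segment_one(logr[:split], alor[:split], critical, min_seg, offset, out)
    _segment_one(logr[split:], alor[split:], critical, min_seg,
                 offset + split, out)


def segment_genome(sites: pd.DataFrame, critical: float,
                   min_seg: int = 8) -> dict[str, list[int]]:
    """Recursive binary segmentation per chromosome.

    Splits the bivariate (logR, |logOR|) series at the position maximizing
    the summed two-sample t^2 statistics, accepting a split when the
    combined statistic exceeds ``critical``.  Returns per-chromosome lists
    of breakpoint site indices (a breakpoint *b* separates sites [0, b) and
    [b, n)); chromosome boundaries are never candidate splits.
    """
    if critical <= 0:
        raise ValueError("critical value must be > 0")
    brks: dict[str, list[int]] = {}
    for chrom, grp in sites.groupby("chrom", sort=False):
        out: list[int] = []
        _segment_one(grp["logr"].to_numpy(), np.abs(grp["logor"].to_numpy()),
                     critical, min_seg, 0, out)
        brks[chrom] = sorted(out)
    return brks


def _summarize_segments(sites: pd.DataFrame, breakpoints: dict[str, list[int]],
                        chrom_lengths: dict[str, float] | None = None
                        ) -> pd.DataFrame:
    """Per-segment means; boundaries placed midway between flanking sites."""
    rows = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["position"].to_numpy()
        n = len(grp)
        cuts = [0] + list(breakpoints.get(chrom, [])) + [n]
        length = chrom_lengths.get(chrom) if chrom_lengths else pos[-1] + (
            pos[-1] - pos[0]) / max(n - 1, 1) / 2
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            sub = grp.iloc[lo:hi]
            start = 0.0 if lo == 0 else (pos[lo - 1] + pos[lo]) / 2.0
            end = float(length) if hi == n else (pos[hi - 1] + pos[hi]) / 2.0
            lor2 = np.mean(sub["logor"].to_numpy() ** 2)
            vbar = float(np.mean(sub["logor_var"]))
            rows.append({
                "chrom": chrom, "start": start, "end": end, "n_sites": hi - lo,
                "mean_logr": float(np.mean(sub["logr"])),
                "lor": float(np.sqrt(max(lor2 - vbar, 0.0))),
                "sigma_lor": float(np.sqrt(vbar)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# purity / ploidy / integer-CN grid fit
# ---------------------------------------------------------------------------

def _cn_pairs(cn_max: int) -> np.ndarray:
    return np.array([(M, m) for t in range(cn_max + 1)
                     for m in range(t // 2 + 1)
                     for M in [t - m] if M >= m], dtype=float)


class PurityPloidyModel:
    """Joint purity / diploid-offset / integer allele-specific CN fit.

    Estimator-style interface: construct with hyperparameters, call
    :meth:`fit` on a segment summary table, then read the fitted attributes
    ``purity_``, ``ploidy_``, ``dip_offset_``, ``segments_``, ``residual_``,
    ``low_confidence_`` and ``excluded_``.

    Parameters
    ----------
    purity_grid : (min, max, step) for the purity scan, default (0.05, 1.0, 0.01).
    cn_max : largest total copy number considered (segments fitting best at
        the boundary are flagged in ``segments_['at_cn_max']``).
    offset_grid : (min, max, step) for the diploid-logR offset scan.
    purity_exclude : samples fitting below this purity are flagged excluded.
    """

    def __init__(self, purity_grid=(0.05, 1.0, 0.01), cn_max: int = 8,
                 offset_grid=(-1.6, 1.6, 0.02), purity_exclude: float = 0.3,
                 cn_penalty: float = 0.001):
        self.purity_grid = purity_grid
        self.cn_max = cn_max
        self.offset_grid = offset_grid
        self.purity_exclude = purity_exclude
        self.cn_penalty = cn_penalty

    # -- sklearn-style parameter plumbing ---------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"purity_grid": self.purity_grid, "cn_max": self.cn_max,
                "offset_grid": self.offset_grid,
                "purity_exclude": self.purity_exclude,
                "cn_penalty": self.cn_penalty}

    def set_params(self, **params) -> "PurityPloidyModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ---------------------------------------------------------------------
    def fit(self, segments: pd.DataFrame) -> "PurityPloidyModel":
        if len(segments) == 0:
            raise ValueError("no segments to fit")
        seg = segments.reset_index(drop=True)
        w = (seg["end"] - seg["start"]).to_numpy(float)
        w = w / w.sum()
        logr = seg["mean_logr"].to_numpy(float)
        lor = seg["lor"].to_numpy(float)

        pmin, pmax, pstep = self.purity_grid
        purities = np.round(np.arange(pmin, pmax + pstep / 2, pstep), 10)
        omin, omax, ostep = self.offset_grid
        offsets = np.arange(omin, omax + ostep / 2, ostep)
        pairs = _cn_pairs(self.cn_max)
        totals = pairs.sum(axis=1)

        candidates = []  # per purity: (residual, ploidy, purity, offset, assignment)
        for ip, p in enumerate(purities):
            # expected logR at zero diploid offset, and expected logOR delta
            num = p * totals + 2.0 * (1.0 - p)
            logr0 = np.log2(np.maximum(num, 1e-12) / 2.0)
            b = (p * pairs[:, 0] + (1.0 - p)) / np.maximum(num, 1e-12)
            b = np.clip(b, 1e-12, 1.0 - 1e-12)
            delta = np.minimum(np.abs(np.log(b / (1.0 - b))), _LOR_CAP)
            lor_term = (lor[:, None] - delta[None, :]) ** 2
            d1 = logr[:, None] - logr0[None, :]    # (S, P)
            cost = ((d1[:, :, None] - offsets[None, None, :]) ** 2
                    + lor_term[:, :, None])        # (S, P, K)
            idx = np.argmin(cost, axis=1)          # (S, K)
            mincost = np.take_along_axis(cost, idx[:, None, :], axis=1)[:, 0, :]
            res_k = w @ mincost                    # (K,)
            kbest = int(np.argmin(res_k))
            assign = idx[:, kbest]
            ploidy = float(w @ totals[assign])
            candidates.append((float(res_k[kbest]), ploidy, float(p),
                               float(offsets[kbest]), assign))

        residual, ploidy, purity, offset, assign = _select(
            candidates, self.cn_penalty)
        # refine the offset in closed form for the chosen assignment
        num = purity * totals[assign] + 2.0 * (1.0 - purity)
        logr0 = np.log2(np.maximum(num, 1e-12) / 2.0)
        offset = float(w @ (logr - logr0))

        out = seg.copy()
        out["cn_major"] = pairs[assign, 0].astype(int)
        out["cn_minor"] = pairs[assign, 1].astype(int)
        out["cn_total"] = out["cn_major"] + out["cn_minor"]
        out["at_cn_max"] = out["cn_total"] == self.cn_max

        self.purity_ = float(purity)
        self.ploidy_ = float(w @ out["cn_total"].to_numpy(float))
        self.dip_offset_ = offset
        self.residual_ = float(residual)
        self.segments_ = out
        states = set(zip(out["cn_major"], out["cn_minor"]))
        self.low_confidence_ = len(states) == 1
        self.excluded_ = self.purity_ < self.purity_exclude
        return self

    def assign(self, segments: pd.DataFrame) -> pd.DataFrame:
        """Assign integer (major, minor) CN to new segments at the fitted
        purity and diploid offset (the fine-pass step)."""
        if not hasattr(self, "purity_"):
            raise RuntimeError("model is not fitted")
        p = self.purity_
        pairs = _cn_pairs(self.cn_max)
        totals = pairs.sum(axis=1)
        num = p * totals + 2.0 * (1.0 - p)
        logr0 = np.log2(np.maximum(num, 1e-12) / 2.0) + self.dip_offset_
        b = (p * pairs[:, 0] + (1.0 - p)) / np.maximum(num, 1e-12)
        b = np.clip(b, 1e-12, 1.0 - 1e-12)
        delta = np.minimum(np.abs(np.log(b / (1.0 - b))), _LOR_CAP)
        seg = segments.reset_index(drop=True).copy()
        logr = seg["mean_logr"].to_numpy(float)
        lor = seg["lor"].to_numpy(float)
        cost = ((logr[:, None] - logr0[None, :]) ** 2
                + (lor[:, None] - delta[None, :]) ** 2)
        assign = np.argmin(cost, axis=1)
        seg["cn_major"] = pairs[assign, 0].astype(int)
        seg["cn_minor"] = pairs[assign, 1].astype(int)
        seg["cn_total"] = seg["cn_major"] + seg["cn_minor"]
        seg["at_cn_max"] = seg["cn_total"] == self.cn_max
        return seg

    def to_profile(self, segments: pd.DataFrame | None = None,
                   sample_id: str | None = None) -> SegmentProfile:
        seg = self.segments_ if segments is None else segments
        w = (seg["end"] - seg["start"]).to_numpy(float)
        ploidy = float(w @ seg["cn_total"].to_numpy(float) / w.sum())
        return SegmentProfile(
            segments=seg, purity=self.purity_, ploidy=ploidy,
            dip_offset=self.dip_offset_, residual=self.residual_,
            low_confidence=self.low_confidence_, excluded=self.excluded_,
            sample_id=sample_id)


def _select(candidates: list[tuple], cn_penalty: float) -> tuple:
    """Pick the fit among per-purity candidates.

    Purity/ploidy grids harbor a doubling ladder: scaling every copy number
    by an integer while remapping purity reproduces the same expected logR
    and logOR almost exactly, so ladder rungs differ in residual only
    through noise and grid quantization; at low purity, closely spaced
    high-CN states can even soak up logOR noise and undercut the true
    model.  A parsimony penalty proportional to ploidy, applied at the
    candidate level only (per-segment assignments stay unpenalized),
    resolves both: among near-equivalent explanations the least-amplified
    genome wins.  Exact ties go to higher purity.
    """
    viable = [c for c in candidates if c[1] >= 1.0]  # ploidy < 1 is unphysical
    if viable:
        candidates = viable
    return min(candidates, key=lambda c: (c[0] + cn_penalty * c[1], -c[2]))


def fit_purity_ploidy(segments: pd.DataFrame, **params) -> SegmentProfile:
    """Functional wrapper over :class:`PurityPloidyModel`."""
    model = PurityPloidyModel(**params)
    model.fit(segments)
    return model.to_profile()


def fit_cn(snp_table: pd.DataFrame,
           critical_coarse: float = DEFAULT_CRITICAL_COARSE,
           critical_fine: float = DEFAULT_CRITICAL_FINE,
           chrom_lengths: dict[str, float] | None = None,
           min_normal_depth: int = 10,
           sample_id: str | None = None,
           **model_params) -> SegmentProfile:
    """Full two-pass allele-specific CN fit for one sample.

    Coarse-pass segments drive the purity/ploidy grid fit; fine-pass
    segments (lower critical value) receive integer CN at the fitted purity
    and offset and form the reported profile.
    """
    sites = site_stats(snp_table, min_normal_depth=min_normal_depth)
    coarse = segment_genome(sites, critical_coarse)
    seg_coarse = _summarize_segments(sites, coarse, chrom_lengths)
    model = PurityPloidyModel(**model_params)
    model.fit(seg_coarse)
    fine = segment_genome(sites, critical_fine)
    seg_fine = model.assign(_summarize_segments(sites, fine, chrom_lengths))
    return model.to_profile(seg_fine, sample_id=sample_id)


# ---------------------------------------------------------------------------
# calls
# ---------------------------------------------------------------------------

def call_wgd(profile: SegmentProfile) -> WgdCall:
    """Whole-genome doubling: major CN >= 2 over >= 50% of the autosomes."""
    seg = profile.segments
    w = (seg["end"] - seg["start"]).to_numpy(float)
    frac = float(w[seg["cn_major"].to_numpy() >= 2].sum() / w.sum())
    return WgdCall(wgd=frac >= 0.5, fraction=frac)


def call_arms(profile: SegmentProfile,
              arm_table: list[tuple[str, str, float, float]],
              baseline_cn: int = 2) -> list[ArmCall]:
    """Arm-level gain/loss: called when > 50% (strict) of the arm is
    above/below ``baseline_cn`` total copies."""
    seg = profile.segments
    chrom_end: dict[str, float] = {}
    for chrom, arm, start, end in arm_table:
        chrom_end[chrom] = max(chrom_end.get(chrom, 0.0), end)
    for _, row in seg.iterrows():
        if row["chrom"] in chrom_end and row["end"] > chrom_end[row["chrom"]] + 1e-6:
            raise ValueError(
                f"segment {row['chrom']}:{row['start']}-{row['end']} extends "
                f"past chromosome end {chrom_end[row['chrom']]}"
            )
    calls = []
    for chrom, arm, a_start, a_end in arm_table:
        sub = seg[seg["chrom"] == chrom]
        arm_len = a_end - a_start
        gain = loss = 0.0
        for _, row in sub.iterrows():
            ov = max(0.0, min(row["end"], a_end) - max(row["start"], a_start))
            if ov <= 0:
                continue
            if row["cn_total"] > baseline_cn:
                gain += ov
            elif row["cn_total"] < baseline_cn:
                loss += ov
        gain_f, loss_f = gain / arm_len, loss / arm_len
        if gain_f > 0.5:
            calls.append(ArmCall(f"{chrom}{arm}", "gain", gain_f))
        elif loss_f > 0.5:
            calls.append(ArmCall(f"{chrom}{arm}", "loss", loss_f))
        else:
            calls.append(ArmCall(f"{chrom}{arm}", "neutral", max(gain_f, loss_f)))
    return calls


def gene_copy_number(profile: SegmentProfile,
                     gene_table: list[tuple[str, str, float, float]],
                     baseline_cn: int = 2) -> pd.DataFrame:
    """Gene-level integer CN inherited from the fine-pass segments.

    A gene inside one segment takes that segment's CN; a gene spanning a
    breakpoint takes the larger-overlap segment, ties going to the more
    aberrant one (total CN farther from ``baseline_cn``).  The rule applied
    is recorded per gene; genes on chromosomes absent from the profile are
    flagged missing rather than fatal.
    """
    seg = profile.segments
    rows = []
    for name, chrom, g_start, g_end in gene_table:
        sub = seg[seg["chrom"] == chrom]
        if len(sub) == 0:
            rows.append({"gene": name, "chrom": chrom, "cn_total": np.nan,
                         "cn_major": np.nan, "cn_minor": np.nan,
                         "rule": "missing"})
            continue
        overlaps = []
        for _, s in sub.iterrows():
            ov = max(0.0, min(s["end"], g_end) - max(s["start"], g_start))
            if ov > 0:
                overlaps.append((ov, s))
        if not overlaps:
            rows.append({"gene": name, "chrom": chrom, "cn_total": np.nan,
                         "cn_major": np.nan, "cn_minor": np.nan,
                         "rule": "missing"})
            continue
        if len(overlaps) == 1:
            chosen, rule = overlaps[0][1], "contained"
        else:
            best_ov = max(ov for ov, _ in overlaps)
            top = [s for ov, s in overlaps if abs(ov - best_ov) < 1e-9]
            if len(top) == 1:
                chosen, rule = top[0], "larger_overlap"
            else:
                chosen = max(top, key=lambda s: abs(s["cn_total"] - baseline_cn))
                rule = "aberrance_tiebreak"
        rows.append({"gene": name, "chrom": chrom,
                     "cn_total": int(chosen["cn_total"]),
                     "cn_major": int(chosen["cn_major"]),
                     "cn_minor": int(chosen["cn_minor"]), "rule": rule})
    return pd.DataFrame(rows)


def differential_gene_cn(cn_dediff: pd.DataFrame, cn_classic: pd.DataFrame,
                         alpha: float = 0.05, fc_min: float = 2.0) -> pd.DataFrame:
    """Paired per-gene copy-number comparison (dedifferentiated vs classic).

    ``cn_dediff`` / ``cn_classic``: genes x patients integer total CN, same
    index and columns.  A paired two-tailed t-test is run per gene, p-values
    are Benjamini–Hochberg adjusted across testable genes, and a gene is
    flagged significant when adjusted p <= ``alpha`` AND the mean CN
    fold-change >= ``fc_min``.  Genes with identical CN in every pair are
    not testable; a constant nonzero difference is degenerate-significant
    (zero variance around a nonzero mean).
    """
    from statsmodels.stats.multitest import multipletests

    if cn_dediff.shape != cn_classic.shape:
        raise ValueError("paired tables must have identical shape")
    if cn_dediff.shape[1] < 3:
        raise ValueError("need >= 3 patient pairs")
    d = cn_dediff.to_numpy(float)
    c = cn_classic.to_numpy(float)
    diff = d - c
    mean_d, mean_c = d.mean(axis=1), c.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_c > 0, mean_d / mean_c, np.inf)
    sd = diff.std(axis=1, ddof=1)
    mean_diff = diff.mean(axis=1)
    not_testable = (sd == 0) & (mean_diff == 0)
    pvals = np.full(len(diff), np.nan)
    degenerate = (sd == 0) & (mean_diff != 0)
    pvals[degenerate] = 0.0
    regular = ~not_testable & ~degenerate
    if regular.any():
        t, p = stats.ttest_rel(d[regular], c[regular], axis=1)
        pvals[regular] = p
    padj = np.full(len(diff), np.nan)
    testable = ~not_testable
    if testable.any():
        padj[testable] = multipletests(pvals[testable], method="fdr_bh")[1]
    out = pd.DataFrame({
        "gene": cn_dediff.index,
        "mean_cn_dediff": mean_d,
        "mean_cn_classic": mean_c,
        "fold_change": fc,
        "p_value": pvals,
        "p_adjusted": padj,
        "not_testable": not_testable,
    })
    out["significant"] = (out["p_adjusted"] <= alpha) & (out["fold_change"] >= fc_min)
    out.loc[out["not_testable"], "significant"] = False
    return out.reset_index(drop=True)
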