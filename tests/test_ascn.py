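"""Copy-number inference: site stats, segmentation, grid fit, calls."""

import numpy as np
import pandas as pd
import pytest

from chromoevo import ascn
from chromoevo.karyosim import default_scenario, expected_baf, expected_logr, \
    simulate_scenario

from conftest import flat_sites


def _snp_frame(t_alt, t_ref, n_alt, n_ref, chrom="1"):
    n = len(t_alt)
    return pd.DataFrame({
        "chrom": chrom, "position": np.arange(n) * 1.0,
        "t_alt": t_alt, "t_ref": t_ref, "n_alt": n_alt, "n_ref": n_ref,
    })


class TestSiteStats:
    def test_identical_tumor_normal_gives_zero(self):
        df = _snp_frame([50] * 20, [50] * 20, [50] * 20, [50] * 20)
        out = ascn.site_stats(df)
        assert np.allclose(out["logr"], 0.0)
        assert np.allclose(out["logor"], 0.0)

    def test_haldane_corrected_logor_value(self):
        df = _snp_frame([60], [40], [50], [50])
        out = ascn.site_stats(df, min_normal_depth=1)
        expected = np.log(60.5 / 40.5) - np.log(50.5 / 50.5)
        assert out["logor"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.4015, abs=5e-4)

    def test_low_normal_depth_site_dropped(self):
        df = _snp_frame([50, 50], [50, 50], [3, 50], [2, 50])
        out = ascn.site_stats(df, min_normal_depth=10)
        assert len(out) == 1

    def test_empty_and_unsorted_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ascn.site_stats(_snp_frame([], [], [], []))
        df = _snp_frame([50] * 3, [50] * 3, [50] * 3, [50] * 3)
        df.loc[2, "position"] = 0.5
        with pytest.raises(ValueError, match="increasing"):
            ascn.site_stats(df)


class TestSegmentation:
    def test_flat_noise_yields_no_breakpoints(self):
        hits = sum(
            len(ascn.segment_genome(flat_sites(seed=s),
                                    ascn.DEFAULT_CRITICAL_FINE)["1"]) > 0
            for s in range(20))
        assert hits == 0

    def test_single_step_localized_against_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        n = 500
        logr = np.where(np.arange(n) < 250, 0.0, -1.0) + rng.normal(0, .05, n)
        sites = flat_sites(n=n, seed=5)
        sites["logr"] = logr
        brk = ascn.segment_genome(sites, ascn.DEFAULT_CRITICAL_FINE)["1"]
        assert len(brk) == 1
        # oracle: exhaustive scan of the squared-mean-difference objective
        best, best_val = None, -np.inf
        for k in range(8, n - 8 + 1):
            m1, m2 = logr[:k].mean(), logr[k:].mean()
            val = k * (n - k) / n * (m1 - m2) ** 2
            if val > best_val:
                best, best_val = k, val
        assert abs(brk[0] - best) <= 3

    def test_chromosome_boundary_is_not_a_split(self):
        a = flat_sites(seed=1, chrom="1")
        b = flat_sites(seed=2, chrom="2")
        b["logr"] += 1.0          # different level on the other chromosome
        sites = pd.concat([a, b], ignore_index=True)
        brks = ascn.segment_genome(sites, ascn.DEFAULT_CRITICAL_FINE)
        assert brks["1"] == [] and brks["2"] == []

    def test_nonpositive_critical_rejected(self):
        with pytest.raises(ValueError, match="critical"):
            ascn.segment_genome(flat_sites(), 0.0)


def _noise_free_segments(purity, states, lengths, n_sites=500):
    """Segment summary straight from the emission model (no noise)."""
    ploidy = np.average([M + m for M, m in states], weights=lengths)
    rows = []
    start = 0.0
    for (M, m), L in zip(states, lengths):
        b = expected_baf(purity, M, m)
        b = min(max(b, 1e-9), 1 - 1e-9)
        rows.append({
            "chrom": "1", "start": start, "end": start + L,
            "n_sites": n_sites,
            "mean_logr": expected_logr(purity, M + m, ploidy),
            "lor": abs(np.log(b / (1 - b))),
            "sigma_lor": 0.3,
        })
        start += L
    return pd.DataFrame(rows)


class TestPurityPloidyFit:
    def test_noise_free_recovery_exact_over_grid(self):
        states = [(1, 1), (1, 0), (2, 0), (2, 1), (3, 1)]
        seg = _noise_free_segments(0.63, states, [100, 80, 60, 50, 40])
        prof = ascn.fit_purity_ploidy(seg)
        assert prof.purity == pytest.approx(0.63, abs=0.005)
        got = list(zip(prof.segments["cn_major"], prof.segments["cn_minor"]))
        assert got == states

    def test_classic_sample_recovered(self, dataset, chrom_lengths):
        snp = dataset.snp_table
        grp = snp[snp["region"] == "R1_classic"]
        prof = ascn.fit_cn(grp, chrom_lengths=chrom_lengths)
        truth = dataset.truth["regions"]["R1_classic"]
        assert abs(prof.purity - truth["purity"]) <= 0.05
        assert abs(prof.ploidy - truth["tumor_ploidy"]) <= 0.2
        seg = prof.segments
        chr17 = seg[seg["chrom"] == "17"]
        assert (chr17["cn_major"] == 1).all() and (chr17["cn_minor"] == 0).all()

    def test_dediff_sample_recovered_with_wgd_state(self, dataset,
                                                    chrom_lengths):
        snp = dataset.snp_table
        grp = snp[snp["region"] == "R2_dediff"]
        prof = ascn.fit_cn(grp, chrom_lengths=chrom_lengths)
        truth = dataset.truth["regions"]["R2_dediff"]
        assert abs(prof.purity - truth["purity"]) <= 0.05
        assert abs(prof.ploidy - truth["tumor_ploidy"]) <= 0.2
        seg = prof.segments
        chr17 = seg[seg["chrom"] == "17"]
        assert (chr17["cn_major"] == 2).all() and (chr17["cn_minor"] == 0).all()

    def test_flat_normal_genome_flagged_low_confidence(self):
        seg = _noise_free_segments(1.0, [(1, 1)] * 4, [100, 90, 80, 70])
        prof = ascn.fit_purity_ploidy(seg)
        assert prof.low_confidence

    def test_low_purity_sample_flagged_excluded(self):
        states = [(1, 1), (1, 0), (2, 1)]
        seg = _noise_free_segments(0.2, states, [100, 80, 60])
        prof = ascn.fit_purity_ploidy(seg)
        assert prof.excluded

    def test_params_roundtrip(self):
        model = ascn.PurityPloidyModel(cn_max=6)
        model.set_params(**model.get_params())
        assert model.get_params()["cn_max"] == 6
        with pytest.raises(ValueError):
            model.set_params(bogus=1)


def _profile(states_lengths, purity=0.7):
    rows = []
    start = 0.0
    for (chrom, M, m, L) in states_lengths:
        rows.append({"chrom": chrom, "start": start, "end": start + L,
                     "n_sites": 100, "mean_logr": 0.0, "lor": 0.0,
                     "cn_major": M, "cn_minor": m, "cn_total": M + m})
        start += L
    seg = pd.DataFrame(rows)
    w = (seg["end"] - seg["start"])
    return ascn.SegmentProfile(
        segments=seg, purity=purity,
        ploidy=float((w * seg["cn_total"]).sum() / w.sum()),
        dip_offset=0.0, residual=0.0)


class TestCalls:
    def test_wgd_full_genome(self):
        prof = _profile([("1", 2, 0, 100), ("2", 2, 1, 100)])
        call = ascn.call_wgd(prof)
        assert call.wgd and call.fraction == 1.0

    def test_wgd_boundary_half_genome_is_positive(self):
        prof = _profile([("1", 2, 0, 100), ("2", 1, 0, 100)])
        assert ascn.call_wgd(prof).wgd            # >= 50% rule, inclusive

    def test_wgd_just_below_half_is_negative(self):
        prof = _profile([("1", 2, 0, 49), ("2", 1, 0, 51)])
        assert not ascn.call_wgd(prof).wgd

    def test_wgd_monotone_in_major_cn(self):
        before = _profile([("1", 2, 0, 60), ("2", 1, 1, 40)])
        after = _profile([("1", 2, 0, 60), ("2", 2, 1, 40)])
        assert ascn.call_wgd(after).wgd >= ascn.call_wgd(before).wgd

    def test_arm_gain_over_half(self):
        prof = _profile([("1", 2, 1, 60), ("1", 1, 1, 40)])
        calls = ascn.call_arms(prof, [("1", "p", 0.0, 100.0)])
        assert calls[0].call == "gain" and calls[0].fraction == pytest.approx(0.6)

    def test_arm_exactly_half_is_neutral(self):
        prof = _profile([("1", 1, 0, 50), ("1", 1, 1, 50)])
        calls = ascn.call_arms(prof, [("1", "p", 0.0, 100.0)])
        assert calls[0].call == "neutral"         # strict > 50%

    def test_whole_arm_loss(self):
        prof = _profile([("1", 1, 0, 100)])
        calls = ascn.call_arms(prof, [("1", "p", 0.0, 100.0)])
        assert calls[0].call == "loss" and calls[0].fraction == 1.0

    def test_segment_past_chromosome_end_rejected(self):
        prof = _profile([("1", 1, 0, 120)])
        with pytest.raises(ValueError, match="past chromosome end"):
            ascn.call_arms(prof, [("1", "p", 0.0, 50.0), ("1", "q", 50.0, 100.0)])


class TestGeneCn:
    def test_gene_inside_segment(self):
        prof = _profile([("1", 1, 0, 100)])
        out = ascn.gene_copy_number(prof, [("G", "1", 10.0, 20.0)])
        assert out["cn_total"].iloc[0] == 1 and out["rule"].iloc[0] == "contained"

    def test_larger_overlap_wins(self):
        prof = _profile([("1", 4, 2, 100), ("1", 2, 1, 100)])
        out = ascn.gene_copy_number(prof, [("G", "1", 60.0, 160.0)])  # 40/60 split
        assert (out["cn_major"].iloc[0], out["cn_minor"].iloc[0]) == (2, 1)
        out2 = ascn.gene_copy_number(prof, [("G2", "1", 40.0, 140.0)])  # 60/40
        assert (out2["cn_major"].iloc[0], out2["cn_minor"].iloc[0]) == (4, 2)

    def test_even_split_resolved_by_aberrance(self):
        prof = _profile([("1", 2, 1, 100), ("1", 3, 1, 100)])
        out = ascn.gene_copy_number(prof, [("G", "1", 50.0, 150.0)])
        assert (out["cn_major"].iloc[0], out["cn_minor"].iloc[0]) == (3, 1)
        assert out["rule"].iloc[0] == "aberrance_tiebreak"

    def test_gene_on_missing_chromosome_flagged(self):
        prof = _profile([("1", 1, 1, 100)])
        out = ascn.gene_copy_number(prof, [("G", "9", 0.0, 1.0)])
        assert out["rule"].iloc[0] == "missing"


class TestDifferentialGeneCn:
    def test_planted_gene_flagged_among_null_genes(self):
        rng = np.random.default_rng(0)
        n_genes, n_pairs = 101, 6
        null = 2 + rng.poisson(0.3, size=(n_genes - 1, n_pairs))
        classic = pd.DataFrame(np.vstack([[2] * n_pairs, null]))
        null2 = 2 + rng.poisson(0.3, size=(n_genes - 1, n_pairs))
        dediff = pd.DataFrame(np.vstack([[4] * n_pairs, null2]))
        out = ascn.differential_gene_cn(dediff, classic)
        assert bool(out["significant"].iloc[0])
        # hand oracle: constant difference of +2 -> zero variance, p = 0
        assert out["p_value"].iloc[0] == 0.0
        assert out["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_identical_gene_not_testable(self):
        cn = pd.DataFrame([[2, 2, 2, 2, 2, 2]])
        out = ascn.differential_gene_cn(cn, cn.copy())
        assert bool(out["not_testable"].iloc[0])
        assert not bool(out["significant"].iloc[0])

    def test_requires_three_pairs(self):
        cn = pd.DataFrame([[2, 2]])
        with pytest.raises(ValueError, match="3 patient pairs"):
            ascn.differential_gene_cn(cn, cn.copy())
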