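import math

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_overlap_mask, random_intervals
from nonotet.chromatin import (
    binned_correlation,
    chi_squared_association,
    identify_reduced_peaks,
    intersect_peaks,
    metagene_profile,
    pct,
    promoter_targets,
    round_half_away,
    stratify_expression_by_binding,
    target_gene_venn,
)
from nonotet.core import (
    GeneModel,
    Interval,
    PeakSet,
    PipelineConfig,
    SignalTrack,
    ValidationError,
)


def _peaks(name, triples):
    return PeakSet.build(name, [Interval(c, s, e) for c, s, e in triples])


class TestIntersectPeaks:
    def test_disjoint_sets(self):
        a = _peaks("a", [("c", 0, 10), ("c", 100, 110)])
        b = _peaks("b", [("c", 50, 60)])
        ov = intersect_peaks(a, b)
        assert ov.n_overlap_a == 0 and ov.n_a_only == 2

    def test_identical_sets_full_overlap(self):
        a = _peaks("a", [("c", 0, 10), ("c", 100, 110)])
        ov = intersect_peaks(a, a)
        assert ov.n_overlap_a == len(a)
        assert ov.pct_a_overlapping == 100

    def test_unsorted_input_rejected_not_silently_sorted(self):
        a = PeakSet("a", [])
        a.intervals = [Interval("c", 100, 110), Interval("c", 0, 10)]
        with pytest.raises(ValidationError, match="sorted"):
            intersect_peaks(a, _peaks("b", [("c", 0, 5)]))

    def test_nested_and_contained_intervals(self):
        # long interval spans a short one that starts earlier
        a = _peaks("a", [("c", 50, 60)])
        b = _peaks("b", [("c", 0, 100), ("c", 10, 20)])
        ov = intersect_peaks(a, b)
        assert ov.n_overlap_a == 1
        assert intersect_peaks(b, a).n_overlap_b == 1

    def test_sweep_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            ta = random_intervals(rng, int(rng.integers(0, 200)))
            tb = random_intervals(rng, int(rng.integers(1, 200)))
            a = _peaks("a", ta)
            b = _peaks("b", tb)
            ov = intersect_peaks(a, b)
            key_a = [(iv.chrom, iv.start, iv.end) for iv in a]
            key_b = [(iv.chrom, iv.start, iv.end) for iv in b]
            assert ov.n_overlap_a == brute_force_overlap_mask(key_a, key_b).sum()
            assert ov.n_overlap_b == brute_force_overlap_mask(key_b, key_a).sum()

    def test_sweep_matches_pyranges(self):
        """Independent interval-library cross-check of the overlap counts."""
        import pyranges as pr
        rng = np.random.default_rng(77)
        ta = random_intervals(rng, 150)
        tb = random_intervals(rng, 150)
        ov = intersect_peaks(_peaks("a", ta), _peaks("b", tb))
        fa = pd.DataFrame(ta, columns=["Chromosome", "Start", "End"])
        fb = pd.DataFrame(tb, columns=["Chromosome", "Start", "End"])
        hits = pr.PyRanges(fa.drop_duplicates()).overlap(pr.PyRanges(fb))
        mask = brute_force_overlap_mask(ta, tb)  # duplicates counted per row
        assert ov.n_overlap_a == mask.sum()
        uniq = {(c, s, e) for (c, s, e), m in zip(ta, mask) if m}
        assert len(hits.df) == len(uniq)

    def test_partition_conservation(self):
        rng = np.random.default_rng(5)
        a = _peaks("a", random_intervals(rng, 80))
        b = _peaks("b", random_intervals(rng, 80))
        ov = intersect_peaks(a, b)
        assert ov.n_a_only + ov.n_overlap_a == ov.n_a == 80
        assert ov.n_b_only + ov.n_overlap_b == ov.n_b == 80
        assert len(ov.a_overlapping) == ov.n_overlap_a
        assert len(ov.a_only) == ov.n_a_only

    def test_reported_percent_matches_published_venn(self):
        # 4948 of 5848 co-occupied peaks print as 85%
        assert pct(4948, 5848) == 85


class TestPromoterTargets:
    genes = [GeneModel("plus", "c", 10_000, 15_000, "+"),
             GeneModel("minus", "c", 30_000, 34_000, "-")]

    def test_peak_covering_tss_targets_gene(self):
        ps = _peaks("p", [("c", 9_900, 10_100)])
        assert promoter_targets(ps, self.genes, 2000).target_genes == {"plus"}

    def test_peak_ending_at_window_start_excluded_half_open(self):
        ps = _peaks("p", [("c", 7_000, 8_000)])  # ends exactly at tss - flank
        assert promoter_targets(ps, self.genes, 2000).target_genes == set()
        just_in = _peaks("p", [("c", 7_000, 8_001)])
        assert promoter_targets(just_in, self.genes,
                                2000).target_genes == {"plus"}

    def test_minus_strand_window_follows_tss_convention(self):
        # TSS of "minus" is 33_999; brute-force the window membership
        rng = np.random.default_rng(17)
        flank = 1500
        for _ in range(50):
            s = int(rng.integers(28_000, 37_000))
            e = s + int(rng.integers(1, 800))
            ps = _peaks("p", [("c", s, e)])
            got = "minus" in promoter_targets(ps, self.genes,
                                              flank).target_genes
            lo, hi = 33_999 - flank, 33_999 + flank
            assert got == (s < hi and e > lo)

    def test_venn_partition_matches_set_algebra(self):
        rng = np.random.default_rng(23)
        genes = [GeneModel(f"g{i}", "c", 1000 + 10_000 * i,
                           5000 + 10_000 * i, "+") for i in range(30)]
        pa = _peaks("a", random_intervals(rng, 60, chroms=("c",),
                                          span=300_000))
        pb = _peaks("b", random_intervals(rng, 60, chroms=("c",),
                                          span=300_000))
        aa = promoter_targets(pa, genes, 2000)
        ab = promoter_targets(pb, genes, 2000)
        common, a_only, b_only = target_gene_venn(aa, ab)
        assert common == aa.target_genes & ab.target_genes
        assert a_only == aa.target_genes - ab.target_genes
        assert b_only == ab.target_genes - aa.target_genes
        assert not (common & a_only or common & b_only or a_only & b_only)


def _flat_track(bin_size, sizes, value):
    return SignalTrack(bin_size, dict(sizes),
                       {c: np.full(math.ceil(n / bin_size), float(value))
                        for c, n in sizes.items()})


class TestReducedPeaks:
    sizes = {"c": 100_000}

    def test_identical_tracks_flag_nothing(self, cfg):
        ps = _peaks("p", [("c", 100, 700), ("c", 5_000, 6_000)])
        t = _flat_track(500, self.sizes, 3.0)
        red = identify_reduced_peaks(ps, t, t, cfg)
        assert not red.flagged.any()
        assert red.log2_ratio == pytest.approx(np.zeros(2))

    def test_zero_ko_closed_form_log_ratio(self, cfg):
        ps = _peaks("p", [("c", 0, 500)])
        wt = _flat_track(500, self.sizes, 10.0)
        ko = _flat_track(500, self.sizes, 0.0)
        red = identify_reduced_peaks(ps, wt, ko, cfg)
        assert red.log2_ratio[0] == pytest.approx(math.log2(0.1 / 10.1))
        assert red.log2_ratio[0] == pytest.approx(-6.66, abs=0.01)
        assert red.flagged.all()

    def test_monotone_in_cutoff(self, default_study):
        ch = default_study.chromatin
        loose = identify_reduced_peaks(ch.peaks["TET1_WT"],
                                       ch.tracks["TET1_WT"],
                                       ch.tracks["TET1_KO"],
                                       PipelineConfig(reduced_log2_cutoff=-0.5))
        strict = identify_reduced_peaks(ch.peaks["TET1_WT"],
                                        ch.tracks["TET1_WT"],
                                        ch.tracks["TET1_KO"],
                                        PipelineConfig(reduced_log2_cutoff=-2.0))
        assert strict.flagged.sum() <= loose.flagged.sum()
        assert not (strict.flagged & ~loose.flagged).any()

    def test_recovers_planted_reduction_fraction(self, default_study):
        ch = default_study.chromatin
        red = identify_reduced_peaks(ch.peaks["TET1_WT"],
                                     ch.tracks["TET1_WT"],
                                     ch.tracks["TET1_KO"], PipelineConfig())
        gene_assoc = np.array([bool(g) for g in ch.tet1_gene_ids])
        frac = red.flagged[gene_assoc].mean()
        assert abs(frac - default_study.cfg.frac_reduced_in_ko) <= 0.05

    def test_mismatched_binning_rejected(self, cfg):
        ps = _peaks("p", [("c", 0, 500)])
        with pytest.raises(ValidationError):
            identify_reduced_peaks(ps, _flat_track(500, self.sizes, 1.0),
                                   _flat_track(1000, self.sizes, 1.0), cfg)


class TestBinnedCorrelation:
    def _track(self, vals, bin_size=10):
        return SignalTrack(bin_size, {"c": len(vals) * bin_size},
                           {"c": np.asarray(vals, dtype=float)})

    def test_self_correlation_is_one(self):
        t = self._track([1, 5, 2, 8, 3])
        r, table = binned_correlation(t, t)
        assert r == pytest.approx(1.0)
        assert len(table) == 5

    def test_perfect_anti_linear(self):
        r, _ = binned_correlation(self._track([1, 2, 3, 4]),
                                  self._track([8, 6, 4, 2]))
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(11)
        a, b = rng.random(500), rng.random(500)
        r, _ = binned_correlation(self._track(a), self._track(b))
        # direct Pearson formula, independent of scipy
        am, bm = a - a.mean(), b - b.mean()
        expect = (am * bm).sum() / np.sqrt((am ** 2).sum() * (bm ** 2).sum())
        assert abs(r - expect) < 1e-12

    def test_affine_invariance(self):
        rng = np.random.default_rng(13)
        a, b = rng.random(200), rng.random(200)
        r0, _ = binned_correlation(self._track(a), self._track(b))
        r1, _ = binned_correlation(self._track(3.5 * a + 2.0), self._track(b))
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_constant_track_is_error_not_nan(self):
        with pytest.raises(ValidationError, match="constant"):
            binned_correlation(self._track([2, 2, 2, 2]),
                               self._track([1, 2, 3, 4]))


class TestMetagene:
    sizes = {"c": 60_000}

    def test_constant_track_gives_flat_profile(self, cfg):
        t = _flat_track(100, self.sizes, 4.2)
        genes = [GeneModel("g1", "c", 20_000, 30_000, "+"),
                 GeneModel("g2", "c", 40_000, 50_000, "-")]
        for mode in ("tss", "genebody"):
            prof = metagene_profile(t, genes, mode, cfg)
            assert prof.mean_signal == pytest.approx(
                np.full(len(prof.positions), 4.2))

    def test_point_signal_peaks_at_tss_center(self, cfg):
        vals = np.zeros(600)
        tss = 20_000
        vals[tss // 100] = 50.0
        t = SignalTrack(100, dict(self.sizes), {"c": vals})
        prof = metagene_profile(t, [GeneModel("g", "c", tss, 30_000, "+")],
                                "tss", cfg, step_bp=100)
        center = len(prof.positions) // 2
        assert prof.positions[center] == 0
        assert np.argmax(prof.mean_signal) == center

    def test_strand_mirror_symmetry(self, cfg):
        # mirrored signal around the chromosome midpoint; a plus-strand gene
        # and its reflected minus-strand twin must produce identical profiles
        rng = np.random.default_rng(29)
        size = self.sizes["c"]
        vals = rng.random(size // 100)
        mirrored = vals[::-1].copy()
        t_fwd = SignalTrack(100, dict(self.sizes), {"c": vals})
        t_rev = SignalTrack(100, dict(self.sizes), {"c": mirrored})
        g_fwd = GeneModel("f", "c", 20_000, 30_000, "+")
        g_rev = GeneModel("r", "c", size - 30_000, size - 20_000, "-")
        for mode in ("tss", "genebody"):
            p_fwd = metagene_profile(t_fwd, [g_fwd], mode, cfg, step_bp=100)
            p_rev = metagene_profile(t_rev, [g_rev], mode, cfg, step_bp=100)
            assert p_rev.mean_signal == pytest.approx(p_fwd.mean_signal)

    def test_empty_gene_list_rejected(self, cfg):
        with pytest.raises(ValidationError):
            metagene_profile(_flat_track(100, self.sizes, 1.0), [], "tss", cfg)


class TestStratification:
    def _inputs(self, ko_factor):
        import pandas as pd
        from nonotet.core import ExpressionMatrix, SampleMeta
        sizes = {"c": 200_000}
        genes = [GeneModel(f"g{i}", "c", 10_000 + 20_000 * i,
                           18_000 + 20_000 * i, "+") for i in range(8)]
        bound = genes[:4]
        peaks = PeakSet.build("TET1", [
            Interval(g.chrom, g.tss - 300, g.tss + 300, signal=5.0)
            for g in bound])
        wt_vals = np.zeros(sizes["c"] // 500)
        for g in bound:
            wt_vals[(g.tss - 500) // 500:(g.tss + 500) // 500] = 8.0
        wt = SignalTrack(500, sizes, {"c": wt_vals.copy()})
        ko = SignalTrack(500, sizes, {"c": wt_vals * ko_factor})
        samples = [SampleMeta.make(g, 0, r) for g in ("WT", "KO")
                   for r in (1, 2)]
        df = pd.DataFrame(
            {s.sample_id: np.full(len(genes), 16.0) for s in samples},
            index=[g.gene_id for g in genes])
        expr = ExpressionMatrix(df, samples)
        assign = promoter_targets(peaks, genes, 2000)
        tracks = {"tet1_wt": wt, "tet1_ko": ko, "hmc_wt": wt, "hmc_ko": ko}
        return genes, assign, tracks, expr

    def test_identical_inputs_give_zero_averages(self, cfg):
        genes, assign, tracks, expr = self._inputs(1.0)
        res = stratify_expression_by_binding(genes, assign, tracks, expr, cfg)
        assert res.group_means.to_numpy() == pytest.approx(np.zeros((2, 3)))

    def test_halved_ko_signal_gives_minus_one_for_bound(self):
        # pseudocount made negligible so the closed form is exact
        cfg = PipelineConfig(pseudocount=1e-9)
        genes, assign, tracks, expr = self._inputs(0.5)
        res = stratify_expression_by_binding(genes, assign, tracks, expr, cfg)
        gm = res.group_means
        assert gm.loc["TET1_bound", "log2_binding"] == pytest.approx(-1.0,
                                                                     abs=1e-3)
        assert gm.loc["not_TET1_bound", "log2_binding"] == pytest.approx(
            0.0, abs=1e-6)
        assert gm.loc["TET1_bound", "log2_expression"] == pytest.approx(0.0)

    def test_planted_coupling_depresses_bound_group(self, default_study, cfg):
        st = default_study
        ch = st.chromatin
        assign = promoter_targets(ch.peaks["TET1_WT"], st.genes,
                                  cfg.promoter_flank_bp)
        res = stratify_expression_by_binding(
            st.genes, assign,
            {"tet1_wt": ch.tracks["TET1_WT"], "tet1_ko": ch.tracks["TET1_KO"],
             "hmc_wt": ch.tracks["hmC_WT"], "hmc_ko": ch.tracks["hmC_KO"]},
            st.expression, cfg)
        bound = res.group_means.loc["TET1_bound"]
        unbound = res.group_means.loc["not_TET1_bound"]
        assert (bound < -0.3).all()
        assert unbound.abs().max() < 0.1


class TestChiSquared:
    def test_independence_gives_zero(self):
        universe = {f"g{i}" for i in range(100)}
        de = {f"g{i}" for i in range(50)}          # half of everything
        red = {f"g{i}" for i in range(0, 100, 2)}  # independent half
        res = chi_squared_association(de, red, universe)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # [[30,10],[10,30]]: all expected cells are 20, so
        # chi2 = 4 * (10^2 / 20) = 20
        universe = {f"g{i}" for i in range(80)}
        ids = sorted(universe)
        de = set(ids[:40])
        red = set(ids[:30]) | set(ids[40:50])
        res = chi_squared_association(de, red, universe)
        assert res.table.tolist() == [[30.0, 10.0], [10.0, 30.0]]
        assert res.chi2 == pytest.approx(20.0)
        assert res.p_value < 0.001

    def test_subset_violation_rejected(self):
        with pytest.raises(ValidationError):
            chi_squared_association({"x"}, set(), {"g1"})

    def test_small_expected_cell_warns(self):
        universe = {f"g{i}" for i in range(1000)}
        ids = sorted(universe)
        res = chi_squared_association(set(ids[:2]), set(ids[2:4]), universe)
        assert res.warning is not None

    def test_planted_association_significant(self, default_study, cfg):
        from nonotet.expression import differential_expression
        st = default_study
        expr = st.expression
        de0 = differential_expression(expr, expr.sample_ids("WT", 0),
                                      expr.sample_ids("KO", 0), cfg)
        de_genes = set(de0.index[de0["status"] != "ns"])
        reduced = set(st.truth.genes.index[st.truth.genes["reduced_in_ko"]])
        res = chi_squared_association(de_genes, reduced,
                                      set(st.truth.genes.index))
        assert res.p_value < 1e-6


def test_percent_rounding_half_away_from_zero():
    assert round_half_away(0.5) == 1
    assert round_half_away(-0.5) == -1
    assert round_half_away(84.6) == 85
    assert pct(851, 2005) == 42
    assert pct(0, 100) == 0
    assert pct(1, 0) == 0
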