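import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dpescan.dpe_stats import (
    DpeCallSet,
    bh_adjust,
    build_design,
    call_dpe,
    dpe_table,
    intersect_signature,
    lrt_test,
    ma_plot_data,
    qlf_test,
    squeeze_quasi_dispersions,
)
from dpescan.pipeline import preprocess_matrix, run_comparison
from dpescan.preprocess import FilterConfig, tmm_factors
from dpescan.types import CountMatrix, SampleInfo


def samples_of(groups):
    return [SampleInfo(f"S{i}", g) for i, g in enumerate(groups)]


class TestBuildDesign:
    def test_m_vs_n_subsets_and_indicator(self):
        d = build_design(samples_of("MMNH"), "M_vs_N")
        assert d.matrix.shape == (3, 2)
        assert d.matrix[:, 1].tolist() == [1.0, 1.0, 0.0]
        assert d.sample_ids == ["S0", "S1", "S2"]

    def test_cancer_pools_m_and_n(self):
        d = build_design(samples_of("MNHH"), "C_vs_H")
        assert d.matrix[:, 1].tolist() == [1.0, 1.0, 0.0, 0.0]
        assert d.contrast_group == "C"

    @pytest.mark.parametrize("cmp_", ["M_vs_N", "C_vs_H", "M_vs_H"])
    def test_u_samples_never_enter_any_design(self, cmp_):
        d = build_design(samples_of("MNUHU"), cmp_)
        assert "S2" not in d.sample_ids and "S4" not in d.sample_ids

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="M_vs_H"):
            build_design(samples_of("MMNN"), "M_vs_H")


class TestBhAdjust:
    def test_hand_worked_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_is_identity(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_min_over_suffix_oracle(self, p):
        p = np.array(p)
        q = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        # brute force: q_(i) = min_{j >= i} p_(j) * m / (j+1), capped at 1
        expected = np.empty(m)
        for rank, idx in enumerate(order):
            expected[idx] = min(
                min(p[order[j]] * m / (j + 1) for j in range(rank, m)), 1.0
            )
        assert np.allclose(q, expected)
        assert np.all(np.diff(q[order]) >= -1e-12)  # non-decreasing in sorted order


def small_two_group_matrix(seed=0, g=60, n=8):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(50, (g, n))
    return CountMatrix(counts, [f"e{i}" for i in range(g)],
                       [f"S{j}" for j in range(n)])


class TestLrtQlf:
    def design(self, n=8):
        return build_design(samples_of("M" * (n // 2) + "N" * (n // 2)), "M_vs_N")

    def test_identical_counts_give_zero_statistic_p_one(self):
        counts = np.tile(np.array([[30], [7]]), (1, 8))
        m = CountMatrix(counts, ["e0", "e1"], [f"S{j}" for j in range(8)],
                        lib_sizes=np.full(8, 1e4))
        d = self.design()
        lrt = lrt_test(m, d, None, np.full(2, 0.1))
        assert np.allclose(lrt.statistic, 0.0, atol=1e-9)
        assert np.allclose(lrt.p_value, 1.0)
        qlf = qlf_test(m, d, None, np.full(2, 0.1))
        assert np.allclose(qlf.statistic, 0.0, atol=1e-6)
        assert np.allclose(qlf.p_value, 1.0, atol=1e-3)

    def test_lrt_statistic_nonnegative(self):
        m = small_two_group_matrix(1)
        d = self.design()
        res = lrt_test(m, d, None, np.full(m.n_exons, 0.1))
        assert np.all(res.statistic >= 0)
        assert np.all((res.p_value >= 0) & (res.p_value <= 1))

    def test_fdr_at_least_p(self):
        m = small_two_group_matrix(2)
        d = self.design()
        res = qlf_test(m, d, None, np.full(m.n_exons, 0.1))
        assert np.all(res.fdr >= res.p_value - 1e-12)

    def test_logfc_finite_everywhere(self):
        # one exon all-zero in one group: prior count keeps logFC finite
        m = small_two_group_matrix(3)
        m.counts[0, :4] = 0
        res = lrt_test(m, self.design(), None, np.full(m.n_exons, 0.1))
        assert np.all(np.isfinite(res.logfc))


class TestQuasiDispersionSqueeze:
    def test_huge_prior_df_returns_trend(self):
        rng = np.random.default_rng(6)
        df = 30
        # nearly constant s2: excess variance ~ 0 so prior df is infinite
        s2 = np.exp(rng.normal(0, 0.001, 500))
        abund = rng.normal(5, 2, 500)
        squeezed, prior_df, trend = squeeze_quasi_dispersions(s2, df, abund)
        assert prior_df == np.inf
        assert np.allclose(squeezed, trend)

    def test_moment_matched_prior_df_recovers_scaled_f(self):
        rng = np.random.default_rng(7)
        df, d0 = 20, 12
        s2 = rng.chisquare(df, 3000) / df * (d0 / rng.chisquare(d0, 3000))
        abund = rng.normal(5, 2, 3000)
        _, prior_df, _ = squeeze_quasi_dispersions(s2, df, abund)
        assert 6 <= prior_df <= 25  # moment estimate in the right range


class TestConsensusCalls:
    def make_result(self, method, exons, fdrs, logfc=None):
        from dpescan.dpe_stats import TestResult

        n = len(exons)
        return TestResult(
            method=method, comparison="M_vs_N", exon_ids=list(exons),
            logfc=np.array(logfc if logfc is not None else [1.0] * n),
            avg_log_cpm=np.zeros(n), statistic=np.zeros(n),
            p_value=np.array(fdrs), fdr=np.array(fdrs),
        )

    def test_intersection_of_both_tests(self):
        lrt = self.make_result("LRT", "abc", [0.0005, 0.0005, 0.5])
        qlf = self.make_result("QLF", "abc", [0.5, 0.0005, 0.0005])
        calls = call_dpe(lrt, qlf, 0.001)
        assert calls.called == {"b"}

    def test_direction_follows_logfc_sign(self):
        lrt = self.make_result("LRT", "ab", [0.0001, 0.0001], logfc=[2.0, -2.0])
        qlf = self.make_result("QLF", "ab", [0.0001, 0.0001])
        calls = call_dpe(lrt, qlf, 0.001)
        assert calls.direction == {"a": "M", "b": "N"}

    def test_zero_threshold_empty(self):
        lrt = self.make_result("LRT", "ab", [0.001, 0.2])
        qlf = self.make_result("QLF", "ab", [0.001, 0.2])
        assert call_dpe(lrt, qlf, 0.0).called == set()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        fdrs1, fdrs2 = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        exons = [f"e{i}" for i in range(50)]
        lrt = self.make_result("LRT", exons, fdrs1)
        qlf = self.make_result("QLF", exons, fdrs2)
        prev = set()
        for tau in [0.001, 0.01, 0.1, 0.5, 1.0]:
            cur = call_dpe(lrt, qlf, tau).called
            assert prev <= cur
            prev = cur

    def test_mismatched_universe_errors(self):
        lrt = self.make_result("LRT", "ab", [0.1, 0.1])
        qlf = self.make_result("QLF", "ac", [0.1, 0.1])
        with pytest.raises(ValueError, match="universe"):
            call_dpe(lrt, qlf)


class TestSignatureIntersection:
    def cs(self, name, ids):
        return DpeCallSet(name, sorted(ids), {e: "M" for e in ids}, 0.001, sorted(ids))

    def test_three_way_intersection(self):
        sig, venn = intersect_signature(
            [self.cs("A", {"a", "b", "c"}), self.cs("B", {"b", "c", "d"}),
             self.cs("C", {"c", "e"})])
        assert sig == {"c"}
        assert venn["A&B&C"] == 1
        assert venn["A&B"] == 1  # exon b: in A and B only
        assert venn["C"] == 1    # exon e: C only

    def test_identical_sets(self):
        sig, _ = intersect_signature([self.cs("A", {"x", "y"}), self.cs("B", {"x", "y"})])
        assert sig == {"x", "y"}

    def test_empty_input_set_gives_empty_signature(self):
        sig, _ = intersect_signature([self.cs("A", {"x"}), DpeCallSet("B", [], {}, 0.001, ["x"])])
        assert sig == set()


class TestMaPlot:
    def test_flags_exactly_called_exons(self):
        m = small_two_group_matrix(9)
        d = build_design(samples_of("MMMMNNNN"), "M_vs_N")
        lrt = lrt_test(m, d, None, np.full(m.n_exons, 0.1))
        qlf = qlf_test(m, d, None, np.full(m.n_exons, 0.1))
        calls = call_dpe(lrt, qlf, 0.5)
        tbl = ma_plot_data(lrt, calls)
        assert len(tbl) == m.n_exons
        assert set(tbl.loc[tbl.is_dpe, "exon_id"]) == calls.called


class TestConsensusProperty:
    def test_consensus_subset_of_each_single_test(self, two_group_cohort):
        matrix, catalog, samples, _ = two_group_cohort
        filt, fac = preprocess_matrix(matrix, catalog, FilterConfig(min_samples=15))
        res = run_comparison(filt, samples, "M_vs_N", fac, fdr_threshold=0.05)
        lrt_set = {e for e, q in zip(res.lrt.exon_ids, res.lrt.fdr) if q <= 0.05}
        qlf_set = {e for e, q in zip(res.qlf.exon_ids, res.qlf.fdr) if q <= 0.05}
        assert res.calls.called <= lrt_set
        assert res.calls.called <= qlf_set
        tbl = dpe_table(res.lrt, res.qlf, res.calls)
        assert tbl["is_dpe"].sum() == len(res.calls.exon_ids)
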