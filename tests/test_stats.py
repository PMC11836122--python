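"""Statistical battery: gated tests, FDR, residualization, chi-square."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as st

from eislope.core import InvalidArgumentError, InvalidDataError
from eislope.stats import (
    bh_fdr,
    chi_square_2x2,
    correlate_clinical,
    lilliefors_test,
    paired_bimodality_test,
    residualize_confounds,
    two_sample_test,
)


class TestLilliefors:
    def test_preconditions(self):
        with pytest.raises(InvalidArgumentError):
            lilliefors_test([1.0, 2.0, 3.0])
        with pytest.raises(InvalidDataError):
            lilliefors_test([1.0] * 10)

    def test_type_i_error_rate(self):
        rng = np.random.default_rng(0)
        rej = [lilliefors_test(rng.standard_normal(100)).p <= 0.05 for _ in range(200)]
        assert np.mean(rej) == pytest.approx(0.05, abs=0.03)

    def test_power_against_uniform(self):
        """Power vs Uniform(0,1) at n=100 is ~0.63 (Monte-Carlo oracle:
        simulated null critical value D=0.0883, power 0.63 over 1000
        draws) — well above alpha but far from 1."""
        rng = np.random.default_rng(1)
        rej = [lilliefors_test(rng.uniform(0, 1, 100)).p <= 0.05 for _ in range(200)]
        assert 0.5 <= np.mean(rej) <= 0.75


class TestTwoSample:
    def test_exact_mann_whitney_p(self):
        """Complete separation at n=3+3: 2 of the 20 labelings are as
        extreme, two-sided p = 0.1."""
        r = two_sample_test([1, 2, 3], [4, 5, 6], gate="nonparametric")
        assert r.name == "mann_whitney"
        assert r.method == "exact enumeration"
        assert r.p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples(self):
        r = two_sample_test([1, 2, 3, 4], [1, 2, 3, 4], gate="parametric")
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_pooled_df_convention(self):
        """31 vs 30 subjects must give the Student (pooled) t with 59 df."""
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(31), rng.standard_normal(30) + 0.1
        r = two_sample_test(a, b, gate="parametric")
        t_manual, p_manual = st.ttest_ind(a, b, equal_var=True)
        assert r.statistic == pytest.approx(float(t_manual))
        assert r.p == pytest.approx(float(p_manual))

    def test_exact_vs_asymptotic_agreement(self):
        """At n1=n2=6, the exact and tie-corrected normal-approximation
        Mann-Whitney p-values differ by < 0.02."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = rng.standard_normal(6), rng.standard_normal(6)
            p_exact = two_sample_test(a, b, gate="nonparametric").p
            p_asym = st.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            ).pvalue
            assert abs(p_exact - p_asym) < 0.02

    def test_gate_recorded(self):
        rng = np.random.default_rng(4)
        r = two_sample_test(rng.standard_normal(30), rng.standard_normal(30))
        assert "Lilliefors" in r.branch


class TestPaired:
    def test_all_zero_differences(self):
        r = paired_bimodality_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.statistic, r.p) == (0.0, 1.0)

    def test_constant_shift_degenerate(self):
        r = paired_bimodality_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert np.isinf(r.statistic) and r.statistic > 0
        assert r.p == 0.0
        assert "degenerate" in r.branch

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            paired_bimodality_test([1.0, 2.0], [1.0])

    def test_power_unit_shift(self):
        """hi = lo + N(1, 0.5), n=31: detected in >= 95% of replicates."""
        rng = np.random.default_rng(5)
        rej = 0
        for _ in range(100):
            lo = rng.standard_normal(31)
            hi = lo + rng.normal(1.0, 0.5, 31)
            rej += paired_bimodality_test(lo, hi).p <= 0.05
        assert rej >= 95


class TestBH:
    def test_stepup_all_rejected(self):
        p_adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05], q=0.05)
        assert rej.all()
        assert p_adj[-1] == pytest.approx(0.05)

    def test_degenerate_cases(self):
        p_adj, rej = bh_fdr([1.0, 1.0, 1.0])
        assert not rej.any() and (p_adj == 1.0).all()
        p_adj, rej = bh_fdr([0.04], q=0.05)
        assert rej[0] and p_adj[0] == pytest.approx(0.04)
        with pytest.raises(InvalidArgumentError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(
        ps=hst.lists(hst.floats(0, 1), min_size=1, max_size=20),
        q=hst.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_monotonicity(self, ps, q):
        p_adj, rej = bh_fdr(ps, q)
        order = np.argsort(ps)
        assert (np.diff(p_adj[order]) >= -1e-12).all()
        assert (p_adj >= np.asarray(ps) - 1e-12).all()
        _, rej_tight = bh_fdr(ps, q / 2)
        assert rej_tight.sum() <= rej.sum()


class TestResidualize:
    def test_orthogonality(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(30)
        X = rng.standard_normal((30, 5))
        r = residualize_confounds(y, X)
        for j in range(5):
            assert abs(np.corrcoef(r, X[:, j])[0, 1]) < 1e-10

    def test_orthogonal_confound_removes_mean_only(self):
        rng = np.random.default_rng(7)
        c = rng.standard_normal(50)
        c -= c.mean()
        y = rng.standard_normal(50)
        y -= (y @ c) / (c @ c) * c  # force orthogonality to the confound
        res = residualize_confounds(y, c)
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-10)

    def test_exact_linear_combination(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((30, 3))
        y = X @ [1.0, -2.0, 0.5] + 4.0
        r = residualize_confounds(y, X)
        assert np.abs(r).max() < 1e-8

    def test_rank_deficiency_named(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(InvalidDataError, match="collinear"):
            residualize_confounds(np.random.default_rng(9).standard_normal(10), X)


class TestCorrelation:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        up = correlate_clinical(x, x**3 + 1, gate="nonparametric")
        dn = correlate_clinical(x, -x - 5, gate="nonparametric")
        assert up.name == "spearman"
        assert up.statistic == pytest.approx(1.0)
        assert dn.statistic == pytest.approx(-1.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(10)
        rs, rej = [], 0
        for _ in range(200):
            x, y = rng.standard_normal(30), rng.standard_normal(30)
            r = correlate_clinical(x, y)
            rs.append(abs(r.statistic))
            rej += r.p <= 0.05
        assert np.mean(rs) < 0.2
        assert rej / 200 == pytest.approx(0.05, abs=0.03)

    def test_constant_rejected(self):
        with pytest.raises(InvalidDataError):
            correlate_clinical(np.ones(10), np.arange(10.0))


class TestChiSquare:
    def test_printed_sex_table(self):
        """11F/19M vs 13F/18M: chi-square = 0.1773 to 4 decimals."""
        r = chi_square_2x2([[11, 19], [13, 18]])
        assert round(r.statistic, 4) == 0.1773

    def test_homogeneous_and_separated(self):
        assert chi_square_2x2([[10, 10], [10, 10]]).statistic == pytest.approx(0.0)
        assert chi_square_2x2([[20, 0], [0, 20]]).statistic == pytest.approx(40.0)

    def test_zero_margin(self):
        with pytest.raises(InvalidDataError):
            chi_square_2x2([[0, 0], [5, 5]])
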