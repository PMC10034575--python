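import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from adaptidose import (
    ValidationError,
    kruskal_wallis,
    linear_fit_with_bands,
    mann_whitney,
    pearson_r,
    wilcoxon_signed_rank,
)


def enumerate_wilcoxon_p(diffs):
    """Two-sided exact p by full 2^n enumeration of sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    total = len(ws)
    p_le = sum(w <= w_obs + 1e-12 for w in ws) / total
    p_ge = sum(w >= w_obs - 1e-12 for w in ws) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def enumerate_mwu_p(x, y):
    """Two-sided exact p by enumeration over all C(n+m, n) labelings."""
    pooled = np.asarray(list(x) + list(y), dtype=float)
    n = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_identical_positive_diffs_exact(self):
        res = wilcoxon_signed_rank([1.0] * 6)
        assert res.mode == "exact"
        assert res.p_value == pytest.approx(2 / 2**6)

    def test_antisymmetric_diffs_center_null(self):
        res = wilcoxon_signed_rank([3.0, -3.0, 1.0, -1.0, 2.0, -2.0])
        assert res.p_value >= 0.9

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            d = rng.normal(0.5, 1.0, size=10)
            res = wilcoxon_signed_rank(d, mode="exact")
            assert res.p_value == pytest.approx(enumerate_wilcoxon_p(d), abs=1e-12)

    def test_exact_handles_tied_ranks(self, rng):
        d = [2.0, 2.0, -2.0, 5.0, 5.0, -1.0, 3.0]
        res = wilcoxon_signed_rank(d, mode="exact")
        assert res.p_value == pytest.approx(enumerate_wilcoxon_p(d), abs=1e-12)

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0

    def test_exact_and_approx_agree_moderate_n(self, rng):
        for _ in range(100):
            d = rng.normal(rng.uniform(-0.5, 0.5), 1.0, size=20)
            pe = wilcoxon_signed_rank(d, mode="exact").p_value
            pa = wilcoxon_signed_rank(d, mode="approx").p_value
            assert abs(pe - pa) < 0.01


class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.mode == "exact"
        assert res.p_value == pytest.approx(2 * (1 / comb(6, 3)))

    def test_identical_samples_high_p(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mode == "approx"  # ties force the corrected approximation
        assert res.p_value == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for n, m in [(3, 4), (4, 4), (5, 3)]:
            x = rng.normal(0.3, 1.0, size=n)
            y = rng.normal(0.0, 1.0, size=m)
            res = mann_whitney(x, y, mode="exact")
            assert res.p_value == pytest.approx(enumerate_mwu_p(x, y), abs=1e-12)

    def test_large_shift_significant(self, rng):
        x = rng.normal(0.0, 1.0, size=50)
        y = rng.normal(2.0, 1.0, size=50)
        assert mann_whitney(x, y).p_value < 0.001


class TestKruskalWallis:
    def test_identical_groups_null(self):
        res = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_group_case_tracks_mann_whitney(self, rng):
        x = rng.normal(0.0, 1.0, size=200)
        y = rng.normal(0.25, 1.0, size=200)
        p_kw = kruskal_wallis([x, y]).p_value
        p_mwu = mann_whitney(x, y).p_value
        assert abs(p_kw - p_mwu) < 0.02

    def test_three_separated_groups(self, rng):
        groups = [rng.normal(mu, 0.5, size=15) for mu in (0.0, 2.0, 4.0)]
        assert kruskal_wallis(groups).p_value < 0.001


class TestPearson:
    def test_perfect_correlation(self):
        assert pearson_r([1, 2, 3, 4], [2, 4, 6, 8]).statistic == pytest.approx(1.0)

    def test_independent_samples_small_r(self, rng):
        x, y = rng.normal(size=500), rng.normal(size=500)
        assert abs(pearson_r(x, y).statistic) < 0.15

    def test_four_point_closed_form(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 6.0])
        r_manual = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert pearson_r(x, y).statistic == pytest.approx(r_manual, rel=1e-12)


class TestLinearFit:
    def test_exact_line_zero_width_bands(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = 2.0 * x + 1.0
        fit = linear_fit_with_bands(x, y)
        lo, hi = fit.confidence_band(x)
        np.testing.assert_allclose(lo, y, atol=1e-9)
        np.testing.assert_allclose(hi, y, atol=1e-9)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            linear_fit_with_bands([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_bands_match_independent_reference(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0, 10, size=40)
        y = 1.5 * x - 2.0 + rng.normal(0, 1.0, size=40)
        fit = linear_fit_with_bands(x, y)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.intercept == pytest.approx(model.params[0], rel=1e-9)
        assert fit.slope == pytest.approx(model.params[1], rel=1e-9)
        grid = np.linspace(0, 10, 7)
        pred = model.get_prediction(sm.add_constant(grid))
        ci = pred.conf_int(alpha=0.05)
        np.testing.assert_allclose(fit.confidence_band(grid)[0], ci[:, 0], rtol=1e-9)
        np.testing.assert_allclose(fit.confidence_band(grid)[1], ci[:, 1], rtol=1e-9)
        pi = pred.conf_int(obs=True, alpha=0.05)
        np.testing.assert_allclose(fit.prediction_band(grid)[0], pi[:, 0], rtol=1e-9)
        np.testing.assert_allclose(fit.prediction_band(grid)[1], pi[:, 1], rtol=1e-9)


class TestCalibration:
    @pytest.mark.parametrize("test_name", ["wilcoxon", "mann_whitney"])
    def test_type_i_error_near_nominal(self, test_name):
        rng = np.random.default_rng(7)
        n_reject, n_sim = 0, 2000
        for _ in range(n_sim):
            if test_name == "wilcoxon":
                p = wilcoxon_signed_rank(rng.normal(size=30)).p_value
            else:
                p = mann_whitney(rng.normal(size=30), rng.normal(size=30)).p_value
            n_reject += p < 0.05
        assert abs(n_reject / n_sim - 0.05) <= 0.01
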