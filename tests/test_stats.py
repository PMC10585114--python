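import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm_api
from hypothesis import given, strategies as st

from msntools import (
    bh_fdr,
    cohort_strengths,
    compare_global_ms,
    fit_regional_contrast,
    frequency_correlation,
    jaccard_flags,
    network_contrast,
    simulate_morphometry,
)
from msntools.stats import RegionalStatMap, _design_matrix

from conftest import make_table


class TestBHFDR:
    def test_printed_four_value_example(self):
        p_fdr, sig = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
        np.testing.assert_allclose(p_fdr, [0.04, 0.04, 0.04, 0.04], atol=1e-12)
        assert sig.all()

    def test_all_ones_and_singleton(self):
        p_fdr, sig = bh_fdr(np.ones(5))
        assert not sig.any() and np.all(p_fdr == 1.0)
        p_fdr, _ = bh_fdr(np.array([0.031]))
        assert p_fdr[0] == pytest.approx(0.031)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_adjusted_never_below_raw(self, ps):
        p = np.asarray(ps)
        p_fdr, sig = bh_fdr(p, alpha=0.05)
        assert np.all(p_fdr >= p - 1e-12)
        assert np.all(p_fdr <= 1.0 + 1e-12)
        assert np.array_equal(sig, p_fdr < 0.05)


class TestRegionalContrast:
    def _fixture(self):
        """6 subjects x 3 regions with a planted group shift in region 0."""
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, size=(6, 3))
        vals[:3, 0] += 2.0  # first three subjects are users
        df = pd.DataFrame(vals)
        df.attrs["kind"] = "ms"
        subjects = make_table(rng.normal(size=(6, 3, 7))).subjects
        subjects["group"] = ["user"] * 3 + ["control"] * 3
        return df, subjects

    def test_matches_statsmodels_ols(self):
        values, subjects = self._fixture()
        out = fit_regional_contrast(values, subjects)
        X, terms = _design_matrix(subjects)
        g = terms.index("group")
        for r in range(3):
            fit = sm_api.OLS(values.to_numpy()[:, r], X).fit()
            assert out.t[r] == pytest.approx(fit.tvalues[g], abs=1e-10)
            assert out.p[r] == pytest.approx(fit.pvalues[g], abs=1e-10)

    def test_fdr_family_is_regions(self):
        values, subjects = self._fixture()
        out = fit_regional_contrast(values, subjects)
        expected, _ = bh_fdr(out.p, 0.05)
        np.testing.assert_allclose(out.p_fdr, expected)
        assert np.array_equal(out.significant, out.p_fdr < 0.05)

    def test_perfect_fit_capped_with_warning(self):
        rng = np.random.default_rng(1)
        subjects = make_table(rng.normal(size=(8, 2, 7))).subjects
        subjects["group"] = ["user"] * 4 + ["control"] * 4
        vals = pd.DataFrame(
            np.column_stack([
                (subjects["group"] == "user").astype(float),  # exact group indicator
                rng.normal(size=8),
            ])
        )
        vals.attrs["kind"] = "ms"
        with pytest.warns(RuntimeWarning, match="perfect"):
            out = fit_regional_contrast(vals, subjects)
        assert abs(out.t[0]) == pytest.approx(1e6)

    def test_group_too_small_rejected(self):
        values, subjects = self._fixture()
        subjects = subjects.copy()
        subjects["group"] = ["user"] + ["control"] * 5
        with pytest.raises(ValueError, match="at least 2"):
            fit_regional_contrast(values, subjects)

    def test_response_schema_mismatch_rejected(self):
        values, subjects = self._fixture()  # tagged 'ms'
        with pytest.raises(ValueError, match="schema"):
            fit_regional_contrast(
                values, subjects, response="ct", mean_ct=np.zeros(6)
            )
        with pytest.raises(ValueError, match="mean_ct"):
            ct_vals = values.copy()
            ct_vals.attrs["kind"] = "ct"
            fit_regional_contrast(ct_vals, subjects, response="ct")

    def test_tiv_covariate_requires_complete_tiv(self):
        values, subjects = self._fixture()
        subjects = subjects.copy()
        subjects.loc[0, "tiv"] = np.nan
        with pytest.raises(ValueError, match="tiv"):
            fit_regional_contrast(values, subjects, extra_covariates=("tiv",))


class TestGlobalComparison:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(4, 10))
        vals = np.vstack([base, base])
        s = pd.DataFrame(vals)
        subjects = make_table(rng.normal(size=(8, 10, 7))).subjects
        subjects["group"] = ["user"] * 4 + ["control"] * 4
        out = compare_global_ms(s, subjects)
        assert out["t"] == pytest.approx(0.0, abs=1e-12)
        assert out["ks_statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_welch_t_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        b = np.array([0.5, 0.6, 0.8, 1.2, 1.4])
        s = pd.DataFrame(np.concatenate([a, b])[:, None] * np.ones((1, 3)))
        subjects = make_table(np.zeros((10, 3, 7)) + np.arange(21).reshape(1, 3, 7)).subjects
        subjects["group"] = ["user"] * 5 + ["control"] * 5
        out = compare_global_ms(s, subjects)
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        assert out["t"] == pytest.approx(t_hand, abs=1e-12)

    def test_small_group_rejected(self):
        s = pd.DataFrame(np.zeros((3, 4)))
        subjects = make_table(np.ones((3, 4, 7)) * np.arange(28).reshape(1, 4, 7)).subjects
        subjects["group"] = ["user", "control", "control"]
        with pytest.raises(ValueError):
            compare_global_ms(s, subjects)


class TestNetworkContrast:
    def test_composition_matches_manual_aggregation(self, parc40):
        table, _ = simulate_morphometry(parc40, n_per_group=6, seed=13)
        strengths = cohort_strengths(table)
        out = network_contrast(strengths, table.subjects, parc40, atlas="yeo7")
        assert len(out) == 7
        # recompute one label by hand through fit_regional_contrast
        lab = out.label.iloc[0]
        mask = parc40.yeo == lab
        agg = pd.DataFrame(strengths.to_numpy()[:, mask].mean(axis=1))
        agg.attrs["kind"] = "ms"
        manual = fit_regional_contrast(agg, table.subjects)
        assert out.t.iloc[0] == pytest.approx(manual.t[0], abs=1e-10)
        # FDR family is the 7 labels
        expected, _ = bh_fdr(out.p.to_numpy(), 0.05)
        np.testing.assert_allclose(out.p_fdr.to_numpy(), expected)

    def test_von_economo_atlas_and_bad_atlas(self, parc40):
        table, _ = simulate_morphometry(parc40, n_per_group=6, seed=13)
        strengths = cohort_strengths(table)
        out = network_contrast(strengths, table.subjects, parc40, atlas="von_economo")
        assert set(out.atlas) == {"von_economo"}
        with pytest.raises(ValueError):
            network_contrast(strengths, table.subjects, parc40, atlas="aal")


class TestFrequencyCorrelation:
    def _setup(self, attendance):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(8, 5))
        s = pd.DataFrame(vals)
        subjects = make_table(rng.normal(size=(8, 5, 7)), attendance=attendance).subjects
        subjects["group"] = ["user"] * 4 + ["control"] * 4
        stat_map = RegionalStatMap(
            t=np.array([2.0, -2.0, 3.0, 0.5, -1.0]),
            p=np.full(5, 0.01),
            p_fdr=np.array([0.01, 0.01, 0.01, 0.5, 0.5]),
            significant=np.array([True, True, True, False, False]),
            model_terms=["group"],
            df_resid=3,
        )
        return s, subjects, stat_map

    def test_monotone_attendance_gives_unit_rho(self):
        s, subjects, stat_map = self._setup(list(range(8)))
        pos = stat_map.significant & (stat_map.t > 0)
        mean_ms = s.to_numpy()[:4][:, pos].mean(axis=1)
        att = np.argsort(np.argsort(mean_ms)).astype(float)  # monotone in mean_ms
        subjects.loc[:3, "attendance"] = att
        out = frequency_correlation(s, subjects, stat_map)
        assert out.set.tolist() == ["positive", "negative", "all"]
        assert out.loc[out.set == "positive", "rho"].iloc[0] == pytest.approx(1.0)

    def test_matches_independent_spearman(self):
        s, subjects, stat_map = self._setup([30.0, 12.0, 400.0, 90.0] + [np.nan] * 4)
        out = frequency_correlation(s, subjects, stat_map)
        from scipy.stats import rankdata

        att = np.array([30.0, 12.0, 400.0, 90.0])
        mean_all = s.to_numpy()[:4][:, stat_map.significant].mean(axis=1)
        ra, rm = rankdata(att), rankdata(mean_all)
        rho_hand = np.corrcoef(ra, rm)[0, 1]
        assert out.loc[out.set == "all", "rho"].iloc[0] == pytest.approx(rho_hand, abs=1e-12)

    def test_constant_attendance_rejected(self):
        s, subjects, stat_map = self._setup([5.0] * 4 + [np.nan] * 4)
        with pytest.raises(ValueError, match="constant"):
            frequency_correlation(s, subjects, stat_map)

    def test_empty_flag_set_skipped_with_warning(self):
        s, subjects, stat_map = self._setup([1.0, 4.0, 2.0, 8.0] + [np.nan] * 4)
        stat_map.significant = np.array([True, False, True, False, False])
        stat_map.t = np.abs(stat_map.t)  # no negative-significant set
        with pytest.warns(UserWarning, match="negative"):
            out = frequency_correlation(s, subjects, stat_map)
        assert "negative" not in set(out.set)


class TestJaccard:
    def test_hand_counted_example(self):
        assert jaccard_flags([1, 1, 0, 1], [1, 0, 0, 1]) == pytest.approx(2 / 3)

    def test_edge_cases(self):
        assert jaccard_flags([True, False], [True, False]) == 1.0
        assert jaccard_flags([True, False], [False, True]) == 0.0
        assert jaccard_flags([False, False], [False, False]) == 1.0
        with pytest.raises(ValueError):
            jaccard_flags([True], [True, False])

    @given(st.lists(st.booleans(), min_size=1, max_size=30), st.data())
    def test_matches_set_oracle(self, a, data):
        b = data.draw(st.lists(st.booleans(), min_size=len(a), max_size=len(a)))
        sa = {i for i, x in enumerate(a) if x}
        sb = {i for i, x in enumerate(b) if x}
        expected = 1.0 if not (sa | sb) else len(sa & sb) / len(sa | sb)
        assert jaccard_flags(a, b) == pytest.approx(expected)
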