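"""Preference classification, chi-square tests, split-plot decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ccaf
from ccaf.preference_stats import (backtransform_means, chi2_independence,
                                   classify_cohort, classify_preference,
                                   preference_table, split_plot_model)


class TestClassify:
    @pytest.mark.parametrize("ci,expected", [
        ((0.8, 0.9), "snack"),       # LD-style interval, entirely above 0
        ((-0.2, 0.02), "neither"),   # HD-style interval straddling 0
        ((-0.5, -0.1), "alcohol"),
    ])
    def test_categories_from_ci(self, ci, expected):
        assert classify_preference(ci) == expected

    @given(lo=st.floats(-5, 5), hi=st.floats(-5, 5))
    @settings(max_examples=100, deadline=None)
    def test_partition_is_exhaustive_and_exclusive(self, lo, hi):
        if lo > hi:
            with pytest.raises(ValueError):
                classify_preference((lo, hi))
            return
        cat = classify_preference((lo, hi))
        assert cat == ("alcohol" if hi < 0 else "snack" if lo > 0 else "neither")

    def test_cohort_table(self):
        cis = {"a": (-1, -0.5), "b": (0.2, 0.8), "c": (-0.1, 0.1)}
        cls = classify_cohort(cis)
        groups = pd.Series({"a": "HD", "b": "LD", "c": "HD"})
        tab = preference_table(cls, groups)
        assert tab.loc["HD", "alcohol"] == 1 and tab.loc["LD", "snack"] == 1
        assert list(tab.columns) == ["alcohol", "snack", "neither"]


def _chi2_oracle(obs):
    # brute-force expected counts from margins
    obs = np.asarray(obs, float)
    total = obs.sum()
    chi2 = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / total
            chi2 += (obs[i, j] - e) ** 2 / e
    return chi2


class TestChi2:
    @given(st.lists(st.lists(st.integers(0, 30), min_size=2, max_size=4),
                    min_size=2, max_size=4).filter(
        lambda rows: len({len(r) for r in rows}) == 1))
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_oracle(self, rows):
        obs = np.array(rows, float)
        if np.any(obs.sum(0) == 0) or np.any(obs.sum(1) == 0):
            return
        res = chi2_independence(obs)
        assert res.chi2 == pytest.approx(_chi2_oracle(obs), abs=1e-9)
        assert res.df == (obs.shape[0] - 1) * (obs.shape[1] - 1)
        assert res.p == pytest.approx(stats.chi2.sf(res.chi2, res.df))

    def test_yates_correction_formula(self):
        obs = np.array([[30, 0], [12, 18]], float)
        res = chi2_independence(obs, correction="yates")
        manual = 0.0
        for i in range(2):
            for j in range(2):
                e = obs[i].sum() * obs[:, j].sum() / obs.sum()
                manual += (abs(obs[i, j] - e) - 0.5) ** 2 / e
        assert res.chi2 == pytest.approx(manual, abs=1e-9)

    def test_independent_table_gives_zero(self):
        assert chi2_independence([[10, 20], [5, 10]]).chi2 == pytest.approx(0)

    def test_errors(self):
        with pytest.raises(ValueError):
            chi2_independence([[1, 2, 3]])
        with pytest.raises(ValueError):
            chi2_independence([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            chi2_independence([[1, 2, 3], [4, 5, 6]], correction="yates")


class TestSplitPlot:
    def test_df_structure_at_reference_size(self, cohort_summary):
        res = split_plot_model(cohort_summary)
        grp = res.effect("group")
        lev = res.effect("relative_point_level")
        assert (grp["df1"], grp["df2"]) == (1, 56)
        assert (lev["df1"], lev["df2"]) == (2, 112)
        assert res.effect("relative_point_level:group:sex")["df2"] == 112

    def test_ss_decomposition_identity(self, cohort_summary):
        res = split_plot_model(cohort_summary)
        a = res.anova
        between = a[a["stratum"] == "between"]["ss"].sum()
        within = a[a["stratum"] == "within"]["ss"].sum()
        assert between == pytest.approx(res.ss_between_total, rel=1e-10)
        assert within == pytest.approx(res.ss_within_total, rel=1e-10)
        assert res.ss_between_total + res.ss_within_total == \
            pytest.approx(res.ss_total, rel=1e-10)

    def test_matches_pingouin_mixed_anova(self, cohort_summary):
        pg = pytest.importorskip("pingouin")
        mine = split_plot_model(cohort_summary, between=("group",))
        other = pg.mixed_anova(
            cohort_summary.rename(columns={"relative_point_level": "level"}),
            dv="elogit", within="level", subject="subject_id", between="group")
        other = other.set_index("Source")
        for eff, key in [("group", "group"),
                         ("relative_point_level", "level"),
                         ("relative_point_level:group", "Interaction")]:
            row = mine.effect(eff)
            assert row["F"] == pytest.approx(other.loc[key, "F"], abs=1e-9)
            assert row["partial_eta_sq"] == \
                pytest.approx(other.loc[key, "np2"], abs=1e-9)

    def test_audit_covariate_model_df(self, cohort_summary):
        # additive between design (audit + group + sex), linear level trend
        res = split_plot_model(cohort_summary, between=("group", "sex"),
                               covariates=("audit",), level_coding="linear",
                               factor_interactions=False)
        aud = res.effect("audit")
        lev = res.effect("relative_point_level")
        assert (aud["df1"], aud["df2"]) == (1, 56)
        assert (lev["df1"], lev["df2"]) == (1, 116)
        assert res.effect("relative_point_level:audit")["df1"] == 1

    def test_unbalanced_rejected_with_subject_list(self, cohort_summary):
        broken = cohort_summary[
            ~((cohort_summary["subject_id"] == "LD001")
              & (cohort_summary["relative_point_level"] == 0))]
        with pytest.raises(ValueError, match="LD001"):
            split_plot_model(broken)

    def test_degenerate_variance_flagged(self):
        rows = []
        for i in range(8):
            grp = "HD" if i < 4 else "LD"
            sex = "female" if i % 2 == 0 else "male"
            for lev in (-2, 0, 2):
                rows.append((f"s{i}", grp, sex, lev, 1.0 if grp == "HD" else -1.0))
        df = pd.DataFrame(rows, columns=["subject_id", "group", "sex",
                                         "relative_point_level", "elogit"])
        res = split_plot_model(df)
        grp = res.effect("group")
        lev = res.effect("relative_point_level")
        assert grp["flag"] == "capped" and grp["F"] >= 1e12
        assert lev["flag"] == "degenerate" and np.isnan(lev["F"])

    def test_type_i_error_quick_null_check(self):
        # small-n sanity companion to the full calibration study
        out = ccaf.type_i_error_study(n_sims=60, n_per_group=10, seed=3)
        assert 0 <= out["rejection_rate"] <= 0.2


class TestBacktransform:
    def test_zero_logit_maps_to_fifty_percent(self):
        rows = [(f"s{i}", "HD", lev, 0.0) for i in range(6)
                for lev in (-2, 0, 2)]
        df = pd.DataFrame(rows, columns=["subject_id", "group",
                                         "relative_point_level", "elogit"])
        out = backtransform_means(df, "group")
        assert out["pct"].iloc[0] == pytest.approx(50.0)
        assert out["pct_lo"].iloc[0] == pytest.approx(50.0)

    def test_roundtrip_of_adjusted_proportion(self):
        from ccaf.preprocessing import empirical_logit
        k, n = 20, 32
        v = empirical_logit(k, n)
        back = 100.0 / (1.0 + np.exp(-v))
        assert back == pytest.approx(100 * (k + 0.5) / (n + 1.0), abs=1e-9)

    def test_marginal_means_recover_cell_probabilities(self, cohort_summary):
        out = backtransform_means(cohort_summary, "relative_point_level")
        out = out.set_index("relative_point_level")
        # monotone in level, and ordering of CI bounds correct
        assert out.loc[-2, "pct"] < out.loc[0, "pct"] < out.loc[2, "pct"]
        assert (out["pct_lo"] <= out["pct"]).all()
        assert (out["pct"] <= out["pct_hi"]).all()
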