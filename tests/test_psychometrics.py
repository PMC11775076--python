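"""Psychometric fitting, PSE interpolation and parametric bootstrap."""

import numpy as np
import pandas as pd
import pytest

import ccaf
from ccaf.cohort import choice_probability
from ccaf.psychometrics import (PsychometricModel, fit_psychometric,
                                fit_vs_covariate, interpolate_pse)

X = np.array([-2.0, 0.0, 2.0])


def _model(k, n=32):
    n = np.full(3, n) if np.isscalar(n) else np.asarray(n)
    return PsychometricModel(X, n, np.asarray(k, float))


class TestFit:
    def test_symmetric_counts_give_zero_pse(self):
        res = _model([4, 16, 28]).fit()
        assert res.converged and not res.separation_flag
        assert res.alpha == pytest.approx(0.0, abs=1e-8)
        assert interpolate_pse(res) == pytest.approx(0.0, abs=1e-8)
        # location definition: fitted curve crosses 0.5 at the PSE
        assert res.predict(res.alpha) == pytest.approx(0.5, abs=1e-10)

    def test_shift_reparameterization_identity(self):
        base = _model([5, 14, 29]).fit()
        for c in (-1.5, 0.7, 3.0):
            shifted = PsychometricModel(X + c, np.full(3, 32.0),
                                        np.array([5, 14, 29.0])).fit()
            assert shifted.alpha == pytest.approx(base.alpha + c, abs=1e-6)
            assert shifted.beta == pytest.approx(base.beta, abs=1e-6)

    def test_agrees_with_glm_intercept_slope_fit(self):
        # independent route: statsmodels binomial GLM, alpha = -b0/b1
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        for _ in range(5):
            k = rng.binomial(32, choice_probability(X, 0.4, 0.9))
            if len(np.unique(k)) == 1:
                continue
            res = _model(k).fit()
            exog = np.column_stack([np.ones(3), X])
            glm = sm.GLM(np.column_stack([k, 32 - k]), exog,
                         family=sm.families.Binomial()).fit()
            b0, b1 = glm.params
            assert res.beta == pytest.approx(b1, abs=1e-6)
            assert res.alpha == pytest.approx(-b0 / b1, abs=1e-6)

    def test_loglik_beats_grid_search(self):
        # optimality: no (alpha, beta) on a fine grid does better
        model = _model([6, 20, 30])
        res = model.fit()
        alphas = np.arange(-1.5, 1.5, 1e-3)
        betas = np.arange(0.05, 3.0, 1e-3)
        p = 1.0 / (1.0 + np.exp(-betas[None, :, None]
                                * (X - alphas[:, None, None])))
        k, n = model.k, model.n
        grid_ll = (k * np.log(p) + (n - k) * np.log1p(-p)).sum(-1)
        kernel_at_fit = float(np.sum(
            k * np.log(res.predict(X)) + (n - k) * np.log1p(-res.predict(X))))
        assert kernel_at_fit >= grid_ll.max() - 1e-9

    def test_separation_flagged_and_stabilised(self):
        res = _model([0, 0, 32]).fit()
        assert res.separation_flag
        assert np.isfinite(res.alpha) and np.isfinite(res.beta)
        boot = res.parametric_bootstrap(200, seed=0)
        assert boot.alpha_ci[0] <= boot.alpha_ci[1]
        assert boot.n_failed <= 40

    def test_saturated_flat_subject_classifies_as_alcohol(self):
        # always-alcohol at every level: PSE draws pin at -inf
        res = _model([32, 32, 32]).fit()
        assert res.separation_flag
        boot = res.parametric_bootstrap(200, seed=1)
        assert boot.alpha_ci[1] < 0

    def test_single_predictor_value_rejected(self):
        with pytest.raises(ValueError):
            PsychometricModel([0.0, 0.0], [32, 32], [10, 12])

    def test_pooled_recovery_from_simulated_group(self):
        # 30 subjects x 96 trials from one observer; quick replicate study
        rng = np.random.default_rng(12)
        n = np.full(3, 960)
        hits = 0
        for _ in range(50):
            k = rng.binomial(960, choice_probability(X, 0.9, 0.98))
            res = PsychometricModel(X, n, k).fit()
            hits += abs(res.alpha - 0.9) < 0.1
        assert hits >= 45


class TestBootstrap:
    def test_percentile_interval_properties(self):
        res = _model([5, 14, 29]).fit()
        boot = res.parametric_bootstrap(1000, seed=4)
        assert boot.alpha_ci[0] < res.alpha < boot.alpha_ci[1]
        assert boot.beta_ci[0] < res.beta < boot.beta_ci[1]
        assert boot.n_failed <= 200

    def test_same_seed_identical(self):
        res = _model([5, 14, 29]).fit()
        a = res.parametric_bootstrap(500, seed=11)
        b = res.parametric_bootstrap(500, seed=11)
        assert a.alpha_ci == b.alpha_ci and a.beta_ci == b.beta_ci

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)
        widths = {}
        for n in (96, 960):
            w = []
            for _ in range(15):
                k = rng.binomial(n, choice_probability(X, 0.4, 0.9))
                res = PsychometricModel(X, np.full(3, n), k).fit()
                boot = res.parametric_bootstrap(300, seed=int(rng.integers(2**31)))
                w.append(boot.alpha_ci[1] - boot.alpha_ci[0])
            widths[n] = np.mean(w)
        assert widths[960] < widths[96]

    def test_invalid_arguments(self):
        res = _model([5, 14, 29]).fit()
        with pytest.raises(ValueError):
            res.parametric_bootstrap(0)
        with pytest.raises(ValueError):
            res.parametric_bootstrap(10, level=1.5)


class TestFromSummaries:
    def test_group_pooling_matches_manual_counts(self, cohort_summary):
        ld = cohort_summary[cohort_summary["group"] == "LD"]
        model = PsychometricModel.from_summaries(ld)
        manual = ld.groupby("relative_point_level")[["k", "n"]].sum()
        np.testing.assert_array_equal(model.k, manual["k"].to_numpy())
        np.testing.assert_array_equal(model.n, manual["n"].to_numpy())

    def test_subject_scope_uses_single_subject(self, cohort_summary):
        sid = cohort_summary["subject_id"].iloc[0]
        res = fit_psychometric(cohort_summary, subject_id=sid)
        assert res.model.scope == "subject"
        assert int(res.model.n.sum()) == 96

    def test_mean_proportion_pooling_runs(self, cohort_summary):
        res = fit_psychometric(cohort_summary, pooling="mean_proportion")
        assert np.isfinite(res.alpha)


class TestCovariateFit:
    def _summary_with_audit_effect(self, decreasing=True):
        # alpha decreases with audit -> more alcohol choice at high audit
        rng = np.random.default_rng(8)
        rows = []
        for i in range(40):
            audit = int(rng.integers(0, 30))
            alpha = (2.0 - 0.15 * audit) if decreasing else 0.5
            for lev in (-2, 0, 2):
                p = choice_probability(lev, alpha, 1.0)
                k = rng.binomial(32, p)
                rows.append((f"s{i}", audit, lev, k, 32))
        df = pd.DataFrame(rows, columns=["subject_id", "audit",
                                         "relative_point_level", "k", "n"])
        df["no_data"] = False
        return df

    def test_positive_slope_when_alpha_falls_with_audit(self):
        df = self._summary_with_audit_effect()
        for lev in (-2, 0, 2):
            res, boot = fit_vs_covariate(df, lev, n_boot=200, seed=1)
            assert res.beta > 0
            assert res.model.predictor == "audit"

    def test_null_covariate_ci_covers_zero(self):
        df = self._summary_with_audit_effect(decreasing=False)
        res, boot = fit_vs_covariate(df, 0, n_boot=400, seed=2)
        assert boot.beta_ci[0] < 0 < boot.beta_ci[1]

    def test_constant_audit_rejected(self):
        df = self._summary_with_audit_effect()
        df["audit"] = 10
        with pytest.raises(ValueError):
            fit_vs_covariate(df, 0)
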