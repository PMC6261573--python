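"""Variance-component models, repeatability, model ranking, bending fits."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from crestvib.errors import (
    DesignError,
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
)
from crestvib.stats import (
    VarianceModelFit,
    adjusted_repeatability,
    aicc_rank,
    fit_bending_trial,
    fit_variance_model,
    marginal_r2,
    summarize_crests,
)


def simulate_grouped(rng, n_groups=15, n_trials=3, sigma2_id=3.0, sigma2_res=1.0,
                     mean=26.0, sex_effect=0.0):
    rows = []
    for g in range(n_groups):
        sex = "male" if g < n_groups // 2 else "female"
        b = rng.normal(0, np.sqrt(sigma2_id))
        for tr in range(n_trials):
            y = mean + (sex_effect if sex == "male" else 0.0) + b \
                + rng.normal(0, np.sqrt(sigma2_res))
            rows.append(dict(crest_id=f"c{g:02d}", sex=sex,
                             orientation="out_of_plane", trial=tr, f_r=y))
    return pd.DataFrame(rows)


class TestSummarizeCrests:
    def _df(self, values_by_crest):
        rows = []
        for cid, vals in values_by_crest.items():
            for i, v in enumerate(vals):
                rows.append(dict(crest_id=cid, sex="female",
                                 orientation="out_of_plane", trial=i,
                                 f_r=v, delta_f=5.0, Q=v / 5.0))
        return pd.DataFrame(rows)

    def test_ci_is_1_96_sem(self):
        out = summarize_crests(self._df({"a": [26.0, 27.0, 28.0]}))
        row = out["per_crest"].iloc[0]
        assert row.f_r_mean == pytest.approx(27.0)
        assert row.f_r_ci_hi - row.f_r_mean == pytest.approx(1.96 / np.sqrt(3), abs=1e-9)

    def test_identical_trials_zero_width_ci(self):
        out = summarize_crests(self._df({"a": [26.0, 26.0, 26.0]}))
        row = out["per_crest"].iloc[0]
        assert row.f_r_ci_hi == row.f_r_ci_lo == row.f_r_mean

    def test_group_mean_weights_crests_equally(self):
        out = summarize_crests(self._df({"a": [26.0] * 5, "b": [28.0, 28.0]}))
        grp = out["groups"].iloc[0]
        assert grp.f_r_mean == pytest.approx(27.0)

    def test_single_trial_crest_has_no_ci(self):
        out = summarize_crests(self._df({"a": [26.0]}))
        row = out["per_crest"].iloc[0]
        assert np.isnan(row.f_r_ci_lo) and row.f_r_mean == 26.0

    def test_invariant_to_row_order(self, rng):
        df = simulate_grouped(rng)
        shuffled = df.sample(frac=1.0, random_state=5)
        a = summarize_crests(df, metrics=("f_r",))["groups"]
        b = summarize_crests(shuffled, metrics=("f_r",))["groups"]
        pd.testing.assert_frame_equal(a, b)


class TestVarianceModel:
    def test_matches_statsmodels_reml(self, rng):
        df = simulate_grouped(rng, sex_effect=1.5)
        own = fit_variance_model(df, "f_r", fixed=["sex"], reml=True)
        sm = smf.mixedlm("f_r ~ sex", df, groups=df["crest_id"]).fit(reml=True)
        assert own.sigma2_id == pytest.approx(float(sm.cov_re.iloc[0, 0]), rel=1e-3)
        assert own.sigma2_res == pytest.approx(float(sm.scale), rel=1e-3)
        assert own.loglik == pytest.approx(float(sm.llf), abs=1e-4)

    def test_matches_method_of_moments_on_balanced_design(self, rng):
        df = simulate_grouped(rng)
        own = fit_variance_model(df, "f_r", reml=True)
        n = 3
        gm = df.groupby("crest_id").f_r.mean()
        msb = n * gm.var(ddof=1)
        msw = (df.groupby("crest_id").f_r
               .apply(lambda s: ((s - s.mean()) ** 2).sum()).sum()
               / (len(gm) * (n - 1)))
        assert own.sigma2_id == pytest.approx((msb - msw) / n, abs=1e-6)
        assert own.sigma2_res == pytest.approx(msw, abs=1e-6)

    def test_zero_among_group_variance_hits_boundary(self, rng):
        # force the sample among-group variance to exactly zero: the REML
        # estimate must sit on the boundary, not go negative
        df = simulate_grouped(rng, sigma2_id=0.0)
        df["f_r"] = df.f_r - df.groupby("crest_id").f_r.transform("mean") + 26.0
        fit = fit_variance_model(df, "f_r")
        assert fit.sigma2_id == 0.0

    def test_constant_extra_column_raises_design_error(self, rng):
        df = simulate_grouped(rng)
        df["const_col"] = 1.0
        with pytest.raises(DesignError):
            fit_variance_model(df, "f_r", fixed=["const_col"])

    def test_recovery_and_repeatability_coverage(self):
        """15 groups x 3 trials, sigma2 = (3, 1): variance components land
        within 50% of truth and the bootstrap CI covers R = 0.75 in most
        replicates (scaled-down coverage study: >= 25 of 30)."""
        covered = 0
        ok_est = 0
        reps = 30
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            df = simulate_grouped(rng, sigma2_id=3.0, sigma2_res=1.0)
            fit = fit_variance_model(df, "f_r")
            if 1.5 <= fit.sigma2_id <= 4.5 and 0.5 <= fit.sigma2_res <= 1.5:
                ok_est += 1
            rep_res = adjusted_repeatability(fit, n_boot=100, seed=rep)
            if rep_res.ci_low <= 0.75 <= rep_res.ci_high:
                covered += 1
        assert covered >= 25
        assert ok_est >= 24

    def test_heteroskedastic_multipliers_track_group_noise(self, rng):
        rows = []
        for g in range(8):
            sd = 0.5 if g < 4 else 2.0
            b = rng.normal(0, 1.5)
            for tr in range(6):
                rows.append(dict(crest_id=f"c{g}", f_r=26 + b + rng.normal(0, sd)))
        df = pd.DataFrame(rows)
        fit = fit_variance_model(df, "f_r", heteroskedastic=True)
        mult = fit.res_multipliers
        assert mult.iloc[4:].mean() > 4 * mult.iloc[:4].mean()


class TestRepeatability:
    def _manual_fit(self, sigma2_id, sigma2_res, n_groups=6, n_per=3):
        labels = np.repeat([f"g{i}" for i in range(n_groups)], n_per)
        X = np.ones((n_groups * n_per, 1))
        return VarianceModelFit(
            beta=pd.Series([0.0], index=["intercept"]),
            se_beta=pd.Series([0.0], index=["intercept"]),
            sigma2_id=sigma2_id, sigma2_res=sigma2_res,
            res_multipliers=pd.Series(1.0, index=[f"g{i}" for i in range(n_groups)]),
            loglik=0.0, reml=True, heteroskedastic=False, n_params=3,
            converged=True, response="y", n_obs=len(labels), X=X,
            group_labels=labels,
        )

    def test_definition(self):
        rep = adjusted_repeatability(self._manual_fit(3.0, 1.0), n_boot=0)
        assert rep.value == pytest.approx(0.75)

    def test_boundary_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="boundary"):
            rep = adjusted_repeatability(self._manual_fit(0.0, 1.0), n_boot=0)
        assert rep.value == 0.0 and rep.boundary

    def test_affine_invariance(self, rng):
        df = simulate_grouped(rng)
        r1 = adjusted_repeatability(fit_variance_model(df, "f_r"), n_boot=0).value
        df2 = df.assign(f_r=7.0 * df.f_r - 100.0)
        r2 = adjusted_repeatability(fit_variance_model(df2, "f_r"), n_boot=0).value
        assert r2 == pytest.approx(r1, rel=1e-4)
        assert 0.0 <= r1 <= 1.0


class TestMarginalR2:
    def test_null_model_is_zero(self, rng):
        df = simulate_grouped(rng)
        fit = fit_variance_model(df, "f_r")
        assert marginal_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_quarter(self):
        n = 40
        X = np.column_stack([np.ones(n), np.tile([1.0, -1.0], n // 2)])
        fit = VarianceModelFit(
            beta=pd.Series([0.0, 1.0], index=["intercept", "x"]),
            se_beta=pd.Series([0.0, 0.0], index=["intercept", "x"]),
            sigma2_id=2.0, sigma2_res=1.0,
            res_multipliers=pd.Series(1.0, index=["g"]),
            loglik=0.0, reml=True, heteroskedastic=False, n_params=4,
            converged=True, response="y", n_obs=n, X=X,
            group_labels=np.repeat(["g"], n),
        )
        # var(X beta) = 1, so R2_m = 1 / (1 + 2 + 1)
        assert marginal_r2(fit) == pytest.approx(0.25)

    def test_strong_fixed_effect_approaches_one(self, rng):
        df = simulate_grouped(rng, sigma2_id=1e-4, sigma2_res=1e-4, sex_effect=10.0)
        fit = fit_variance_model(df, "f_r", fixed=["sex"])
        assert marginal_r2(fit) > 0.99


class TestAiccRank:
    def _fit(self, loglik, k, fixed):
        return VarianceModelFit(
            beta=pd.Series(dtype=float), se_beta=pd.Series(dtype=float),
            sigma2_id=1.0, sigma2_res=1.0,
            res_multipliers=pd.Series(1.0, index=["g"]), loglik=loglik,
            reml=False, heteroskedastic=False, n_params=k, converged=True,
            response="f_r", fixed=fixed, n_obs=45,
        )

    def test_closed_form_value(self):
        tab = aicc_rank([self._fit(-100.0, 3, [])], n=45)
        assert tab.aicc.iloc[0] == pytest.approx(200 + 6 + 24 / 41, abs=1e-3)
        assert tab.delta_aicc.iloc[0] == 0.0

    def test_penalty_prefers_smaller_model_at_equal_loglik(self):
        tab = aicc_rank([self._fit(-100.0, 4, ["a"]), self._fit(-100.0, 3, [])], n=45)
        assert tab.iloc[0].k == 3

    def test_reml_fits_rejected(self):
        f = self._fit(-100.0, 3, [])
        f.reml = True
        with pytest.raises(InvalidParameterError):
            aicc_rank([f], n=45)

    def test_small_n_correction_undefined(self):
        with pytest.raises(InvalidParameterError):
            aicc_rank([self._fit(-10.0, 5, [])], n=6)


class TestBending:
    def test_exact_line(self):
        d = np.arange(0, 12.0, 0.5)
        fit = fit_bending_trial(d, 0.003 * d)
        assert fit.k == pytest.approx(0.003, rel=1e-9)
        assert fit.r2_adj == pytest.approx(1.0)
        assert fit.linear_range_mm == pytest.approx(d[-1] - d[0])

    def test_saturation_breakpoint_detected(self):
        # force plateaus beyond 10 mm; the detected linear range must end there
        d = np.arange(0, 16.0, 0.5)
        F = 0.003 * np.minimum(d, 10.0)
        fit = fit_bending_trial(d, F)
        assert 9.0 <= fit.linear_range_mm <= 11.0
        assert fit.k == pytest.approx(0.003, rel=0.05)

    def test_pure_noise_has_no_linear_range(self):
        rng = np.random.default_rng(3)
        d = np.arange(0, 10.0, 0.5)
        with pytest.raises((FitFailureError, InsufficientDataError)):
            fit_bending_trial(d, rng.normal(0, 1.0, size=len(d)))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_bending_trial(np.arange(4.0), 0.003 * np.arange(4.0))
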