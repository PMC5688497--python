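import math
import warnings

import numpy as np
import pandas as pd
import pytest

from birthrisk import (PanelParams, blup_random_effects, build_design,
                       fit_hierarchical, fit_ols, generate_panel,
                       report_per10, reml_criterion)
from birthrisk.aggregate import SurveyAggregate
from birthrisk.errors import FitError
from birthrisk.models import _design_matrix

from conftest import ols_oracle


def _agg(sid, cid, pct, mcpr=30.0, perm=15.0, larc=20.0, n=200):
    return SurveyAggregate(
        survey_id=sid, country_id=cid, year=2000, mcpr_pct=mcpr,
        pct_permanent=perm, pct_larc=larc, n_births_window=n,
        category_pct={("parity", "5+"): pct})


def _random_rows(rng, n, n_countries=8):
    return pd.DataFrame({
        "y": rng.normal(2.0, 0.5, n),
        "mcpr_pct": rng.uniform(5, 75, n),
        "pct_permanent": rng.uniform(0, 40, n),
        "pct_larc": rng.uniform(0, 50, n),
        "country_id": [f"C{i % n_countries}" for i in range(n)],
        "survey_id": [f"S{i}" for i in range(n)],
    })


class TestBuildDesign:
    def test_log_of_percent(self):
        rows = build_design([_agg("S1", "C1", 10.0)], "parity", "5+")
        assert rows.loc[0, "y"] == pytest.approx(math.log(10.0))

    def test_zero_percent_continuity_rule(self):
        rows = build_design([_agg("S1", "C1", 0.0, n=200),
                             _agg("S2", "C1", 10.0)], "parity", "5+")
        assert rows.loc[0, "y"] == pytest.approx(math.log(100 * 0.5 / 200))

    def test_survey_without_window_births_dropped(self):
        rows = build_design([_agg("S1", "C1", 10.0, n=0),
                             _agg("S2", "C1", 10.0)], "parity", "5+")
        assert list(rows["survey_id"]) == ["S2"]

    def test_all_zero_category_is_an_error(self):
        with pytest.raises(FitError):
            build_design([_agg("S1", "C1", 0.0), _agg("S2", "C1", 0.0)],
                         "parity", "5+")


class TestOls:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        rows = _random_rows(rng, 60)
        beta = np.array([1.5, -0.014, 0.006, 0.002])
        X, _, names = _design_matrix(rows, True)
        rows["y"] = X @ beta
        fit = fit_ols(rows, True)
        for name, b in zip(names, beta):
            assert fit.coef[name] == pytest.approx(b, abs=1e-10)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            rows = _random_rows(rng, int(rng.integers(10, 60)))
            include_mix = bool(rng.integers(0, 2))
            fit = fit_ols(rows, include_mix)
            X, y, names = _design_matrix(rows, include_mix)
            expected = ols_oracle(X, y)
            got = np.array([fit.coef[n] for n in names])
            assert np.allclose(got, expected, atol=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        rows = _random_rows(rng, 40)
        fit = fit_ols(rows, True)
        X, y, names = _design_matrix(rows, True)
        res = sm.OLS(y, X).fit()
        assert np.allclose([fit.coef[n] for n in names], res.params,
                           atol=1e-10)
        assert np.allclose([fit.se[n] for n in names], res.bse, atol=1e-10)
        assert np.allclose([fit.p_value[n] for n in names], res.pvalues,
                           atol=1e-10)

    def test_effective_intercept_is_mean_of_logs(self):
        # with mcpr centred and its slope orthogonal to the intercept,
        # the fitted intercept equals the mean of the log responses
        rows = pd.DataFrame({
            "y": [0.0, 2.0, 0.0, 2.0], "mcpr_pct": [-5.0, 5.0, 5.0, -5.0],
            "pct_permanent": [0.0] * 4, "pct_larc": [0.0] * 4,
            "country_id": list("ABCD"), "survey_id": list("abcd")})
        fit = fit_ols(rows[["y", "mcpr_pct", "country_id",
                            "survey_id"]].assign(pct_permanent=0,
                                                 pct_larc=0), False)
        assert fit.coef["intercept"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_covariate_rejected(self):
        rows = pd.DataFrame({
            "y": [0.0, 2.0, 1.0], "mcpr_pct": [10.0, 10.0, 10.0],
            "pct_permanent": [0.0] * 3, "pct_larc": [0.0] * 3,
            "country_id": list("ABC"), "survey_id": list("abc")})
        with pytest.raises(FitError, match="mcpr"):
            fit_ols(rows, False)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(3)
        rows = _random_rows(rng, 30)
        rows["pct_larc"] = 2.0 * rows["pct_permanent"]
        with pytest.raises(FitError, match="pct_larc"):
            fit_ols(rows, True)

    def test_too_few_surveys(self):
        rng = np.random.default_rng(4)
        rows = _random_rows(rng, 4)
        with pytest.raises(FitError):
            fit_ols(rows, True)

    def test_t_and_p_invariant_under_covariate_rescaling(self):
        rng = np.random.default_rng(5)
        rows = _random_rows(rng, 50)
        fit = fit_ols(rows, True)
        scaled = rows.copy()
        scaled["mcpr_pct"] = rows["mcpr_pct"] * 4.0 + 0.0
        fit2 = fit_ols(scaled, True)
        assert fit2.coef["mcpr"] == pytest.approx(fit.coef["mcpr"] / 4.0)
        assert fit2.p_value["mcpr"] == pytest.approx(fit.p_value["mcpr"],
                                                     abs=1e-12)


class TestHierarchical:
    def _panel_rows(self, seed=7, tau2=0.04, **kw):
        params = PanelParams(seed=seed, n_countries=40, total_surveys=120,
                             tau2=tau2, **kw)
        aggs, _ = generate_panel(params)
        return build_design(aggs, "parity", "5+")

    def test_boundary_equivalence_with_ols(self):
        rows = self._panel_rows(seed=9, tau2=0.0)
        fit3 = fit_hierarchical(rows)
        fit2 = fit_ols(rows, True)
        assert fit3.tau2 == pytest.approx(0.0, abs=1e-6)
        for name in fit2.coef:
            assert fit3.coef[name] == pytest.approx(fit2.coef[name],
                                                    abs=1e-6)

    def test_maximises_reml_criterion_over_grid(self):
        rows = self._panel_rows(seed=9)
        fit = fit_hierarchical(rows)
        for lam in np.linspace(0.0, 20.0, 50):
            assert fit.reml_loglik >= reml_criterion(rows, lam) - 1e-6

    def test_matches_statsmodels_mixedlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rows = self._panel_rows(seed=10)
        fit = fit_hierarchical(rows)
        X, y, names = _design_matrix(rows, True)
        res = sm.regression.mixed_linear_model.MixedLM(
            y, X, groups=rows["country_id"].to_numpy()).fit(reml=True)
        assert np.allclose([fit.coef[n] for n in names], res.fe_params,
                           atol=1e-5)
        assert fit.tau2 == pytest.approx(float(np.asarray(res.cov_re)[0, 0]),
                                         rel=1e-2, abs=1e-5)
        assert fit.sigma2 == pytest.approx(res.scale, rel=1e-2)
        assert fit.reml_loglik >= res.llf - 1e-6

    def test_invariant_to_country_relabelling_and_row_order(self):
        rows = self._panel_rows(seed=11)
        fit = fit_hierarchical(rows)
        relabel = {c: f"X{i}" for i, c in
                   enumerate(reversed(sorted(rows["country_id"].unique())))}
        shuffled = rows.sample(frac=1.0, random_state=4).copy()
        shuffled["country_id"] = shuffled["country_id"].map(relabel)
        fit2 = fit_hierarchical(shuffled)
        # summation order changes perturb the optimum within the search
        # tolerance, so agreement is to ~1e-6, not machine precision
        assert fit2.tau2 == pytest.approx(fit.tau2, rel=1e-4, abs=1e-9)
        for name in fit.coef:
            assert fit2.coef[name] == pytest.approx(fit.coef[name],
                                                    rel=1e-6, abs=1e-9)
        for cid, b in fit.random_effects.items():
            assert fit2.random_effects[relabel[cid]] == pytest.approx(
                b, rel=1e-4, abs=1e-7)

    def test_singleton_countries_fall_back_to_ols(self):
        rng = np.random.default_rng(12)
        rows = _random_rows(rng, 30, n_countries=30)  # 1 survey each
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit3 = fit_hierarchical(rows)
        fit2 = fit_ols(rows, True)
        assert fit3.tau2 == 0.0
        for name in fit2.coef:
            assert fit3.coef[name] == pytest.approx(fit2.coef[name],
                                                    abs=1e-8)


class TestBlup:
    def _fit_rows(self, seed=13):
        rng = np.random.default_rng(seed)
        return _random_rows(rng, 40, n_countries=10)

    def test_zero_tau2_gives_full_shrinkage(self):
        rows = self._fit_rows()
        beta = {"intercept": 2.0, "mcpr": -0.01, "pct_permanent": 0.0,
                "pct_larc": 0.0}
        re = blup_random_effects(beta, 0.0, 0.01, rows)
        assert all(b == 0.0 for b in re.values())

    def test_small_sigma2_gives_no_shrinkage(self):
        rows = self._fit_rows().iloc[:10].copy()
        rows["country_id"] = [f"C{i}" for i in range(10)]  # n_i = 1
        beta = {"intercept": 0.0, "mcpr": 0.0, "pct_permanent": 0.0,
                "pct_larc": 0.0}
        re = blup_random_effects(beta, 1.0, 1e-12, rows)
        for cid, b in re.items():
            rbar = rows.loc[rows["country_id"] == cid, "y"].mean()
            assert b == pytest.approx(rbar, rel=1e-9)

    def test_equal_variances_four_surveys_gives_0_8(self):
        rows = pd.DataFrame({
            "y": [1.0, 2.0, 3.0, 4.0],
            "mcpr_pct": [10.0, 20.0, 30.0, 40.0],
            "pct_permanent": [0.0] * 4, "pct_larc": [0.0] * 4,
            "country_id": ["C1"] * 4, "survey_id": list("abcd")})
        beta = {"intercept": 0.0, "mcpr": 0.0, "pct_permanent": 0.0,
                "pct_larc": 0.0}
        re = blup_random_effects(beta, 0.5, 0.5, rows)
        # shrinkage 4/(4+1) = 0.8 times the mean residual 2.5
        assert re["C1"] == pytest.approx(0.8 * 2.5, abs=1e-10)

    def test_shrinkage_monotone_in_group_size(self):
        beta = {"intercept": 0.0, "mcpr": 0.0, "pct_permanent": 0.0,
                "pct_larc": 0.0}
        values = []
        for ni in (1, 2, 4, 8, 16):
            rows = pd.DataFrame({
                "y": [1.0] * ni, "mcpr_pct": [10.0] * ni,
                "pct_permanent": [0.0] * ni, "pct_larc": [0.0] * ni,
                "country_id": ["C"] * ni,
                "survey_id": [f"s{i}" for i in range(ni)]})
            values.append(blup_random_effects(beta, 0.3, 0.7, rows)["C"])
        assert all(b2 >= b1 for b1, b2 in zip(values, values[1:]))

    def test_magnitude_bounded_by_mean_residual(self):
        rows = self._fit_rows(seed=14)
        fit = fit_hierarchical(rows)
        X, y, names = _design_matrix(rows, True)
        resid = y - X @ np.array([fit.coef[n] for n in names])
        for cid, b in fit.random_effects.items():
            rbar = resid[(rows["country_id"] == cid).to_numpy()].mean()
            assert abs(b) <= abs(rbar) + 1e-12


class TestReportPer10:
    def test_slopes_scaled_by_ten(self):
        rows = _random_rows(np.random.default_rng(15), 40)
        fit = fit_ols(rows, True)
        fit.coef["mcpr"] = -0.022
        table = report_per10(fit).set_index("coefficient")
        assert table.loc["mcpr", "estimate_per10"] == pytest.approx(-0.220)
        assert table.loc["mcpr", "p_value"] == fit.p_value["mcpr"]
        assert table.loc["intercept", "estimate_per10"] == \
            fit.coef["intercept"]

    def test_round_trip_identity(self):
        rows = _random_rows(np.random.default_rng(16), 40)
        fit = fit_ols(rows, True)
        table = report_per10(fit).set_index("coefficient")
        for name in fit.coef:
            scale = 1.0 if name == "intercept" else 10.0
            assert table.loc[name, "estimate_per10"] / scale == \
                pytest.approx(fit.coef[name], rel=1e-15)
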