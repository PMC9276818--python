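"""Variance-components layer: pair likelihood against the closed-form
bivariate normal, optimizer against exhaustive grid search, nesting,
profile CIs, and AIC-based model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinbeliefs.biometric import (
    EP,
    BiometricFit,
    default_biometric_covariates,
    fit_biometric,
    model_selection,
    pair_loglikelihood,
    prepare_pairs,
    profile_ci,
    selection_table,
)

from conftest import simulate_trait_pairs


def grid_search_m2ll(y1, y2, mz, grid_step=0.01, v_max=2.0):
    """Independent oracle: exhaustive grid over (sA2, sC2, sE2) with the
    grand mean profiled out by generalized least squares at each node."""
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    s = y1 + y2
    axis = np.arange(grid_step, v_max + grid_step / 2, grid_step)
    best = np.inf
    n = len(y1)
    grid_c, grid_e = np.meshgrid(axis, axis, indexing="ij")
    for va in np.arange(0.0, v_max + grid_step / 2, grid_step):
        V = va + grid_c + grid_e
        off_mz = va + grid_c
        off_dz = 0.5 * va + grid_c
        # GLS mean: each pair weighs 2/(V+off)
        w_mz, w_dz = 2.0 / (V + off_mz), 2.0 / (V + off_dz)
        sum_w = w_mz * (2 * mz.sum()) / 2 + w_dz * (2 * (~mz).sum()) / 2
        mu = (w_mz / 2 * s[mz].sum() + w_dz / 2 * s[~mz].sum()) / sum_w
        m2ll = np.zeros_like(V)
        for msk, off in ((mz, off_mz), (~mz, off_dz)):
            r1, r2 = y1[msk], y2[msk]
            det = V**2 - off**2
            S2 = ((r1[:, None, None] - mu) ** 2 + (r2[:, None, None] - mu) ** 2).sum(axis=0)
            S11 = ((r1[:, None, None] - mu) * (r2[:, None, None] - mu)).sum(axis=0)
            m2ll += msk.sum() * (2 * np.log(2 * np.pi) + np.log(det)) + (
                V * S2 - 2 * off * S11
            ) / det
        best = min(best, float(m2ll.min()))
    return best


class TestPairLoglikelihood:
    def test_single_pair_closed_form_oracle(self):
        """MZ pair (1.0, 0.5), sA2=0.5, sE2=0.5: the hand-checked bivariate
        normal log-density with covariance [[1, .5], [.5, 1]]."""
        ll = pair_loglikelihood(
            np.array([1.0]), np.array([0.5]), np.array([True]),
            {"a": 0.5, "c": 0.0, "e": 0.5},
        )
        assert ll[0] == pytest.approx(-2.194036030183455)

    def test_matches_scipy_multivariate_normal(self):
        rng = np.random.default_rng(0)
        y1, y2 = rng.standard_normal(6), rng.standard_normal(6)
        mz = np.array([True, True, True, False, False, False])
        var = {"a": 0.3, "c": 0.2, "e": 0.5}
        ll = pair_loglikelihood(y1, y2, mz, var, mean1=0.1, mean2=0.1)
        for i in range(6):
            off = 0.5 if mz[i] else 0.35
            ref = stats.multivariate_normal(
                mean=[0.1, 0.1], cov=[[1.0, off], [off, 1.0]]
            ).logpdf([y1[i], y2[i]])
            assert ll[i] == pytest.approx(ref)

    def test_independence_factorizes(self):
        y1, y2 = np.array([0.4]), np.array([-1.2])
        mz = np.array([True])
        ll = pair_loglikelihood(y1, y2, mz, {"e": 0.8})
        uni = stats.norm(scale=np.sqrt(0.8))
        assert ll[0] == pytest.approx(uni.logpdf(0.4) + uni.logpdf(-1.2))

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            pair_loglikelihood(np.zeros(1), np.zeros(1), np.array([True]), {"a": -1, "e": 1})


class TestFit:
    def test_optimizer_matches_grid_oracle(self):
        """30 covariate-free pairs: ML deviance within 0.05 of an exhaustive
        0.01-resolution grid over the three variances."""
        phen = simulate_trait_pairs(0.4, 0.2, 0.4, n_mz=20, n_dz=10, seed=31)
        data = prepare_pairs(phen, "trait", covariates=[])
        fit = fit_biometric(data, "ACE", seed=0)
        oracle = grid_search_m2ll(data.y1, data.y2, data.mz)
        assert fit.minus2ll <= oracle + 0.05

    def test_parameter_recovery_large_n(self):
        """AE world with 40% heritability at 5,000/5,000 pairs."""
        phen = simulate_trait_pairs(0.4, 0.0, 0.6, n_mz=5000, n_dz=5000, seed=32)
        data = prepare_pairs(phen, "trait", covariates=[])
        fit = fit_biometric(data, "AE", seed=0)
        assert fit.standardized["a"] == pytest.approx(40.0, abs=3.0)

    def test_nesting_never_fits_worse(self, small_phenotypes):
        data = prepare_pairs(small_phenotypes, "vividness_mean", covariates=[])
        fits = {f.model: f for f in model_selection(data, seed=0)}
        assert fits["ACE"].minus2ll <= fits["AE"].minus2ll + 1e-6
        assert fits["AE"].minus2ll <= fits["E"].minus2ll + 1e-6
        assert fits["CE"].minus2ll <= fits["E"].minus2ll + 1e-6
        assert fits["ADE"].minus2ll <= fits["AE"].minus2ll + 1e-6

    def test_aic_ep_df_arithmetic(self, small_phenotypes):
        data = prepare_pairs(small_phenotypes, "memory_score")
        for model in ("ACE", "AE", "E"):
            fit = fit_biometric(data, model, seed=0)
            assert fit.aic == pytest.approx(fit.minus2ll + 2 * EP[model])
            assert fit.df == fit.n_subjects - EP[model]

    def test_standardized_components_sum_to_100(self, small_phenotypes):
        data = prepare_pairs(small_phenotypes, "memory_score")
        fit = fit_biometric(data, "ACE", seed=0)
        assert sum(fit.standardized.values()) == pytest.approx(100.0)
        assert all(0 <= v <= 100 for v in fit.standardized.values())

    def test_de_model_rejected(self, small_phenotypes):
        data = prepare_pairs(small_phenotypes, "memory_score")
        with pytest.raises(ValueError, match="not identified"):
            fit_biometric(data, "DE")

    def test_covariate_adjustment_shifts_mean(self):
        phen = simulate_trait_pairs(0.4, 0.0, 0.6, n_mz=300, n_dz=150, seed=33)
        phen["trait"] = phen["trait"] + 0.05 * (phen["age"] - 50)
        data = prepare_pairs(phen, "trait", covariates=["age"])
        fit = fit_biometric(data, "AE", seed=0)
        # age is z-scored internally; the coefficient recovers 0.05 * sd(age)
        sd_age = np.repeat(phen.groupby("pair_id")["age"].first().to_numpy(), 2).std()
        assert fit.beta["age"] == pytest.approx(0.05 * sd_age, rel=0.2)


class TestProfileCI:
    def test_e_model_ci_degenerate_at_100(self, small_phenotypes):
        data = prepare_pairs(small_phenotypes, "memory_score", covariates=[])
        fit = fit_biometric(data, "E", seed=0)
        assert profile_ci(fit, "e") == (100.0, 100.0)

    def test_no_heritability_gives_zero_lower_bound(self):
        phen = simulate_trait_pairs(0.0, 0.0, 1.0, n_mz=200, n_dz=100, seed=34)
        data = prepare_pairs(phen, "trait", covariates=[])
        fit = fit_biometric(data, "AE", seed=0)
        lo, hi = profile_ci(fit, "a")
        assert lo == pytest.approx(0.0, abs=0.5)

    def test_interval_brackets_estimate_and_truth(self):
        phen = simulate_trait_pairs(0.4, 0.0, 0.6, n_mz=400, n_dz=200, seed=35)
        data = prepare_pairs(phen, "trait", covariates=[])
        fit = fit_biometric(data, "AE", seed=0)
        lo, hi = profile_ci(fit, "a")
        assert lo <= fit.standardized["a"] <= hi
        assert hi - lo < 40  # informative at this n
        assert lo <= 40.0 <= hi

    def test_complementary_components_mirror(self):
        phen = simulate_trait_pairs(0.4, 0.0, 0.6, n_mz=300, n_dz=150, seed=36)
        data = prepare_pairs(phen, "trait", covariates=[])
        fit = fit_biometric(data, "AE", seed=0, with_ci=True)
        lo_a, hi_a = fit.ci["a"]
        lo_e, hi_e = fit.ci["e"]
        assert lo_a == pytest.approx(100 - hi_e, abs=1.0)
        assert hi_a == pytest.approx(100 - lo_e, abs=1.0)


class TestModelSelection:
    def test_e_world_selects_e(self):
        phen = simulate_trait_pairs(0.0, 0.0, 1.0, n_mz=2000, n_dz=1000, seed=37)
        data = prepare_pairs(phen, "trait", covariates=[])
        ranked = model_selection(data, seed=0)
        assert ranked[0].model == "E"

    def test_c_world_selects_ce(self):
        phen = simulate_trait_pairs(0.0, 0.5, 0.5, n_mz=2000, n_dz=1000, seed=38)
        data = prepare_pairs(phen, "trait", covariates=[])
        ranked = model_selection(data, ("ACE", "AE", "CE", "E"), seed=0)
        assert ranked[0].model == "CE"

    def test_ae_world_selects_ae(self):
        phen = simulate_trait_pairs(0.4, 0.0, 0.6, n_mz=2000, n_dz=1000, seed=39)
        data = prepare_pairs(phen, "trait", covariates=[])
        ranked = model_selection(data, seed=0)
        assert ranked[0].model == "AE"

    def test_ties_break_toward_fewer_parameters(self, small_phenotypes):
        data = prepare_pairs(small_phenotypes, "vividness_mean", covariates=[])
        ranked = model_selection(data, seed=0)
        aics = [f.aic for f in ranked]
        assert aics == sorted(aics)
        for f1, f2 in zip(ranked, ranked[1:]):
            if abs(f1.aic - f2.aic) < 1e-9:
                assert f1.ep <= f2.ep

    def test_selection_table_layout(self, small_phenotypes):
        data = prepare_pairs(small_phenotypes, "vividness_mean")
        table = selection_table(model_selection(data, seed=0))
        assert set(table["model"]) == {"ACE", "ADE", "AE", "CE", "E"}
        assert table["winner"].sum() == 1
        assert (table.sort_values("rank")["AIC"].diff().dropna() >= -1e-9).all()


class TestCovariatePolicy:
    def test_default_covariates_include_demographics(self):
        cov = default_biometric_covariates("memory_score")
        assert {"age", "sex", "age_x_sex"} <= set(cov)
        assert "memory_score" not in cov

    def test_prior_excludes_memory(self):
        assert "memory_score" not in default_biometric_covariates("prior_mean")

    def test_update_includes_estimation_error(self):
        assert "estimation_error_mean" in default_biometric_covariates("update_mean")


class TestFalconerConsistency:
    def test_standardized_a_matches_twice_correlation_difference(self):
        """At 50,000 pairs per zygosity the fitted standardized A agrees
        with Falconer's 2(rMZ - rDZ) within 2 points."""
        phen = simulate_trait_pairs(0.4, 0.1, 0.5, n_mz=50_000, n_dz=50_000, seed=40)
        data = prepare_pairs(phen, "trait", covariates=[])
        fit = fit_biometric(data, "ACE", seed=0)

        def twin_r(mask):
            a = np.concatenate([data.y1[mask], data.y2[mask]])
            b = np.concatenate([data.y2[mask], data.y1[mask]])
            return np.corrcoef(a, b)[0, 1]

        falconer = 200.0 * (twin_r(data.mz) - twin_r(~data.mz))
        assert fit.standardized["a"] == pytest.approx(falconer, abs=2.0)
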