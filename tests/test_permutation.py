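"""Twin-similarity layer: partial correlations, covariate construction,
and the A/B-reassignment permutation distribution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinbeliefs import (
    interval_overlap,
    partial_correlation,
    permutation_twin_correlation,
)
from twinbeliefs.permutation import (
    PermutationResult,
    build_pair_covariates,
    default_covariate_spec,
)

from conftest import simulate_trait_pairs


class TestCovariateSpec:
    def test_focal_phenotype_not_its_own_control(self):
        for phen in ("memory_score", "vividness_mean", "prior_mean"):
            assert phen not in default_covariate_spec(phen)

    def test_update_controls_for_estimation_error(self):
        assert "estimation_error_mean" in default_covariate_spec("update_mean")
        assert "estimation_error_mean" not in default_covariate_spec("learning_score")

    def test_prior_does_not_control_for_memory(self):
        spec = default_covariate_spec("prior_mean")
        assert "memory_score" not in spec
        assert "vividness_mean" in spec

    def test_build_covariates_antisymmetry(self):
        fa = np.array([3.0, 2.0, 5.0])
        fb = np.array([1.0, 4.0, 5.0])
        v_ab = build_pair_covariates(fa, fb, age=50.0)
        v_ba = build_pair_covariates(fb, fa, age=50.0)
        assert v_ab[0] == v_ba[0] == 50.0  # age unchanged by the swap
        assert np.allclose(v_ab[1:], -v_ba[1:])

    def test_identical_twins_give_zero_differences(self):
        f = np.array([3.0, 2.0])
        assert np.allclose(build_pair_covariates(f, f, age=40.0)[1:], 0.0)


class TestPartialCorrelation:
    def test_reduces_to_plain_correlation_without_covariates(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        assert partial_correlation(x, y) == pytest.approx(stats.pearsonr(x, y).statistic)

    def test_identical_vectors_give_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        z = rng.standard_normal(30)
        assert partial_correlation(x, x, z) == pytest.approx(1.0, abs=1e-10)

    def test_matches_recursive_formula_oracle(self):
        """Fixed 8-point set, one covariate: r_xy.z from the textbook
        recursion (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
        x = np.array([2.0, 4, 3, 6, 5, 8, 7, 9])
        y = np.array([1.0, 3, 2, 5, 4, 7, 8, 9])
        z = np.array([1.0, 2, 1, 3, 2, 4, 3, 5])
        assert partial_correlation(x, y, z) == pytest.approx(0.8232656882456724)

    def test_rank_deficient_covariates_warn(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        z = rng.standard_normal(40)
        Z = np.column_stack([z, 2 * z])
        with pytest.warns(UserWarning, match="rank-deficient"):
            r = partial_correlation(x, y, Z)
        assert -1 <= r <= 1


class TestPermutationDistribution:
    def test_identical_phenotype_within_pairs_gives_r_one(self):
        rng = np.random.default_rng(3)
        n = 30
        vals = rng.standard_normal(2 * n).reshape(n, 2).mean(axis=1)
        phen = pd.DataFrame({
            "subject_id": np.arange(2 * n),
            "pair_id": np.repeat(np.arange(n), 2),
            "zygosity": ["MZ"] * n + ["DZ"] * n,
            "age": np.repeat(rng.uniform(20, 80, n), 2),
            "trait": np.repeat(vals, 2),
        })
        res = permutation_twin_correlation(phen, "trait", covariate_spec=[],
                                           n_perm=200, seed=0, keep_distribution=True)
        for z in ("MZ", "DZ"):
            assert np.allclose(res[z].r_distribution, 1.0)

    def test_exhaustive_enumeration_matches_monte_carlo(self):
        """All 2^10 assignments on 10 pairs vs the 10,000-draw mean."""
        phen = simulate_trait_pairs(0.5, 0.0, 0.5, n_mz=10, n_dz=10, seed=21)
        phen = phen.rename(columns={"trait": "value"})
        exact = permutation_twin_correlation(phen, "value", covariate_spec=[],
                                             exhaustive=True, min_pairs=10)
        mc = permutation_twin_correlation(phen, "value", covariate_spec=[],
                                          n_perm=10_000, seed=5, min_pairs=10)
        for z in ("MZ", "DZ"):
            assert exact[z].n_permutations == 2**10
            assert mc[z].mean_r == pytest.approx(exact[z].mean_r, abs=0.01)

    def test_seed_invariance_of_mean(self):
        phen = simulate_trait_pairs(0.4, 0.0, 0.6, n_mz=150, n_dz=80, seed=22)
        r1 = permutation_twin_correlation(phen, "trait", covariate_spec=[],
                                          n_perm=10_000, seed=1)
        r2 = permutation_twin_correlation(phen, "trait", covariate_spec=[],
                                          n_perm=10_000, seed=2)
        for z in ("MZ", "DZ"):
            assert r1[z].mean_r == pytest.approx(r2[z].mean_r, abs=0.005)

    def test_mean_matches_anova_intraclass_correlation(self):
        """With no covariates the permutation mean converges to the one-way
        ANOVA intraclass correlation on the same pairs."""
        phen = simulate_trait_pairs(0.5, 0.2, 0.3, n_mz=200, n_dz=100, seed=23)
        res = permutation_twin_correlation(phen, "trait", covariate_spec=[],
                                           n_perm=10_000, seed=3)
        for z in ("MZ", "DZ"):
            sub = phen[phen["zygosity"] == z]
            wide = sub.groupby("pair_id")["trait"].apply(list)
            y = np.array(wide.tolist())
            n, k = y.shape
            grand = y.mean()
            msb = k * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
            msw = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (k - 1))
            icc = (msb - msw) / (msb + (k - 1) * msw)
            assert res[z].mean_r == pytest.approx(icc, abs=0.02)

    def test_heritable_trait_mz_exceeds_dz(self):
        phen = simulate_trait_pairs(0.4, 0.0, 0.6, n_mz=400, n_dz=400, seed=24)
        res = permutation_twin_correlation(phen, "trait", covariate_spec=[],
                                           n_perm=2_000, seed=4)
        assert res["MZ"].mean_r > res["DZ"].mean_r
        assert res["MZ"].mean_r == pytest.approx(0.4, abs=0.1)
        assert res["DZ"].mean_r == pytest.approx(0.2, abs=0.1)

    def test_insufficient_pairs_error_names_zygosity(self):
        phen = simulate_trait_pairs(0.4, 0.0, 0.6, n_mz=20, n_dz=3, seed=25)
        with pytest.raises(ValueError, match="DZ"):
            permutation_twin_correlation(phen, "trait", covariate_spec=[], n_perm=10)

    def test_percentiles_bracket_mean(self, small_phenotypes):
        res = permutation_twin_correlation(small_phenotypes, "vividness_mean",
                                           n_perm=500, seed=6)
        for z in ("MZ", "DZ"):
            r = res[z]
            assert r.percentile_2_5 <= r.mean_r <= r.percentile_97_5
            assert -1 <= r.percentile_2_5 and r.percentile_97_5 <= 1


class TestIntervalOverlap:
    def _result(self, lo, hi, mean=None, phen="update_mean", zyg="MZ"):
        return PermutationResult(
            phenotype=phen, zygosity=zyg, n_pairs=100, n_permutations=100,
            mean_r=mean if mean is not None else (lo + hi) / 2,
            percentile_2_5=lo, percentile_97_5=hi, covariates=[], seed=0,
        )

    def test_disjoint_intervals_mz_larger(self):
        verdict = interval_overlap(self._result(0.30, 0.34),
                                   self._result(0.03, 0.16, zyg="DZ"))
        assert verdict["overlap"] is False
        assert verdict["larger"] == "MZ"

    def test_disjoint_learning_intervals(self):
        verdict = interval_overlap(self._result(0.25, 0.28),
                                   self._result(0.13, 0.22, zyg="DZ"))
        assert verdict["overlap"] is False

    def test_identical_intervals_overlap(self):
        verdict = interval_overlap(self._result(0.1, 0.3),
                                   self._result(0.1, 0.3, zyg="DZ"))
        assert verdict["overlap"] is True

    def test_phenotype_mismatch_rejected(self):
        with pytest.raises(ValueError):
            interval_overlap(self._result(0.1, 0.3),
                             self._result(0.1, 0.3, phen="prior_mean", zyg="DZ"))
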