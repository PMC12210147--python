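import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import sdikit as sk
from sdikit.stats import TMap, bonferroni_mask, degree_sdi_correlation, group_glm_tmap, severity_correlation


def make_covars(groups, rng=None):
    rng = rng or np.random.default_rng(0)
    n = len(groups)
    return pd.DataFrame(
        {
            "group": groups,
            "gender": rng.integers(0, 2, n),
            "mean_fd": rng.uniform(0.05, 0.2, n),
            "severity": np.where(np.asarray(groups) == 1, rng.uniform(17, 35, n), np.nan),
        }
    )


class TestGroupGLM:
    def test_toy_data_matches_pooled_two_sample_t(self):
        y = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        covars = pd.DataFrame({"group": [0, 0, 0, 1, 1, 1]})
        tmap = group_glm_tmap(y, covars, covariates=())
        # pooled t of {4,5,6} vs {1,2,3}; positive = patient > control
        assert tmap.t[0] == pytest.approx(3.674, abs=1e-3)
        scipy_t = sps.ttest_ind([4, 5, 6], [1, 2, 3]).statistic
        assert tmap.t[0] == pytest.approx(scipy_t, abs=1e-10)

    def test_reduces_to_pooled_t_without_covariates(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((30, 8))
        groups = np.array([1] * 16 + [0] * 14)
        tmap = group_glm_tmap(y, pd.DataFrame({"group": groups}), covariates=())
        ref = sps.ttest_ind(y[groups == 1], y[groups == 0], equal_var=True)
        np.testing.assert_allclose(tmap.t, ref.statistic, atol=1e-10)
        np.testing.assert_allclose(tmap.p, ref.pvalue, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        covars = make_covars([1] * 20 + [0] * 20, rng)
        y = rng.standard_normal((40, 5))
        tmap = group_glm_tmap(y, covars)
        X = np.column_stack(
            [np.ones(40), covars["group"], covars["gender"], covars["mean_fd"]]
        )
        for r in range(5):
            beta = np.linalg.solve(X.T @ X, X.T @ y[:, r])
            resid = y[:, r] - X @ beta
            sigma2 = resid @ resid / (40 - 4)
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            assert tmap.t[r] == pytest.approx(beta[1] / se, abs=1e-8)

    def test_type_one_error_rate_near_alpha_under_null(self):
        rng = np.random.default_rng(3)
        rejections, total = 0, 0
        for _ in range(20):
            y = rng.standard_normal((40, 50))
            covars = make_covars([1] * 20 + [0] * 20, rng)
            tmap = group_glm_tmap(y, covars)
            rejections += (tmap.p < 0.05).sum()
            total += 50
        rate = rejections / total
        ci = sps.binomtest(rejections, total, 0.05).proportion_ci(0.999)
        assert ci.low < 0.05 < ci.high or abs(rate - 0.05) < 0.02

    def test_collinear_column_named(self):
        covars = make_covars([1] * 10 + [0] * 10)
        covars["gender"] = covars["group"]  # perfectly collinear
        with pytest.raises(ValueError, match="collinear"):
            group_glm_tmap(np.random.default_rng(4).standard_normal((20, 3)), covars)


class TestBonferroni:
    def test_all_ones_empty_mask(self):
        tmap = TMap(t=np.zeros(10), p=np.ones(10), df=5)
        assert not bonferroni_mask(tmap)["mask"].any()

    def test_threshold_arithmetic(self):
        p = np.ones(400)
        p[7] = 0.04 / 400
        tmap = TMap(t=np.ones(400), p=p, df=100)
        mask = bonferroni_mask(tmap, alpha=0.05)
        assert mask["mask"].sum() == 1 and mask["mask"][7]
        assert mask["higher"][7] and not mask["lower"].any()

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(5)
        tmap = TMap(t=rng.standard_normal(100), p=rng.random(100) * 0.01, df=50)
        m_strict = bonferroni_mask(tmap, alpha=0.01)["mask"]
        m_loose = bonferroni_mask(tmap, alpha=0.05)["mask"]
        assert np.all(~m_strict | m_loose)


class TestSeverityCorrelation:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(6)
        covars = make_covars([1] * 10 + [0] * 5, rng)
        y = rng.standard_normal((15, 4))
        y[:10, 2] = covars["severity"][:10]
        out = severity_correlation(y, covars, regions=np.array([2]))
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_one_over_n_threshold_recorded(self):
        rng = np.random.default_rng(7)
        covars = make_covars([1] * 30 + [0] * 10, rng)
        y = rng.standard_normal((40, 30))
        out = severity_correlation(y, covars, regions=np.arange(30))
        assert out.attrs["p_max"] == pytest.approx(1 / 30)
        assert out["significant"].equals(out["p"] < 1 / 30)

    def test_too_few_patients_rejected(self):
        covars = make_covars([1, 1, 0, 0, 0])
        covars.loc[1, "severity"] = np.nan
        with pytest.raises(ValueError, match="at least 3"):
            severity_correlation(np.zeros((5, 2)), covars, regions=np.array([0]))

    def test_linked_cohort_recovers_negative_correlation(self):
        from sdikit.pipeline import cohort_sdi_maps

        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            p = sk.gen_parcellation(60, seed=seed)
            spec = sk.CohortSpec(
                n_regions=60, n_timepoints=200, n_per_group=(40, 10),
                effect_regions=(5, 15, 25), effect_size=2.0,
                severity_link_regions=(5, 15, 25), severity_rho=-0.4, seed=seed,
            )
            cohort = sk.gen_cohort(spec, p)
            maps, _, _ = cohort_sdi_maps(cohort, basis_mode="pooled")
            covars = pd.DataFrame(
                {
                    "group": cohort.group, "gender": cohort.gender,
                    "mean_fd": cohort.mean_fd, "severity": cohort.severity,
                }
            )
            pat = cohort.group == 1
            linked_mean = maps[pat][:, [4, 14, 24]].mean(axis=1)
            r = np.corrcoef(cohort.severity[pat], linked_mean)[0, 1]
            # per-region table should agree in overall direction
            out = severity_correlation(maps, covars, regions=np.array([4, 14, 24]))
            if r < 0 and (out["r"] < 0).sum() >= 2:
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestDegreeSDICorrelation:
    def test_perfect_negative(self):
        degree = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = degree_sdi_correlation(degree, -degree)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(8)
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        r, _ = degree_sdi_correlation(a, b)
        am, bm = a - a.mean(), b - b.mean()
        oracle = np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_independent_vectors_weakly_correlated(self):
        rng = np.random.default_rng(9)
        small = sum(
            abs(degree_sdi_correlation(rng.standard_normal(400), rng.standard_normal(400))[0]) < 0.15
            for _ in range(20)
        )
        assert small >= 18

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            degree_sdi_correlation(np.ones(10), np.arange(10.0))
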