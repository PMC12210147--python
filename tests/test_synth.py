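import numpy as np
import pytest
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components

import sdikit as sk
from sdikit import gsp
from sdikit.pipeline import cohort_sdi_maps


class TestParcellation:
    def test_unit_norm_distinct_centroids(self):
        p = sk.gen_parcellation(8, seed=1)
        np.testing.assert_allclose(np.linalg.norm(p.centroid, axis=1), 1.0, atol=1e-9)
        assert len(np.unique(p.centroid.round(12), axis=0)) == 8

    def test_hemisphere_balance_at_400(self):
        p = sk.gen_parcellation(400, seed=1)
        n_left = (p.hemisphere == "L").sum()
        assert abs(n_left - 200) <= 20

    def test_deterministic(self):
        a, b = sk.gen_parcellation(50, seed=9), sk.gen_parcellation(50, seed=9)
        np.testing.assert_array_equal(a.centroid, b.centroid)
        np.testing.assert_array_equal(a.volume, b.volume)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            sk.gen_parcellation(7)


class TestStructuralConnectome:
    def test_full_density_complete_graph(self):
        p = sk.gen_parcellation(12, seed=2)
        sc = sk.gen_structural_connectome(p, density=1.0, seed=2)
        off = sc[~np.eye(12, dtype=bool)]
        assert np.all(off > 0)

    def test_symmetry_exact(self):
        p = sk.gen_parcellation(30, seed=3)
        sc = sk.gen_structural_connectome(p, density=0.15, seed=3)
        np.testing.assert_array_equal(sc, sc.T)
        assert np.all(np.diag(sc) == 0)

    def test_connected_at_low_density(self):
        p = sk.gen_parcellation(50, seed=7)
        sc = sk.gen_structural_connectome(p, density=0.05, seed=7)
        n_comp, _ = connected_components(sc > 0, directed=False)
        assert n_comp == 1

    def test_deterministic(self):
        p = sk.gen_parcellation(20, seed=4)
        a = sk.gen_structural_connectome(p, density=0.3, seed=5)
        b = sk.gen_structural_connectome(p, density=0.3, seed=5)
        np.testing.assert_array_equal(a, b)


class TestSubjectTimeseries:
    def test_zero_high_gain_gives_zero_sdi(self, basis60):
        ts = sk.gen_subject_timeseries(basis60, 1.0, 0.0, 200, seed=1)
        coeffs = gsp.gft(ts, basis60)
        x_c, x_d = gsp.split_filter(coeffs, basis60.cutoff)
        assert np.abs(gsp.sdi(x_c, x_d)).max() < 1e-10

    def test_sdi_invariant_to_uniform_gain_scaling(self, basis60):
        maps = []
        for scale in (1.0, 5.0):
            ts = sk.gen_subject_timeseries(basis60, scale, scale, 200, seed=2)
            x_c, x_d = gsp.split_filter(gsp.gft(ts, basis60), basis60.cutoff)
            maps.append(gsp.sdi(x_c, x_d))
        np.testing.assert_allclose(maps[0], maps[1], atol=1e-10)

    def test_mean_sdi_increases_when_high_gain_doubled(self, basis60):
        """Monte-Carlo ground-truth monotonicity over a seed ladder."""
        boosted = np.arange(10)
        deltas = []
        for rep in range(50):
            base = sk.gen_subject_timeseries(basis60, 1.0, 1.0, 500, seed=1000 + rep)
            high = np.ones(60)
            high[boosted] = 2.0
            ts = sk.gen_subject_timeseries(basis60, 1.0, high, 500, seed=1000 + rep)
            for x, store in ((base, 0), (ts, 1)):
                x_c, x_d = gsp.split_filter(gsp.gft(x, basis60), basis60.cutoff)
                s = gsp.sdi(x_c, x_d)[boosted].mean()
                deltas.append(s if store else -s)
        assert np.sum(deltas) > 0  # boosted minus baseline, pooled over reps
        paired = np.array(deltas).reshape(50, 2).sum(axis=1)
        assert (paired > 0).mean() > 0.9

    def test_nonpositive_low_gain_rejected(self, basis60):
        with pytest.raises(ValueError, match="low_gain"):
            sk.gen_subject_timeseries(basis60, 0.0, 1.0, 50, seed=0)


class TestCohort:
    def test_null_effect_not_significant(self):
        """effect_size=1 plants nothing: Bonferroni mask stays empty in most seeds."""
        import pandas as pd

        clean = 0
        n_seeds = 10
        for seed in range(n_seeds):
            p = sk.gen_parcellation(60, seed=seed)
            spec = sk.CohortSpec(
                n_regions=60, n_timepoints=200, n_per_group=(20, 20),
                effect_regions=(1, 5, 9), effect_size=1.0, seed=seed,
            )
            cohort = sk.gen_cohort(spec, p)
            maps, _, _ = cohort_sdi_maps(cohort, basis_mode="pooled")
            covars = pd.DataFrame(
                {"group": cohort.group, "gender": cohort.gender, "mean_fd": cohort.mean_fd}
            )
            tmap = sk.group_glm_tmap(maps, covars)
            if not sk.bonferroni_mask(tmap)["mask"].any():
                clean += 1
        assert clean >= 0.9 * n_seeds

    def test_null_severity_correlation_small(self):
        p = sk.gen_parcellation(60, seed=5)
        spec = sk.CohortSpec(
            n_regions=60, n_timepoints=150, n_per_group=(60, 10),
            severity_link_regions=(1, 2, 3), severity_rho=0.0, seed=5,
        )
        cohort = sk.gen_cohort(spec, p)
        maps, _, _ = cohort_sdi_maps(cohort, basis_mode="pooled")
        pat = cohort.group == 1
        linked_sdi = maps[pat][:, :3].mean(axis=1)
        r = np.corrcoef(cohort.severity[pat], linked_sdi)[0, 1]
        assert abs(r) < 0.2  # pure sampling error at n=60 patients

    def test_covariate_imbalance_is_mild(self):
        p = sk.gen_parcellation(60, seed=6)
        spec = sk.CohortSpec(n_regions=60, n_timepoints=100, n_per_group=(200, 200), seed=6)
        cohort = sk.gen_cohort(spec, p)
        f_pat = cohort.gender[cohort.group == 1].mean()
        f_con = cohort.gender[cohort.group == 0].mean()
        assert 0 < f_pat - f_con < 0.25

    def test_invalid_severity_rho_rejected(self):
        with pytest.raises(ValueError, match="severity_rho"):
            sk.CohortSpec(severity_rho=1.0).validate()

    def test_effect_regions_must_be_region_ids(self):
        with pytest.raises(ValueError, match="effect_regions"):
            sk.CohortSpec(n_regions=10, effect_regions=(11,)).validate()


class TestExpression:
    def test_all_planted_no_noise_fully_explains_map(self, parcellation100):
        planted = sk.gen_annotation_map(parcellation100, smoothness=0.5, seed=1)
        X, genes, _ = sk.gen_expression(
            parcellation100, n_genes=5, planted=planted, n_planted=5, noise_sd=0.0, seed=2
        )
        model = sk.pls_fit(X, planted, n_components=1, genes=genes)
        assert model.explained_variance[0] == pytest.approx(100.0, abs=1e-6)

    def test_columns_standardized(self, parcellation100):
        X, _, _ = sk.gen_expression(parcellation100, n_genes=20, noise_sd=1.0, seed=3)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(X.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_negative_noise_rejected(self, parcellation100):
        with pytest.raises(ValueError, match="noise_sd"):
            sk.gen_expression(parcellation100, n_genes=5, noise_sd=-1.0)


class TestAnnotationMap:
    def test_linked_map_approaches_target(self, parcellation100):
        target = sk.gen_annotation_map(parcellation100, smoothness=0.5, seed=4)
        m = sk.gen_annotation_map(
            parcellation100, smoothness=0.5, link=(target, 1 - 1e-9), seed=5
        )
        assert sps.spearmanr(m, target).statistic > 0.999

    def test_unlinked_maps_weakly_correlated(self, parcellation100):
        rhos = []
        for seed in range(20):
            a = sk.gen_annotation_map(parcellation100, smoothness=0.5, seed=seed)
            b = sk.gen_annotation_map(parcellation100, smoothness=0.5, seed=100 + seed)
            rhos.append(abs(sps.spearmanr(a, b).statistic))
        assert np.median(rhos) < 0.2

    def test_deterministic(self, parcellation100):
        a = sk.gen_annotation_map(parcellation100, smoothness=0.4, seed=6)
        b = sk.gen_annotation_map(parcellation100, smoothness=0.4, seed=6)
        np.testing.assert_array_equal(a, b)

    def test_rho_out_of_range_rejected(self, parcellation100):
        target = np.random.default_rng(0).standard_normal(100)
        with pytest.raises(ValueError, match="correlation"):
            sk.gen_annotation_map(parcellation100, link=(target, 1.0), seed=0)
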