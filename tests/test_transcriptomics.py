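import numpy as np
import pandas as pd
import pytest

import sdikit as sk
from sdikit import transcriptomics as tx


@pytest.fixture(scope="module")
def planted_setup(parcellation100):
    """Expression with 20 planted genes (signs split half/half) on a smooth map."""
    planted_map = sk.gen_annotation_map(parcellation100, smoothness=0.6, seed=21)
    loadings = np.concatenate([np.full(10, 1.0), np.full(10, -1.0)])
    X, genes, _ = sk.gen_expression(
        parcellation100, n_genes=200, planted=planted_map, n_planted=20,
        noise_sd=0.5, seed=22, planted_loadings=loadings, length_scale=0.05,
    )
    return X, genes, planted_map


class TestPLSFit:
    def test_exact_linear_combination_fully_explained(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = 2 * X[:, 0] - X[:, 1] + 0.5 * X[:, 2]
        model = tx.pls_fit(X, y, n_components=3)
        assert model.explained_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_univariate_collapse_to_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((40, 1))
        y = rng.standard_normal(40)
        model = tx.pls_fit(x, y, n_components=1)
        r = np.corrcoef(model.scores[:, 0], y)[0, 1]
        expected = abs(np.corrcoef(x[:, 0], y)[0, 1])
        assert abs(r) == pytest.approx(expected, abs=1e-10)

    def test_matches_sklearn_oracle(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 50))
        y = rng.standard_normal(100)
        model = tx.pls_fit(X, y, n_components=5)
        ref = PLSRegression(n_components=5, scale=False).fit(X - X.mean(0), y - y.mean())
        yc = y - y.mean()
        ss = yc @ yc
        prev, ev = 0.0, []
        for k in range(5):
            Tk = ref.x_scores_[:, : k + 1]
            coef, *_ = np.linalg.lstsq(Tk, yc, rcond=None)
            r2 = 1 - np.sum((yc - Tk @ coef) ** 2) / ss
            ev.append(100 * (r2 - prev))
            prev = r2
        np.testing.assert_allclose(model.explained_variance, ev, atol=1e-8)

    def test_weights_unit_norm_and_ev_bounds(self):
        rng = np.random.default_rng(3)
        model = tx.pls_fit(rng.standard_normal((60, 30)), rng.standard_normal(60), 4)
        np.testing.assert_allclose(np.linalg.norm(model.weights, axis=0), 1.0, atol=1e-10)
        assert np.all(model.explained_variance >= -1e-10)
        assert model.explained_variance.sum() <= 100 + 1e-8

    def test_sign_flip_of_response_flips_weights(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 20))
        y = rng.standard_normal(50)
        m1 = tx.pls_fit(X, y, 3)
        m2 = tx.pls_fit(X, -y, 3)
        np.testing.assert_allclose(m1.weights, -m2.weights, atol=1e-10)
        np.testing.assert_allclose(m1.explained_variance, m2.explained_variance, atol=1e-10)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            tx.pls_fit(np.random.default_rng(5).standard_normal((20, 5)), np.ones(20), 1)


class TestComponentSpinTest:
    def test_planted_signal_significant(self, parcellation100, planted_setup):
        X, genes, planted_map = planted_setup
        null = sk.spin_rotations(parcellation100, 199, seed=23)
        p = tx.component_spin_test(X, planted_map, null, n_components=2)
        assert p[0] <= 0.05

    def test_null_calibration(self, parcellation100):
        null = sk.spin_rotations(parcellation100, 99, seed=24)
        rejections = 0
        for seed in range(10):
            X, _, _ = sk.gen_expression(
                parcellation100, n_genes=50, noise_sd=1.0, seed=700 + seed, length_scale=0.05
            )
            y = np.random.default_rng(800 + seed).standard_normal(100)
            p = tx.component_spin_test(X, y, null, n_components=1)
            rejections += p[0] < 0.1
        assert rejections <= 3

    def test_p_bounded_below(self, parcellation100, planted_setup):
        X, _, planted_map = planted_setup
        null = sk.spin_rotations(parcellation100, 19, seed=25)
        p = tx.component_spin_test(X, planted_map, null, n_components=1)
        assert np.all(p >= 1 / 20)


class TestBootstrapGeneZ:
    def test_planted_genes_recovered_with_correct_signs(self, planted_setup):
        X, genes, planted_map = planted_setup
        table = tx.bootstrap_gene_z(X, planted_map, genes, component=0, n_boot=300, seed=26)
        z = table["z"].to_numpy()
        # orientation of the component is arbitrary; align to the positive block
        if z[:10].mean() < 0:
            z = -z
        correct = (z[:10] > tx.Z_CRITICAL).sum() + (z[10:20] < -tx.Z_CRITICAL).sum()
        assert correct >= 18

    def test_noise_gene_false_positive_rate(self, planted_setup):
        X, genes, planted_map = planted_setup
        table = tx.bootstrap_gene_z(X, planted_map, genes, component=0, n_boot=300, seed=27)
        noise_z = table["z"].to_numpy()[20:]
        assert (np.abs(noise_z) > tx.Z_CRITICAL).mean() <= 0.05

    def test_z_stable_in_n_boot(self, planted_setup):
        X, genes, planted_map = planted_setup
        t1 = tx.bootstrap_gene_z(X, planted_map, genes, component=0, n_boot=200, seed=28)
        t2 = tx.bootstrap_gene_z(X, planted_map, genes, component=0, n_boot=400, seed=29)
        rel = np.abs(t2["z"] - t1["z"]) / np.maximum(np.abs(t1["z"]), 1e-9)
        assert np.median(rel) < 0.10

    def test_list_membership_matches_threshold(self, planted_setup):
        X, genes, planted_map = planted_setup
        table = tx.bootstrap_gene_z(X, planted_map, genes, component=0, n_boot=150, seed=30)
        assert ((table["z"] > 2.58) == (table["list"] == "PLS1+")).all()
        assert ((table["z"] < -2.58) == (table["list"] == "PLS1-")).all()


class TestGeneSetComparison:
    @staticmethod
    def _table(weights, prefix="G"):
        genes = [f"{prefix}{k}" for k in range(len(weights))]
        return pd.DataFrame({"gene": genes, "weight": weights}), genes

    def test_identical_sets_p_one(self):
        table, genes = self._table(np.random.default_rng(6).standard_normal(20))
        out = tx.gene_set_weight_comparison(
            table, {"a": genes[:10], "b": genes[:10]}, n_perm=99, seed=7
        )
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_shifted_populations_detected(self):
        rng = np.random.default_rng(8)
        w = np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30)])
        table, genes = self._table(w)
        out = tx.gene_set_weight_comparison(
            table, {"low": genes[:30], "high": genes[30:]}, n_perm=199, seed=9
        )
        assert out["p"].iloc[0] <= 0.05

    def test_two_sided_symmetry_in_set_order(self):
        rng = np.random.default_rng(10)
        table, genes = self._table(rng.standard_normal(40))
        sets_ab = {"a": genes[:20], "b": genes[20:]}
        sets_ba = {"b": genes[20:], "a": genes[:20]}
        p1 = tx.gene_set_weight_comparison(table, sets_ab, n_perm=199, seed=11)["p"].iloc[0]
        p2 = tx.gene_set_weight_comparison(table, sets_ba, n_perm=199, seed=11)["p"].iloc[0]
        assert p1 == pytest.approx(p2, abs=0.12)  # same distribution, mirrored draws

    def test_empty_intersection_named(self):
        table, _ = self._table(np.zeros(5))
        with pytest.raises(ValueError, match="missing_set"):
            tx.gene_set_weight_comparison(table, {"missing_set": ["NOPE"]}, n_perm=99)
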