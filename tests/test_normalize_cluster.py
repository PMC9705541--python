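import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from il2tome import normalize_cluster as nc
from il2tome.config import SimulationConfig
from il2tome import synthetic_data as syn
from il2tome import pipeline
from conftest import make_toy_dataset


class TestLogNormalize:
    def test_known_value(self):
        # count 10 in a cell totalling 10,000 -> ln(1 + 1e4 * 10/1e4) = ln(11)
        counts = np.zeros((1, 3))
        counts[0] = [10, 9990, 0]
        out = nc.lognormalize_rna(counts)
        assert out[0, 0] == pytest.approx(np.log(11.0), abs=1e-12)
        assert out[0, 2] == 0.0

    def test_within_cell_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 20, size=(5, 8)).astype(float)
        np.testing.assert_allclose(
            nc.lognormalize_rna(counts), nc.lognormalize_rna(2 * counts), atol=1e-12
        )

    def test_zero_total_cell_is_error(self):
        counts = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="zero total"):
            nc.lognormalize_rna(counts)


class TestCLR:
    def test_equal_counts_give_zero(self):
        out = nc.clr_normalize_protein(np.full((2, 5), 7.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=20))
    def test_row_sums_are_zero(self, row):
        out = nc.clr_normalize_protein(np.array([row], dtype=float))
        assert abs(out.sum()) < 1e-6

    def test_scale_invariance_in_small_pseudo_limit(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 50, size=(4, 6)).astype(float)
        a = nc.clr_normalize_protein(counts, pseudo=1e-9)
        b = nc.clr_normalize_protein(10 * counts, pseudo=1e-9)
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_nonpositive_pseudo_rejected(self):
        with pytest.raises(ValueError):
            nc.clr_normalize_protein(np.ones((1, 2)), pseudo=0.0)


class TestScaleRegress:
    def test_orthogonal_covariate_reduces_to_zscore(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(200, 3))
        c = np.tile([1.0, -1.0], 100)
        y = y - np.outer(c, c @ y) / (c @ c)  # make features exactly orthogonal
        out = nc.scale_regress(y, pd.DataFrame({"c": c}))
        centred = y - y.mean(0)
        z = centred / centred.std(0, ddof=1)
        np.testing.assert_allclose(out, z, atol=1e-8)

    def test_feature_linear_in_covariate_becomes_zero(self):
        x = np.linspace(0, 1, 50)
        y = np.column_stack([3 * x + 1, np.random.default_rng(3).normal(size=50)])
        out = nc.scale_regress(y, pd.DataFrame({"x": x}))
        np.testing.assert_allclose(out[:, 0], 0.0, atol=1e-8)

    def test_residuals_match_lstsq_oracle_and_unit_sd(self):
        rng = np.random.default_rng(4)
        n = 120
        cov = pd.DataFrame({
            "a": rng.normal(size=n),
            "participant": rng.choice(["p1", "p2", "p3"], size=n),
        })
        y = rng.normal(size=(n, 5)) + cov["a"].to_numpy()[:, None]
        out = nc.scale_regress(y, cov)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-3)
        # oracle: explicit OLS residuals, column by column
        X = np.column_stack([
            np.ones(n), cov["a"],
            (cov["participant"] == "p2").astype(float),
            (cov["participant"] == "p3").astype(float),
        ])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        resid -= resid.mean(0)
        expected = resid / resid.std(0, ddof=1)
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_collinear_covariates_dropped_not_fatal(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        cov = pd.DataFrame({"a": x, "b": 2 * x})
        out = nc.scale_regress(rng.normal(size=(40, 2)), cov)
        assert np.isfinite(out).all()


class TestClustering:
    @staticmethod
    def _blobs(seed=0, n_per=300, sep=12.0):
        rng = np.random.default_rng(seed)
        centers = np.array([[0, 0], [sep, 0], [0, sep]], dtype=float)
        X = np.vstack([rng.normal(c, 1.0, size=(n_per, 2)) for c in centers])
        X = np.hstack([X, rng.normal(size=(3 * n_per, 8))])  # noise dims
        labels = np.repeat([0, 1, 2], n_per)
        return X, labels

    def test_three_separated_blobs_give_three_clusters(self):
        X, truth = self._blobs()
        out = nc.embed_and_cluster(X, None, n_pcs=5, resolution=0.5, seed=0)
        assert len(set(out.labels)) == 3
        assert adjusted_rand_score(truth, out.labels) > 0.99
        # independent oracle: k-means at k=3 agrees
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=3, n_init=5, random_state=0).fit_predict(X[:, :2])
        assert adjusted_rand_score(km, out.labels) > 0.99

    def test_nine_cell_satellite_is_dissolved(self):
        X, _ = self._blobs(n_per=300)
        satellite = np.random.default_rng(7).normal([40, 40], 0.1, size=(9, 2))
        satellite = np.hstack([satellite, np.zeros((9, 8))])
        out = nc.embed_and_cluster(
            np.vstack([X, satellite]), None, n_pcs=5, resolution=0.5, seed=0
        )
        # the 9 satellite cells are reassigned, so only 3 clusters survive
        assert len(set(out.labels)) == 3

    def test_same_seed_identical_labels(self):
        X, _ = self._blobs(seed=1)
        a = nc.embed_and_cluster(X, None, n_pcs=5, resolution=0.5, seed=11)
        b = nc.embed_and_cluster(X, None, n_pcs=5, resolution=0.5, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_too_few_cells_is_error(self):
        with pytest.raises(ValueError, match="cells"):
            nc.embed_and_cluster(np.zeros((5, 20)), None, n_pcs=10)


class TestAnnotation:
    def test_rules_label_generator_clusters(self, dataset_small):
        # use the ground-truth clusters as "clustering" and check the marker
        # rules recover the planted identities
        truth_clusters = dataset_small.cell_meta["true_cluster"].to_numpy()
        names = sorted(set(truth_clusters))
        labels = np.array([names.index(c) for c in truth_clusters])
        ann = nc.annotate_clusters(dataset_small, labels)
        by_name = {names[i]: ann.loc[i, "label"] for i in ann.index}
        assert by_name["naive_treg"] == "naive Treg"
        assert by_name["memory_treg"] == "memory Treg"
        assert by_name["teff_cd25"] == "CD25+ Teff"
        assert by_name["mait"] == "MAIT"
        assert by_name["vd2"] == "Vg9Vd2"
        assert by_name["bcell_contam"] == "B cell contamination"
        assert by_name["dn_t"] == "DN T"
        assert by_name["cd56dim"].startswith("CD56dim")
        assert by_name["cd56br"].startswith("CD56br")

    def test_cycling_label_from_module_scores(self, dataset_small):
        truth_clusters = dataset_small.cell_meta["true_cluster"].to_numpy()
        names = sorted(set(truth_clusters))
        labels = np.array([names.index(c) for c in truth_clusters])
        lognorm = nc.lognormalize_rna(dataset_small.rna_counts)
        scores = nc.score_cell_modules(lognorm, dataset_small.gene_names, seed=0)
        ann = nc.annotate_clusters(dataset_small, labels, module_scores=scores)
        assert ann.loc[names.index("cycling"), "label"] == "cycling"

    def test_rule_with_absent_feature_is_error(self, dataset_small):
        rules = [nc.AnnotationRule("x", "other", {"NOT_A_GENE": "+"})]
        with pytest.raises(KeyError, match="NOT_A_GENE"):
            nc.annotate_clusters(dataset_small, np.zeros(dataset_small.n_cells, int),
                                 rules=rules)


class TestModuleScores:
    def test_zero_expression_scores_zero(self, dataset_small):
        x = np.zeros((10, len(dataset_small.gene_names)))
        s = nc.score_cell_modules(x, dataset_small.gene_names, seed=0)
        np.testing.assert_allclose(s, 0.0)

    def test_constant_module_minus_zero_controls(self, dataset_small):
        genes = dataset_small.gene_names
        x = np.zeros((4, len(genes)))
        for g in nc.PROLIFERATION_GENES:
            x[:, genes.index(g)] = 2.5
        s = nc.score_cell_modules(x, genes, seed=0)
        np.testing.assert_allclose(s, 2.5)

    def test_control_seed_stability_on_cycling_cells(self, dataset_small):
        lognorm = nc.lognormalize_rna(dataset_small.rna_counts)
        cyc = dataset_small.cell_meta["true_cycling"].to_numpy()
        assert cyc.sum() >= 5
        means = [
            nc.score_cell_modules(lognorm[cyc], dataset_small.gene_names, seed=s).mean()
            for s in range(20)
        ]
        assert np.std(means) <= 0.15 * abs(np.mean(means))

    def test_missing_module_gene_is_error(self):
        with pytest.raises(KeyError, match="missing"):
            nc.score_cell_modules(np.zeros((2, 3)), ["A", "B", "C"],
                                  module_genes=["MKI67"], n_control=1)


class TestFoxp3Classifier:
    def test_rule_scoped_to_tconv_gate(self, dataset_small):
        out = nc.classify_foxp3_positive(dataset_small)
        gate = dataset_small.cell_meta["gate"]
        foxp3 = dataset_small.rna_counts[
            :, dataset_small.gene_index("FOXP3")
        ].toarray().ravel()
        assert out[gate != "Tconv"].isna().all()
        tconv = gate == "Tconv"
        np.testing.assert_array_equal(
            out[tconv].to_numpy(dtype=bool), foxp3[tconv.to_numpy()] >= 1
        )


class TestClusterRecoveryOnSyntheticTruth:
    def test_five_populations_ari(self):
        sim = SimulationConfig(cells_per_visit=700, n_participants=1)
        truth = syn.five_population_truth(sim)
        ds, _ = syn.generate_dataset(truth, sim, seed=3)
        _, _, rna_scaled, prot_scaled = pipeline.normalize_dataset(ds)
        out = nc.embed_and_cluster(rna_scaled, prot_scaled, resolution=0.5, seed=0)
        ari = adjusted_rand_score(ds.cell_meta["true_cluster"], out.labels)
        assert ari >= 0.9
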