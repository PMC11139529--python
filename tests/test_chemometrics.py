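import numpy as np
import pandas as pd
import pytest
from herbqc import datasets
from herbqc.chemometrics import (
    DataMatrix,
    autoscale,
    composite_score,
    hcluster,
    oplsda,
    pca,
    permutation_test,
    ttest,
    vip,
)
from herbqc.simulate import gen_batches

from conftest import two_group_config


def _random_matrix(seed, n=10, p=4):
    rng = np.random.default_rng(seed)
    return DataMatrix(
        sample_ids=[f"S{i}" for i in range(n)],
        variable_names=[f"V{j}" for j in range(p)],
        values=rng.normal(size=(n, p)),
    )


class TestAutoscale:
    def test_simple_column(self):
        m = DataMatrix(["a", "b", "c"], ["x"], np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(autoscale(m).values.ravel(), [-1, 0, 1])

    def test_idempotent(self):
        m = _random_matrix(0)
        once = autoscale(m)
        twice = autoscale(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_zero_mean_unit_sd(self):
        scaled = autoscale(_random_matrix(1)).values
        assert np.abs(scaled.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(scaled.std(axis=0, ddof=1), 1.0)

    def test_constant_column_rejected(self):
        m = DataMatrix(["a", "b", "c"], ["x", "y"], np.array([[1, 5], [2, 5], [3, 5.0]]))
        with pytest.raises(ValueError):
            autoscale(m)


class TestHCluster:
    def test_identical_rows_merge_first(self):
        m = DataMatrix(
            ["a", "b", "c"],
            ["x", "y"],
            np.array([[1.0, 1.0], [1.0, 1.0], [9.0, 9.0]]),
        )
        tree = hcluster(m)
        assert tree.heights[0] == 0.0
        cut = tree.cut(2)
        assert cut["a"] == cut["b"] != cut["c"]

    def test_collinear_points(self):
        # squared-distance matrix by hand: d(0,1)=1, d(1,10)=81, d(0,10)=100
        m = DataMatrix(["p0", "p1", "p10"], ["x"], np.array([[0.0], [1.0], [10.0]]))
        tree = hcluster(m)
        assert tree.heights[0] == pytest.approx(1.0)
        cut = tree.cut(2)
        assert cut["p0"] == cut["p1"] != cut["p10"]

    def test_recovers_planted_blobs(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, size=(7, 3))
        b = rng.normal(8.0, 1.0, size=(7, 3))
        m = DataMatrix(
            [f"S{i}" for i in range(14)],
            ["x", "y", "z"],
            np.vstack([a, b]),
        )
        cut = hcluster(m).cut(2)
        labels = np.array([cut[f"S{i}"] for i in range(14)])
        assert len(set(labels[:7])) == 1
        assert len(set(labels[7:])) == 1
        assert labels[0] != labels[7]

    def test_cut_extremes(self):
        m = _random_matrix(3, n=6)
        tree = hcluster(m)
        assert len(set(tree.cut(1).values())) == 1
        assert len(set(tree.cut(6).values())) == 6

    def test_single_sample_rejected(self):
        m = DataMatrix(["a"], ["x", "y"], np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            hcluster(m)

    def test_sample_order_invariance(self):
        m = _random_matrix(4, n=8)
        perm = np.random.default_rng(0).permutation(8)
        m2 = DataMatrix(
            [m.sample_ids[i] for i in perm], m.variable_names, m.values[perm]
        )
        cut1 = hcluster(m).cut(3)
        cut2 = hcluster(m2).cut(3)
        # same partition of sample ids, labels possibly permuted
        groups1 = {}
        groups2 = {}
        for s in m.sample_ids:
            groups1.setdefault(cut1[s], set()).add(s)
            groups2.setdefault(cut2[s], set()).add(s)
        assert set(map(frozenset, groups1.values())) == set(
            map(frozenset, groups2.values())
        )


class TestPCA:
    def test_eigenvalue_conservation(self):
        model = pca(_random_matrix(5, n=12, p=4))
        assert model.eigenvalues.sum() == pytest.approx(4.0)
        assert model.contribution_pct.sum() == pytest.approx(100.0)
        assert model.cumulative_pct[-1] == pytest.approx(100.0)

    def test_independent_columns_near_unit_eigenvalues(self):
        model = pca(_random_matrix(6, n=4000, p=4))
        np.testing.assert_allclose(model.eigenvalues, 1.0, atol=0.15)

    def test_against_brute_force_eigensolver(self):
        m = _random_matrix(7, n=6, p=4)
        model = pca(m)
        corr = np.corrcoef(m.values, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(model.eigenvalues, eigvals, atol=1e-8)
        # loadings reproduce the correlation matrix restricted to all comps
        z = autoscale(m).values
        recon = model.scores @ model.loadings.T
        # projection residual must be orthogonal to retained loadings
        resid = z - recon
        assert np.abs(resid @ model.loadings).max() < 1e-8

    def test_sign_convention(self):
        model = pca(_random_matrix(8, n=20, p=5))
        for j in range(model.retained):
            col = model.loadings[:, j]
            assert col[np.abs(col).argmax()] > 0

    def test_scores_are_standardized_projections(self):
        m = _random_matrix(9, n=30, p=4)
        model = pca(m)
        z = autoscale(m).values
        np.testing.assert_allclose(
            model.scores, z @ model.score_coefficients, atol=1e-12
        )

    def test_rank_deficient_drops_zero_eigenvalues(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(10, 2))
        values = np.column_stack([base, base[:, 0] + base[:, 1]])
        m = DataMatrix([f"S{i}" for i in range(10)], ["a", "b", "c"], values)
        model = pca(m)
        assert len(model.eigenvalues) == 2
        assert model.eigenvalues.sum() == pytest.approx(3.0)

    def test_sample_order_invariance(self):
        m = _random_matrix(11, n=12, p=4)
        perm = np.random.default_rng(1).permutation(12)
        m2 = DataMatrix(
            [m.sample_ids[i] for i in perm], m.variable_names, m.values[perm]
        )
        s1 = pca(m).score_frame()
        s2 = pca(m2).score_frame()
        np.testing.assert_allclose(
            s1.loc[m.sample_ids, "composite_score"],
            s2.loc[m.sample_ids, "composite_score"],
            atol=1e-10,
        )


class TestCompositeScore:
    CONTRIBUTIONS = datasets.load_pca_contributions()

    @pytest.mark.parametrize(
        "scores,expected", [((3.26, 2.01), 2.78), ((-0.98, 0.17), -0.54)]
    )
    def test_published_rows(self, scores, expected):
        composite, _ = composite_score([scores], self.CONTRIBUTIONS)
        assert round(float(composite[0]), 2) == expected

    def test_equal_scores_pass_through(self):
        composite, _ = composite_score([(1.7, 1.7)], self.CONTRIBUTIONS)
        assert float(composite[0]) == pytest.approx(1.7)

    def test_published_rank_extremes(self):
        scores = datasets.load_pca_component_scores()
        composite, ranks = composite_score(
            scores.to_numpy(), self.CONTRIBUTIONS
        )
        by_batch = dict(zip(scores.index, ranks))
        assert by_batch["S4"] == 1
        assert by_batch["S14"] == 14

    def test_exact_ties_get_averaged_rank(self):
        composite, ranks = composite_score(
            [(1.0, 1.0), (2.0, 2.0), (1.0, 1.0)], [60.0, 40.0]
        )
        assert ranks.tolist() == [2.5, 1.0, 2.5]

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=(20, 3))
        weights = [50.0, 30.0, 20.0]
        composite, _ = composite_score(scores, weights)
        assert np.all(composite <= scores.max(axis=1) + 1e-12)
        assert np.all(composite >= scores.min(axis=1) - 1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            composite_score([(1.0, 2.0)], [50.0, 30.0, 20.0])

    def test_nonpositive_contribution(self):
        with pytest.raises(ValueError):
            composite_score([(1.0, 2.0)], [50.0, -1.0])


class TestOPLSDA:
    def test_perfect_predictor_column(self):
        rng = np.random.default_rng(13)
        y = np.array([-1.0] * 7 + [1.0] * 7)
        noise = rng.normal(size=(14, 3))
        # orthogonalize the noise columns against y so the predictive
        # direction carries the class information exactly
        noise -= np.outer(y, y @ noise) / (y @ y)
        m = DataMatrix(
            [f"S{i}" for i in range(14)], ["y", "a", "b", "c"],
            np.column_stack([y, noise]),
        )
        model = oplsda(autoscale(m), y)
        assert model.r2y == pytest.approx(1.0, abs=1e-9)

    def test_planted_groups_good_q2(self, planted_matrix):
        scaled, labels = planted_matrix
        model = oplsda(scaled, labels, seed=1)
        assert model.q2 > 0.5
        assert model.r2y >= model.q2

    def test_permuted_labels_poor_q2(self, planted_matrix):
        # null simulation: permutations with high label overlap keep some
        # genuine predictive power, so the bulk (not all) must collapse
        scaled, labels = planted_matrix
        rng = np.random.default_rng(99)
        q2s = np.array(
            [oplsda(scaled, rng.permutation(labels), seed=1).q2 for _ in range(40)]
        )
        assert (q2s <= 0.2).mean() >= 0.8
        assert np.median(q2s) < 0.0

    def test_orthogonal_scores_orthogonal_to_predictive(self, planted_matrix):
        scaled, labels = planted_matrix
        model = oplsda(scaled, labels, seed=1, q2_tol=-1.0)  # force >=1 ortho
        assert model.n_ortho >= 1
        inner = model.ortho_scores.T @ model.scores_pred
        assert np.abs(inner).max() < 1e-10

    def test_single_class_rejected(self, planted_matrix):
        scaled, _ = planted_matrix
        with pytest.raises(ValueError):
            oplsda(scaled, [1] * scaled.n_samples)

    def test_r2x_bounded(self, planted_matrix):
        scaled, labels = planted_matrix
        model = oplsda(scaled, labels)
        assert 0.0 < model.r2x <= 1.0


class TestPermutationTest:
    def test_informative_data_valid(self, planted_matrix):
        scaled, labels = planted_matrix
        result = permutation_test(scaled, labels, n_perm=30, seed=4)
        assert result["q2_original"] > result["permuted_q2"].max()
        assert result["q2_intercept"] < result["q2_original"]
        assert result["valid"]

    def test_identity_permutation_reproduces_r2y(self, planted_matrix):
        scaled, labels = planted_matrix
        model = oplsda(scaled, labels, seed=1)
        result = permutation_test(scaled, labels, n_perm=25, seed=1)
        # the stored original point equals the refit model
        assert result["r2y_original"] == pytest.approx(model.r2y)

    def test_pure_noise_intercept_near_mean(self):
        m = _random_matrix(21, n=14, p=4)
        labels = [1] * 7 + [2] * 7
        result = permutation_test(autoscale(m), labels, n_perm=40, seed=3)
        assert abs(result["q2_intercept"] - result["permuted_q2"].mean()) < 0.3

    def test_too_few_permutations(self, planted_matrix):
        scaled, labels = planted_matrix
        with pytest.raises(ValueError):
            permutation_test(scaled, labels, n_perm=5)


class TestVIP:
    def test_normalization_identity(self, planted_matrix):
        scaled, labels = planted_matrix
        values = vip(oplsda(scaled, labels))
        assert float((values**2).sum()) == pytest.approx(scaled.n_variables)

    def test_planted_informative_variables(self):
        config = two_group_config(seed=8, n_informative=2)
        peaks, truth = gen_batches(config)
        wide = peaks.pivot(index="batch_id", columns="analyte", values="area")
        groups = truth.drop_duplicates("batch_id").set_index("batch_id")["group"]
        m = DataMatrix.from_frame(wide)
        labels = [groups[s] for s in m.sample_ids]
        values = vip(oplsda(autoscale(m), labels))
        informative = {"GA", "PEGG"}
        top_two = set(values.nlargest(2).index)
        assert top_two == informative
        assert (values[list(informative)] > 1).all()

    def test_identical_columns_unit_vip(self):
        rng = np.random.default_rng(30)
        col = np.array([-1.0] * 7 + [1.0] * 7) + rng.normal(0, 0.1, 14)
        x = np.column_stack([col] * 4)
        m = DataMatrix([f"S{i}" for i in range(14)], list("abcd"), x)
        labels = [1] * 7 + [2] * 7
        values = vip(oplsda(autoscale(m), labels))
        np.testing.assert_allclose(values.to_numpy(), 1.0, atol=1e-9)


class TestTTest:
    def test_identical_groups(self):
        result = ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.statistic == 0.0
        assert result.pvalue == pytest.approx(1.0)

    def test_published_ga_grouping(self, contents_table):
        groups = datasets.load_batch_groups()
        table = contents_table.set_index("batch_id")
        g1 = table.loc[groups["group1"], "GA_esm"].tolist()
        g2 = table.loc[groups["group2"], "GA_esm"].tolist()
        result = ttest(g1, g2)
        assert result.pvalue == pytest.approx(0.195, abs=0.005)
        assert result.df == len(g1) + len(g2) - 2

    def test_near_degenerate_separation(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0.0, 1e-3, 4)
        b = 1.0 + rng.normal(0.0, 1e-3, 4)
        assert ttest(a, b).pvalue < 1e-4

    def test_antisymmetric_statistic(self):
        rng = np.random.default_rng(18)
        a, b = rng.normal(size=5), rng.normal(1.0, 1.0, size=6)
        assert ttest(a, b).statistic == pytest.approx(-ttest(b, a).statistic)

    def test_matches_closed_form(self):
        from scipy import stats as ss

        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 4.0, 6.0]
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
            na + nb - 2
        )
        t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * ss.t.sf(abs(t), na + nb - 2)
        result = ttest(a, b)
        assert result.statistic == pytest.approx(t)
        assert result.pvalue == pytest.approx(p)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            ttest([1.0], [2.0, 3.0])


class TestParameterRecovery:
    def test_pipeline_recovers_planted_labels(self):
        # clustering, PCA score split and OPLS-DA prediction all agree with
        # the planted two-group structure on nearly every seed
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            config = two_group_config(seed=seed)
            peaks, truth = gen_batches(config)
            wide = peaks.pivot(index="batch_id", columns="analyte", values="area")
            groups = truth.drop_duplicates("batch_id").set_index("batch_id")["group"]
            m = DataMatrix.from_frame(wide)
            true_labels = np.array([groups[s] for s in m.sample_ids])
            scaled = autoscale(m)
            cut = hcluster(scaled).cut(2)
            cluster_labels = np.array([cut[s] for s in m.sample_ids])
            cluster_ok = (
                max(
                    (cluster_labels == true_labels).mean(),
                    (cluster_labels == 3 - true_labels).mean(),
                )
                == 1.0
            )
            model = oplsda(scaled, true_labels, seed=1)
            pred = model.predict_class(scaled.values)
            coded = np.where(true_labels == sorted(set(true_labels))[0], -1, 1)
            opls_ok = (pred == coded).all()
            hits += cluster_ok and opls_ok
        assert hits / n_seeds >= 0.95
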