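import numpy as np
import pytest
from scipy import stats

from scgale.containers import CellGraph, CountMatrix
from scgale.graph import knn_graph
from scgale.metrics import (bias_overlap, feature_coverage,
                            feature_expression, homogeneity, mse,
                            mse_top_covered, nb_loss, spearman, specificity,
                            stability, stn_ratio, xai_da_similarity)


def _cm(counts, labels=None):
    counts = np.asarray(counts, dtype=float)
    n, f = counts.shape
    return CountMatrix(counts=counts, cell_ids=[f"c{i}" for i in range(n)],
                       feature_ids=[f"g{j}" for j in range(f)], labels=labels)


class TestReconstructionMetrics:
    def test_identity_pair(self):
        X = np.random.default_rng(0).random((6, 4))
        assert mse(X, X) == 0.0
        assert np.isclose(spearman(X, X + 0.0), 1.0)

    def test_reversal_gives_minus_one(self):
        assert np.isclose(
            spearman(np.array([[1.0, 2.0, 3.0]]), np.array([[3.0, 2.0, 1.0]])),
            -1.0)

    def test_spearman_matches_bruteforce_ranks(self):
        rng = np.random.default_rng(1)
        X, Y = rng.random((5, 5)), rng.random((5, 5))
        rx = stats.rankdata(X.ravel())
        ry = stats.rankdata(Y.ravel())
        expected = np.corrcoef(rx, ry)[0, 1]
        assert np.isclose(spearman(X, Y), expected)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones((3, 3)), np.random.random((3, 3)))

    def test_mse_top_covered_single_column(self):
        X = np.array([[1.0, 0.0, 2.0], [3.0, 0.0, 4.0], [0.0, 0.0, 5.0]])
        Xhat = X + np.array([1.0, 0.0, 0.0])
        got = mse_top_covered(X, Xhat, basis="observed", top_frac=1 / 3)
        # column 2 is the most covered; direct column MSE
        assert np.isclose(got, ((X[:, 2] - Xhat[:, 2]) ** 2).mean())

    def test_mse_top_covered_limits(self):
        rng = np.random.default_rng(2)
        X, Xhat = rng.random((8, 10)), rng.random((8, 10))
        assert mse_top_covered(X, X, basis="observed") == 0.0
        assert mse_top_covered(X, X, basis="imputed") == 0.0
        assert np.isclose(mse_top_covered(X, Xhat, top_frac=1.0), mse(X, Xhat))


class TestNBLoss:
    def test_closed_form_zero_count(self):
        # P(0 | mu=1, theta=1) = 1/2, NLL = log 2
        got = nb_loss(np.array([[0.0]]), np.array([[1.0]]), theta=1.0)
        assert abs(got - np.log(2.0)) < 1e-9

    def test_poisson_limit(self):
        x = np.arange(6).reshape(1, -1).astype(float)
        mu = np.full_like(x, 2.5)
        nb = nb_loss(x, mu, theta=1e6)
        poisson = -stats.poisson.logpmf(x.astype(int), 2.5).mean()
        assert abs(nb - poisson) < 1e-3

    def test_minimised_at_observation(self):
        x = np.array([[4.0]])
        best = nb_loss(x, np.array([[4.0]]), theta=3.0)
        for mu in np.linspace(0.5, 12, 40):
            assert best <= nb_loss(x, np.array([[mu]]), theta=3.0) + 1e-12

    def test_theta_guard(self):
        with pytest.raises(ValueError):
            nb_loss(np.ones((2, 2)), np.ones((2, 2)), theta=0.0)


class TestHomogeneity:
    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 4))
        labels = rng.integers(0, 5, 80)
        g = knn_graph(X, k=6)
        C = 5
        het = []
        for i in range(80):
            het.append(len(set(labels[g.neighbors[i]])) / (6 * C))
        assert np.isclose(homogeneity(g, labels), 1 - np.mean(het))

    def test_bounded(self):
        rng = np.random.default_rng(4)
        g = knn_graph(rng.standard_normal((50, 3)), k=5)
        h = homogeneity(g, rng.integers(0, 3, 50))
        assert 0.0 <= h <= 1.0


class TestSetMetrics:
    def test_specificity_calibration(self):
        same = {"a": list(range(50)), "b": list(range(50))}
        disjoint = {"a": list(range(50)), "b": list(range(50, 100))}
        half = {"a": list(range(50)), "b": list(range(25, 75))}
        assert specificity(same) == 0.0
        assert specificity(disjoint) == 1.0
        assert np.isclose(specificity(half), 0.5)

    def test_specificity_size_guard(self):
        with pytest.raises(ValueError):
            specificity({"a": [1], "b": [2]}, n=50)

    def test_stability_calibration(self):
        r = {"a": list(range(50))}
        assert stability([r, r, r]) == 1.0
        assert stability([{"a": list(range(50))},
                          {"a": list(range(50, 100))}]) == 0.0

    def test_stability_worked_example(self):
        # pairwise overlaps 50/50, 25/50, 25/50 → (1 + 0.5 + 0.5)/3 = 2/3
        r1 = {"a": list(range(50))}
        r2 = {"a": list(range(50))}
        r3 = {"a": list(range(25)) + list(range(100, 125))}
        assert np.isclose(stability([r1, r2, r3]), 2 / 3)

    def test_stability_missing_class_names_run(self):
        with pytest.raises(ValueError, match="run 1"):
            stability([{"a": list(range(50))}, {"b": list(range(50))}])

    def test_similarity(self):
        a = [f"f{i}" for i in range(50)]
        b = [f"f{i}" for i in range(40, 90)]
        assert xai_da_similarity(a, a) == 1.0
        assert np.isclose(xai_da_similarity(a, b), 0.2)
        assert np.isclose(
            xai_da_similarity(a, b, jaccard=True), 10 / 90)


class TestFeatureStats:
    def test_coverage_and_expression(self):
        m = _cm(np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 2.0], [2.0, 0.0, 1.0]]))
        assert list(feature_coverage(m)) == [2, 0, 2]
        assert list(feature_expression(m)) == [3.0, 0.0, 3.0]
        assert (feature_coverage(m) <= m.n_cells).all()

    def test_bias_overlap_extremes_and_bruteforce(self):
        rng = np.random.default_rng(5)
        m = _cm(rng.poisson(3, (20, 30)).astype(float))
        expr = m.counts.sum(axis=0)
        top10 = [f"g{j}" for j in np.argsort(-expr, kind="stable")[:10]]
        assert bias_overlap(top10, m, "expression") == 1.0
        bottom = [f"g{j}" for j in np.argsort(expr, kind="stable")[:10]]
        expected = len(set(top10) & set(bottom)) / 10
        assert np.isclose(bias_overlap(bottom, m, "expression"), expected)

    def test_stn_symmetric_distributions_zero(self):
        rng = np.random.default_rng(6)
        col = rng.normal(5, 1, 200)
        m = _cm(np.abs(col)[:, None])
        labels = np.array(["a"] * 100 + ["b"] * 100)
        val = stn_ratio(["g0"], m, labels, "a")
        assert abs(val) < 0.3

    def test_stn_sign_forced_for_constant_groups(self):
        counts = np.concatenate([np.full(10, 3.0), np.zeros(10)])[:, None]
        m = _cm(counts)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        assert stn_ratio(["g0"], m, labels, "a") > 1e6

    def test_stn_marker_beats_background(self, processed, cluster_fixture):
        _, _, truth = cluster_fixture
        j = sorted(truth.marker_sets[0])[0]
        marker = stn_ratio([f"feat_{j}"], processed, processed.labels, "type_0")
        background = stn_ratio(["feat_119"], processed, processed.labels,
                               "type_0")
        assert marker > background
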