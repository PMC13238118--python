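import itertools

import numpy as np
import pandas as pd
import pytest

import scgale as sg
from scgale.containers import CountMatrix
from scgale.preprocess import (log_transform, normalize_library_size,
                               qc_filter_gex, qc_filter_peaks,
                               select_hv_peaks, select_hvg_gex, wilcoxon_da)


def _gex(counts, labels=None, qc=None, **kw):
    counts = np.asarray(counts, dtype=float)
    n, f = counts.shape
    return CountMatrix(
        counts=counts,
        cell_ids=[f"c{i}" for i in range(n)],
        feature_ids=[f"g{j}" for j in range(f)],
        labels=labels, qc=qc, **kw,
    )


class TestQC:
    def test_identical_cells_nothing_removed(self):
        m = _gex(np.tile([1, 0, 2, 3], (20, 1)))
        out, rep = qc_filter_gex(m)
        assert out.n_cells == 20
        assert rep.removals["cells_outside_nonzero_gene_band"] == 0

    def test_nonzero_gene_band_matches_enumeration(self):
        # cells i has i+1 nonzero genes; brute-force the linear-interpolation
        # quantile rule on 1..100
        n, f = 100, 120
        counts = np.zeros((n, f))
        for i in range(n):
            counts[i, : i + 1] = 1.0
        m = _gex(counts)
        nz = counts.astype(bool).sum(axis=1)
        q5, q95 = np.quantile(nz, 0.05), np.quantile(nz, 0.95)
        expected_removed = int(((nz < q5) | (nz > q95)).sum())
        out, rep = qc_filter_gex(m)
        assert rep.removals["cells_outside_nonzero_gene_band"] == expected_removed
        assert out.n_cells == n - expected_removed

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            qc_filter_gex(_gex(np.zeros((10, 5))))

    def test_missing_mito_column_recorded_not_fatal(self):
        m = _gex(np.random.default_rng(0).poisson(3, (40, 30)).astype(float))
        _, rep = qc_filter_gex(m)
        assert "mito_count" in rep.skipped_rules

    def test_tss_threshold_removes_exactly_low_cell(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3, (30, 25)).astype(float) + 1  # equal nonzero counts
        tss = np.full(30, 5.0)
        tss[7] = 1.9
        qc = pd.DataFrame({"tss_enrichment": tss,
                           "nucleosome_signal": np.ones(30)})
        m = _gex(counts, qc=qc, modality="PEAKS")
        out, rep = qc_filter_peaks(m)
        assert rep.removals["cells_failing_tss"] == 1
        assert "c7" not in set(out.cell_ids)

    def test_benign_signal_scores_remove_nothing(self):
        counts = np.ones((20, 10))
        qc = pd.DataFrame({"tss_enrichment": np.full(20, 5.0),
                           "nucleosome_signal": np.ones(20)})
        m = _gex(counts, qc=qc, modality="PEAKS")
        _, rep = qc_filter_peaks(m)
        assert rep.removals["cells_failing_tss"] == 0
        assert rep.removals["cells_failing_nucleosome"] == 0

    def test_feature_detection_filter_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        counts = (rng.random((60, 40)) < rng.uniform(0.1, 0.9, 40)).astype(float)
        counts[:, 0] = 1.0  # give every cell a nonzero entry
        m = _gex(counts, modality="PEAKS")
        out, _ = qc_filter_peaks(m)
        kept_cells = np.isin(m.cell_ids, out.cell_ids)
        det = (counts[kept_cells] > 0).sum(axis=0)
        q5, q95 = np.quantile(det, 0.05), np.quantile(det, 0.95)
        expected = set(np.asarray(m.feature_ids)[(det >= q5) & (det <= q95)])
        assert set(out.feature_ids) == expected

    def test_cell_qc_converges_when_band_interior_is_tied(self):
        # bulk of cells share one detection count: after outliers are cut
        # the recomputed band collapses onto the tied value and a second
        # pass removes nothing (strict-outside rule)
        counts = np.zeros((100, 60))
        for i in range(90):
            counts[i, :30] = 1.0
        for i in range(90, 95):
            counts[i, :2] = 1.0
        for i in range(95, 100):
            counts[i, :] = 1.0
        m = _gex(counts)
        once, _ = qc_filter_gex(m)
        twice, rep2 = qc_filter_gex(once)
        assert rep2.removals["cells_outside_nonzero_gene_band"] == 0
        assert twice.n_cells == once.n_cells


class TestNormalizeLog:
    def test_equal_totals_median_target_is_identity(self):
        m = _gex(np.full((5, 4), 2.0))
        out = normalize_library_size(m)
        assert np.allclose(out.counts, m.counts)

    def test_explicit_target_scale_factors(self):
        m = _gex([[100.0, 0.0], [0.0, 300.0]])
        out = normalize_library_size(m, target_sum=200)
        assert np.allclose(out.counts[0, 0], 200.0)
        assert np.allclose(out.counts[1, 1], 200.0)

    def test_totals_equal_target_after_op(self):
        rng = np.random.default_rng(0)
        m = _gex(rng.poisson(5, (30, 12)).astype(float) + 1)
        out = normalize_library_size(m, target_sum=1000)
        assert np.allclose(out.counts.sum(axis=1), 1000.0, rtol=1e-6)

    def test_zero_total_cell_rejected(self):
        m = _gex([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="QC"):
            normalize_library_size(m)

    def test_log_transform_values_and_guards(self):
        m = _gex([[0.0, np.e - 1.0]])
        m.is_normalised = True
        out = log_transform(m)
        assert out.counts[0, 0] == 0.0
        assert np.isclose(out.counts[0, 1], 1.0)
        with pytest.raises(ValueError):
            log_transform(out)

    def test_orderings_and_ids_preserved(self, processed, cluster_fixture):
        _, m, _ = cluster_fixture
        assert list(processed.cell_ids) == list(m.cell_ids)
        assert list(processed.feature_ids) == list(m.feature_ids)


class TestFeatureSelection:
    def test_hvg_count_and_bruteforce_set(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(rng.uniform(1, 20, 100), (50, 100)).astype(float)
        m = _gex(counts)
        m.is_normalised = True
        out = select_hvg_gex(m, top_frac=0.10)
        assert out.n_features == 10
        var = counts.var(axis=0)
        expected = set(np.asarray(m.feature_ids)[np.argsort(-var)[:10]])
        assert set(out.feature_ids) == expected

    def test_constant_matrix_tie_break_keeps_first_block(self):
        m = _gex(np.ones((10, 20)))
        m.is_normalised = True
        out = select_hvg_gex(m, top_frac=0.10)
        assert list(out.feature_ids) == ["g0", "g1"]

    def test_hv_peaks_quantile_rule(self):
        rng = np.random.default_rng(6)
        counts = rng.normal(0, rng.uniform(0.5, 5, 100), (60, 100)) ** 2
        m = _gex(counts, modality="PEAKS")
        m.is_normalised = True
        out = select_hv_peaks(m, var_quantile=0.80)
        assert out.n_features == 20

    def test_hv_peaks_max_features_cap(self):
        rng = np.random.default_rng(8)
        counts = rng.normal(0, rng.uniform(0.5, 5, 200), (30, 200)) ** 2
        m = _gex(counts, modality="PEAKS")
        m.is_normalised = True
        out = select_hv_peaks(m, var_quantile=0.5, max_features=40)
        assert out.n_features == 40

    def test_all_equal_variances_error(self):
        m = _gex(np.tile([1.0, 2.0], (10, 15)))
        m.is_normalised = True
        with pytest.raises(ValueError, match="quantile"):
            select_hv_peaks(m)

    def test_bad_top_frac(self):
        m = _gex(np.ones((5, 5)))
        m.is_normalised = True
        with pytest.raises(ValueError):
            select_hvg_gex(m, top_frac=1.5)


class TestWilcoxon:
    def _labelled(self, col_a, col_rest):
        vals = np.concatenate([col_a, col_rest])[:, None]
        labels = ["A"] * len(col_a) + ["B"] * len(col_rest)
        m = _gex(np.hstack([vals, vals[::-1]]), labels=np.array(labels))
        m.is_normalised = m.is_log = True
        return m

    def test_three_vs_three_exact_p(self):
        m = self._labelled([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        res = wilcoxon_da(m, n_top=1)
        tab = res.tables["A"].set_index("feature_id")
        assert np.isclose(tab.loc["g0", "pvalue"], 0.1)
        assert tab.loc["g0", "statistic"] < 0

    def test_constant_feature_statistic_zero(self):
        counts = np.ones((8, 2))
        counts[:, 1] = np.arange(8)
        m = _gex(counts, labels=np.array(["A"] * 4 + ["B"] * 4))
        m.is_normalised = m.is_log = True
        res = wilcoxon_da(m, n_top=1)
        tab = res.tables["A"].set_index("feature_id")
        assert tab.loc["g0", "statistic"] == 0.0

    def test_exact_p_matches_independent_enumeration(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(4, (8, 5)).astype(float)
        labels = np.array(["A"] * 3 + ["B"] * 5)
        m = _gex(counts, labels=labels)
        m.is_normalised = m.is_log = True
        res = wilcoxon_da(m, n_top=5)
        from scipy.stats import rankdata

        ranks = rankdata(counts, axis=0)
        in_a = labels == "A"
        for j, fid in enumerate(m.feature_ids):
            obs = ranks[in_a, j].sum()
            mu = in_a.sum() * (len(labels) + 1) / 2
            sums = [
                ranks[list(cmb), j].sum()
                for cmb in itertools.combinations(range(8), 3)
            ]
            p_exact = np.mean(np.abs(np.array(sums) - mu) >= abs(obs - mu) - 1e-12)
            got = res.tables["A"].set_index("feature_id").loc[fid, "pvalue"]
            assert np.isclose(got, p_exact)

    def test_small_class_errors_with_name(self):
        m = _gex(np.ones((4, 3)), labels=np.array(["A", "B", "B", "B"]))
        m.is_normalised = m.is_log = True
        with pytest.raises(ValueError, match="A"):
            wilcoxon_da(m)

    def test_statistics_match_scanpy(self, processed):
        scanpy = pytest.importorskip("scanpy")
        from scgale.io import to_anndata

        res = wilcoxon_da(processed, n_top=20)
        ad = to_anndata(processed)
        scanpy.tl.rank_genes_groups(ad, "cell_type", method="wilcoxon",
                                    tie_correct=True)
        for grp in ("type_0", "type_3"):
            sc_z = dict(zip(ad.uns["rank_genes_groups"]["names"][grp],
                            ad.uns["rank_genes_groups"]["scores"][grp]))
            mine = res.tables[grp].set_index("feature_id")["statistic"]
            diffs = [abs(sc_z[f] - mine[f]) for f in mine.index]
            assert max(diffs) < 1e-5

    def test_planted_markers_dominate_top_set(self):
        spec = sg.SyntheticSpec(n_cells=2000, n_features=500, seed=17)
        m, truth = sg.generate_counts(spec)
        ml = log_transform(normalize_library_size(m))
        res = wilcoxon_da(ml, n_top=50)
        for c in range(spec.n_types):
            top = set(res.top_sets()[f"type_{c}"])
            markers = {f"feat_{j}" for j in truth.marker_sets[c]}
            assert markers <= top
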