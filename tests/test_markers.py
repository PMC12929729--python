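"""Dropout screening, ranking, z-scores, intersection, subtype positivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse

from conftest import make_table
from spotmark import markers, tumor
from spotmark.containers import TUMOR_LABELS
from spotmark.markers import DropoutProfile


class TestDropoutRates:
    def test_fraction_of_zero_cells(self):
        counts = np.zeros((10, 1), dtype=int)
        counts[4:, 0] = 1  # 4 zero cells of 10 in the tumor fraction
        mask = np.ones(10, bool)
        counts = np.vstack([counts, np.ones((5, 1), dtype=int)])
        mask = np.concatenate([mask, np.zeros(5, bool)])
        d_t, d_n = markers.dropout_rates(sparse.csr_matrix(counts), mask)
        assert d_t[0] == pytest.approx(0.4)
        assert d_n[0] == 0.0

    def test_everywhere_detected_and_all_zero_extremes(self):
        counts = np.array([[1, 0], [2, 0], [3, 0], [1, 0]])
        mask = np.array([True, True, False, False])
        d_t, d_n = markers.dropout_rates(sparse.csr_matrix(counts), mask)
        assert d_t[0] == 0.0 and d_n[0] == 0.0
        assert d_t[1] == 1.0 and d_n[1] == 1.0

    def test_empty_fraction_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            markers.dropout_rates(sparse.csr_matrix(np.ones((3, 1))), np.ones(3, bool))


class TestClassifyDropout:
    @pytest.mark.parametrize("d_t,d_n,expected", [
        (0.5, 0.9, "tumor_specific"),
        (0.9, 0.5, "normal_specific"),
        (0.5, 0.5, "common_positive"),
        (0.9, 0.9, "common_negative"),
        (0.75, 0.75, "common_negative"),   # boundary: >= on both axes
        (0.74999, 0.75, "tumor_specific"),
        (0.75, 0.74999, "normal_specific"),
    ])
    def test_quadrant_rule(self, d_t, d_n, expected):
        assert markers.classify_dropout(d_t, d_n)[0] == expected

    def test_bad_tau_rejected(self):
        with pytest.raises(ValueError):
            markers.classify_dropout(0.5, 0.5, tau=1.0)

    @settings(max_examples=200, deadline=None)
    @given(
        d_t=st.floats(0, 1), d_n=st.floats(0, 1),
        tau=st.floats(0.01, 0.99),
    )
    def test_categories_partition_the_unit_square(self, d_t, d_n, tau):
        """Every rate pair gets exactly one category, determined by the two
        half-plane indicators (strict < tau on the expressed side)."""
        cat = markers.classify_dropout(d_t, d_n, tau)[0]
        t_expr, n_expr = d_t < tau, d_n < tau
        ref = ("common_positive" if t_expr and n_expr else
               "tumor_specific" if t_expr else
               "normal_specific" if n_expr else "common_negative")
        assert cat == ref


class TestTopTumorSpecific:
    def _profile(self):
        df = pd.DataFrame({
            "d_T": [0.1, 0.2, 0.3, 0.1],
            "d_N": [0.9, 0.9, 0.5, 0.9],
            "category": ["tumor_specific", "tumor_specific",
                         "common_positive", "tumor_specific"],
            "total_tumor_expression": [10, 5, 7, 5],
        }, index=pd.Index(["gB", "gC", "gA", "gAA"], name="gene"))
        return DropoutProfile(table=df, tau=0.75)

    def test_ranked_by_total_descending(self):
        top = markers.top_tumor_specific(self._profile(), k=2)
        assert top.index.tolist() == ["gB", "gA"]

    def test_ties_break_alphabetically(self):
        top = markers.top_tumor_specific(self._profile(), k=4)
        assert top.index.tolist() == ["gB", "gA", "gAA", "gC"]

    def test_strict_variant_filters_first(self):
        top = markers.top_tumor_specific(self._profile(), k=3, strict=True)
        assert top.index.tolist() == ["gB", "gAA", "gC"]
        assert (top["category"] == "tumor_specific").all()

    def test_planted_markers_with_dominant_rates_occupy_top_ranks(self):
        rng = np.random.default_rng(0)
        n = 400
        counts = rng.poisson(0.5, (n, 10))
        counts[:, [2, 5, 7]] = rng.poisson(8.0, (n, 3))  # dominant planted trio
        table = make_table(counts, genes=[f"g{i}" for i in range(10)])
        mask = np.zeros(n, bool)
        mask[: n // 2] = True
        profile = markers.dropout_profile(table, mask)
        top = markers.top_tumor_specific(profile, k=3)
        assert set(top.index) == {"g2", "g5", "g7"}

    def test_glut1_like_gene_ranks_in_strict_top_k(self, spatial_run):
        *_, report = spatial_run
        assert "SLC2A1" in set(report["top_k_tumor_specific"])


class TestClusterZscores:
    def test_identical_cluster_means_give_zero(self):
        norm = sparse.csr_matrix(np.ones((6, 1)))
        z = markers.cluster_zscore_matrix(norm, np.repeat([1, 2, 3], 2), ["g"])
        assert np.allclose(z.to_numpy(), 0)

    def test_two_clusters_population_sd_convention(self):
        # cluster means 0 and 2: population SD of the means is 1 -> z = -+1
        norm = sparse.csr_matrix(np.array([[0.0], [0.0], [2.0], [2.0]]))
        z = markers.cluster_zscore_matrix(norm, np.array([1, 1, 2, 2]), ["g"])
        assert z.loc["g"].to_numpy() == pytest.approx([-1.0, 1.0])
        # the sample-SD convention remains available and gives -+0.707
        z1 = markers.cluster_zscore_matrix(norm, np.array([1, 1, 2, 2]), ["g"], ddof=1)
        assert z1.loc["g"].to_numpy() == pytest.approx(
            [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_rows_have_zero_mean_unit_sd(self, clustered_tissue):
        _, table, _, clusters = clustered_tissue
        z = markers.cluster_zscore_matrix(
            table.norm, clusters.labels, table.genes, genes=["EPCAM", "SLC2A1", "VIM"])
        zv = z.to_numpy()
        assert np.allclose(zv.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(zv.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_single_cluster_rejected(self):
        norm = sparse.csr_matrix(np.ones((4, 1)))
        with pytest.raises(ValueError, match="2 clusters"):
            markers.cluster_zscore_matrix(norm, np.ones(4, int), ["g"])


class TestIntersectSamples:
    def test_shared_genes_sorted(self):
        assert markers.intersect_samples(["C", "A", "B"], ["B", "D", "C"]) == ["B", "C"]

    def test_disjoint_and_identical(self):
        assert markers.intersect_samples(["A"], ["B"]) == []
        assert markers.intersect_samples(["B", "A"], ["A", "B"]) == ["A", "B"]

    @settings(max_examples=100, deadline=None)
    @given(a=st.lists(st.sampled_from("ABCDEFG")), b=st.lists(st.sampled_from("ABCDEFG")))
    def test_commutative_and_idempotent(self, a, b):
        ab = markers.intersect_samples(a, b)
        assert ab == markers.intersect_samples(b, a)
        assert markers.intersect_samples(ab, ab) == sorted(set(ab))


class TestSubtypes:
    def test_cell_in_subtype_polygon_gets_label(self, sim_default):
        cfg, table, truth = sim_default
        labels = markers.annotate_subtypes(table.cells, cfg.regions)
        true_labels = truth.cell_labels
        tumor_mask = true_labels.isin(TUMOR_LABELS).to_numpy()
        assert (labels[tumor_mask] == true_labels[tumor_mask]).all()
        # stromal and normal-focus cells stay unlabeled
        assert labels[~tumor_mask].isna().all()

    def test_labeled_counts_conserve(self, sim_default):
        cfg, table, truth = sim_default
        labels = markers.annotate_subtypes(table.cells, cfg.regions)
        counts = labels.value_counts()
        assert counts.sum() == labels.notna().sum()

    def test_missing_subtype_rejected(self):
        counts = np.ones((6, 2), dtype=int)
        table = make_table(counts, genes=["g1", "g2"])
        table.norm = tumor.normalize_by_area(table.raw, table.cells["cell_area"].to_numpy())
        labels = pd.Series(["ADC"] * 3 + ["SCC"] * 3)
        with pytest.raises(ValueError, match="TTF1neg_p40neg"):
            markers.subtype_positivity(table, labels, ["g1"])

    def test_positivity_extremes_and_delta(self):
        counts = np.array([[1], [1], [0], [0], [0], [0]])
        table = make_table(counts, genes=["g"])
        table.norm = tumor.normalize_by_area(table.raw, table.cells["cell_area"].to_numpy())
        labels = pd.Series(["ADC", "ADC", "TTF1neg_p40neg", "TTF1neg_p40neg",
                            "SCC", "SCC"])
        out = markers.subtype_positivity(table, labels, ["g"])
        assert out.loc["g", "frac_ADC"] == 1.0
        assert out.loc["g", "frac_SCC"] == 0.0
        assert out.loc["g", "delta1"] == 1.0
        assert out.loc["g", "delta2"] == 0.0

    def test_positivity_unchanged_by_area_normalization(self, sim_default):
        _, table, truth = sim_default
        gi = table.gene_index("SLC2A1")
        pos_raw = np.asarray((table.raw[:, gi] > 0).todense()).ravel()
        norm = tumor.normalize_by_area(table.raw, table.cells["cell_area"].to_numpy())
        pos_norm = np.asarray((norm[:, gi] > 0).todense()).ravel()
        assert np.array_equal(pos_raw, pos_norm)


class TestScreenRecovery:
    def test_planted_tumor_specific_recovered(self, spatial_run):
        *_, report = spatial_run
        rec = report["recovery"]
        assert rec["screen_precision"] >= 0.9
        assert rec["screen_recall"] >= 0.9

    def test_glut1_like_gene_is_monotone_across_subtypes(self, spatial_run):
        _, out, report = spatial_run
        pos = pd.read_csv(out / "subtype_positivity.csv", index_col=0)
        row = pos.loc["SLC2A1"]
        assert row["frac_SCC"] > row["frac_TTF1neg_p40neg"] > row["frac_ADC"]
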