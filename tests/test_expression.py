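"""Normalization, marker detection, state construction and heatmaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepaquant.dge import DGEMatrix
from hepaquant.expression import (
    AmbiguousClusterError,
    NormalizedMatrix,
    build_states,
    conserved_marker_heatmap,
    dotplot_stats,
    find_markers,
    identify_cluster,
    log_normalize,
    merge_indistinct_clusters,
    minmax_scale_rows,
    parse_state,
    state_heatmap,
)
from hepaquant.simulate import StateSimSpec, simulate_state_expression


def two_cluster_sim(seed=0, fold=8.0, n_markers=5, n_null=45, cells=100):
    markers = [f"mk{i}" for i in range(n_markers)]
    nulls = [f"nu{i}" for i in range(n_null)]
    programs = {
        "sig": (markers, {"A.x": fold, "B.x": 1.0}),
        "bg": (nulls, {"A.x": 2.0, "B.x": 2.0}),
    }
    spec = StateSimSpec(["A.x", "B.x"], cells, programs, dispersion=2.0, seed=seed)
    counts, meta = simulate_state_expression(spec)
    return counts, meta.set_index("cell")["state"], markers


class TestLogNormalize:
    def test_closed_form_value(self):
        m = DGEMatrix(["g1", "g2"], ["c1"], np.array([[1], [1]]))
        nm = log_normalize(m)
        assert nm.values[0, 0] == pytest.approx(np.log(5001))

    def test_zero_count_maps_to_zero(self):
        m = DGEMatrix(["g1", "g2"], ["c1"], np.array([[0], [4]]))
        assert log_normalize(m).values[0, 0] == 0.0

    def test_depth_invariance(self):
        m1 = DGEMatrix(["g1", "g2"], ["c1"], np.array([[3], [7]]))
        m2 = DGEMatrix(["g1", "g2"], ["c1"], np.array([[6], [14]]))
        assert np.allclose(log_normalize(m1).values, log_normalize(m2).values)

    def test_zero_total_cell_named_in_error(self):
        m = DGEMatrix(["g1"], ["good", "empty"], np.array([[3, 0]]))
        with pytest.raises(ValueError, match="empty"):
            log_normalize(m)


class TestDotplotStats:
    def test_fraction_expressing(self):
        m = DGEMatrix(["g"], list("abcd"), np.array([[2, 0, 0, 0]]))
        nm = log_normalize(
            DGEMatrix(["g", "tot"], list("abcd"), np.array([[2, 0, 0, 0], [5, 5, 5, 5]]))
        )
        stats = dotplot_stats(nm, pd.Series("c0", index=list("abcd")), ["g"])
        assert stats.loc[0, "fraction_expressing"] == 0.25

    def test_absent_gene_all_zero(self):
        nm = log_normalize(
            DGEMatrix(["g", "tot"], ["a", "b"], np.array([[0, 0], [5, 5]]))
        )
        stats = dotplot_stats(nm, pd.Series("c0", index=["a", "b"]), ["g"])
        assert stats.loc[0, "avg_expression"] == 0.0
        assert stats.loc[0, "fraction_expressing"] == 0.0

    def test_matches_per_cell_loop_oracle(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(2, size=(6, 20))
        counts[:, 0] += 1  # no zero-total cells
        m = DGEMatrix([f"g{i}" for i in range(6)], [f"c{i:02d}" for i in range(20)], counts)
        nm = log_normalize(m)
        labels = pd.Series(["k1"] * 10 + ["k2"] * 10, index=m.barcodes)
        stats = dotplot_stats(nm, labels, m.genes).set_index(["gene", "cluster"])
        for gi, g in enumerate(m.genes):
            for cl, cols in [("k1", range(10)), ("k2", range(10, 20))]:
                vals = [nm.values[gi, j] for j in cols]
                assert stats.loc[(g, cl), "avg_expression"] == pytest.approx(np.mean(vals))
                assert stats.loc[(g, cl), "fraction_expressing"] == pytest.approx(
                    np.mean([v > 0 for v in vals])
                )


class TestFindMarkers:
    def test_shifted_genes_reported_for_high_cluster_only(self):
        counts, labels, markers = two_cluster_sim(seed=1)
        res = find_markers(log_normalize(counts), labels)
        for g in markers:
            assert g in set(res.loc[res["cluster"] == "A.x", "gene"])
        assert not set(markers) & set(res.loc[res["cluster"] == "B.x", "gene"])

    def test_positive_only_never_reports_depleted_genes(self):
        counts, labels, markers = two_cluster_sim(seed=2)
        res = find_markers(log_normalize(counts), labels)
        # marker genes are depleted in B.x relative to A.x
        assert (res["mean_in"] > res["mean_out"]).all()
        assert not set(markers) & set(res.loc[res["cluster"] == "B.x", "gene"])

    def test_tiny_cluster_skipped_with_warning(self):
        counts, labels, _ = two_cluster_sim(seed=3, cells=50)
        labels = labels.copy()
        labels.iloc[:2] = "C.x"  # 2-cell cluster
        with pytest.warns(UserWarning, match="fewer than 3"):
            res = find_markers(log_normalize(counts), labels)
        assert "C.x" not in set(res["cluster"])

    def test_agrees_with_naive_per_gene_oracle(self):
        """Retained genes equal a brute-force loop applying the same
        prefilter, rank-sum p (scipy) and all-genes Bonferroni rule."""
        import scipy.stats

        counts, labels, _ = two_cluster_sim(seed=4, n_markers=3, n_null=17, cells=30)
        nm = log_normalize(counts)
        res = find_markers(nm, labels)
        got = {(r.cluster, r.gene) for r in res.itertuples()}
        expected = set()
        lab = labels.loc[nm.cells].to_numpy()
        for cl in ["A.x", "B.x"]:
            inn, out = lab == cl, lab != cl
            for gi, g in enumerate(nm.genes):
                vi, vo = nm.values[gi, inn], nm.values[gi, out]
                if max((vi > 0).mean(), (vo > 0).mean()) < 0.1:
                    continue
                lfc = np.log((np.expm1(vi).mean() + 1) / (np.expm1(vo).mean() + 1))
                if lfc < 0.25:
                    continue
                p = scipy.stats.mannwhitneyu(vi, vo, alternative="two-sided").pvalue
                if min(1, p * len(nm.genes)) < 0.05 and vi.mean() > vo.mean():
                    expected.add((cl, g))
        assert got == expected

    def test_requires_two_clusters(self):
        counts, labels, _ = two_cluster_sim(seed=5, cells=10)
        with pytest.raises(ValueError):
            find_markers(log_normalize(counts), labels.replace("B.x", "A.x"))


class TestIdentifyCluster:
    PANEL = {
        "hepatocyte": ["fabp10a", "tfa", "cp"],
        "BEC": ["anxa4", "krt18a.1", "alcama"],
    }

    def markers_frame(self, genes, cluster="c0"):
        return pd.DataFrame({"gene": genes, "cluster": cluster})

    def test_three_panel_markers_assign_cell_type(self):
        res = identify_cluster(self.markers_frame(["fabp10a", "tfa", "cp", "other"]), self.PANEL)
        assert res["c0"] == "hepatocyte"

    def test_two_of_three_is_unassigned(self):
        res = identify_cluster(self.markers_frame(["fabp10a", "tfa"]), self.PANEL)
        assert res["c0"] == "unassigned"

    def test_empty_markers_unassigned(self):
        assert identify_cluster(pd.DataFrame(columns=["gene", "cluster"]), self.PANEL) == {}

    def test_ambiguous_cluster_raises(self):
        genes = ["fabp10a", "tfa", "cp", "anxa4", "krt18a.1", "alcama"]
        with pytest.raises(AmbiguousClusterError, match="hepatocyte"):
            identify_cluster(self.markers_frame(genes), self.PANEL)

    def test_short_panel_rejected(self):
        with pytest.raises(ValueError):
            identify_cluster(self.markers_frame(["a"]), {"t": ["a", "b"]})


class TestMergeClusters:
    def test_exchangeable_clusters_merge(self):
        counts, labels, _ = two_cluster_sim(seed=6, fold=1.0)  # no real difference
        merged = merge_indistinct_clusters(log_normalize(counts), labels)
        assert merged.nunique() == 1
        assert set(merged) == {"A.x"}  # smallest label survives

    def test_distinct_clusters_not_merged(self):
        counts, labels, _ = two_cluster_sim(seed=7, fold=8.0, n_markers=10)
        merged = merge_indistinct_clusters(log_normalize(counts), labels)
        assert merged.nunique() == 2

    def test_transitive_closure_collapses_chain(self):
        """Three exchangeable clusters collapse to one component."""
        counts, labels, _ = two_cluster_sim(seed=8, fold=1.0, cells=60)
        labels = labels.copy()
        third = labels.index[labels == "B.x"][:30]
        labels.loc[third] = "C.x"
        merged = merge_indistinct_clusters(log_normalize(counts), labels)
        assert set(merged) == {"A.x"}

    def test_single_cluster_unchanged(self):
        counts, labels, _ = two_cluster_sim(seed=9, cells=10)
        single = labels.replace("B.x", "A.x")
        merged = merge_indistinct_clusters(log_normalize(counts), single)
        assert merged.equals(single)


class TestStates:
    def test_concatenation(self):
        meta = pd.DataFrame(
            {"cell": ["c1", "c2"], "timepoint": ["0dpa", "mock"], "cell_type": ["BEC", "HC"]}
        )
        out = build_states(meta)
        assert out["state"].tolist() == ["0dpa.BEC", "mock.HC"]

    def test_parse_round_trip(self):
        for tp, ct in [("0dpa", "BEC"), ("mock", "HC"), ("7dpa", "BEC")]:
            meta = pd.DataFrame({"cell": ["x"], "timepoint": [tp], "cell_type": [ct]})
            assert parse_state(build_states(meta)["state"].iloc[0]) == (tp, ct)

    def test_missing_label_names_cell(self):
        meta = pd.DataFrame(
            {"cell": ["c1", "c2"], "timepoint": ["0dpa", None], "cell_type": ["BEC", "HC"]}
        )
        with pytest.raises(ValueError, match="c2"):
            build_states(meta)

    def test_injective_on_distinct_inputs(self):
        meta = pd.DataFrame(
            {
                "cell": list("abcd"),
                "timepoint": ["mock", "mock", "2dpa", "2dpa"],
                "cell_type": ["BEC", "HC", "BEC", "HC"],
            }
        )
        assert build_states(meta)["state"].nunique() == 4


class TestHeatmaps:
    def test_linear_row_scaling(self):
        df = pd.DataFrame([[2.0, 4.0, 6.0]], index=["g"], columns=list("abc"))
        assert minmax_scale_rows(df).loc["g"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_row_is_all_zero(self):
        df = pd.DataFrame([[3.0, 3.0, 3.0]], index=["g"], columns=list("abc"))
        assert minmax_scale_rows(df).loc["g"].tolist() == [0.0, 0.0, 0.0]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rows_span_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(rng.integers(1, 8), rng.integers(2, 8))))
        scaled = minmax_scale_rows(df)
        assert ((scaled >= 0) & (scaled <= 1)).all().all()
        for _, row in scaled.iterrows():
            if row.nunique() > 1:
                assert row.min() == 0.0 and row.max() == 1.0
            else:
                assert (row == 0.0).all()

    def test_decaying_program_orders_states(self):
        """A biliary program decaying along the hepatocyte branch yields
        a scaled row maximal at the first state and minimal at the last."""
        states = ["0dpa.HC", "1dpa.HC", "3dpa.HC", "7dpa.HC"]
        levels = {"0dpa.HC": 10.0, "1dpa.HC": 6.0, "3dpa.HC": 3.0, "7dpa.HC": 0.5}
        spec = StateSimSpec(states, 80, {"biliary": (["anxa4"], levels)}, seed=12)
        counts, meta = simulate_state_expression(spec)
        counts.counts[0, counts.counts[0] == 0] += 0  # keep integer type
        # add a constant housekeeping gene so no cell has zero total
        full = DGEMatrix(
            ["anxa4", "hk"],
            counts.barcodes,
            np.vstack([counts.counts, np.full(counts.shape[1], 20)]),
        )
        hm = state_heatmap(
            log_normalize(full), meta.set_index("cell")["state"], ["anxa4"], states
        )
        row = hm.loc["anxa4"]
        assert row["0dpa.HC"] == 1.0
        assert row["7dpa.HC"] == 0.0
        assert list(row) == sorted(row, reverse=True)

    def test_unknown_gene_and_empty_state_errors(self):
        counts, labels, _ = two_cluster_sim(seed=13, cells=5)
        nm = log_normalize(counts)
        with pytest.raises(KeyError, match="nope"):
            state_heatmap(nm, labels, ["nope"], ["A.x", "B.x"])
        with pytest.raises(ValueError, match="C.x"):
            state_heatmap(nm, labels, [nm.genes[0]], ["A.x", "C.x"])


class TestConservedHeatmap:
    def build_species(self, seed, gene_names):
        programs = {
            "p0": ([gene_names[0]], {"k0.x": 8.0, "k1.x": 1.0}),
            "p1": ([gene_names[1]], {"k0.x": 1.0, "k1.x": 8.0}),
        }
        spec = StateSimSpec(["k0.x", "k1.x"], 40, programs, seed=seed)
        counts, meta = simulate_state_expression(spec)
        counts = DGEMatrix(
            counts.genes + ["hk"],
            counts.barcodes,
            np.vstack([counts.counts, np.full(counts.shape[1], 10)]),
        )
        return log_normalize(counts), meta.set_index("cell")["state"]

    def test_identical_species_give_identical_heatmaps(self):
        nm, labels = self.build_species(1, ["gA", "gB"])
        table = pd.DataFrame({"human": ["gA", "gB"], "mouse": ["gA", "gB"]})
        out = conserved_marker_heatmap(
            {"human": (nm, labels), "mouse": (nm, labels)}, table
        )
        assert out["human"].equals(out["mouse"])

    def test_argmax_matches_generating_cluster_across_species(self):
        data = {}
        tables = {}
        for sp, seed in [("human", 1), ("mouse", 2), ("zebrafish", 3)]:
            nm, labels = self.build_species(seed, [f"{sp}_g0", f"{sp}_g1"])
            data[sp] = (nm, labels)
            tables[sp] = [f"{sp}_g0", f"{sp}_g1"]
        out = conserved_marker_heatmap(data, pd.DataFrame(tables))
        for sp, hm in out.items():
            assert hm.iloc[0].idxmax() == "k0.x"
            assert hm.iloc[1].idxmax() == "k1.x"
            assert ((hm >= 0) & (hm <= 1)).all().all()

    def test_unresolvable_ortholog_dropped_with_warning(self):
        nm, labels = self.build_species(4, ["gA", "gB"])
        table = pd.DataFrame({"human": ["gA", "missing"], "mouse": ["gA", "gB"]})
        with pytest.warns(UserWarning, match="dropped"):
            out = conserved_marker_heatmap(
                {"human": (nm, labels), "mouse": (nm, labels)}, table
            )
        assert len(out["human"]) == 1
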