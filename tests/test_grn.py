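import numpy as np
import pandas as pd
import pytest

from stemnet.clustering import ClusterAssignment
from stemnet.datamodel import DEFAULT_CONTROL, ExpressionMatrix, GeneAnnotation, Network
from stemnet.grn import (
    InferenceConfig,
    InferenceError,
    consensus,
    default_cell_contexts,
    importance_scores,
    infer_single_network,
    run_rtpstar,
    run_timepoint_networks,
    trim_edges,
)
from stemnet.synthetic import expression_from_truth, make_truth

from conftest import timecourse_expression


def _flat_expr(values: dict, n: int):
    """One pseudo cell type, n samples."""
    samples = [f"s{i}" for i in range(n)]
    v = pd.DataFrame(values, index=samples).T
    meta = pd.DataFrame(
        {"cell_type": "X", "replicate": range(1, n + 1), "time_hours": np.nan},
        index=samples,
    )
    return ExpressionMatrix(v, meta)


class TestImportanceScores:
    def test_planted_regulator_wins(self):
        rng = np.random.default_rng(0)
        wins = 0
        for seed in range(40):
            r1 = rng.uniform(1, 10, 20)
            expr = _flat_expr(
                {
                    "R1": r1,
                    "R2": rng.uniform(1, 10, 20),
                    "R3": rng.uniform(1, 10, 20),
                    "T": r1,  # identical to R1
                },
                20,
            )
            w = importance_scores("T", ["R1", "R2", "R3"], expr, n_trees=50, seed=seed)
            wins += w.idxmax() == "R1"
        assert wins >= 38  # >= 95% of seeds

    def test_constant_target_gives_zero_weights(self):
        expr = _flat_expr({"R": [1.0, 2, 3, 4], "T": [5.0, 5, 5, 5]}, 4)
        w = importance_scores("T", ["R"], expr, n_trees=10, seed=0)
        assert (w == 0).all()

    def test_single_regulator_normalizes_to_one(self):
        expr = _flat_expr({"R": [1.0, 2, 3, 4], "T": [2.0, 4, 6, 8]}, 4)
        w = importance_scores("T", ["R"], expr, n_trees=10, seed=0)
        assert w["R"] == pytest.approx(1.0)

    def test_too_few_samples_raises(self):
        expr = _flat_expr({"R": [1.0, 2], "T": [2.0, 4]}, 2)
        with pytest.raises(InferenceError):
            importance_scores("T", ["R"], expr, n_trees=10, seed=0)


class TestTrimEdges:
    def _edges(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "regulator": [f"R{i}" for i in range(n)],
                "target": [f"T{i}" for i in range(n)],
                "weight": rng.uniform(0, 1, n),
            }
        )

    def test_keeps_top_ceil_factor_times_ntf(self):
        kept = trim_edges(self._edges(10), n_tf=1, trim_factor=5)
        assert len(kept) == 5
        assert kept["weight"].min() >= self._edges(10)["weight"].sort_values().iloc[-5]

    def test_caps_at_available(self):
        assert len(trim_edges(self._edges(3), n_tf=2, trim_factor=5)) == 3

    def test_monotone_in_ntf(self):
        e = self._edges(40)
        for n_tf in range(1, 7):
            a = len(trim_edges(e, n_tf=n_tf))
            b = len(trim_edges(e, n_tf=2 * n_tf))
            assert b >= a

    def test_deterministic_tie_break(self):
        e = pd.DataFrame(
            {
                "regulator": ["B", "A", "C"],
                "target": ["x", "x", "x"],
                "weight": [0.5, 0.5, 0.5],
            }
        )
        kept = trim_edges(e, n_tf=1, trim_factor=2)  # keep 2 of 3 tied
        assert list(kept["regulator"]) == ["A", "B"]


class TestConsensus:
    def _net(self, pairs):
        return Network(
            pd.DataFrame(
                {"regulator": [p[0] for p in pairs], "target": [p[1] for p in pairs]}
            )
        )

    def test_at_least_one_third_retained(self):
        nets = [self._net([("A", "B")])] * 34 + [self._net([("C", "D")])] * 66
        out = consensus(nets, maxprop=1 / 3)
        assert ("A", "B") in out.pairs()
        sup = out.edges.set_index(["regulator", "target"])["support"]
        assert sup[("A", "B")] == pytest.approx(0.34)

    def test_below_forty_five_percent_dropped(self):
        nets = [self._net([("A", "B")])] * 44 + [self._net([("C", "D")])] * 56
        out = consensus(nets, maxprop=0.45)
        assert ("A", "B") not in out.pairs()

    def test_boundary_support_exactly_maxprop_retained(self):
        nets = [self._net([("A", "B")])] * 45 + [self._net([("C", "D")])] * 55
        out = consensus(nets, maxprop=0.45)
        assert ("A", "B") in out.pairs()

    def test_all_networks_gives_support_one(self):
        out = consensus([self._net([("A", "B")])] * 10, maxprop=1.0)
        assert out.edges.loc[0, "support"] == 1.0

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            consensus([], maxprop=0.5)

    def test_monotone_in_maxprop(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(8)]
        nets = []
        for _ in range(20):
            pairs = set()
            while len(pairs) < 6:
                r, t = rng.choice(genes, 2, replace=False)
                pairs.add((r, t))
            nets.append(self._net(sorted(pairs)))
        prev = None
        for mp in [0.1, 0.3, 0.5, 0.7, 0.9]:
            cur = consensus(nets, mp).pairs()
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestInferSingleNetwork:
    def test_planted_edge_in_shared_cluster(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(1, 10, 12)
        expr = _flat_expr({"A": a, "B": 2 * a + rng.normal(0, 0.1, 12)}, 12)
        ann = GeneAnnotation({"A": True, "B": False})
        clusters = ClusterAssignment(pd.Series([0, 0], index=["A", "B"]), 1, 0)
        cfg = InferenceConfig(numiter=1, n_trees=30, seed=0)
        net = infer_single_network(expr, ann, clusters, cfg)
        assert ("A", "B") in net.pairs()

    def test_separated_clusters_give_empty_network(self):
        expr = _flat_expr({"A": [1.0, 2, 3, 4], "B": [2.0, 4, 6, 8]}, 4)
        ann = GeneAnnotation({"A": True, "B": True})
        clusters = ClusterAssignment(pd.Series([0, 1], index=["A", "B"]), 2, 0)
        net = infer_single_network(expr, ann, clusters, InferenceConfig(n_trees=10))
        assert len(net) == 0

    def test_no_tfs_gives_empty_network(self):
        expr = _flat_expr({"A": [1.0, 2, 3, 4], "B": [2.0, 4, 6, 8]}, 4)
        ann = GeneAnnotation({"A": False, "B": False})
        clusters = ClusterAssignment(pd.Series([0, 0], index=["A", "B"]), 1, 0)
        net = infer_single_network(expr, ann, clusters, InferenceConfig(n_trees=10))
        assert len(net) == 0

    def test_cluster_label_permutation_leaves_network_unchanged(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(1, 10, 10)
        b = rng.uniform(1, 10, 10)
        expr = _flat_expr(
            {"A": a, "B": 2 * a, "C": b, "D": 3 * b + rng.normal(0, 0.1, 10)}, 10
        )
        ann = GeneAnnotation({"A": True, "C": True, "B": False, "D": False})
        cfg = InferenceConfig(numiter=1, n_trees=20, seed=0)
        lab1 = ClusterAssignment(pd.Series([0, 0, 1, 1], index=["A", "B", "C", "D"]), 2, 0)
        lab2 = ClusterAssignment(pd.Series([1, 1, 0, 0], index=["A", "B", "C", "D"]), 2, 0)
        n1 = infer_single_network(expr, ann, lab1, cfg).sorted()
        n2 = infer_single_network(expr, ann, lab2, cfg).sorted()
        assert n1.pairs() == n2.pairs()


@pytest.fixture(scope="module")
def study():
    truth = make_truth(n_genes=20, tf_frac=0.25, n_edges=6, seed=8)
    expr, enrichment, _ = expression_from_truth(truth, 3, 0.25, seed=8)
    return truth, expr, enrichment


class TestRunRtpstar:
    def _cfg(self, numiter=4):
        return InferenceConfig(numiter=numiter, n_trees=20, seed=17)

    def test_deterministic_under_fixed_seed(self, study):
        truth, expr, enrichment = study
        ctx = default_cell_contexts(expr, DEFAULT_CONTROL)
        a = run_rtpstar(expr, truth.annotation, self._cfg(), ctx, enrichment)
        b = run_rtpstar(expr, truth.annotation, self._cfg(), ctx, enrichment)
        pd.testing.assert_frame_equal(a.edges, b.edges)

    def test_single_iteration_support_is_one(self, study):
        truth, expr, enrichment = study
        ctx = default_cell_contexts(expr, DEFAULT_CONTROL)
        net = run_rtpstar(expr, truth.annotation, self._cfg(numiter=1), ctx, enrichment)
        assert len(net) > 0
        assert (net.edges["support"] == 1.0).all()

    def test_every_cell_contributes_labeled_edges(self, study):
        truth, expr, enrichment = study
        ctx = default_cell_contexts(expr, DEFAULT_CONTROL)
        net = run_rtpstar(expr, truth.annotation, self._cfg(), ctx, enrichment)
        assert set(net.edges["cell_type"]) <= set(ctx)
        assert len(set(net.edges["cell_type"])) >= 4

    def test_regulators_are_always_tfs(self, study):
        truth, expr, enrichment = study
        ctx = default_cell_contexts(expr, DEFAULT_CONTROL)
        net = run_rtpstar(expr, truth.annotation, self._cfg(), ctx, enrichment)
        assert all(truth.annotation.is_tf[r] for r in net.edges["regulator"])


class TestTimepointNetworks:
    def test_one_network_per_time_point(self):
        truth = make_truth(n_genes=12, tf_frac=0.25, n_edges=4, seed=4)
        from stemnet.synthetic import timecourse_from_truth

        tc = timecourse_from_truth(
            truth, t_points=[96.0, 104.0, 112.0], n_replicates=3, noise_sd=0.1, seed=4
        )
        expr = timecourse_expression(tc)
        cfg = InferenceConfig(numiter=3, maxprop=0.45, n_trees=15, seed=0)
        nets = run_timepoint_networks(expr, truth.annotation, cfg)
        assert sorted(nets) == [96.0, 104.0, 112.0]

    def test_temporal_signal_appears_only_in_its_time_point(self):
        # target tracks the regulator only in the last time point's replicates
        rng = np.random.default_rng(12)
        n_rep, genes = 6, [f"g{i}" for i in range(12)]
        tps = [96.0, 104.0, 112.0]
        cols, ids, meta_rows = [], [], []
        reg_vals = {}
        for t in tps:
            reg = rng.uniform(1, 10, n_rep)
            reg_vals[t] = reg
            for r in range(n_rep):
                ids.append(f"t{t:g}_r{r+1}")
                col = rng.uniform(1, 10, 12)
                col[0] = reg[r]  # g0 = regulator
                if t == tps[-1]:
                    col[1] = 2 * reg[r] + rng.normal(0, 0.05)
                meta_rows.append({"cell_type": "SCN", "replicate": r + 1, "time_hours": t})
                cols.append(col)
        values = pd.DataFrame(np.column_stack(cols), index=genes, columns=ids)
        meta = pd.DataFrame(meta_rows, index=ids)
        expr = ExpressionMatrix(values, meta)
        ann = GeneAnnotation({g: g in ("g0", "g2") for g in genes})
        # single cluster + tight trimming: an edge survives a restart only by
        # out-ranking the other candidates on importance
        cfg = InferenceConfig(
            numiter=8, maxprop=0.45, n_trees=25, trim_factor=2.0, seed=3, k=1
        )
        nets = run_timepoint_networks(expr, ann, cfg)
        assert ("g0", "g1") in nets[112.0].pairs()
        assert ("g0", "g1") not in nets[96.0].pairs()

    def test_edges_labeled_with_all_coenriched_cells(self):
        from stemnet.grn import _label_edges_by_enrichment
        from stemnet.datamodel import EnrichmentTable

        net = Network(pd.DataFrame({"regulator": ["A"], "target": ["B"]}))
        t = pd.DataFrame(
            {
                "q_value": [0.01, 0.01],
                "fc_vs_control": [5.0, 5.0],
                "enriched_cells": [frozenset({"QC", "Xyl"}), frozenset({"QC", "Xyl", "CEI"})],
                "ubiquity_class": ["specific", "specific"],
            },
            index=["A", "B"],
        )
        out = _label_edges_by_enrichment(net, EnrichmentTable(t))
        assert sorted(out.edges["cell_type"]) == ["QC", "Xyl"]
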