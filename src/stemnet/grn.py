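"""Consensus GRN inference over k-means clustering restarts.

The pipeline mirrors the regression-tree consensus scheme used for root
stem-cell networks: genes are clustered on their spatial profile, a
tree-ensemble regression (GENIE3-style importance scoring) is run within
each cluster with that cluster's transcription factors as candidate
regulators, edges are trimmed in proportion to the TF count, and only edges
appearing in at least a ``maxprop`` fraction of clustering restarts survive
into the consensus.  Per-cell networks (inferred from each stem cell's own
replicates plus the niche control) are finally combined by union with
cell-type edge labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor

from .clustering import ClusterAssignment, choose_default_k, cluster_genes, mean_profile
from .datamodel import EnrichmentTable, ExpressionMatrix, GeneAnnotation, Network

log = logging.getLogger(__name__)

#: Minimum samples for a tree-ensemble fit.
MIN_SAMPLES = 3


class InferenceError(RuntimeError):
    pass


@dataclass
class InferenceConfig:
    """Parameters of one consensus-inference run.

    numiter
        Clustering restarts voted over (100 in the reference runs).
    maxprop
        Minimum fraction of restart networks an edge must appear in
        (1/3 for the spatial niche network, 0.45 for time-point networks).
    n_trees
        Trees per target in the importance ensemble.
    trim_factor
        Edges kept per cluster = ceil(trim_factor * number of cluster TFs);
        more TFs, more edges kept.
    """

    numiter: int = 100
    maxprop: float = 1.0 / 3.0
    n_trees: int = 1000
    trim_factor: float = 5.0
    seed: int = 0
    standardize: bool = True
    k: int | None = None  # None -> choose_default_k(n_genes)

    def __post_init__(self) -> None:
        if self.numiter < 1:
            raise ValueError("numiter must be >= 1")
        if not (0 < self.maxprop <= 1):
            raise ValueError("maxprop must lie in (0, 1]")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.trim_factor <= 0:
            raise ValueError("trim_factor must be > 0")


#: maxprop used for time-point-specific networks.
TIMEPOINT_MAXPROP = 0.45


def _subseed(seed: int, *idx: int) -> int:
    """Stable per-component seed below 2**31."""
    h = np.uint64(seed & 0x7FFFFFFF)
    for i in idx:
        h = (h * np.uint64(1000003) + np.uint64(i + 1)) % np.uint64(2**31 - 1)
    return int(h)


def importance_scores(
    target: str,
    regulators: list[str],
    expr: ExpressionMatrix | pd.DataFrame,
    n_trees: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Tree-ensemble importance of each candidate regulator for one target.

    An extra-trees regression ensemble predicts the target's unit-variance-
    scaled expression from the regulators; the returned weights are the
    summed variance-reduction importances, normalized to sum to one when any
    split occurred.  A zero-variance target yields all-zero weights.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if target in regulators:
        raise ValueError("target must not be among its candidate regulators")
    if values.shape[1] < MIN_SAMPLES:
        raise InferenceError(
            f"need >= {MIN_SAMPLES} samples for importance scoring, "
            f"got {values.shape[1]}"
        )
    y = values.loc[target].to_numpy(dtype=float)
    zeros = pd.Series(0.0, index=list(regulators))
    if len(regulators) == 0:
        return zeros
    sd = y.std()
    if sd == 0:
        return zeros
    y = y / sd  # unit-variance target: importances comparable across targets
    X = values.loc[list(regulators)].to_numpy(dtype=float).T
    est = ExtraTreesRegressor(
        n_estimators=int(n_trees),
        max_features="sqrt",
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    est.fit(X, y)
    imp = est.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=list(regulators))


def trim_edges(weighted_edges: pd.DataFrame, n_tf: int, trim_factor: float = 5.0) -> pd.DataFrame:
    """Keep the top ceil(trim_factor * n_tf) edges by weight.

    Ties at the cutoff break lexicographically on (regulator, target), so the
    result is deterministic whatever the input order.
    """
    if n_tf < 1:
        raise ValueError("n_tf must be >= 1")
    keep = math.ceil(trim_factor * n_tf)
    e = weighted_edges.sort_values(
        ["weight", "regulator", "target"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return e.head(keep).reset_index(drop=True)


def infer_single_network(
    expr: ExpressionMatrix,
    annotation: GeneAnnotation,
    clusters: ClusterAssignment,
    cfg: InferenceConfig,
    seed: int | None = None,
) -> Network:
    """One unsigned network from one clustering.

    Within each cluster every gene is a candidate target and the cluster's
    transcription factors are the candidate regulators; edges are therefore
    intra-cluster only.  Per-cluster edges are trimmed in proportion to the
    cluster's TF count.  Clusters without any TF contribute no edges.
    """
    seed = cfg.seed if seed is None else seed
    frames = []
    for ci, members in clusters.clusters().items():
        tfs = [g for g in members if annotation.is_tf.get(g, False)]
        if not tfs:
            log.debug("cluster %d has no TF; skipped", ci)
            continue
        rows = []
        for tj, target in enumerate(members):
            regs = [t for t in tfs if t != target]
            if not regs:
                continue
            w = importance_scores(
                target, regs, expr, n_trees=cfg.n_trees, seed=_subseed(seed, ci, tj)
            )
            for reg, weight in w.items():
                if weight > 0:
                    rows.append({"regulator": reg, "target": target, "weight": weight})
        if rows:
            cluster_edges = pd.DataFrame(rows)
            frames.append(trim_edges(cluster_edges, len(tfs), cfg.trim_factor))
    if not frames:
        return Network()
    return Network(pd.concat(frames, ignore_index=True))


def consensus(networks: list[Network], maxprop: float) -> Network:
    """Retain edges present in at least a ``maxprop`` fraction of networks.

    Edge identity is the (regulator, target) pair; the retained edge carries
    support = presence fraction and weight = mean weight over the networks
    containing it.  The boundary counts as present (support == maxprop is
    retained, matching the "at least" semantics).
    """
    if not networks:
        raise ValueError("consensus over an empty network list")
    n = len(networks)
    counts: dict[tuple[str, str], int] = {}
    weights: dict[tuple[str, str], float] = {}
    for net in networks:
        for _, row in net.edges.iterrows():
            key = (row["regulator"], row["target"])
            counts[key] = counts.get(key, 0) + 1
            weights[key] = weights.get(key, 0.0) + row["weight"]
    rows = []
    for key in sorted(counts):
        support = counts[key] / n
        if support + 1e-12 >= maxprop:
            rows.append(
                {
                    "regulator": key[0],
                    "target": key[1],
                    "weight": weights[key] / counts[key],
                    "support": support,
                }
            )
    return Network(pd.DataFrame(rows)) if rows else Network()


def _consensus_over_restarts(
    expr_sub: ExpressionMatrix,
    profile: pd.DataFrame,
    annotation: GeneAnnotation,
    cfg: InferenceConfig,
) -> Network:
    k = cfg.k if cfg.k is not None else choose_default_k(profile.shape[0])
    nets = []
    for i in range(cfg.numiter):
        cl = cluster_genes(profile, k, seed=cfg.seed + i, standardize=cfg.standardize)
        nets.append(infer_single_network(expr_sub, annotation, cl, cfg, seed=cfg.seed + i))
    return consensus(nets, cfg.maxprop)


def run_rtpstar(
    expr: ExpressionMatrix,
    annotation: GeneAnnotation,
    cfg: InferenceConfig,
    cell_contexts: dict[str, list[str]],
    enrichment: EnrichmentTable,
) -> Network:
    """Full spatial pipeline: one consensus network per stem cell, then union.

    ``cell_contexts`` maps each stem-cell type to the sample ids used for its
    inference (that cell's replicates plus the niche-control replicates).
    Each cell's gene universe is the set of genes enriched in that cell
    (multi-cell genes enter each of their cells); clustering always uses the
    full spatial mean profile restricted to that universe.
    """
    profile_all = mean_profile(expr, by="cell_type")
    combined = []
    for cell in cell_contexts:
        genes = [g for g in enrichment.genes_for_cell(cell) if g in expr.values.index]
        if len(genes) < 2:
            log.warning("cell %s: <2 enriched genes, skipped", cell)
            continue
        sub = expr.subset(genes=genes, sample_ids=cell_contexts[cell])
        net = _consensus_over_restarts(sub, profile_all.loc[genes], annotation, cfg)
        if len(net):
            combined.append(net.with_cell_type(cell).edges)
        log.info("cell %s: %d consensus edges from %d genes", cell, len(net), len(genes))
    if not combined:
        return Network()
    return Network(pd.concat(combined, ignore_index=True)).sorted()


def run_timepoint_networks(
    expr: ExpressionMatrix,
    annotation: GeneAnnotation,
    cfg: InferenceConfig,
    gene_subset: list[str] | None = None,
    enrichment: EnrichmentTable | None = None,
    cluster_profile: pd.DataFrame | None = None,
) -> dict[float, Network]:
    """One consensus network per time point of a replicated time course.

    ``gene_subset`` restricts inference (e.g. to perturbation-responsive,
    stem-cell-enriched genes).  Clustering uses ``cluster_profile`` when
    given (e.g. the spatial mean-per-cell-type profile); otherwise the mean
    per time point over the whole course.  Edges are labeled with every cell
    type in which both endpoints are enriched, when an enrichment table is
    supplied.  Time points with too few replicates are skipped with a
    warning.
    """
    if cfg.maxprop != TIMEPOINT_MAXPROP:
        log.info("time-point networks typically use maxprop=%.2f", TIMEPOINT_MAXPROP)
    genes = list(gene_subset) if gene_subset is not None else expr.gene_ids
    genes = [g for g in genes if g in expr.values.index]
    if cluster_profile is None:
        cluster_profile = mean_profile(expr, by="time_hours")
    profile = cluster_profile.loc[genes]
    out: dict[float, Network] = {}
    for t in sorted(expr.samples["time_hours"].dropna().unique()):
        ids = expr.samples_of(time_point=t)
        if len(ids) < MIN_SAMPLES:
            log.warning("time point %s h: only %d replicates, skipped", t, len(ids))
            continue
        sub = expr.subset(genes=genes, sample_ids=ids)
        net = _consensus_over_restarts(sub, profile, annotation, cfg)
        if enrichment is not None and len(net):
            net = _label_edges_by_enrichment(net, enrichment)
        out[float(t)] = net
    return out


def _label_edges_by_enrichment(net: Network, enrichment: EnrichmentTable) -> Network:
    rows = []
    for _, row in net.edges.iterrows():
        try:
            cells = enrichment.enriched_cells(row["regulator"]) & enrichment.enriched_cells(
                row["target"]
            )
        except KeyError:
            cells = frozenset()
        if cells:
            for c in sorted(cells):
                r = row.to_dict()
                r["cell_type"] = c
                rows.append(r)
        else:
            rows.append(row.to_dict())
    return Network(pd.DataFrame(rows)).sorted()


def default_cell_contexts(
    expr: ExpressionMatrix, control_cell: str, stem_cells: list[str] | None = None
) -> dict[str, list[str]]:
    """Per-cell sample contexts: the cell's replicates plus the control's."""
    if stem_cells is None:
        stem_cells = [c for c in expr.cell_types if c != control_cell]
    ctrl = expr.samples_of(control_cell)
    return {c: expr.samples_of(c) + ctrl for c in stem_cells}
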