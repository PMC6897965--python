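"""Directed network-motif counting, the Network Motif Score (NMS), motif
enrichment against random graphs, and edge validation against perturbation
data.

Five motif classes are scored: feed-forward loop, feedback (3-cycle),
diamond, bi-fan, and the multilayer (4-node) cascade.  Matches are counted
as non-induced subgraph monomorphisms modulo pattern automorphism, i.e. each
distinct placed instance counts once, extra edges among the matched nodes do
not disqualify it.  The NMS of a gene is the sum over motifs of its
participation count normalized by the maximum count of any gene in that
motif, so it ranges from 0 to the number of motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import isomorphism

from .datamodel import Network


def _pattern(edges) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return g


#: The five scored motif classes.
DEFAULT_MOTIFS: dict[str, nx.DiGraph] = {
    "feed_forward": _pattern([("A", "B"), ("A", "C"), ("B", "C")]),
    "feedback": _pattern([("A", "B"), ("B", "C"), ("C", "A")]),
    "diamond": _pattern([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]),
    "bi_fan": _pattern([("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]),
    "multilayer": _pattern([("A", "B"), ("B", "C"), ("C", "D")]),
}


@dataclass
class MotifCatalog:
    """Named small directed patterns (weakly connected, 3-4 nodes, no loops).

    User-overridable so alternative shapes for the feedback or multilayer
    classes can be supplied.
    """

    patterns: dict[str, nx.DiGraph] = field(
        default_factory=lambda: dict(DEFAULT_MOTIFS)
    )

    def __post_init__(self) -> None:
        for name, p in self.patterns.items():
            if not 3 <= p.number_of_nodes() <= 4:
                raise ValueError(f"motif {name!r} must have 3-4 nodes")
            if not nx.is_weakly_connected(p):
                raise ValueError(f"motif {name!r} must be weakly connected")
            if any(u == v for u, v in p.edges):
                raise ValueError(f"motif {name!r} has a self-loop")

    @property
    def names(self) -> list[str]:
        return list(self.patterns)


def motif_instances(graph: nx.DiGraph, pattern: nx.DiGraph) -> list[frozenset]:
    """Distinct placed instances of ``pattern`` in ``graph``.

    Each instance is identified by its image edge set (a frozenset of
    directed edges), which collapses the pattern's automorphisms so that
    every placement is counted exactly once.
    """
    matcher = isomorphism.DiGraphMatcher(graph, pattern)
    seen: set[frozenset] = set()
    for mapping in matcher.subgraph_monomorphisms_iter():
        inv = {v: k for k, v in mapping.items()}
        image = frozenset((inv[u], inv[v]) for u, v in pattern.edges)
        seen.add(image)
    return list(seen)


def count_motifs(net: Network, catalog: MotifCatalog | None = None) -> pd.DataFrame:
    """Per-gene participation counts in each motif class.

    Returns a genes x motifs integer DataFrame covering every gene of the
    network (isolated genes get zero rows).
    """
    catalog = catalog or MotifCatalog()
    g = net.to_digraph()
    genes = sorted(g.nodes)
    counts = pd.DataFrame(0, index=genes, columns=catalog.names, dtype=int)
    for name, pattern in catalog.patterns.items():
        for image in motif_instances(g, pattern):
            nodes = {u for e in image for u in e}
            for node in nodes:
                counts.at[node, name] += 1
    return counts


def motif_totals(net: Network, catalog: MotifCatalog | None = None) -> pd.Series:
    """Total number of distinct instances per motif class."""
    catalog = catalog or MotifCatalog()
    g = net.to_digraph()
    return pd.Series(
        {name: len(motif_instances(g, p)) for name, p in catalog.patterns.items()}
    )


def nms(counts: pd.DataFrame) -> pd.DataFrame:
    """Network Motif Score: per-motif counts normalized to [0, 1] and summed.

    Per motif, a gene's normalized score is its count divided by the maximum
    count of any gene in that motif (0/0 -> 0); the NMS column is the sum
    over motifs, in [0, number of motifs].
    """
    if counts.empty:
        raise ValueError("empty motif count table")
    maxima = counts.max(axis=0)
    norm = counts / maxima.replace(0, 1)
    out = norm.copy()
    out["nms"] = norm.sum(axis=1)
    return out


class MotifEnrichment(NamedTuple):
    observed_total: int
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float


def motif_enrichment(
    net: Network,
    catalog: MotifCatalog | None = None,
    n_random: int = 100,
    seed: int = 0,
    null: str = "gnm",
) -> pd.DataFrame:
    """Motif totals versus random networks of the same size.

    The null is Erdos-Renyi G(n, m) with the observed node and edge counts
    (``null="gnm"``), or degree-preserving rewiring (``null="rewire"``).
    ``empirical_p`` is the fraction of null totals >= observed; ``z`` is NaN
    when a motif is absent from both the observed network and every null.
    """
    import warnings

    if len(net) == 0:
        raise ValueError("network has no edges")
    if n_random < 10:
        warnings.warn("n_random < 10 gives a very coarse null", stacklevel=2)
    catalog = catalog or MotifCatalog()
    g = net.to_digraph()
    n, m = g.number_of_nodes(), g.number_of_edges()
    observed = motif_totals(net, catalog)
    rng = np.random.default_rng(seed)
    null_totals = {name: [] for name in catalog.names}
    for _ in range(n_random):
        s = int(rng.integers(0, 2**31 - 1))
        if null == "gnm":
            rg = nx.gnm_random_graph(n, m, seed=s, directed=True)
        elif null == "rewire":
            rg = g.copy()
            nx.directed_edge_swap(rg, nswap=max(m, 1), max_tries=100 * m + 100, seed=s)
        else:
            raise ValueError(f"unknown null model {null!r}")
        for name, pattern in catalog.patterns.items():
            null_totals[name].append(len(motif_instances(rg, pattern)))
    rows = []
    for name in catalog.names:
        arr = np.array(null_totals[name], dtype=float)
        obs = int(observed[name])
        mean, sd = arr.mean(), arr.std(ddof=1)
        if obs == 0 and (arr == 0).all():
            z = np.nan
        elif sd == 0:
            z = np.nan if obs == mean else np.inf * np.sign(obs - mean)
        else:
            z = (obs - mean) / sd
        p = float((arr >= obs).mean())
        rows.append(
            MotifEnrichment(obs, float(mean), float(sd), float(z), p)._asdict()
            | {"motif": name}
        )
    return pd.DataFrame(rows).set_index("motif")


def degree_stats(net: Network) -> pd.DataFrame:
    """Unique-edge indegree and outdegree per gene."""
    g = net.to_digraph()
    return pd.DataFrame(
        {
            "indegree": pd.Series(dict(g.in_degree), dtype=int),
            "outdegree": pd.Series(dict(g.out_degree), dtype=int),
        }
    ).sort_index()


class EdgeValidation(NamedTuple):
    frac_de: float
    frac_correct_cell: float
    frac_correct_sign: float
    n_targets: int
    n_edges: int


def score_edge_validation(
    predicted: Network, observed_de: pd.DataFrame, focal_gene: str
) -> EdgeValidation:
    """Score predicted direct targets of a focal gene against perturbation data.

    ``observed_de`` has columns (gene, cell_type, is_de, direction) from a
    knockout experiment, ``direction`` being the sign of the expression
    change in the mutant.  Three fractions are reported: targets DE in any
    cell, edges whose target is DE in the edge's own labeled cell, and --
    among correct-cell edges with a predicted sign -- signs consistent with
    a knockout (predicted activation => target down in the mutant).
    Fractions with empty denominators are NaN.
    """
    if focal_gene not in predicted.genes:
        raise ValueError(f"focal gene {focal_gene!r} absent from the network")
    edges = predicted.out_edges(focal_gene)
    targets = sorted(set(edges["target"]))
    de_any = set(observed_de.loc[observed_de["is_de"].astype(bool), "gene"])
    frac_de = (
        np.mean([t in de_any for t in targets]) if targets else float("nan")
    )
    de_map = {
        (row["gene"], row["cell_type"]): (bool(row["is_de"]), int(np.sign(row["direction"])))
        for _, row in observed_de.iterrows()
    }
    correct_cell = []
    sign_checks = []
    for _, row in edges.iterrows():
        key = (row["target"], row["cell_type"])
        is_de, direction = de_map.get(key, (False, 0))
        correct_cell.append(is_de)
        if is_de and row["sign"] != 0 and direction != 0:
            # knockout of an activator lowers the target, of a repressor raises it
            sign_checks.append(int(row["sign"]) == -direction)
    frac_cell = float(np.mean(correct_cell)) if len(edges) else float("nan")
    frac_sign = float(np.mean(sign_checks)) if sign_checks else float("nan")
    return EdgeValidation(float(frac_de), frac_cell, frac_sign, len(targets), len(edges))
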