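import numpy as np
import pandas as pd
import pytest

from stemnet.datamodel import ExpressionMatrix, GeneAnnotation, Network
from stemnet.signs import TimeCourse


@pytest.fixture
def small_expr():
    """3 cell types x 2 replicates, 4 genes, deterministic values."""
    rng = np.random.default_rng(7)
    cells = ["QC", "Xyl", "NSC"]
    samples = [f"{c}_r{j}" for c in cells for j in (1, 2)]
    values = pd.DataFrame(
        rng.uniform(1, 30, size=(4, 6)),
        index=["g1", "g2", "g3", "g4"],
        columns=samples,
    )
    meta = pd.DataFrame(
        {
            "cell_type": [c for c in cells for _ in (1, 2)],
            "replicate": [1, 2] * 3,
            "time_hours": np.nan,
        },
        index=samples,
    )
    return ExpressionMatrix(values, meta)


@pytest.fixture
def ffl_bifan_network():
    """6-gene worked network: one feed-forward loop + one bi-fan.

    FFL on (A, B, C); bi-fan with sources (D, E) and targets (B, F).
    """
    return Network(
        pd.DataFrame(
            {
                "regulator": ["A", "A", "B", "D", "D", "E", "E"],
                "target": ["B", "C", "C", "B", "F", "B", "F"],
            }
        )
    )


@pytest.fixture
def annotation4():
    return GeneAnnotation({"g1": True, "g2": True, "g3": False, "g4": False})


def timecourse_expression(tc: TimeCourse, cell_type: str = "SCN") -> ExpressionMatrix:
    """Reshape a replicated TimeCourse into an ExpressionMatrix with time metadata."""
    vals = tc.values
    n_g, n_t, n_r = vals.shape
    ids, cols = [], []
    for j, t in enumerate(tc.time_points):
        for r in range(n_r):
            ids.append(f"t{t:g}_r{r + 1}")
            cols.append(vals[:, j, r])
    values = pd.DataFrame(np.column_stack(cols), index=tc.gene_ids, columns=ids)
    meta = pd.DataFrame(
        {
            "cell_type": cell_type,
            "replicate": [r + 1 for _ in tc.time_points for r in range(n_r)],
            "time_hours": [t for t in tc.time_points for _ in range(n_r)],
        },
        index=ids,
    )
    return ExpressionMatrix(values, meta)


def brute_force_motif_instances(graph, pattern):
    """Independent oracle: exhaustive enumeration over node permutations.

    Distinct instances are identified by their image edge sets, the same
    identity the production code uses, but the search itself is a plain
    permutation scan.
    """
    from itertools import permutations

    pnodes = list(pattern.nodes)
    pedges = list(pattern.edges)
    gnodes = list(graph.nodes)
    found = set()
    for combo in permutations(gnodes, len(pnodes)):
        mapping = dict(zip(pnodes, combo))
        if all(graph.has_edge(mapping[u], mapping[v]) for u, v in pedges):
            found.add(frozenset((mapping[u], mapping[v]) for u, v in pedges))
    return found
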