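"""Enrichment and ubiquity classification of stem-cell expression profiles.

A gene is stem-cell-enriched when it passes the control gate (q-value < 0.06
and fold-change > 2 versus the non-stem-cell control; the permissive q cutoff
follows the behaviour of canonical niche markers).  Among enriched genes,
per-cell-type membership uses fold-change > 2 against the other stem cells,
with genes expressed at comparable levels in several cell types assigned to
all of them.  Genes enriched in >= 4 of the 6 stem-cell types are
"ubiquitous", in 1-3 "specific", otherwise "not_enriched".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    EnrichmentTable,
    ExpressionMatrix,
    ubiquity_class_for,
)

#: Control-gate defaults.
Q_THRESHOLD = 0.06
FC_THRESHOLD = 2.0


class ConfigurationError(ValueError):
    pass


def cell_type_means(expr: ExpressionMatrix, cell_types=None) -> pd.DataFrame:
    """Mean expression per gene per cell type (over that cell's replicates)."""
    if cell_types is None:
        cell_types = expr.cell_types
    cols = {}
    for c in cell_types:
        ids = expr.samples_of(c)
        if not ids:
            raise ConfigurationError(f"cell type {c!r} has no samples")
        cols[c] = expr.values[ids].mean(axis=1)
    return pd.DataFrame(cols)


def classify_enrichment(
    expr: ExpressionMatrix,
    de: pd.DataFrame,
    control_cell: str,
    q_threshold: float = Q_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
    pseudocount: float = 1.0,
    denominator: str = "max",
) -> EnrichmentTable:
    """Classify every gene's stem-cell enrichment and ubiquity.

    Parameters
    ----------
    expr : ExpressionMatrix
        Must contain the control cell type plus >= 2 stem cell types.
    de : pandas.DataFrame
        Index = gene ids (covering ``expr``), columns ``q_value`` and
        ``fc_vs_control`` from the upstream differential-expression run
        (q-values are consumed, never computed here).
    control_cell : str
        Name of the non-stem-cell control population.
    pseudocount : float
        Added to every cell-type mean before ratios; guards dropout genes
        with zero means.  FPKM scale, default 1.0.
    denominator : {"max", "mean"}
        Per-cell fold-change denominator: the strongest competing cell type
        (conservative, default) or the mean of the other cell types.

    Notes
    -----
    Membership rule per gene that passes the control gate: cell ``c`` is
    enriched when mean(c) exceeds ``fc_threshold`` times the denominator
    over the other stem cells.  If no single cell passes, the gene is
    "equally expressed" across its top cells: every cell within a factor
    ``fc_threshold`` of the maximum is enriched, provided there are >= 2
    such cells.
    """
    if denominator not in ("max", "mean"):
        raise ConfigurationError(f"unknown denominator {denominator!r}")
    if control_cell not in expr.cell_types:
        raise ConfigurationError(f"control cell type {control_cell!r} not in data")
    stem_cells = [c for c in expr.cell_types if c != control_cell]
    if len(stem_cells) < 2:
        raise ConfigurationError("need >= 2 stem cell types besides the control")
    missing = [g for g in expr.gene_ids if g not in de.index]
    if missing:
        raise ConfigurationError(f"DE table missing genes: {missing[:5]}")

    means = cell_type_means(expr, stem_cells) + pseudocount
    arr = means.to_numpy()
    n_cells = arr.shape[1]

    rows = []
    fc_cols = np.zeros_like(arr)
    for i, gene in enumerate(expr.gene_ids):
        q = float(de.at[gene, "q_value"])
        fc0 = float(de.at[gene, "fc_vs_control"])
        m = arr[i]
        # fold-change of each cell vs the other stem cells
        fcs = np.empty(n_cells)
        for j in range(n_cells):
            others = np.delete(m, j)
            denom = others.max() if denominator == "max" else others.mean()
            fcs[j] = m[j] / denom
        fc_cols[i] = fcs
        if q < q_threshold and fc0 > fc_threshold:
            enriched = {stem_cells[j] for j in range(n_cells) if fcs[j] > fc_threshold}
            if not enriched:
                # equally-expressed rule: all cells within a factor
                # fc_threshold of the top cell share the enrichment
                close = {
                    stem_cells[j]
                    for j in range(n_cells)
                    if m[j] >= m.max() / fc_threshold
                }
                if len(close) >= 2:
                    enriched = close
        else:
            enriched = set()
        rows.append(
            {
                "q_value": q,
                "fc_vs_control": fc0,
                "enriched_cells": frozenset(enriched),
                "ubiquity_class": ubiquity_class_for(len(enriched)),
            }
        )
    table = pd.DataFrame(rows, index=list(expr.gene_ids))
    fc_df = pd.DataFrame(fc_cols, index=list(expr.gene_ids), columns=stem_cells)
    return EnrichmentTable(table, fc_df)
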