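"""Core domain containers for stem-cell niche expression data and networks.

Expression values are on the FPKM scale (non-negative, heteroskedastic).
Samples carry (cell_type, replicate, time_hours) metadata so the same
container serves the spatial stem-cell profile (6 stem-cell types + 1
non-stem control, 3-4 replicates each) and the 7-point / 8-hour time course.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six stem-cell populations profiled in the root stem cell niche, plus
#: the non-stem-cell control sorted from the surrounding meristem.
DEFAULT_CELL_TYPES = ("QC", "CEI", "CSC", "Epi", "Xyl", "Phlo")
DEFAULT_CONTROL = "NSC"

UBIQUITOUS = "ubiquitous"
SPECIFIC = "specific"
NOT_ENRICHED = "not_enriched"

#: A gene is called stem-cell-ubiquitous when enriched in at least this many
#: of the six stem-cell types.
UBIQUITY_MIN_CELLS = 4


class ValidationError(ValueError):
    """Input data violate a container invariant."""


class FormatError(ValueError):
    """A file is structurally malformed (e.g. duplicate gene ids)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with per-sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative expression values, genes in rows (index = gene ids),
        samples in columns.
    samples : pandas.DataFrame
        One row per sample, index matching ``values.columns``, with columns
        ``cell_type`` (str), ``replicate`` (positive int) and optionally
        ``time_hours`` (non-negative float; NaN when not a time course).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if not v.index.is_unique:
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be non-negative")
        meta = self.samples
        if list(meta.index) != list(v.columns):
            raise ValidationError("sample metadata does not match value columns")
        for col in ("cell_type", "replicate"):
            if col not in meta.columns:
                raise ValidationError(f"sample metadata missing column {col!r}")
        if "time_hours" not in meta.columns:
            self.samples = meta = meta.assign(time_hours=np.nan)
        if (pd.to_numeric(meta["replicate"]) <= 0).any():
            raise ValidationError("replicate numbers must be positive")
        key = meta[["cell_type", "replicate", "time_hours"]]
        if key.duplicated().any():
            raise ValidationError(
                "sample records must be unique on (cell_type, replicate, time_hours)"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["cell_type"]:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def samples_of(self, cell_types=None, time_point=None) -> list[str]:
        """Sample ids matching the given cell types and/or time point."""
        meta = self.samples
        mask = pd.Series(True, index=meta.index)
        if cell_types is not None:
            if isinstance(cell_types, str):
                cell_types = [cell_types]
            mask &= meta["cell_type"].isin(list(cell_types))
        if time_point is not None:
            mask &= meta["time_hours"] == time_point
        return list(meta.index[mask])

    def subset(self, genes=None, sample_ids=None) -> "ExpressionMatrix":
        """Row/column subset preserving order of the selectors."""
        v = self.values
        if genes is not None:
            missing = [g for g in genes if g not in v.index]
            if missing:
                raise ValidationError(f"unknown gene ids: {missing[:5]}")
            v = v.loc[list(genes)]
        meta = self.samples
        if sample_ids is not None:
            v = v[list(sample_ids)]
            meta = meta.loc[list(sample_ids)]
        return ExpressionMatrix(v, meta)


@dataclass
class GeneAnnotation:
    """Transcription-factor flag per gene; regulators are restricted to TFs."""

    is_tf: dict[str, bool] = field(default_factory=dict)

    @classmethod
    def from_tf_list(cls, tfs, all_genes=None) -> "GeneAnnotation":
        tfset = set(tfs)
        genes = list(all_genes) if all_genes is not None else sorted(tfset)
        return cls({g: (g in tfset) for g in genes})

    def tfs(self) -> list[str]:
        return [g for g, t in self.is_tf.items() if t]

    def __contains__(self, gene: str) -> bool:
        return gene in self.is_tf


NETWORK_COLUMNS = ["regulator", "target", "weight", "sign", "cell_type", "support"]


@dataclass
class Network:
    """Directed, weighted edge list with optional sign and cell-type label.

    ``sign`` is +1 (activation), -1 (repression) or 0 (unknown).  ``support``
    is the fraction of consensus restarts the edge appeared in, in [0, 1].
    At most one edge per (regulator, target, cell_type) triple; no self-edges.
    """

    edges: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.edges is None:
            self.edges = pd.DataFrame(columns=NETWORK_COLUMNS)
        e = self.edges
        for col, default in (
            ("weight", 1.0),
            ("sign", 0),
            ("cell_type", ""),
            ("support", 1.0),
        ):
            if col not in e.columns:
                e[col] = default
        e = e[NETWORK_COLUMNS].copy()
        e["regulator"] = e["regulator"].astype(str)
        e["target"] = e["target"].astype(str)
        e["cell_type"] = e["cell_type"].fillna("").astype(str)
        e["sign"] = e["sign"].astype(int)
        e["weight"] = e["weight"].astype(float)
        e["support"] = e["support"].astype(float)
        e = e.reset_index(drop=True)
        if (e["regulator"] == e["target"]).any():
            raise ValidationError("self-edges are not allowed")
        if not e["sign"].isin([-1, 0, 1]).all():
            raise ValidationError("edge sign must be one of {-1, 0, +1}")
        if (e["weight"] < 0).any():
            raise ValidationError("edge weights must be >= 0")
        if ((e["support"] < 0) | (e["support"] > 1)).any():
            raise ValidationError("edge support must lie in [0, 1]")
        if e.duplicated(subset=["regulator", "target", "cell_type"]).any():
            raise ValidationError(
                "at most one edge per (regulator, target, cell_type)"
            )
        self.edges = e

    @classmethod
    def from_edges(cls, edges) -> "Network":
        """Build from an iterable of dicts or (regulator, target[, ...]) tuples."""
        rows = []
        for item in edges:
            if isinstance(item, dict):
                rows.append(item)
            else:
                row = dict(zip(NETWORK_COLUMNS, item))
                rows.append(row)
        return cls(pd.DataFrame(rows, columns=NETWORK_COLUMNS if not rows else None))

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> set[str]:
        return set(self.edges["regulator"]) | set(self.edges["target"])

    def pairs(self) -> set[tuple[str, str]]:
        """Unique (regulator, target) pairs, cell labels collapsed."""
        return set(zip(self.edges["regulator"], self.edges["target"]))

    def out_edges(self, gene: str) -> pd.DataFrame:
        return self.edges[self.edges["regulator"] == gene]

    def with_cell_type(self, cell_type: str) -> "Network":
        e = self.edges.copy()
        e["cell_type"] = cell_type
        return Network(e)

    def to_digraph(self):
        """Collapse cell labels into a simple networkx DiGraph."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.pairs())
        return g

    def sorted(self) -> "Network":
        e = self.edges.sort_values(
            ["regulator", "target", "cell_type"], kind="mergesort"
        ).reset_index(drop=True)
        return Network(e)


@dataclass
class EnrichmentTable:
    """Per-gene enrichment calls against the non-stem control and per cell type.

    ``table`` has one row per gene (index = gene id) with columns
    ``q_value``, ``fc_vs_control``, ``enriched_cells`` (frozenset of cell
    types) and ``ubiquity_class``; fold-changes per cell type live in
    ``fc_per_celltype`` (genes x cell types DataFrame).
    """

    table: pd.DataFrame
    fc_per_celltype: pd.DataFrame = None

    def __post_init__(self) -> None:
        t = self.table
        need = {"q_value", "fc_vs_control", "enriched_cells", "ubiquity_class"}
        if not need <= set(t.columns):
            raise ValidationError(f"enrichment table missing {need - set(t.columns)}")
        for gene, row in t.iterrows():
            cells = row["enriched_cells"]
            n = len(cells)
            expected = (
                UBIQUITOUS
                if n >= UBIQUITY_MIN_CELLS
                else SPECIFIC
                if n >= 1
                else NOT_ENRICHED
            )
            if row["ubiquity_class"] != expected:
                raise ValidationError(
                    f"gene {gene}: ubiquity_class {row['ubiquity_class']!r} "
                    f"inconsistent with {n} enriched cells"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def genes_for_cell(self, cell_type: str) -> list[str]:
        t = self.table
        return [g for g in t.index if cell_type in t.at[g, "enriched_cells"]]

    def enriched_cells(self, gene: str) -> frozenset:
        return self.table.at[gene, "enriched_cells"]

    def ubiquity_class(self, gene: str) -> str:
        return self.table.at[gene, "ubiquity_class"]


def ubiquity_class_for(n_enriched: int) -> str:
    """Map a count of enriched stem-cell types to its ubiquity class."""
    if n_enriched >= UBIQUITY_MIN_CELLS:
        return UBIQUITOUS
    if n_enriched >= 1:
        return SPECIFIC
    return NOT_ENRICHED
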