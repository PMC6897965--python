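"""Readers and writers: expression TSV/CSV, sample metadata, networks (TSV/SIF),
TF lists, enrichment tables, time courses.

All delimited files are UTF-8 with '.' decimals.  Lines starting with '#' are
treated as comments; writers emit a provenance comment header (tool version
and seed) which readers skip.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    EnrichmentTable,
    ExpressionMatrix,
    FormatError,
    GeneAnnotation,
    Network,
    NETWORK_COLUMNS,
    ValidationError,
    ubiquity_class_for,
)

SIF_RELATIONS = {1: "activates", -1: "represses", 0: "regulates"}
SIF_SIGNS = {v: k for k, v in SIF_RELATIONS.items()}


def _header(seed=None) -> str:
    line = f"# stemnet v{__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path, metadata_path) -> ExpressionMatrix:
    """Read a genes x samples table and its sample metadata.

    The first column of ``path`` holds gene ids; remaining columns are
    samples.  ``metadata_path`` is a TSV/CSV with columns ``sample_id``,
    ``cell_type``, ``replicate`` and optionally ``time_hours``, one row per
    sample column, in any order (matched on sample_id).
    """
    values = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    if not values.index.is_unique:
        dup = values.index[values.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in {path}")
    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path), comment="#")
    if "sample_id" not in meta.columns:
        raise FormatError(f"{metadata_path} lacks a sample_id column")
    meta = meta.set_index("sample_id")
    missing = [s for s in values.columns if s not in meta.index]
    extra = [s for s in meta.index if s not in values.columns]
    if missing or extra:
        raise ValidationError(
            f"metadata/sample mismatch (missing {missing[:3]}, extra {extra[:3]})"
        )
    meta = meta.loc[list(values.columns)]
    values.index = values.index.astype(str)
    return ExpressionMatrix(values.astype(float), meta)


def write_expression(expr: ExpressionMatrix, path, metadata_path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        expr.values.to_csv(fh, sep=_sep_for(path), index_label="gene_id")
    with open(metadata_path, "w") as fh:
        fh.write(_header(seed))
        expr.samples.to_csv(fh, sep=_sep_for(metadata_path), index_label="sample_id")


def read_tf_list(path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_tf_list(tfs, path) -> None:
    Path(path).write_text(_header() + "\n".join(tfs) + "\n")


def write_network(net: Network, path, dialect: str = "tsv", seed=None) -> None:
    """Write a network as TSV (full columns) or Cytoscape SIF."""
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write(_header(seed))
            net.edges.to_csv(fh, sep="\t", index=False)
    elif dialect == "sif":
        with open(path, "w") as fh:
            for _, row in net.edges.iterrows():
                rel = SIF_RELATIONS[int(row["sign"])]
                fh.write(f"{row['regulator']}\t{rel}\t{row['target']}\n")
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")


def read_network(path, dialect: str = "tsv") -> Network:
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        for col in NETWORK_COLUMNS:
            if col in ("regulator", "target") and col not in df.columns:
                raise FormatError(f"network file {path} lacks column {col!r}")
        if "cell_type" in df.columns:
            df["cell_type"] = df["cell_type"].fillna("")
        return Network(df)
    if dialect == "sif":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            reg, rel, target = line.split("\t")
            rows.append(
                {"regulator": reg, "target": target, "sign": SIF_SIGNS[rel]}
            )
        return Network(pd.DataFrame(rows))
    raise ValueError(f"unknown network dialect {dialect!r}")


def write_enrichment(enr: EnrichmentTable, path, seed=None) -> None:
    t = enr.table.copy()
    t["enriched_cells"] = [",".join(sorted(c)) for c in t["enriched_cells"]]
    with open(path, "w") as fh:
        fh.write(_header(seed))
        t.to_csv(fh, sep="\t", index_label="gene_id")


def read_enrichment(path) -> EnrichmentTable:
    t = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
    cells = []
    for s in t["enriched_cells"].fillna(""):
        cells.append(frozenset(x for x in str(s).split(",") if x))
    t["enriched_cells"] = cells
    t["ubiquity_class"] = [ubiquity_class_for(len(c)) for c in cells]
    t.index = t.index.astype(str)
    return EnrichmentTable(t)


def read_annotation(tf_path, all_genes=None) -> GeneAnnotation:
    return GeneAnnotation.from_tf_list(read_tf_list(tf_path), all_genes)


def write_timecourse(tc, path, seed=None) -> None:
    """Write a TimeCourse as long-format TSV (gene_id, time_hours, replicate, value)."""
    rows = []
    vals = tc.values  # (genes, times, reps)
    for i, g in enumerate(tc.gene_ids):
        for j, t in enumerate(tc.time_points):
            for r in range(vals.shape[2]):
                rows.append((g, t, r + 1, vals[i, j, r]))
    df = pd.DataFrame(rows, columns=["gene_id", "time_hours", "replicate", "value"])
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep="\t", index=False)


def read_timecourse(path):
    from .signs import TimeCourse

    df = pd.read_csv(path, sep="\t", comment="#")
    genes = list(dict.fromkeys(df["gene_id"].astype(str)))
    times = np.array(sorted(df["time_hours"].unique()), dtype=float)
    reps = sorted(df["replicate"].unique())
    vals = np.full((len(genes), len(times), len(reps)), np.nan)
    gi = {g: i for i, g in enumerate(genes)}
    ti = {t: j for j, t in enumerate(times)}
    ri = {r: k for k, r in enumerate(reps)}
    for _, row in df.iterrows():
        vals[gi[str(row["gene_id"])], ti[row["time_hours"]], ri[row["replicate"]]] = row[
            "value"
        ]
    return TimeCourse(vals, genes, times)


def atomic_write(path, text: str) -> None:
    """Write text to path atomically (temp file + rename)."""
    tmp = f"{path}.tmp{os.getpid()}"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)
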