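"""Pseudo-random k-means partitioning of genes on their spatial expression profile.

Genes are clustered on their mean expression per cell type.  A single random
initialization per restart is deliberate: the restart-to-restart variability
of k-means is the randomness the consensus step votes over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .datamodel import ExpressionMatrix
from .enrichment import cell_type_means


@dataclass
class ClusterAssignment:
    """Gene -> cluster index in [0, k) for one k-means restart."""

    labels: pd.Series
    k: int
    seed: int

    def __post_init__(self) -> None:
        lab = self.labels.astype(int)
        if ((lab < 0) | (lab >= self.k)).any():
            raise ValueError("cluster index out of range")
        self.labels = lab

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def clusters(self) -> dict[int, list[str]]:
        return {c: self.members(c) for c in sorted(self.labels.unique())}

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("cluster").rename_axis("gene_id").reset_index()


def mean_profile(expr: ExpressionMatrix, by: str = "cell_type") -> pd.DataFrame:
    """Genes x groups matrix of replicate means.

    ``by`` is "cell_type" (spatial profile, the default clustering space) or
    "time_hours" (mean per time point, for time-course-only data).
    """
    if by == "cell_type":
        return cell_type_means(expr)
    if by == "time_hours":
        cols = {}
        for t in sorted(expr.samples["time_hours"].dropna().unique()):
            ids = expr.samples_of(time_point=t)
            cols[t] = expr.values[ids].mean(axis=1)
        if not cols:
            raise ValueError("no time_hours metadata to group on")
        return pd.DataFrame(cols)
    raise ValueError(f"unknown grouping {by!r}")


def standardize_profile(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score; constant rows map to zeros.

    Clustering should group expression *shapes* across cell types, not
    magnitudes, so each gene's profile is centered and scaled first.
    """
    arr = profile.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (arr - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    return pd.DataFrame(out, index=profile.index, columns=profile.columns)


def choose_default_k(n_genes: int) -> int:
    """Default cluster count: max(2, ceil(sqrt(n/2))), capped at n_genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return min(n_genes, max(2, math.ceil(math.sqrt(n_genes / 2))))


def cluster_genes(
    profile: pd.DataFrame,
    k: int,
    seed: int,
    standardize: bool = True,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterAssignment:
    """One k-means restart (Lloyd, Euclidean, single random initialization).

    Deterministic given (profile, k, seed).  Empty clusters are re-seeded by
    the implementation with the point farthest from its centroid, keeping k
    fixed.
    """
    n = profile.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    x = standardize_profile(profile) if standardize else profile
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=1,
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed) % (2**31),
    )
    labels = km.fit_predict(x.to_numpy(dtype=float))
    return ClusterAssignment(pd.Series(labels, index=profile.index), k, seed)
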