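"""Edge-sign (activation/repression) inference from a time course.

A first-order-Markov reading of the dynamics: regulation acts with one time
step of delay, so an edge's sign is the sign of the Pearson correlation
between the regulator at t_i and the target at t_{i+1} over consecutive
time-point pairs, with a small dead band so that noise does not generate
spurious signs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import Network

log = logging.getLogger(__name__)

#: Correlation dead band: |r| <= TAU leaves the sign undetermined (0).
TAU = 0.1


@dataclass
class TimeCourse:
    """Genes x time points (x replicates) of non-negative expression.

    ``values`` has shape (n_genes, n_times) or (n_genes, n_times, n_reps);
    ``time_points`` are strictly increasing hours.
    """

    values: np.ndarray
    gene_ids: list[str]
    time_points: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 2:
            v = v[:, :, None]
        if v.ndim != 3:
            raise ValueError("values must be 2-D or 3-D")
        t = np.asarray(self.time_points, dtype=float)
        if len(t) < 2:
            raise ValueError("need >= 2 time points")
        if not (np.diff(t) > 0).all():
            raise ValueError("time points must be strictly increasing")
        if v.shape[0] != len(self.gene_ids) or v.shape[1] != len(t):
            raise ValueError("values shape inconsistent with gene/time labels")
        self.values = v
        self.time_points = t
        self.gene_ids = [str(g) for g in self.gene_ids]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def mean_values(self) -> pd.DataFrame:
        """Replicate-mean series, genes x time points."""
        return pd.DataFrame(
            np.nanmean(self.values, axis=2), index=self.gene_ids, columns=self.time_points
        )

    def series(self, gene: str) -> np.ndarray:
        return self.mean_values().loc[gene].to_numpy()


def infer_edge_sign(
    regulator_series: np.ndarray, target_series: np.ndarray, tau: float = TAU
) -> int:
    """Sign of a single edge from aligned series: lag-1 Pearson correlation.

    Returns +1 (activation) when r > tau, -1 (repression) when r < -tau,
    else 0.  Zero-variance series are undetermined (0).
    """
    x = np.asarray(regulator_series, dtype=float)[:-1]
    y = np.asarray(target_series, dtype=float)[1:]
    if len(x) < 1 or len(x) != len(y):
        raise ValueError("series must align on >= 2 time points")
    if x.std() == 0 or y.std() == 0:
        return 0
    r = float(np.corrcoef(x, y)[0, 1])
    if r > tau:
        return 1
    if r < -tau:
        return -1
    return 0


def sign_network(net: Network, tc: TimeCourse, tau: float = TAU) -> Network:
    """Assign a sign to every edge from replicate-mean time series.

    Edges whose endpoint genes are absent from the time course keep sign 0
    (logged).  Weights and support are untouched.
    """
    if len(net) == 0:
        return net
    means = tc.mean_values()
    signs = []
    missing = set()
    for _, row in net.edges.iterrows():
        reg, tgt = row["regulator"], row["target"]
        if reg not in means.index or tgt not in means.index:
            missing.add(reg if reg not in means.index else tgt)
            signs.append(0)
            continue
        signs.append(
            infer_edge_sign(means.loc[reg].to_numpy(), means.loc[tgt].to_numpy(), tau)
        )
    if missing:
        log.warning("%d genes absent from time course; their edges keep sign 0", len(missing))
    e = net.edges.copy()
    e["sign"] = signs
    return Network(e)
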