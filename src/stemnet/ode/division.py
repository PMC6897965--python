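"""Division-timing classification from modeled expression dynamics.

The focal regulator's modeled expression is compared between consecutive
time-window endpoints; a fold-change above the threshold (default 1.5)
calls a significant increase or decrease.  A significant decrease across
the final window pair marks the cell as dividing (the regulator's
disappearance precedes division); otherwise a final significant increase is
an "increase" call and anything else "quiescent" (stable or high).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import OdeModelSpec, Trajectory

log = logging.getLogger(__name__)

DIVISION = "division"
QUIESCENT = "quiescent"
INCREASE = "increase"

FC_THRESHOLD = 1.5


def window_endpoint_values(
    traj: Trajectory, focal_gene: str, window_bounds
) -> pd.DataFrame:
    """Focal-gene expression per cell at each window boundary time."""
    rows = {}
    for name in traj.species:
        gene, cell = name.split("@", 1)
        if gene == focal_gene:
            rows[cell] = [float(traj.at(t)[name]) for t in window_bounds]
    if not rows:
        raise ValueError(f"focal gene {focal_gene!r} not present in any cell")
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(window_bounds))


def classify_division(
    traj: Trajectory,
    focal_gene: str,
    windows=None,
    fc_threshold: float = FC_THRESHOLD,
    pseudocount: float = 1e-6,
    spec: OdeModelSpec | None = None,
) -> pd.DataFrame:
    """Per-cell division-timing calls from window-endpoint fold-changes.

    ``windows`` is the sequence of boundary times (defaults to the spec's
    window bounds when given).  Returns one row per cell with the
    fold-change and direction of every consecutive endpoint pair and a
    final ``call`` column in {division, quiescent, increase}.
    """
    if windows is None:
        if spec is None:
            raise ValueError("need windows or spec")
        windows = spec.window_bounds
    windows = list(windows)
    if len(windows) < 2:
        raise ValueError("need >= 2 window boundary times")
    vals = window_endpoint_values(traj, focal_gene, windows)
    records = []
    for cell, row in vals.iterrows():
        rec = {"cell": cell}
        last_dir, last_sig = 0, False
        for a, b in zip(windows[:-1], windows[1:]):
            va, vb = row[a], row[b]
            if min(va, vb) <= 0:
                log.info("cell %s: zero baseline at %s-%s h, pseudocount applied", cell, a, b)
            va, vb = va + pseudocount, vb + pseudocount
            fc = max(va, vb) / min(va, vb)
            direction = int(np.sign(vb - va))
            sig = fc > fc_threshold
            rec[f"fc_{a:g}_{b:g}"] = fc
            rec[f"dir_{a:g}_{b:g}"] = direction
            rec[f"sig_{a:g}_{b:g}"] = sig
            last_dir, last_sig = direction, sig
        if last_sig and last_dir < 0:
            rec["call"] = DIVISION
        elif last_sig and last_dir > 0:
            rec["call"] = INCREASE
        else:
            rec["call"] = QUIESCENT
        records.append(rec)
    return pd.DataFrame(records).set_index("cell")
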