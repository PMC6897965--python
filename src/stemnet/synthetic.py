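"""Planted-truth synthetic data emulating stem-cell-niche expression studies.

The generator mirrors the structure of the profiling designs this toolkit
targets: six stem-cell populations plus a non-stem control with 3-4
replicates each, and a 7-point time course sampled every 8 h from day 4 to
day 6 with 2-3 replicates.  Expression noise is multiplicative log-normal
(FPKM-scale data are positive and heteroskedastic) and mean-corrected, so
expected values do not depend on the noise level.

Every quantity is planted and recorded: the signed network (edges only from
TFs), per-cell enrichment (>= 2x mean separation, so the enrichment
classifier is exercised exactly at its fold-change-2 threshold), kinetic
parameters for the ODE dynamics, and optionally exact counts of seeded
motif instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_CELL_TYPES,
    DEFAULT_CONTROL,
    EnrichmentTable,
    GeneAnnotation,
    Network,
    ubiquity_class_for,
)
from .signs import TimeCourse

#: Mean FPKM in enriched vs non-enriched cells (10x separation; the
#: classifier's own threshold is 2x).
MEAN_ENRICHED = 20.0
MEAN_BASELINE = 2.0

#: Regulator-deviation exponent embedding regulator->target dependencies.
COUPLING = 1.0

#: Motif templates as (n_tf_roles, edge list over role indices); roles below
#: n_tf_roles must be TFs.
_MOTIF_TEMPLATES = {
    "feed_forward": (2, [(0, 1), (0, 2), (1, 2)]),
    "feedback": (3, [(0, 1), (1, 2), (2, 0)]),
    "diamond": (3, [(0, 1), (0, 2), (1, 3), (2, 3)]),
    "bi_fan": (2, [(0, 2), (0, 3), (1, 2), (1, 3)]),
    "multilayer": (3, [(0, 1), (1, 2), (2, 3)]),
}


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic study."""

    network: Network
    annotation: GeneAnnotation
    enrichment_plan: dict[str, frozenset]
    beta: dict[str, float]
    delta: dict[str, float]
    K: dict[tuple[str, str], float]
    hill: dict[tuple[str, str], float]
    x0: dict[str, float]
    cells: tuple[str, ...] = DEFAULT_CELL_TYPES
    control_cell: str = DEFAULT_CONTROL
    noise_sd: float = 0.25
    seed: int = 0
    seeded_motifs: dict[str, int] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.beta)

    @property
    def tf_ids(self) -> list[str]:
        return self.annotation.tfs()

    def edge_signs(self) -> dict[tuple[str, str], int]:
        return {
            (r, t): int(s)
            for r, t, s in zip(
                self.network.edges["regulator"],
                self.network.edges["target"],
                self.network.edges["sign"],
            )
        }


def make_truth(
    n_genes: int = 50,
    tf_frac: float = 0.2,
    n_edges: int = 15,
    motif_seeding: dict[str, int] | None = None,
    seed: int = 0,
    p_ubiquitous: float = 0.2,
) -> SyntheticTruth:
    """Plant a signed regulator network with cell assignments and kinetics.

    ``motif_seeding`` maps motif names to counts of instances built from
    dedicated node groups, so the truth contains at least that many placed
    instances of each requested motif.  Remaining edges (up to ``n_edges``
    total) are random TF -> gene edges.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_tf = max(1, round(tf_frac * n_genes))
    if n_edges > n_tf * (n_genes - 1):
        raise ValueError("requested more edges than TF x target pairs")
    tfs = [f"TF{i + 1:02d}" for i in range(n_tf)]
    others = [f"G{i + 1:03d}" for i in range(n_genes - n_tf)]
    genes = tfs + others

    edges: list[tuple[str, str]] = []
    edge_set: set[tuple[str, str]] = set()
    free_tf = list(tfs)
    free_other = list(others)
    seeded = dict(motif_seeding or {})
    for name, count in seeded.items():
        n_tf_roles, template = _MOTIF_TEMPLATES[name]
        n_roles = max(max(p) for p in template) + 1
        for _ in range(count):
            if len(free_tf) < n_tf_roles or len(free_other) < n_roles - n_tf_roles:
                raise ValueError(f"not enough fresh genes to seed motif {name!r}")
            nodes = [free_tf.pop(0) for _ in range(n_tf_roles)] + [
                free_other.pop(0) for _ in range(n_roles - n_tf_roles)
            ]
            for a, b in template:
                e = (nodes[a], nodes[b])
                if e not in edge_set:
                    edge_set.add(e)
                    edges.append(e)
    if len(edges) > n_edges:
        raise ValueError("motif seeding requires more edges than n_edges allows")

    candidates = [
        (r, t) for r in tfs for t in genes if r != t and (r, t) not in edge_set
    ]
    rng.shuffle(candidates)
    # favour fresh targets so most genes have a single planted regulator
    candidates.sort(key=lambda e: sum(1 for _, t in edge_set if t == e[1]))
    for e in candidates:
        if len(edges) >= n_edges:
            break
        edge_set.add(e)
        edges.append(e)

    signs = rng.choice([-1, 1], size=len(edges))
    net = Network(
        pd.DataFrame(
            {
                "regulator": [e[0] for e in edges],
                "target": [e[1] for e in edges],
                "weight": 1.0,
                "sign": signs,
            }
        )
    )

    cells = DEFAULT_CELL_TYPES
    plan: dict[str, frozenset] = {}
    for g in genes:
        if rng.random() < p_ubiquitous:
            size = int(rng.integers(4, len(cells) + 1))
        else:
            size = int(rng.integers(1, 4))
        plan[g] = frozenset(rng.choice(cells, size=size, replace=False))
    # a regulated gene is expressed where its regulator is: targets inherit
    # the regulator's cell set (small mutations keep profiles realistic but
    # correlated, which is what the spatial clustering stage groups on)
    for r, t in edges:
        inherited = set(plan[r])
        if rng.random() < 0.3:
            c = cells[int(rng.integers(0, len(cells)))]
            if c in inherited and len(inherited) > 1:
                inherited.discard(c)
            else:
                inherited.add(c)
        plan[t] = frozenset(inherited)
    for r, t in edges:  # guarantee co-enrichment somewhere
        if not (plan[r] & plan[t]):
            extra = sorted(plan[r])[int(rng.integers(0, len(plan[r])))]
            plan[t] = plan[t] | {extra}

    beta = {g: float(rng.uniform(5.0, 20.0)) for g in genes}
    delta = {g: float(rng.uniform(0.05, 0.2)) for g in genes}
    K = {}
    hill = {}
    for r, t in edges:
        K[(r, t)] = 0.5 * beta[r] / delta[r]
        hill[(r, t)] = 2.0
    has_parent = {t for _, t in edges}
    sign_of = {e: int(s) for e, s in zip(edges, signs)}
    x0 = {}
    flip = 0
    for g in genes:
        ss = beta[g] / delta[g]
        if g in has_parent:
            x0[g] = 0.5 * ss
        else:
            # alternate low/high starts so source genes traverse both
            # directions and lag-1 dependencies are informative
            x0[g] = 0.05 * ss if flip % 2 == 0 else 1.8 * ss
            flip += 1
    # regulated genes start at their regulated quasi-steady state given the
    # regulators' initial levels, so their subsequent movement follows the
    # regulator's transient in the direction the edge sign dictates (the
    # lag-1 dependency the sign-inference stage reads); fixed-point passes
    # handle chains and cycles
    parents: dict[str, list[tuple[str, str]]] = {}
    for e in edges:
        parents.setdefault(e[1], []).append(e)
    for _ in range(6):
        for t, plist in parents.items():
            prod = beta[t]
            for e in plist:
                xr, k, h = x0[e[0]], K[e], hill[e]
                hterm = xr**h / (k**h + xr**h)
                prod *= hterm if sign_of[e] >= 0 else (1.0 - hterm)
            x0[t] = prod / delta[t]
    annotation = GeneAnnotation({g: g in set(tfs) for g in genes})
    return SyntheticTruth(
        network=net,
        annotation=annotation,
        enrichment_plan=plan,
        beta=beta,
        delta=delta,
        K=K,
        hill=hill,
        x0=x0,
        seed=seed,
        seeded_motifs=seeded,
    )


def _lognormal_factor(rng, sd: float, size) -> np.ndarray:
    """exp(sd*Z - sd^2/2): unit-mean multiplicative noise."""
    z = rng.standard_normal(size)
    return np.exp(sd * z - 0.5 * sd * sd), z


def expression_from_truth(
    truth: SyntheticTruth, n_replicates: int = 4, noise_sd: float = 0.25, seed: int = 0
):
    """Replicate steady-state expression respecting the planted enrichment.

    Returns ``(expr, enrichment, de)``: the expression matrix (6 stem cells
    + control, ``n_replicates`` each), the planted EnrichmentTable, and the
    gene-level differential-expression summary (q-value, fold-change vs
    control) the enrichment classifier consumes.

    Regulator-target dependencies are embedded multiplicatively: a target's
    replicate value scales with exp(sign * coupling * sd * Z_regulator), a
    monotone function of the regulator's own noise deviation, so
    tree-ensemble importance scoring can recover planted edges.  All noise
    factors are mean-corrected (expected value independent of noise_sd).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, seed, 1)))
    cells = list(truth.cells) + [truth.control_cell]
    genes = truth.gene_ids
    gi = {g: i for i, g in enumerate(genes)}
    n_g, n_c = len(genes), len(cells)

    mu = np.full((n_g, n_c), MEAN_BASELINE)
    for g, cset in truth.enrichment_plan.items():
        for c in cset:
            mu[gi[g], cells.index(c)] = MEAN_ENRICHED

    z = rng.standard_normal((n_g, n_c, n_replicates))
    logx = np.log(mu)[:, :, None] + noise_sd * z - 0.5 * noise_sd**2
    # regulator deviations modulate targets (mean-corrected per edge)
    for _, row in truth.network.edges.iterrows():
        r, t, s = gi[row["regulator"]], gi[row["target"]], int(row["sign"])
        s = s if s != 0 else 1
        logx[t] += s * COUPLING * noise_sd * z[r] - 0.5 * (COUPLING * noise_sd) ** 2
    values = np.exp(logx)

    sample_ids = [f"{c}_r{j + 1}" for c in cells for j in range(n_replicates)]
    mat = values.reshape(n_g, n_c * n_replicates)
    vdf = pd.DataFrame(mat, index=genes, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "cell_type": [c for c in cells for _ in range(n_replicates)],
            "replicate": [j + 1 for _ in cells for j in range(n_replicates)],
            "time_hours": np.nan,
        },
        index=sample_ids,
    )
    from .datamodel import ExpressionMatrix

    expr = ExpressionMatrix(vdf, meta)

    table = pd.DataFrame(
        {
            "q_value": 0.001,
            "fc_vs_control": MEAN_ENRICHED / MEAN_BASELINE,
            "enriched_cells": [truth.enrichment_plan[g] for g in genes],
            "ubiquity_class": [
                ubiquity_class_for(len(truth.enrichment_plan[g])) for g in genes
            ],
        },
        index=genes,
    )
    enrichment = EnrichmentTable(table)
    de = table[["q_value", "fc_vs_control"]].copy()
    return expr, enrichment, de


def ode_spec_from_truth(truth: SyntheticTruth, t_span=(96.0, 144.0)):
    """Single-compartment ODE model of the truth network with theta*."""
    from .ode import ParameterSet, build_model

    spec = build_model(
        [truth.network],
        cells=["root"],
        window_bounds=tuple(t_span),
        species=[(g, "root") for g in truth.gene_ids],
    )
    values = {}
    for g in truth.gene_ids:
        values[f"beta[{g}@root]"] = truth.beta[g]
        values[f"delta[{g}@root]"] = truth.delta[g]
        values[f"x0[{g}@root]"] = truth.x0[g]
    for (r, t), k in truth.K.items():
        values[f"K[{r}->{t}@root]"] = k
        values[f"h[{r}->{t}@root]"] = truth.hill[(r, t)]
    params = ParameterSet(values, spec.parameter_names())
    return spec, params


def timecourse_from_truth(
    truth: SyntheticTruth,
    t_points=None,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeCourse:
    """Integrate the planted kinetics and sample a replicated time course.

    Defaults to the 7-point design: every 8 h from 96 h (day 4) to 144 h
    (day 6).  Noise is mean-corrected multiplicative log-normal.  Planted
    signs manifest as lag-1 dependencies (activated targets track their
    regulator's transient with delay; repressed targets move against it).
    """
    from .ode import simulate

    if t_points is None:
        t_points = np.arange(96.0, 144.0 + 1e-9, 8.0)
    t_points = np.asarray(t_points, dtype=float)
    spec, params = ode_spec_from_truth(truth, (t_points[0], t_points[-1]))
    traj = simulate(spec, params, t_points, rtol=1e-8, atol=1e-10)
    base = traj.values  # (genes, times)
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, seed, 2)))
    if noise_sd > 0:
        factor, _ = _lognormal_factor(
            rng, noise_sd, (base.shape[0], base.shape[1], n_replicates)
        )
    else:
        factor = np.ones((base.shape[0], base.shape[1], n_replicates))
    values = base[:, :, None] * factor
    return TimeCourse(values, truth.gene_ids, t_points)
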