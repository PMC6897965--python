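"""Least-squares fitting of model parameters by LHS-seeded simulated annealing.

The search follows the reference procedure: Latin hypercube sampling draws
50 initial parameter vectors, each is refined by simulated annealing on the
sum-of-squares residual, and the final estimate is the elementwise average
of the 10 refined vectors with the lowest error.  The annealing budget is a
fixed number of objective evaluations per start (hardware-independent
determinism), not wall-clock time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .model import OdeModelSpec, ParameterSet, species_name
from .simulate import CompiledModel

#: Defaults of the reference procedure.
DEFAULT_N_STARTS = 50
DEFAULT_TOP = 10
DEFAULT_BUDGET = 2000


def _observed_frame(observed) -> pd.DataFrame:
    """Normalize observations to tidy (species, time_hours, value)."""
    df = observed.copy()
    if "species" not in df.columns:
        df["species"] = [
            species_name(g, c) for g, c in zip(df["gene"], df["cell"])
        ]
    return df[["species", "time_hours", "value"]]


def residual(
    params: ParameterSet,
    spec: OdeModelSpec,
    observed: pd.DataFrame,
    _cm: CompiledModel | None = None,
) -> float:
    """Sum of squared differences between simulated and observed values.

    ``observed`` is tidy with columns (gene, cell, time_hours, value) or
    (species, time_hours, value); observed species must exist in the model.
    """
    cm = _cm or CompiledModel(spec)
    obs = _observed_frame(observed)
    sp_index = {s: i for i, s in enumerate(spec.species_names)}
    missing = set(obs["species"]) - set(sp_index)
    if missing:
        raise ValueError(f"observed species not in model: {sorted(missing)[:5]}")
    times = np.sort(obs["time_hours"].unique())
    sim = cm.trajectory(params.vector(), times)
    tpos = {t: j for j, t in enumerate(times)}
    sse = 0.0
    for _, row in obs.iterrows():
        diff = sim[sp_index[row["species"]], tpos[row["time_hours"]]] - row["value"]
        sse += diff * diff
    return float(sse)


class _Objective:
    """Residual as a function of the free-parameter subvector."""

    def __init__(self, spec, observed, params0: ParameterSet, free: list[str]):
        self.cm = CompiledModel(spec)
        self.order = params0.order
        self.theta = params0.vector()
        self.free_idx = np.array([self.order.index(n) for n in free])
        obs = _observed_frame(observed)
        sp_index = {s: i for i, s in enumerate(spec.species_names)}
        missing = set(obs["species"]) - set(sp_index)
        if missing:
            raise ValueError(f"observed species not in model: {sorted(missing)[:5]}")
        self.times = np.sort(obs["time_hours"].unique())
        tpos = {t: j for j, t in enumerate(self.times)}
        self.rows = np.array([sp_index[s] for s in obs["species"]])
        self.cols = np.array([tpos[t] for t in obs["time_hours"]])
        self.vals = obs["value"].to_numpy(dtype=float)

    def __call__(self, free_vec: np.ndarray) -> float:
        self.theta[self.free_idx] = free_vec
        sim = self.cm.trajectory(self.theta, self.times)
        d = sim[self.rows, self.cols] - self.vals
        return float(d @ d)

    def full_vector(self, free_vec: np.ndarray) -> np.ndarray:
        th = self.theta.copy()
        th[self.free_idx] = free_vec
        return th


def _anneal(
    obj,
    x0,
    lo,
    hi,
    budget,
    rng,
    t_end_frac=1e-6,
    step0=0.3,
    step_min=0.01,
    polish_frac=0.4,
):
    """Simulated annealing with geometric cooling, plus a local polish.

    The proposal scale shrinks with temperature from ``step0`` to
    ``step_min`` times the box range; the last ``polish_frac`` of the
    evaluation budget runs a Nelder-Mead refinement from the best annealed
    point (the hybrid-function pattern of classical annealing toolboxes),
    so every start converges tightly enough for the top-k average to be
    meaningful.  Bounds are enforced by clipping.  Returns (best_x, best_f)
    after at most ``budget`` evaluations.
    """
    span = hi - lo
    x = x0.copy()
    f = obj(x)
    best_x, best_f = x.copy(), f
    if budget <= 0:
        return best_x, best_f
    n_polish = int(budget * polish_frac)
    n_sa = budget - n_polish
    T0 = max(abs(f), 1e-12)
    cool = t_end_frac ** (1.0 / max(n_sa, 1))
    T = T0
    for _ in range(n_sa):
        frac = max(step0 * np.sqrt(T / T0), step_min)
        prop = np.clip(x + rng.normal(0.0, frac * span), lo, hi)
        fp = obj(prop)
        if fp <= f or rng.random() < np.exp(-(fp - f) / max(T, 1e-300)):
            x, f = prop, fp
            if f < best_f:
                best_x, best_f = x.copy(), f
        T *= cool
    if n_polish > 0:
        from scipy.optimize import minimize

        res = minimize(
            lambda z: obj(np.clip(z, lo, hi)),
            best_x,
            method="Nelder-Mead",
            options={"maxfev": n_polish, "xatol": 1e-10, "fatol": 1e-12},
        )
        xr = np.clip(res.x, lo, hi)
        if res.fun < best_f:
            best_x, best_f = xr, float(res.fun)
    return best_x, best_f


@dataclass
class FitResult:
    """Outcome of a multistart annealing fit.

    ``best_parameters`` is the elementwise average of the ``top_n``
    lowest-error refined vectors (free parameters only; fixed parameters
    pass through).  ``starts`` records every start's seed and final error.
    """

    best_parameters: ParameterSet
    starts: pd.DataFrame
    free: list[str]
    residual_definition: str = "sum of squared simulated-minus-observed values"
    top_n: int = DEFAULT_TOP

    @property
    def best_error(self) -> float:
        return float(self.starts["error"].min())

    def summary(self) -> str:
        lines = [
            "Simulated-annealing fit",
            "=" * 55,
            f"starts: {len(self.starts)}   averaged top: {self.top_n}",
            f"residual: {self.residual_definition}",
            f"best single-start error: {self.best_error:.6g}",
            "-" * 55,
            f"{'parameter':<30}{'estimate':>14}",
        ]
        for n in self.free:
            lines.append(f"{n:<30}{self.best_parameters[n]:>14.6g}")
        return "\n".join(lines)


def fit(
    spec: OdeModelSpec,
    observed: pd.DataFrame,
    bounds: dict[str, tuple[float, float]],
    params0: ParameterSet,
    n_starts: int = DEFAULT_N_STARTS,
    budget: int = DEFAULT_BUDGET,
    seed: int = 0,
) -> FitResult:
    """LHS + simulated annealing over the free parameters in ``bounds``.

    Parameters held fixed (e.g. measured diffusion coefficients and
    oligomeric states) stay at their ``params0`` values and are excluded
    from the search.  Deterministic given ``seed``.  ``budget`` counts
    objective evaluations per start; budget 0 degenerates to ranking the
    LHS initials.
    """
    if n_starts < DEFAULT_TOP:
        raise ValueError(f"n_starts must be >= {DEFAULT_TOP} to average the top {DEFAULT_TOP}")
    free = list(bounds)
    lo = np.array([bounds[n][0] for n in free], dtype=float)
    hi = np.array([bounds[n][1] for n in free], dtype=float)
    if not np.isfinite(lo).all() or not np.isfinite(hi).all() or (hi <= lo).any():
        raise ValueError("bounds must be finite with hi > lo")
    obj = _Objective(spec, observed, params0, free)
    sampler = qmc.LatinHypercube(d=len(free), seed=int(seed) % (2**31))
    initials = lo + sampler.random(n=n_starts) * (hi - lo)
    records = []
    finals = []
    ss = np.random.SeedSequence(int(seed) % (2**31))
    child_seeds = ss.spawn(n_starts)
    for s in range(n_starts):
        rng = np.random.default_rng(child_seeds[s])
        x_best, f_best = _anneal(obj, initials[s], lo, hi, budget, rng)
        finals.append(x_best)
        records.append({"start": s, "error": f_best})
    starts = pd.DataFrame(records)
    for j, n in enumerate(free):
        starts[n] = [v[j] for v in finals]
    top = starts.nsmallest(DEFAULT_TOP, "error", keep="first")
    mean_free = top[free].to_numpy().mean(axis=0)
    best = params0.with_vector(obj.full_vector(mean_free))
    return FitResult(best_parameters=best, starts=starts, free=free)
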