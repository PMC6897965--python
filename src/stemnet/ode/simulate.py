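"""Integration backends for the windowed GRN ODE model.

Two routes share one right-hand side definition:

* :func:`simulate` — adaptive LSODA via scipy, tight tolerances, for
  user-facing trajectories;
* :class:`CompiledModel` — a numba-jitted fixed-step RK4 used inside the
  simulated-annealing and Sobol loops, where hundreds of thousands of
  objective evaluations make adaptive-solver call overhead prohibitive.

Consistency of the two integrators is unit-tested; states are clipped at
zero (concentrations cannot go negative).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .model import OdeModelSpec, ParameterSet, Trajectory

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


class IntegrationError(RuntimeError):
    pass


@njit
def _rhs(x, beta, delta, tgt, reg, act, K, h, msrc, mdst, mD, mn, out):
    n = x.shape[0]
    for i in range(n):
        out[i] = 1.0
    for e in range(tgt.shape[0]):
        xr = x[reg[e]]
        if xr < 0.0:
            xr = 0.0
        num = xr ** h[e]
        kh = K[e] ** h[e]
        if act[e]:
            out[tgt[e]] *= num / (kh + num)
        else:
            out[tgt[e]] *= kh / (kh + num)
    for i in range(n):
        xi = x[i] if x[i] > 0.0 else 0.0
        out[i] = beta[i] * out[i] - delta[i] * xi
    for m in range(msrc.shape[0]):
        xs = x[msrc[m]] if x[msrc[m]] > 0.0 else 0.0
        xd = x[mdst[m]] if x[mdst[m]] > 0.0 else 0.0
        flow = mD[m] * (xs ** mn[m] - xd ** mn[m])
        out[mdst[m]] += flow
    return out


@njit
def _rk4_window(x0, t0, dt, n_steps, beta, delta, tgt, reg, act, K, h,
                msrc, mdst, mD, mn):
    n = x0.shape[0]
    traj = np.empty((n_steps + 1, n))
    traj[0] = x0
    x = x0.copy()
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    tmp = np.empty(n)
    for s in range(n_steps):
        _rhs(x, beta, delta, tgt, reg, act, K, h, msrc, mdst, mD, mn, k1)
        for i in range(n):
            tmp[i] = x[i] + 0.5 * dt * k1[i]
        _rhs(tmp, beta, delta, tgt, reg, act, K, h, msrc, mdst, mD, mn, k2)
        for i in range(n):
            tmp[i] = x[i] + 0.5 * dt * k2[i]
        _rhs(tmp, beta, delta, tgt, reg, act, K, h, msrc, mdst, mD, mn, k3)
        for i in range(n):
            tmp[i] = x[i] + dt * k3[i]
        _rhs(tmp, beta, delta, tgt, reg, act, K, h, msrc, mdst, mD, mn, k4)
        for i in range(n):
            x[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if x[i] < 0.0:
                x[i] = 0.0
        traj[s + 1] = x
    return traj


class CompiledModel:
    """Per-window index arrays + parameter-vector slices for fast evaluation.

    The parameter vector follows ``spec.parameter_names()`` exactly:
    [betas | deltas | Ks | hs | Ds | x0s].
    """

    def __init__(self, spec: OdeModelSpec, n_steps_per_window: int = 48):
        self.spec = spec
        self.n_steps = int(n_steps_per_window)
        names = spec.species_names
        self.n_species = len(names)
        idx = {s: i for i, s in enumerate(names)}
        ekeys = spec.edge_keys()
        ekey_pos = {k: i for i, k in enumerate(ekeys)}
        self.windows = []
        for edges in spec.window_edges:
            tgt, reg, act, kix = [], [], [], []
            for _, row in edges.iterrows():
                c = row["cell_type"]
                tgt.append(idx[f"{row['target']}@{c}"])
                reg.append(idx[f"{row['regulator']}@{c}"])
                act.append(int(row["sign"]) >= 0)  # unsigned edges activate
                kix.append(ekey_pos[(row["regulator"], row["target"], c)])
            self.windows.append(
                (
                    np.array(tgt, dtype=np.int64),
                    np.array(reg, dtype=np.int64),
                    np.array(act, dtype=np.bool_),
                    np.array(kix, dtype=np.int64),
                )
            )
        msrc, mdst, mpow = [], [], []
        for g, a, b in spec.mobility_keys():
            msrc.append(idx[f"{g}@{a}"])
            mdst.append(idx[f"{g}@{b}"])
            mpow.append(float(spec.oligomer.get((g, a), 1)))
        self.msrc = np.array(msrc, dtype=np.int64)
        self.mdst = np.array(mdst, dtype=np.int64)
        self.mpow = np.array(mpow, dtype=np.float64)
        ns, ne, nm = self.n_species, len(ekeys), len(msrc)
        self.sl_beta = slice(0, ns)
        self.sl_delta = slice(ns, 2 * ns)
        self.sl_K = slice(2 * ns, 2 * ns + ne)
        self.sl_h = slice(2 * ns + ne, 2 * ns + 2 * ne)
        self.sl_D = slice(2 * ns + 2 * ne, 2 * ns + 2 * ne + nm)
        self.sl_x0 = slice(2 * ns + 2 * ne + nm, 2 * ns + 2 * ne + nm + ns)
        self.n_params = 2 * ns + 2 * ne + nm + ns

    def _window_args(self, theta: np.ndarray, w: int):
        tgt, reg, act, kix = self.windows[w]
        K = np.ascontiguousarray(theta[self.sl_K][kix]) if len(kix) else np.empty(0)
        h = np.ascontiguousarray(theta[self.sl_h][kix]) if len(kix) else np.empty(0)
        return (
            np.ascontiguousarray(theta[self.sl_beta]),
            np.ascontiguousarray(theta[self.sl_delta]),
            tgt,
            reg,
            act,
            K,
            h,
            self.msrc,
            self.mdst,
            np.ascontiguousarray(theta[self.sl_D]),
            self.mpow,
        )

    def trajectory(self, theta: np.ndarray, t_eval: np.ndarray) -> np.ndarray:
        """Fixed-step RK4 values at t_eval, shape (n_species, len(t_eval))."""
        wb = self.spec.window_bounds
        t_eval = np.asarray(t_eval, dtype=float)
        x = np.maximum(theta[self.sl_x0], 0.0).copy()
        out = np.empty((self.n_species, len(t_eval)))
        for w in range(self.spec.n_windows):
            t0, t1 = wb[w], wb[w + 1]
            dt = (t1 - t0) / self.n_steps
            grid = _rk4_window(x, t0, dt, self.n_steps, *self._window_args(theta, w))
            x = grid[-1].copy()
            tgrid = t0 + dt * np.arange(self.n_steps + 1)
            mask = (t_eval >= t0) & (t_eval <= t1) if w == 0 else (t_eval > t0) & (
                t_eval <= t1
            )
            if mask.any():
                for i in range(self.n_species):
                    out[i, mask] = np.interp(t_eval[mask], tgrid, grid[:, i])
        return out


def _rhs_python(spec_cm: CompiledModel, theta: np.ndarray, w: int):
    args = spec_cm._window_args(theta, w)

    def rhs(t, x):
        out = np.empty_like(x)
        _rhs(x, *args, out)
        return out

    return rhs


def simulate(
    spec: OdeModelSpec,
    params: ParameterSet,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Adaptive integration across all windows, continuous at boundaries.

    ``t_grid`` must lie within the model's window span.  Output states are
    clipped at zero.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    wb = spec.window_bounds
    if t_grid.min() < wb[0] - 1e-9 or t_grid.max() > wb[-1] + 1e-9:
        raise ValueError(f"t_grid outside model span {wb[0]}..{wb[-1]}")
    cm = CompiledModel(spec)
    theta = params.vector()
    x = np.maximum(theta[cm.sl_x0], 0.0).copy()
    values = np.empty((cm.n_species, len(t_grid)))
    for w in range(spec.n_windows):
        t0, t1 = wb[w], wb[w + 1]
        mask = (
            (t_grid >= t0 - 1e-9) & (t_grid <= t1 + 1e-9)
            if w == 0
            else (t_grid > t0) & (t_grid <= t1 + 1e-9)
        )
        t_eval = np.clip(np.sort(t_grid[mask]), t0, t1)
        sol = solve_ivp(
            _rhs_python(cm, theta, w),
            (t0, t1),
            x,
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=np.unique(np.concatenate([t_eval, [t1]])),
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(f"window {w}: {sol.message}")
        x = np.maximum(sol.y[:, -1], 0.0)
        if mask.any():
            order = np.argsort(np.argsort(np.clip(t_grid[mask], t0, t1)))
            sel = np.searchsorted(sol.t, np.sort(np.clip(t_grid[mask], t0, t1)))
            values[:, mask] = np.maximum(sol.y[:, sel], 0.0)[:, order]
    return Trajectory(t_grid, values, spec.species_names)
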