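"""Piecewise-in-time multicellular ODE model of a signed GRN.

One state variable per (gene, cell).  Within each time window the dynamics
of species x_{g,c} are

    dx/dt = beta * prod_act x_a^h/(K^h + x_a^h) * prod_rep K^h/(K^h + x_r^h)
            - delta * x
            + sum_{c' adjacent} D_{g,c'->c} * (x_{g,c'}^n - x_{g,c}^n)

with multiplicative Hill regulation from the window's signed edge list
(edges without a predicted sign are assumed activating), linear
degradation, and intercellular movement whose rate depends on the protein's
oligomeric state n.  The edge set changes at the window boundaries while
the state stays continuous.  Time is in hours with the 4-day time point at
96 h; concentrations are on the FPKM scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..datamodel import Network, ValidationError

#: Default window boundaries: 4D, 4D8H, 4D16H, 5D.
DEFAULT_WINDOW_BOUNDS = (96.0, 104.0, 112.0, 120.0)


def species_name(gene: str, cell: str) -> str:
    return f"{gene}@{cell}"


@dataclass
class OdeModelSpec:
    """Structure of the model: species, windowed edge sets, movement, oligomers."""

    cells: list[str]
    species: list[tuple[str, str]]  # (gene, cell)
    window_bounds: tuple[float, ...]
    window_edges: list[pd.DataFrame]  # per window: regulator, target, sign, cell_type
    adjacency: set[frozenset] = field(default_factory=set)
    mobility: pd.DataFrame = None  # gene, source_cell, dest_cell (D value in params)
    oligomer: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wb = tuple(float(t) for t in self.window_bounds)
        if len(wb) < 2 or not all(b > a for a, b in zip(wb, wb[1:])):
            raise ValidationError("window boundaries must be strictly increasing")
        if len(self.window_edges) != len(wb) - 1:
            raise ValidationError(
                f"expected {len(wb) - 1} window edge lists, got {len(self.window_edges)}"
            )
        self.window_bounds = wb
        if self.mobility is None:
            self.mobility = pd.DataFrame(columns=["gene", "source_cell", "dest_cell"])
        for _, row in self.mobility.iterrows():
            pair = frozenset((row["source_cell"], row["dest_cell"]))
            if self.adjacency and pair not in self.adjacency:
                raise ValidationError(
                    f"mobility between non-adjacent cells {sorted(pair)}"
                )
        sp = set(self.species)
        if len(sp) != len(self.species):
            raise ValidationError("duplicate species")

    # -- canonical parameter order --------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [species_name(g, c) for g, c in self.species]

    @property
    def n_windows(self) -> int:
        return len(self.window_edges)

    def edge_keys(self) -> list[tuple[str, str, str]]:
        """Unique (regulator, target, cell) regulation keys over all windows;
        K and h are shared by an edge across windows."""
        keys = []
        seen = set()
        for edges in self.window_edges:
            for _, row in edges.iterrows():
                key = (row["regulator"], row["target"], row["cell_type"])
                if key not in seen:
                    seen.add(key)
                    keys.append(key)
        return keys

    def mobility_keys(self) -> list[tuple[str, str, str]]:
        return [
            (row["gene"], row["source_cell"], row["dest_cell"])
            for _, row in self.mobility.iterrows()
        ]

    def parameter_names(self) -> list[str]:
        """The documented vectorization order: betas, deltas, Ks, hs, Ds, x0s."""
        names = []
        for s in self.species_names:
            names.append(f"beta[{s}]")
        for s in self.species_names:
            names.append(f"delta[{s}]")
        for r, t, c in self.edge_keys():
            names.append(f"K[{r}->{t}@{c}]")
        for r, t, c in self.edge_keys():
            names.append(f"h[{r}->{t}@{c}]")
        for g, a, b in self.mobility_keys():
            names.append(f"D[{g}:{a}->{b}]")
        for s in self.species_names:
            names.append(f"x0[{s}]")
        return names

    def window_of(self, t: float) -> int:
        wb = self.window_bounds
        if not (wb[0] <= t <= wb[-1]):
            raise ValueError(f"time {t} outside model span {wb[0]}..{wb[-1]}")
        for w in range(self.n_windows):
            if t < wb[w + 1]:
                return w
        return self.n_windows - 1


@dataclass
class ParameterSet:
    """All rate constants and initial conditions, keyed by canonical names.

    beta (FPKM/h) >= 0, delta (1/h) > 0, K (FPKM) > 0, Hill h >= 1,
    mobility D (1/h) >= 0, x0 (FPKM) >= 0.
    """

    values: dict[str, float]
    order: list[str]

    def __post_init__(self) -> None:
        missing = [n for n in self.order if n not in self.values]
        if missing:
            raise ValidationError(f"missing parameters: {missing[:5]}")
        for n in self.order:
            v = float(self.values[n])
            if n.startswith(("beta", "D", "x0")) and v < 0:
                raise ValidationError(f"{n} must be >= 0")
            if n.startswith("delta") and v < 0:
                # zero degradation is allowed (e.g. conservative transport)
                raise ValidationError(f"{n} must be >= 0")
            if n.startswith("K") and v <= 0:
                raise ValidationError(f"{n} must be > 0")
            if n.startswith("h[") and v < 1:
                raise ValidationError(f"{n} must be >= 1")

    def vector(self) -> np.ndarray:
        return np.array([float(self.values[n]) for n in self.order])

    def replace(self, **kv) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(kv)
        return ParameterSet(vals, self.order)

    def with_vector(self, vec: np.ndarray) -> "ParameterSet":
        vals = dict(self.values)
        for n, v in zip(self.order, vec):
            vals[n] = float(v)
        return ParameterSet(vals, self.order)

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    @classmethod
    def defaults(
        cls,
        spec: OdeModelSpec,
        beta: float = 10.0,
        delta: float = 0.1,
        K: float = 50.0,
        h: float = 2.0,
        D: float = 0.05,
        x0: float = 0.0,
    ) -> "ParameterSet":
        """A ParameterSet with uniform default values, to be overridden."""
        base = {"beta": beta, "delta": delta, "K": K, "h": h, "D": D, "x0": x0}
        order = spec.parameter_names()
        return cls({n: base[n.split("[", 1)[0]] for n in order}, order)


def build_model(
    window_networks,
    mobility_table: pd.DataFrame | None = None,
    oligomer_table: dict | pd.DataFrame | None = None,
    cells: list[str] | None = None,
    adjacency=None,
    window_bounds=DEFAULT_WINDOW_BOUNDS,
    species: list[tuple[str, str]] | None = None,
) -> OdeModelSpec:
    """Assemble an OdeModelSpec from per-window networks.

    ``window_networks`` is an ordered sequence of Network objects (or a dict
    keyed by window start hour), one per window.  Regulation acts within a
    cell: an edge labeled with cell c couples regulator and target in c.
    Edges with sign 0 are kept and treated as activating.  Species default
    to every (gene, cell) seen in any window's edges or the mobility table.
    """
    if isinstance(window_networks, dict):
        nets = [window_networks[k] for k in sorted(window_networks)]
    else:
        nets = list(window_networks)
    window_edges = []
    seen_species: list[tuple[str, str]] = []

    def add_sp(g, c):
        if (g, c) not in seen_species:
            seen_species.append((g, c))

    all_cells = list(cells) if cells is not None else []
    for net in nets:
        e = net.edges if isinstance(net, Network) else pd.DataFrame(net)
        e = e.copy()
        if "cell_type" not in e.columns:
            e["cell_type"] = ""
        e["cell_type"] = e["cell_type"].replace("", all_cells[0] if all_cells else "root")
        if cells is not None:
            bad = set(e["cell_type"]) - set(cells)
            if bad:
                raise ValidationError(f"edge cell labels not in cells: {sorted(bad)}")
        for _, row in e.iterrows():
            add_sp(row["regulator"], row["cell_type"])
            add_sp(row["target"], row["cell_type"])
            if row["cell_type"] not in all_cells:
                all_cells.append(row["cell_type"])
        window_edges.append(
            e[["regulator", "target", "sign", "cell_type"]].reset_index(drop=True)
        )
    mobility = mobility_table
    if mobility is not None:
        for _, row in mobility.iterrows():
            add_sp(row["gene"], row["source_cell"])
            add_sp(row["gene"], row["dest_cell"])
            for c in (row["source_cell"], row["dest_cell"]):
                if c not in all_cells:
                    all_cells.append(c)
    if species is not None:
        seen_species = list(species)
    oligomer = {}
    if oligomer_table is not None:
        if isinstance(oligomer_table, pd.DataFrame):
            for _, row in oligomer_table.iterrows():
                oligomer[(row["gene"], row["cell_type"])] = int(row["n"])
        else:
            oligomer = {k: int(v) for k, v in oligomer_table.items()}
    adj = set()
    if adjacency:
        adj = {frozenset(p) for p in adjacency}
    return OdeModelSpec(
        cells=all_cells,
        species=seen_species,
        window_bounds=window_bounds,
        window_edges=window_edges,
        adjacency=adj,
        mobility=mobility,
        oligomer=oligomer,
    )


@dataclass
class Trajectory:
    """Simulated concentrations on a time grid (species x times, FPKM, hours)."""

    times: np.ndarray
    values: np.ndarray  # (n_species, n_times)
    species: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species), len(self.times)):
            raise ValueError("trajectory shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.times)

    def at(self, t) -> pd.Series:
        """Linear interpolation of every species at time t."""
        t = float(t)
        vals = [np.interp(t, self.times, self.values[i]) for i in range(len(self.species))]
        return pd.Series(vals, index=self.species)

    def series(self, gene: str, cell: str) -> np.ndarray:
        return self.values[self.species.index(species_name(gene, cell))]

    def plot(self, species=None, ax=None):
        """Quick trajectory plot (one line per species)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in species or self.species:
            ax.plot(self.times, self.values[self.species.index(name)], label=name)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("expression (FPKM)")
        ax.legend(fontsize="small")
        return ax
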