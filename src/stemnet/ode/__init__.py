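"""Multicellular windowed ODE modeling of signed GRNs.

The functional API (build_model, simulate, residual, fit, sobol_total,
sensitivity_significance, classify_division) is wrapped by a statsmodels-
style pair: :class:`GrnOdeModel` holds the structure and the data, its
``fit()`` returns an :class:`OdeFitResult` carrying estimates, per-start
errors and a ``summary()``; simulation, sensitivity and division calls hang
off these two objects.
"""

from __future__ import annotations

import numpy as np

from .division import classify_division
from .fit import FitResult, fit, residual
from .model import (
    DEFAULT_WINDOW_BOUNDS,
    OdeModelSpec,
    ParameterSet,
    Trajectory,
    build_model,
    species_name,
)
from .sensitivity import (
    SobolResult,
    sensitivity_significance,
    sobol_total,
    sobol_total_indices,
)
from .simulate import CompiledModel, IntegrationError, simulate

__all__ = [
    "DEFAULT_WINDOW_BOUNDS",
    "OdeModelSpec",
    "ParameterSet",
    "Trajectory",
    "build_model",
    "simulate",
    "residual",
    "fit",
    "FitResult",
    "sobol_total",
    "sobol_total_indices",
    "sensitivity_significance",
    "SobolResult",
    "classify_division",
    "CompiledModel",
    "IntegrationError",
    "GrnOdeModel",
    "OdeFitResult",
    "species_name",
]


class GrnOdeModel:
    """A windowed multicellular GRN ODE model bound to observed dynamics.

    Parameters
    ----------
    spec : OdeModelSpec
        Model structure (from :func:`build_model`).
    observed : pandas.DataFrame, optional
        Tidy observations with columns (gene, cell, time_hours, value) or
        (species, time_hours, value); required for fitting.
    params0 : ParameterSet, optional
        Baseline values for parameters not being estimated.
    """

    def __init__(self, spec: OdeModelSpec, observed=None, params0: ParameterSet = None):
        self.spec = spec
        self.observed = observed
        self.params0 = params0 or ParameterSet.defaults(spec)

    @classmethod
    def from_networks(cls, window_networks, observed=None, **build_kwargs):
        return cls(build_model(window_networks, **build_kwargs), observed=observed)

    def simulate(self, params: ParameterSet = None, t_grid=None, **kw) -> Trajectory:
        if t_grid is None:
            wb = self.spec.window_bounds
            t_grid = np.linspace(wb[0], wb[-1], 97)
        return simulate(self.spec, params or self.params0, t_grid, **kw)

    def residual(self, params: ParameterSet = None) -> float:
        self._need_observed()
        return residual(params or self.params0, self.spec, self.observed)

    def fit(self, bounds, n_starts=50, budget=2000, seed=0) -> "OdeFitResult":
        self._need_observed()
        res = fit(
            self.spec,
            self.observed,
            bounds,
            self.params0,
            n_starts=n_starts,
            budget=budget,
            seed=seed,
        )
        return OdeFitResult(self, res)

    def sensitivity(self, param_ranges, base_sample_n=1024, seed=0, output=None,
                    n_bootstrap=100) -> SobolResult:
        return sobol_total(
            self.spec,
            param_ranges,
            base_sample_n=base_sample_n,
            seed=seed,
            params0=self.params0,
            output=output,
            observed=self.observed if output is None else None,
            n_bootstrap=n_bootstrap,
        )

    def _need_observed(self):
        if self.observed is None:
            raise ValueError("model has no observed data")


class OdeFitResult:
    """Fit estimates plus diagnostics; delegates to the underlying FitResult."""

    def __init__(self, model: GrnOdeModel, result: FitResult):
        self.model = model
        self._result = result

    @property
    def params(self) -> ParameterSet:
        return self._result.best_parameters

    @property
    def starts(self):
        return self._result.starts

    @property
    def best_error(self) -> float:
        return self._result.best_error

    def summary(self) -> str:
        return self._result.summary()

    def trajectory(self, t_grid=None, **kw) -> Trajectory:
        return self.model.simulate(self.params, t_grid, **kw)

    def classify_division(self, focal_gene, fc_threshold=1.5):
        return classify_division(
            self.trajectory(), focal_gene, windows=self.model.spec.window_bounds,
            fc_threshold=fc_threshold,
        )
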