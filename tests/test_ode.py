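import numpy as np
import pandas as pd
import pytest

from stemnet.datamodel import Network, ValidationError
from stemnet.ode import (
    CompiledModel,
    GrnOdeModel,
    OdeModelSpec,
    ParameterSet,
    Trajectory,
    build_model,
    classify_division,
    fit,
    residual,
    simulate,
)
from stemnet.synthetic import make_truth, ode_spec_from_truth


def _single_gene_spec(t0=0.0, t1=24.0):
    return build_model(
        [Network()], species=[("g", "root")], cells=["root"], window_bounds=(t0, t1)
    )


def _params(spec, **kv):
    return ParameterSet.defaults(spec).replace(**kv)


class TestBuildModel:
    def test_single_unregulated_gene(self):
        spec = _single_gene_spec()
        assert spec.species_names == ["g@root"]
        assert spec.parameter_names() == [
            "beta[g@root]", "delta[g@root]", "x0[g@root]"
        ]

    def test_unsigned_edge_becomes_activation(self):
        net = Network(pd.DataFrame({"regulator": ["A"], "target": ["B"], "sign": [0]}))
        spec = build_model([net], cells=["root"], window_bounds=(0.0, 10.0))
        cm = CompiledModel(spec)
        assert cm.windows[0][2][0]  # activation flag

    def test_windows_change_dynamics(self):
        e1 = Network(pd.DataFrame({"regulator": ["A"], "target": ["B"], "sign": [1]}))
        e2 = Network(pd.DataFrame({"regulator": ["A"], "target": ["B"], "sign": [-1]}))
        spec = build_model([e1, e2], cells=["root"], window_bounds=(0.0, 10.0, 20.0))
        p = _params(spec, **{"x0[A@root]": 100.0, "x0[B@root]": 0.0, "K[A->B@root]": 10.0})
        traj = simulate(spec, p, np.linspace(0, 20, 81))
        b = traj.series("B", "root")
        # activation first (B rises), repression after the boundary (B decays)
        assert b[40] > 5.0
        assert b[-1] < b[40]

    def test_mobility_between_nonadjacent_cells_rejected(self):
        net = Network(pd.DataFrame({"regulator": ["A"], "target": ["B"], "sign": [1],
                                    "cell_type": ["QC"]}))
        mob = pd.DataFrame(
            {"gene": ["A"], "source_cell": ["QC"], "dest_cell": ["Phlo"]}
        )
        with pytest.raises(ValidationError):
            build_model(
                [net], mobility_table=mob, cells=["QC", "Phlo"],
                adjacency=[("QC", "CEI")], window_bounds=(0.0, 10.0),
            )


class TestSimulate:
    def test_unregulated_species_matches_closed_form(self):
        spec = _single_gene_spec()
        beta, delta = 8.0, 0.3
        p = _params(spec, **{"beta[g@root]": beta, "delta[g@root]": delta, "x0[g@root]": 0.0})
        t = np.linspace(0, 24, 49)
        traj = simulate(spec, p, t)
        expected = beta / delta * (1 - np.exp(-delta * t))
        rel = np.abs(traj.values[0, 1:] - expected[1:]) / expected[1:]
        assert rel.max() < 1e-5

    def test_pure_diffusion_conserves_mass_and_equilibrates(self):
        mob = pd.DataFrame(
            {"gene": ["g", "g"], "source_cell": ["A", "B"], "dest_cell": ["B", "A"]}
        )
        spec = build_model(
            [Network()], mobility_table=mob, species=[("g", "A"), ("g", "B")],
            cells=["A", "B"], adjacency=[("A", "B")], window_bounds=(0.0, 200.0),
        )
        p = _params(
            spec,
            **{
                "beta[g@A]": 0.0, "beta[g@B]": 0.0,
                "delta[g@A]": 0.0, "delta[g@B]": 0.0,
                "x0[g@A]": 10.0, "x0[g@B]": 2.0,
                "D[g:A->B]": 0.05, "D[g:B->A]": 0.05,
            },
        )
        traj = simulate(spec, p, np.linspace(0, 200, 51))
        totals = traj.values.sum(axis=0)
        assert np.abs(totals - 12.0).max() < 1e-8
        assert traj.values[:, -1] == pytest.approx([6.0, 6.0], abs=1e-6)

    def test_saturated_repressor_shuts_production_off(self):
        net = Network(pd.DataFrame({"regulator": ["R"], "target": ["T"], "sign": [-1]}))
        spec = build_model([net], cells=["root"], window_bounds=(0.0, 300.0))
        p = _params(
            spec,
            **{
                "beta[R@root]": 50.0, "delta[R@root]": 0.05,
                "x0[R@root]": 1000.0, "K[R->T@root]": 1.0,
                "beta[T@root]": 10.0, "delta[T@root]": 0.5, "x0[T@root]": 5.0,
            },
        )
        traj = simulate(spec, p, np.array([0.0, 300.0]))
        assert traj.series("T", "root")[-1] < 1e-3

    def test_state_continuous_across_window_boundary(self):
        e1 = Network(pd.DataFrame({"regulator": ["A"], "target": ["B"], "sign": [1]}))
        e2 = Network(pd.DataFrame({"regulator": ["A"], "target": ["B"], "sign": [-1]}))
        spec = build_model([e1, e2], cells=["root"], window_bounds=(0.0, 10.0, 20.0))
        p = _params(spec, **{"x0[A@root]": 50.0})
        eps = 1e-6
        traj = simulate(spec, p, np.array([10.0 - eps, 10.0, 10.0 + eps]))
        jumps = np.abs(np.diff(traj.values, axis=1))
        assert jumps.max() < 1e-4

    def test_fast_integrator_agrees_with_adaptive(self):
        truth = make_truth(n_genes=4, tf_frac=0.3, n_edges=3, seed=6)
        spec, params = ode_spec_from_truth(truth, (96.0, 144.0))
        t = np.arange(96.0, 144.01, 4.0)
        ref = simulate(spec, params, t).values
        fast = CompiledModel(spec, n_steps_per_window=96).trajectory(params.vector(), t)
        denom = np.maximum(np.abs(ref), 1.0)
        assert (np.abs(fast - ref) / denom).max() < 1e-3

    def test_activator_increase_never_decreases_production(self):
        # production term is monotone in the activator level
        for h in (1.0, 2.0, 4.0):
            x = np.linspace(0, 100, 200)
            term = x**h / (10.0**h + x**h)
            assert (np.diff(term) >= 0).all()


class TestResidual:
    def test_zero_for_exact_observations(self):
        spec = _single_gene_spec()
        p = _params(spec, **{"beta[g@root]": 5.0, "delta[g@root]": 0.2})
        t = np.array([2.0, 5.0, 10.0])
        cm = CompiledModel(spec)
        sim = cm.trajectory(p.vector(), t)
        obs = pd.DataFrame(
            {"gene": "g", "cell": "root", "time_hours": t, "value": sim[0]}
        )
        assert residual(p, spec, obs) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_offset_squares(self):
        spec = _single_gene_spec()
        p = _params(spec, **{"beta[g@root]": 5.0, "delta[g@root]": 0.2})
        t = np.array([4.0])
        sim = CompiledModel(spec).trajectory(p.vector(), t)
        obs = pd.DataFrame(
            {"gene": "g", "cell": "root", "time_hours": t, "value": sim[0] + 2.0}
        )
        assert residual(p, spec, obs) == pytest.approx(4.0)

    def test_matches_independent_recomputation(self):
        truth = make_truth(n_genes=3, tf_frac=0.34, n_edges=2, seed=13)
        spec, p = ode_spec_from_truth(truth, (96.0, 120.0))
        t = np.arange(96.0, 120.01, 6.0)
        rng = np.random.default_rng(0)
        obs = pd.DataFrame(
            [
                {"gene": g, "cell": "root", "time_hours": tt, "value": rng.uniform(0, 50)}
                for g in truth.gene_ids
                for tt in t
            ]
        )
        traj = simulate(spec, p, t)
        expected = 0.0
        for _, row in obs.iterrows():
            sim_val = traj.at(row["time_hours"])[f"{row['gene']}@root"]
            expected += (sim_val - row["value"]) ** 2
        assert residual(p, spec, obs) == pytest.approx(expected, rel=1e-6)


class TestFit:
    def _setup(self):
        spec = _single_gene_spec()
        p_true = _params(spec, **{"beta[g@root]": 6.0, "delta[g@root]": 0.25})
        t = np.arange(0.0, 24.01, 2.0)
        sim = CompiledModel(spec).trajectory(p_true.vector(), t)
        obs = pd.DataFrame({"gene": "g", "cell": "root", "time_hours": t, "value": sim[0]})
        bounds = {"beta[g@root]": (1.0, 20.0), "delta[g@root]": (0.01, 1.0)}
        return spec, p_true, obs, bounds

    def test_zero_budget_averages_ten_best_initials(self):
        spec, p_true, obs, bounds = self._setup()
        res = fit(spec, obs, bounds, p_true, n_starts=15, budget=0, seed=1)
        # with budget 0 the finals are exactly the LHS initials
        assert len(res.starts) == 15
        top = res.starts.nsmallest(10, "error")
        assert res.best_parameters["beta[g@root]"] == pytest.approx(
            top["beta[g@root]"].mean()
        )

    def test_deterministic_given_seed(self):
        spec, p_true, obs, bounds = self._setup()
        a = fit(spec, obs, bounds, p_true, n_starts=10, budget=50, seed=3)
        b = fit(spec, obs, bounds, p_true, n_starts=10, budget=50, seed=3)
        pd.testing.assert_frame_equal(a.starts, b.starts)

    def test_too_few_starts_rejected(self):
        spec, p_true, obs, bounds = self._setup()
        with pytest.raises(ValueError):
            fit(spec, obs, bounds, p_true, n_starts=5, budget=10, seed=0)

    def test_recovers_noiseless_two_parameter_model(self):
        spec, p_true, obs, bounds = self._setup()
        res = fit(spec, obs, bounds, p_true, n_starts=10, budget=400, seed=2)
        assert res.best_parameters["beta[g@root]"] == pytest.approx(6.0, rel=0.1)
        assert res.best_parameters["delta[g@root]"] == pytest.approx(0.25, rel=0.1)

    def test_model_results_wrapper_summary(self):
        spec, p_true, obs, bounds = self._setup()
        model = GrnOdeModel(spec, obs, p_true)
        res = model.fit(bounds, n_starts=10, budget=100, seed=4)
        text = res.summary()
        assert "beta[g@root]" in text and "starts: 10" in text
        assert res.best_error >= 0


class TestClassifyDivision:
    def _traj(self, values):
        times = np.array([96.0, 104.0, 112.0, 120.0])
        return Trajectory(times, np.array([values]), ["TCX2@QC"])

    def test_significant_drop_calls_division(self):
        calls = classify_division(self._traj([10.0, 10.0, 10.0, 4.0]), "TCX2",
                                  windows=[96, 104, 112, 120])
        assert calls.at["QC", "call"] == "division"

    def test_1_6_fold_rise_calls_increase(self):
        calls = classify_division(self._traj([10.0, 10.0, 10.0, 16.0]), "TCX2",
                                  windows=[96, 104, 112, 120])
        assert calls.at["QC", "call"] == "increase"

    def test_sub_threshold_change_is_quiescent(self):
        calls = classify_division(self._traj([10.0, 10.0, 10.0, 14.0]), "TCX2",
                                  windows=[96, 104, 112, 120])
        assert calls.at["QC", "call"] == "quiescent"

    def test_constant_expression_quiescent(self):
        calls = classify_division(self._traj([7.0, 7.0, 7.0, 7.0]), "TCX2",
                                  windows=[96, 104, 112, 120])
        assert calls.at["QC", "call"] == "quiescent"

    def test_missing_focal_gene_raises(self):
        with pytest.raises(ValueError):
            classify_division(self._traj([1, 1, 1, 1]), "WOX5",
                              windows=[96, 104, 112, 120])
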