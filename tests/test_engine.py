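"""Stock-flow engine: validation diagnostics, Euler stepping, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from ymhsim.engine import (
    ConvergenceError,
    ModelGraph,
    Override,
    SimulationError,
    SimulationSettings,
    compose,
    parse_expression,
    refine_until_converged,
    simulate,
    validate_graph,
)


def constant_inflow_graph(initial=0.0, rate=10.0):
    g = ModelGraph()
    g.add_stock("tank", initial)
    g.add_param("fill", rate)
    g.add_flow("filling", "fill", sink="tank")
    return g


def decay_graph(s0=100.0, k=0.3):
    g = ModelGraph()
    g.add_stock("mass", s0)
    g.add_param("k", k)
    g.add_flow("loss", "k * mass", source="mass")
    return g


class TestValidation:
    def test_minimal_valid_graph(self):
        assert validate_graph(constant_inflow_graph()) == []

    def test_smallest_auxiliary_cycle(self):
        g = ModelGraph()
        g.add_aux("a", "b")
        g.add_aux("b", "a")
        diags = validate_graph(g)
        assert [d.rule for d in diags] == ["cyclic-auxiliaries"]

    def test_undefined_parameter_reference(self):
        g = ModelGraph()
        g.add_stock("s", 1.0)
        g.add_flow("out", "k * s", source="s")
        diags = validate_graph(g)
        assert len(diags) == 1
        assert diags[0].rule == "undefined-symbol"
        assert "'k'" in diags[0].message

    def test_unknown_flow_endpoint_and_bad_lookup(self):
        g = ModelGraph()
        g.add_stock("s", 1.0)
        g.add_flow("move", "1", source="s", sink="nowhere")
        g.add_lookup("tbl", [(0.0, 1.0), (0.0, 2.0)])
        rules = {d.rule for d in validate_graph(g)}
        assert rules == {"unknown-endpoint", "bad-lookup"}

    def test_duplicate_symbol_rejected_at_declaration(self):
        g = ModelGraph()
        g.add_stock("s", 1.0)
        with pytest.raises(ValueError, match="already defined"):
            g.add_param("s", 2.0)

    def test_expression_parser_round_trips_structure(self):
        node = parse_expression("min(a + b, 2) * -c ^ 2")
        assert node[0] == "bin" and node[1] == "*"


class TestSimulate:
    def test_linear_accumulation(self):
        traj = simulate(constant_inflow_graph(), SimulationSettings(0.0, 5.0, 1.0 / 12))
        assert traj["tank"][-1] == pytest.approx(50.0, abs=1e-9)

    def test_exponential_decay_matches_closed_form(self):
        """First-order decay tracks 100*exp(-0.3 t) within 0.5% of scale at dt=1/64.

        Error is measured relative to the series scale (the same metric the
        dt-refinement loop uses); explicit first-order stepping has a known
        pointwise-relative error of k^2*t*dt/2 that exceeds any fixed
        pointwise tolerance for late, near-zero values.
        """
        traj = simulate(decay_graph(), SimulationSettings(0.0, 10.0, 1.0 / 64))
        exact = 100.0 * np.exp(-0.3 * traj.time)
        assert np.max(np.abs(traj["mass"] - exact)) <= 0.005 * np.max(exact)
        # pointwise agreement also holds wherever the state is not yet tiny
        body = exact >= 20.0
        assert np.all(np.abs(traj["mass"] - exact)[body] <= 0.005 * exact[body])

    def test_closed_two_stock_chain_conserves_mass(self):
        g = ModelGraph()
        g.add_stock("a", 70.0)
        g.add_stock("b", 30.0)
        g.add_param("r", 0.4)
        g.add_flow("transfer", "r * a", source="a", sink="b")
        traj = simulate(g, SimulationSettings(0.0, 20.0, 0.25))
        total = traj["a"] + traj["b"]
        assert np.max(np.abs(total - 100.0)) <= 1e-9 * 100.0

    def test_override_identity_is_bit_exact(self):
        g = decay_graph()
        s = SimulationSettings(0.0, 10.0, 1.0 / 12)
        base = simulate(g, s)
        ident = simulate(g, s, [Override("k", "multiply", 1.0, 2.0, 8.0)])
        assert base.equals(ident)

    def test_override_window_applies_inclusively_from_start(self):
        g = constant_inflow_graph(rate=1.0)
        s = SimulationSettings(0.0, 4.0, 0.5)
        traj = simulate(g, s, [Override("fill", "set", 0.0, 2.0, math.inf)])
        # inflow of 1/yr for 2 years, then shut off exactly at t=2
        assert traj["tank"][-1] == pytest.approx(2.0)
        assert np.all(traj["filling"][traj.time >= 2.0] == 0.0)

    def test_nonnegative_stock_outflow_is_rescaled_not_clamped(self):
        g = ModelGraph()
        g.add_stock("q", 1.0)
        g.add_stock("sink_a", 0.0)
        g.add_stock("sink_b", 0.0)
        g.add_param("big", 30.0)
        g.add_flow("to_a", "big", source="q", sink="sink_a")
        g.add_flow("to_b", "3 * big", source="q", sink="sink_b")
        traj = simulate(g, SimulationSettings(0.0, 1.0, 0.25))
        assert np.all(traj["q"] >= 0.0)
        # proportional split of the limited budget is preserved: 1:3
        assert traj["sink_b"][-1] == pytest.approx(3.0 * traj["sink_a"][-1])
        assert traj["sink_a"][-1] + traj["sink_b"][-1] == pytest.approx(1.0)

    def test_nonfinite_run_aborts_with_symbol_named(self):
        g = ModelGraph()
        g.add_stock("s", 1.0, nonnegative=False)
        g.add_param("r", 80.0)
        g.add_flow("blow", "r * s * s", sink="s")
        with pytest.raises(SimulationError, match="t="):
            simulate(g, SimulationSettings(0.0, 40.0, 0.5))

    def test_invalid_graph_refused(self):
        g = ModelGraph()
        g.add_aux("a", "b")
        with pytest.raises(ValueError, match="undefined"):
            simulate(g, SimulationSettings(0.0, 1.0, 0.5))

    def test_lookup_interpolates_and_clamps(self):
        g = ModelGraph()
        g.add_stock("s", 0.0)
        g.add_lookup("ramp", [(0.0, 0.0), (2.0, 4.0)])
        g.add_aux("level", "ramp(t)")
        g.add_flow("fill", "level", sink="s")
        traj = simulate(g, SimulationSettings(0.0, 4.0, 0.5))
        lv = traj["level"]
        assert lv[1] == pytest.approx(1.0)  # t=0.5 -> 1.0
        assert lv[-1] == pytest.approx(4.0)  # clamped beyond x=2


class TestRefinement:
    def test_linear_model_converges_at_first_refinement(self):
        g = constant_inflow_graph()
        traj, dt = refine_until_converged(g, SimulationSettings(0.0, 5.0, 0.5))
        assert dt == 0.25
        assert traj["tank"][-1] == pytest.approx(50.0)

    def test_stiff_decay_converges_by_dt_1_64(self):
        g = decay_graph(k=5.0)
        traj, dt = refine_until_converged(g, SimulationSettings(0.0, 2.0, 1.0 / 8))
        assert dt <= 1.0 / 64
        exact = 100.0 * np.exp(-5.0 * traj.time)
        scale = np.maximum(exact, 1e-6)
        assert np.max(np.abs(traj["mass"] - exact) / scale[0]) < 0.01

    def test_refinement_floor_raises_with_worst_series(self):
        g = decay_graph(k=5.0)
        with pytest.raises(ConvergenceError, match="mass"):
            refine_until_converged(
                g, SimulationSettings(0.0, 2.0, 1.0 / 256), rel_tol=1e-9, min_dt=1.0 / 1024
            )


class TestComposition:
    def test_compose_merges_and_rejects_collisions(self):
        a = constant_inflow_graph()
        b = decay_graph()
        g = compose(a, b)
        assert set(g.stocks) == {"tank", "mass"}
        with pytest.raises(ValueError, match="collision"):
            compose(a, constant_inflow_graph())


@hyp_settings(max_examples=40, deadline=None, derandomize=True)
@given(
    init=st.lists(st.floats(1.0, 1e4), min_size=3, max_size=3),
    rates=st.lists(st.floats(0.0, 2.0), min_size=3, max_size=3),
)
def test_closed_chain_conservation_property(init, rates):
    """Any closed three-stock loop conserves its total to 1e-9 relative."""
    g = ModelGraph()
    names = ["x0", "x1", "x2"]
    for n, v in zip(names, init):
        g.add_stock(n, v)
    for i, r in enumerate(rates):
        g.add_param(f"r{i}", r)
        g.add_flow(f"f{i}", f"r{i} * {names[i]}", source=names[i], sink=names[(i + 1) % 3])
    traj = simulate(g, SimulationSettings(0.0, 5.0, 1.0 / 12))
    total = sum(traj[n] for n in names)
    assert np.max(np.abs(total - total[0])) <= 1e-9 * total[0]


def test_settings_validation():
    with pytest.raises(ValueError):
        SimulationSettings(2.0, 1.0, 0.1)
    with pytest.raises(ValueError):
        SimulationSettings(0.0, 1.0, 0.3)
    assert SimulationSettings(2025.0, 2035.0, 1.0 / 12).n_steps == 120
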