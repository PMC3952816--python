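"""Reduced right-hand sides, simulation, steady states, trajectory analysis."""

import numpy as np
import pytest

import retronet as rn
from retronet.dynamics import (
    ReducedModel,
    detect_oscillation,
    find_steady_states,
    is_stable,
    reduced_rhs_connected,
    reduced_rhs_isolated,
    reduced_rhs_with_input,
    response_time,
    simulate_reduced,
    steady_state,
)
from retronet.errors import AnalysisError, ConfigurationError
from retronet.mechanistic import Trajectory
from retronet.signals import constant, pulse, sinusoid
from retronet import _network as netw


def test_hill_mode_is_plain_hill_field(autoreg_module):
    m = ReducedModel.from_spec(autoreg_module, mode="hill")
    x = np.array([40.0])
    b = autoreg_module.node("x1").binding
    expected = rn.hill_production(b, [40.0]) - 1.0 * 40.0
    assert m.rhs(0.0, x)[0] == pytest.approx(expected)


def test_autoregulation_premultiplier_scalar_form(autoreg_module):
    """dx/dt = (H - delta x)/(1 + R): the slowdown factor of autoregulation."""
    x = np.array([40.0])
    b = autoreg_module.node("x1").binding
    f = rn.hill_production(b, [40.0]) - 40.0
    R = rn.node_retroactivity(b, [40.0]).R[0, 0]
    assert reduced_rhs_isolated(autoreg_module, x)[0] == pytest.approx(f / (1.0 + R))
    assert R > 0


def test_clock_premultiplier_couples_nodes():
    """Competitive two-parent promoter gives a full 2x2 premultiplier."""
    mod = rn.ModuleSpec(
        "clock",
        (
            rn.NodeSpec(
                "A",
                1.0,
                rn.BindingSpec(
                    "competitive",
                    ("A", "B"),
                    (2, 4),
                    (25.0, 160000.0),
                    15.0,
                    rn.Production(alpha0=0.3, alpha1=7.0),
                ),
            ),
            rn.NodeSpec(
                "B",
                0.3,
                rn.BindingSpec(
                    "single", ("A",), (2,), (25.0,), 15.0, rn.Production(alpha1=1.3)
                ),
            ),
        ),
    )
    x = np.array([5.0, 20.0])
    R = rn.internal_retroactivity(mod, x)
    assert R[0, 1] < 0 and R[1, 0] < 0  # competitive coupling
    f = ReducedModel.from_spec(mod, mode="hill").rhs(0.0, x)
    dx = reduced_rhs_isolated(mod, x)
    np.testing.assert_allclose((np.eye(2) + R) @ dx, f, rtol=1e-12)


def test_with_input_frozen_equals_isolated():
    mod = rn.ModuleSpec(
        "m",
        (
            rn.NodeSpec(
                "x1",
                1.0,
                rn.BindingSpec(
                    "single", ("u1",), (1,), (50.0,), 10.0, rn.Production(alpha1=60.0)
                ),
            ),
        ),
        inputs=("u1",),
    )
    x = np.array([30.0])
    dx_frozen = reduced_rhs_with_input(mod, x, u=[20.0], udot=[0.0])
    sigs = {"u1": constant("u1", 20.0)}
    m = ReducedModel.from_spec(mod, signals=sigs)
    np.testing.assert_allclose(dx_frozen, m.rhs(0.0, x))


def test_input_derivative_moves_free_tf_with_frozen_totals():
    """Competitive input binding: with f == 0, dx = -(I+R)^{-1} S du."""
    mod = rn.ModuleSpec(
        "m",
        (
            rn.NodeSpec("x1", 1e-12, rn.BindingSpec("none", promoter_total=0.0)),
            rn.NodeSpec(
                "x2",
                1e-12,
                rn.BindingSpec(
                    "competitive", ("x1", "u1"), (1, 1), (20.0, 20.0), 50.0
                ),
            ),
        ),
        inputs=("u1",),
    )
    x = np.array([10.0, 0.0])
    dx = reduced_rhs_with_input(mod, x, u=[15.0], udot=[8.0])
    # production/decay negligible, yet free x1 changes: S-driven displacement
    assert dx[0] > 1e-3
    dx0 = reduced_rhs_with_input(mod, x, u=[15.0], udot=[0.0])
    assert abs(dx0[0]) < 1e-9


def test_connected_reduces_to_isolated_when_unwired(toggle_module, load_context):
    ic = rn.InterconnectionSpec(toggle_module, load_context)
    x = [100.0, 20.0]
    v = [5.0, 5.0]
    sigs = {"u1": constant("u1", 0.0), "u2": constant("u2", 0.0)}
    dx, dv = reduced_rhs_connected(ic, x, v, signals=sigs)
    np.testing.assert_allclose(dx, reduced_rhs_isolated(toggle_module, x), rtol=1e-12)


def test_scalar_scaling_slows_dynamics():
    """Scaling retroactivity rescales a scalar module: dx_conn = f/(1+R+Sbar)."""
    mod = rn.ModuleSpec(
        "m",
        (
            rn.NodeSpec(
                "x",
                1.0,
                rn.BindingSpec(
                    "single", ("x",), (1,), (100.0,), 20.0, rn.Production(alpha0=30.0)
                ),
            ),
        ),
    )
    ctx = rn.ModuleSpec(
        "ctx",
        (
            rn.NodeSpec(
                "y",
                1.0,
                rn.BindingSpec("single", ("u",), (1,), (50.0,), 200.0, rn.Production()),
            ),
        ),
        inputs=("u",),
    )
    ic = rn.InterconnectionSpec(mod, ctx, context_wiring={"u": "x"})
    x, v = [40.0], [10.0]
    b = mod.node("x").binding
    f = rn.hill_production(b, x) - x[0]
    R = rn.node_retroactivity(b, x).R[0, 0]
    Sbar = rn.node_retroactivity(ctx.node("y").binding, x).R[0, 0]
    dx, dv = reduced_rhs_connected(ic, x, v)
    assert dx[0] == pytest.approx(f / (1.0 + R + Sbar), rel=1e-10)
    assert abs(dx[0]) < abs(f / (1.0 + R))  # slower than isolated


def test_slowdown_pointwise_everywhere():
    """|dx_conn| < |dx_iso| wherever f != 0 for scalar module with Sbar > 0."""
    mod = rn.ModuleSpec(
        "m",
        (
            rn.NodeSpec(
                "x",
                1.0,
                rn.BindingSpec(
                    "single", ("x",), (1,), (1.0,), 60.0, rn.Production(alpha0=20.0)
                ),
            ),
        ),
    )
    ctx = rn.ModuleSpec(
        "ctx",
        (
            rn.NodeSpec(
                "y",
                1.0,
                rn.BindingSpec("single", ("u",), (1,), (50.0,), 120.0, rn.Production()),
            ),
        ),
        inputs=("u",),
    )
    ic = rn.InterconnectionSpec(mod, ctx, context_wiring={"u": "x"})
    for x in np.geomspace(0.1, 500.0, 25):
        dx_iso = reduced_rhs_isolated(mod, [x])[0]
        dx_conn, _ = reduced_rhs_connected(ic, [x], [10.0])
        if abs(dx_iso) > 1e-9:
            assert abs(dx_conn[0]) < abs(dx_iso)


def test_reduced_simulation_matches_closed_form():
    mod = rn.ModuleSpec(
        "c",
        (
            rn.NodeSpec(
                "x1",
                1.0,
                rn.BindingSpec(
                    "none", promoter_total=10.0, production=rn.Production(alpha0=60.0)
                ),
            ),
        ),
    )
    m = ReducedModel.from_spec(mod, mode="hill")
    tr = simulate_reduced(m, [0.0], t_end=6.0, dt_out=0.05)
    np.testing.assert_allclose(
        tr.states[:, 0], 600.0 * (1 - np.exp(-tr.times)), rtol=1e-6, atol=1e-5
    )


def test_total_tf_identity_along_trajectory(autoreg_module):
    """(I + R(x)) dx/dt equals d/dt of (free + bound) along the solution."""
    m = ReducedModel.from_spec(autoreg_module)
    tr = simulate_reduced(m, [2.0], t_end=5.0, dt_out=0.01)
    net = m.network
    totals = np.array(
        [z + netw.total_bound(net, np.array([z]), {})[0] for z in tr.states[:, 0]]
    )
    dtot = np.gradient(totals, tr.times)
    f = np.array([m.slow_field(t, np.array([z]))[0] for t, z in zip(tr.times, tr.states[:, 0])])
    interior = slice(30, -5)
    np.testing.assert_allclose(dtot[interior], f[interior], rtol=5e-3, atol=1e-3)


def test_steady_state_constitutive():
    mod = rn.ModuleSpec(
        "c",
        (
            rn.NodeSpec(
                "x1",
                1.0,
                rn.BindingSpec(
                    "none", promoter_total=10.0, production=rn.Production(alpha0=60.0)
                ),
            ),
        ),
    )
    m = ReducedModel.from_spec(mod)
    assert steady_state(m, guess=[1.0])[0] == pytest.approx(600.0)


def test_reduced_and_full_equilibria_coincide(autoreg_module):
    m_red = ReducedModel.from_spec(autoreg_module)
    x_star = steady_state(m_red, guess=[100.0])
    m_full = rn.build_full_model(autoreg_module)
    tr = rn.simulate_full(m_full, x_star, t_end=50.0, dt_out=1.0)
    assert tr.states[-1, 0] == pytest.approx(x_star[0], rel=1e-6)


def test_toggle_multistart_finds_three_equilibria(toggle_module):
    m = ReducedModel.from_spec(toggle_module)
    roots = find_steady_states(m)
    assert len(roots) == 3
    stabilities = sorted(is_stable(m, r) for r in roots)
    assert stabilities == [False, True, True]


def test_response_time_closed_form():
    t = np.linspace(0.0, 10.0, 2001)
    x = 100.0 * (1 - np.exp(-t))
    traj = Trajectory(times=t, states=x[:, None], labels=("x",))
    assert response_time(traj, 0.5) == pytest.approx(np.log(2.0), abs=2e-3)
    assert response_time(traj, 0.9) == pytest.approx(np.log(10.0), abs=2e-3)


def test_response_time_requires_convergence():
    t = np.linspace(0.0, 10.0, 500)
    x = t.copy()  # never settles
    traj = Trajectory(times=t, states=x[:, None], labels=("x",))
    with pytest.raises(AnalysisError):
        response_time(traj, 0.5)


def test_oscillation_verdicts_on_synthetic_waveforms():
    t = np.linspace(0.0, 40.0, 4001)
    flat = Trajectory(times=t, states=np.ones((t.size, 1)), labels=("x",))
    assert detect_oscillation(flat).verdict == "none"
    sin = Trajectory(
        times=t, states=(5.0 + np.sin(t))[:, None], labels=("x",)
    )
    v = detect_oscillation(sin)
    assert v.verdict == "sustained"
    assert v.period == pytest.approx(2 * np.pi, rel=0.02)
    damped = Trajectory(
        times=t,
        states=(5.0 + np.exp(-0.2 * t) * np.sin(t))[:, None],
        labels=("x",),
    )
    assert detect_oscillation(damped).verdict != "sustained"


def test_missing_signal_raises(toggle_module, load_context):
    ic = rn.InterconnectionSpec(toggle_module, load_context, context_wiring={"u1": "x1"})
    m = ReducedModel.from_spec(ic)  # u2 unwired, no signal bound
    with pytest.raises(ConfigurationError):
        m.rhs(0.0, np.array([1.0, 1.0, 1.0, 1.0]))
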