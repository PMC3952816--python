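"""Promoter occupancy, Hill production and retroactivity matrices.

The closed forms are pinned against two independent numeric routes: a
damped-Newton solve of the binding fixed point (occupancies) and central
finite differences of the total-bound map (retroactivities).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import retronet as rn
from retronet.errors import ConditioningError, ContractError, DomainError
from retronet.retroactivity import STATE_CATALOG
from conftest import make_binding, random_parent_concs


def total_bound(binding, x):
    res = rn.qss_complexes(binding, x)
    M = rn.node_retroactivity(binding, np.maximum(x, 1e-30)).M
    return M @ res.gamma


def fd_jacobian(binding, x, rel=1e-6):
    x = np.asarray(x, dtype=float)
    J = np.zeros((x.size, x.size))
    for k in range(x.size):
        h = rel * max(x[k], 1.0)
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] = max(xm[k] - h, 0.0)
        J[:, k] = (total_bound(binding, xp) - total_bound(binding, xm)) / (xp[k] - xm[k])
    return J


# -- occupancies -------------------------------------------------------------


def test_single_monomer_half_occupancy():
    b = rn.BindingSpec("single", ("x",), (1,), (100.0,), 10.0, rn.Production(alpha0=60.0))
    res = rn.qss_complexes(b, [100.0])
    assert res.gamma[1] == pytest.approx(5.0)
    assert res.free_promoter == pytest.approx(5.0)


def test_zero_parents_leave_promoter_empty():
    for btype in ("single", "independent", "competitive", "cooperative"):
        n_par = 1 if btype == "single" else 2
        b = rn.BindingSpec(
            btype,
            tuple(f"p{i}" for i in range(n_par)),
            (2,) * n_par,
            (50.0,) * n_par,
            7.0,
        )
        res = rn.qss_complexes(b, [0.0] * n_par)
        assert res.gamma[0] == pytest.approx(7.0)
        assert np.all(res.gamma[1:] == 0.0)


@pytest.mark.parametrize("seed", range(30))
def test_qss_matches_newton_oracle(seed):
    """Closed-form occupancies equal the damped-Newton binding fixed point."""
    rng = np.random.default_rng(seed)
    b = make_binding(rng)
    x = random_parent_concs(rng, b)
    g_closed = rn.qss_complexes(b, x).gamma
    g_newton = rn.qss_newton(b, x).gamma
    assert np.max(np.abs(g_closed - g_newton)) <= 1e-8 * b.promoter_total


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_qss_partition_invariants(seed):
    """States are nonnegative and always sum to the promoter total."""
    rng = np.random.default_rng(seed)
    b = make_binding(rng)
    x = random_parent_concs(rng, b)
    res = rn.qss_complexes(b, x)
    assert np.all(res.gamma >= 0)
    assert res.gamma.sum() == pytest.approx(b.promoter_total, rel=1e-12)
    assert np.all(np.isfinite(res.jacobian))


def test_negative_concentration_rejected():
    b = rn.BindingSpec("single", ("x",), (1,), (1.0,), 1.0)
    with pytest.raises(DomainError):
        rn.qss_complexes(b, [-0.5])


# -- Hill production ---------------------------------------------------------


def test_hill_constitutive_and_repressor_examples():
    none = rn.BindingSpec("none", promoter_total=10.0, production=rn.Production(alpha0=60.0))
    assert rn.hill_production(none) == pytest.approx(600.0)
    rep = rn.BindingSpec(
        "single", ("x",), (1,), (100.0,), 10.0, rn.Production(alpha0=60.0, alpha1=0.0)
    )
    assert rn.hill_production(rep, [100.0]) == pytest.approx(300.0)


def test_repressor_production_vanishes_monotonically():
    rep = rn.BindingSpec(
        "single", ("x",), (2,), (100.0,), 10.0, rn.Production(alpha0=60.0)
    )
    xs = np.geomspace(0.1, 1e4, 50)
    H = np.array([rn.hill_production(rep, [x]) for x in xs])
    assert np.all(np.diff(H) < 0)
    assert H[-1] < 1e-3 * H[0]


# -- node retroactivity ------------------------------------------------------


def test_monomer_and_dimer_closed_forms():
    mono = rn.BindingSpec("single", ("x",), (1,), (100.0,), 100.0)
    # p_T K / (K + x)^2 at x = 0
    assert rn.node_retroactivity(mono, [0.0]).R[0, 0] == pytest.approx(1.0)
    dim = rn.BindingSpec("single", ("x",), (2,), (100.0,), 100.0)
    # finite difference of bound = 2 p_T x^2/(K + x^2) at x = 10
    assert rn.node_retroactivity(dim, [10.0]).R[0, 0] == pytest.approx(10.0)


def test_no_parents_has_no_retroactivity():
    b = rn.BindingSpec("none", promoter_total=5.0)
    with pytest.raises(ContractError):
        rn.node_retroactivity(b, [])


@pytest.mark.parametrize("seed", range(50))
def test_matches_finite_difference_oracle(seed):
    """Closed-form R_i equals the FD Jacobian of the total-bound map."""
    rng = np.random.default_rng(1000 + seed)
    b = make_binding(rng)
    x = random_parent_concs(rng, b)
    R = rn.node_retroactivity(b, x).R
    R_fd = fd_jacobian(b, x)
    scale = max(np.abs(R_fd).max(), 1e-9)
    assert np.abs(R - R_fd).max() <= 1e-5 * scale


def test_sign_structure_all_types():
    rng = np.random.default_rng(7)
    seen = set()
    for _ in range(300):
        b = make_binding(rng)
        x = random_parent_concs(rng, b)
        R = rn.node_retroactivity(b, x).R
        seen.add(b.binding_type)
        assert np.all(np.diag(R) >= 0)
        if b.binding_type == "independent":
            assert R[0, 1] == 0.0 and R[1, 0] == 0.0
        elif b.binding_type == "competitive":
            assert R[0, 1] <= 0 and R[1, 0] <= 0
        elif b.binding_type == "cooperative":
            assert R[0, 1] >= 0 and R[1, 0] >= 0
    assert seen == {"single", "independent", "competitive", "cooperative"}


def test_retroactivity_scales_with_promoter_total():
    rng = np.random.default_rng(3)
    for _ in range(20):
        b = make_binding(rng)
        x = random_parent_concs(rng, b)
        R1 = rn.node_retroactivity(b, x).R
        b2 = rn.BindingSpec(
            b.binding_type,
            b.parents,
            b.multimerization,
            b.dissociation,
            2.0 * b.promoter_total,
            b.production,
        )
        R2 = rn.node_retroactivity(b2, x).R
        np.testing.assert_allclose(R2, 2.0 * R1, rtol=1e-12)


def test_single_parent_limits():
    x = 50.0
    # decreasing branch: K above the parent concentration
    Ks = np.geomspace(100.0, 1e8, 30)
    Rs = [
        rn.node_retroactivity(
            rn.BindingSpec("single", ("x",), (1,), (K,), 10.0), [x]
        ).R[0, 0]
        for K in Ks
    ]
    assert np.all(np.diff(Rs) < 0) and Rs[-1] < 1e-5
    xs = np.geomspace(1.0, 1e6, 30)
    b = rn.BindingSpec("single", ("x",), (1,), (100.0,), 10.0)
    Rx = [rn.node_retroactivity(b, [x]).R[0, 0] for x in xs]
    assert Rx[-1] < 1e-6 * Rx[0]


# -- module-level assembly ---------------------------------------------------


def test_internal_retroactivity_trivial_and_autoreg(autoreg_module):
    const = rn.ModuleSpec(
        "c",
        (
            rn.NodeSpec(
                "x1", 1.0, rn.BindingSpec("none", promoter_total=1.0)
            ),
        ),
    )
    assert rn.internal_retroactivity(const, [5.0]).tolist() == [[0.0]]
    node = autoreg_module.node("x1")
    R = rn.internal_retroactivity(autoreg_module, [40.0])
    expected = rn.node_retroactivity(node.binding, [40.0]).R[0, 0]
    assert R[0, 0] == pytest.approx(expected)


def test_two_node_chain_places_load_on_parent():
    """x1 -> x2 regulation loads x1 only, at position (1,1)."""
    chain = rn.ModuleSpec(
        "chain",
        (
            rn.NodeSpec("x1", 1.0, rn.BindingSpec("none", promoter_total=2.0)),
            rn.NodeSpec(
                "x2",
                1.0,
                rn.BindingSpec("single", ("x1",), (2,), (400.0,), 30.0),
            ),
        ),
    )
    x = [15.0, 99.0]
    R = rn.internal_retroactivity(chain, x)
    b2 = chain.node("x2").binding
    expected = rn.node_retroactivity(b2, [15.0]).R[0, 0]
    assert R[0, 0] == pytest.approx(expected)
    assert R[0, 1] == R[1, 0] == R[1, 1] == 0.0


def test_external_retroactivity_structure():
    def module(btype):
        return rn.ModuleSpec(
            "m",
            (
                rn.NodeSpec("x1", 1.0, rn.BindingSpec("none", promoter_total=1.0)),
                rn.NodeSpec(
                    "x2",
                    1.0,
                    rn.BindingSpec(btype, ("x1", "u1"), (1, 1), (10.0, 10.0), 5.0),
                ),
            ),
            inputs=("u1",),
        )

    x, u = [8.0, 1.0], [6.0]
    S_ind = rn.external_retroactivity(module("independent"), x, u)
    assert np.all(S_ind == 0.0)
    S_comp = rn.external_retroactivity(module("competitive"), x, u)
    assert S_comp.shape == (2, 1)
    assert S_comp[0, 0] < 0  # input binding displaces bound internal TF
    no_inputs = rn.ModuleSpec(
        "m0", (rn.NodeSpec("x1", 1.0, rn.BindingSpec("none", promoter_total=1.0)),)
    )
    assert rn.external_retroactivity(no_inputs, [1.0]).shape == (1, 0)


def test_interconnection_matrix_structure(toggle_ic):
    mats = rn.interconnection_matrices(toggle_ic, [140.0, 6.0], [200.0, 10.0])
    # single-parent context: scaling diagonal, no mixing anywhere
    assert np.all(mats.Mbar == 0.0) and np.all(mats.Mbar_from_module == 0.0)
    assert mats.Sbar[0, 1] == 0.0 and mats.Sbar[1, 0] == 0.0
    assert mats.Sbar[0, 0] > 0 and mats.Sbar[1, 1] > 0
    # context nodes have no internal parents
    assert np.all(mats.Rbar == 0.0)
    # toggle internal retroactivity is diagonal (each TF loaded by the other's promoter)
    assert mats.R[0, 1] == 0.0 and mats.R[1, 0] == 0.0


def test_unwired_pair_has_zero_interconnection_blocks(toggle_module, load_context):
    ic = rn.InterconnectionSpec(toggle_module, load_context)
    mats = rn.interconnection_matrices(ic, [1.0, 2.0], [3.0, 4.0], u_ext={"u1": 0.0, "u2": 0.0})
    for M in (mats.Sbar, mats.Mbar, mats.Sbar_from_module, mats.Mbar_from_module):
        assert np.all(M == 0.0)


def test_premultiplier_equals_identity_plus_blocks(toggle_ic):
    z = np.array([100.0, 10.0, 150.0, 20.0])
    mats = rn.interconnection_matrices(toggle_ic, z[:2], z[2:])
    A = mats.premultiplier
    n = 2
    np.testing.assert_allclose(A[:n, :n], np.eye(n) + mats.R + mats.Sbar)
    np.testing.assert_allclose(A[n:, n:], np.eye(2) + mats.Rbar + mats.Sbar_from_module)
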