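"""Schema validation, selector bookkeeping, IO round trips, fixture generator."""

import numpy as np
import pytest
import yaml

import retronet as rn
from retronet.errors import (
    ConsistencyError,
    ReferenceError_,
    ValidationError,
)
from retronet.netspec import PARAMETER_RANGES, serialize_module, with_promoter_total


def test_binding_type_parent_count_consistency():
    with pytest.raises(ConsistencyError):
        rn.BindingSpec("single", parents=())
    with pytest.raises(ConsistencyError):
        rn.BindingSpec(
            "none", parents=("a",), multimerization=(1,), dissociation=(1.0,)
        )
    with pytest.raises(ConsistencyError):
        rn.BindingSpec(
            "competitive", parents=("a",), multimerization=(1,), dissociation=(1.0,)
        )


def test_forbidden_production_states():
    # competitive: no doubly bound complex exists
    with pytest.raises(ConsistencyError):
        rn.BindingSpec(
            "competitive",
            ("a", "b"),
            (1, 1),
            (1.0, 1.0),
            1.0,
            rn.Production(alpha12=5.0),
        )
    # cooperative: second parent cannot bind alone
    with pytest.raises(ConsistencyError):
        rn.BindingSpec(
            "cooperative",
            ("a", "b"),
            (1, 1),
            (1.0, 1.0),
            1.0,
            rn.Production(alpha2=5.0),
        )


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(multimerization=(0,), dissociation=(1.0,)),
        dict(multimerization=(1,), dissociation=(0.0,)),
        dict(multimerization=(1,), dissociation=(-2.0,)),
    ],
)
def test_positivity_invariants(kwargs):
    with pytest.raises(ValidationError):
        rn.BindingSpec("single", parents=("a",), promoter_total=1.0, **kwargs)


def test_dangling_parent_reference_rejected():
    with pytest.raises(ReferenceError_):
        rn.ModuleSpec(
            "m",
            (
                rn.NodeSpec(
                    "x1",
                    1.0,
                    rn.BindingSpec("single", ("ghost",), (1,), (1.0,), 1.0),
                ),
            ),
        )


def test_selector_matrices_examples(toggle_module, autoreg_module):
    # autoregulation: V_1 = [1], no input columns
    V, W = autoreg_module.selector_matrices("x1")
    assert V.tolist() == [[1.0]]
    assert W.shape == (1, 0)
    # toggle: x1's parent is x2 and vice versa
    V1, _ = toggle_module.selector_matrices("x1")
    V2, _ = toggle_module.selector_matrices("x2")
    assert V1.tolist() == [[0.0, 1.0]]
    assert V2.tolist() == [[1.0, 0.0]]


def test_selector_stack_recovers_parents():
    """V_i @ x + W_i @ u reproduces the declared parent vector, in order."""
    spec = rn.ModuleSpec(
        "m",
        (
            rn.NodeSpec(
                "x1",
                1.0,
                rn.BindingSpec(
                    "competitive", ("u1", "x2"), (1, 2), (10.0, 20.0), 5.0
                ),
            ),
            rn.NodeSpec("x2", 1.0, rn.BindingSpec("none", promoter_total=1.0)),
        ),
        inputs=("u1",),
    )
    x = np.array([3.0, 7.0])
    u = np.array([11.0])
    V, W = spec.selector_matrices("x1")
    np.testing.assert_array_equal(V @ x + W @ u, [11.0, 7.0])
    assert np.all((V.sum(axis=1) + W.sum(axis=1)) == 1.0)


def test_constitutive_module_has_no_internal_parents():
    spec = rn.ModuleSpec(
        "m",
        (
            rn.NodeSpec(
                "x1",
                1.0,
                rn.BindingSpec("none", promoter_total=1.0, production=rn.Production(alpha0=1.0)),
            ),
        ),
    )
    assert spec.internal_parent_nodes == ()
    assert spec.input_parent_nodes == ()


def test_yaml_round_trip(tmp_path, toggle_module):
    path = tmp_path / "toggle.yaml"
    rn.save_module(toggle_module, path)
    loaded = rn.load_module(path)
    assert rn.module_to_dict(loaded) == rn.module_to_dict(toggle_module)


def test_json_round_trip(tmp_path):
    spec = rn.generate_fixture(seed=42, n_nodes=4, density=0.7)
    path = tmp_path / "m.json"
    rn.save_module(spec, path)
    assert rn.module_to_dict(rn.load_module(path)) == rn.module_to_dict(spec)


def test_load_reports_missing_field(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text(yaml.safe_dump({"name": "m", "nodes": [{"id": "x1", "delta": 1.0}]}))
    with pytest.raises(ValidationError, match="binding"):
        rn.load_module(path)


def test_fixture_determinism_and_bounds():
    a = serialize_module(rn.generate_fixture(seed=1, n_nodes=5, density=0.8))
    b = serialize_module(rn.generate_fixture(seed=1, n_nodes=5, density=0.8))
    assert a == b  # byte identical
    # distribution bounds over many modules
    lo_K, hi_K = PARAMETER_RANGES["K_half"]
    lo_p, hi_p = PARAMETER_RANGES["p_T"]
    lo_d, hi_d = PARAMETER_RANGES["delta"]
    for seed in range(200):
        m = rn.generate_fixture(seed=seed, n_nodes=3, density=1.0)
        for node in m.nodes:
            assert lo_d <= node.delta <= hi_d
            b = node.binding
            assert b.n_parents >= 1  # density 1: every node regulated
            assert lo_p <= b.promoter_total <= hi_p
            for K, n in zip(b.dissociation, b.multimerization):
                assert lo_K <= K ** (1.0 / n) <= hi_K * (1 + 1e-12)


def test_fixture_density_zero_has_no_edges():
    m = rn.generate_fixture(seed=3, n_nodes=5, density=0.0)
    assert m.internal_parent_nodes == ()


def test_validate_interconnection_flags(toggle_ic):
    rep = rn.validate_interconnection(toggle_ic)
    # all context nodes single-parent: load yes, mixing no
    assert rep.mixing_zero and not rep.scaling_zero
    assert rep.module_mixing_zero and rep.module_scaling_zero


def test_validate_interconnection_mixed_promoter(toggle_module):
    ctx = rn.ModuleSpec(
        "ctx",
        (
            rn.NodeSpec(
                "c1",
                1.0,
                rn.BindingSpec(
                    "competitive", ("w", "c2"), (1, 1), (10.0, 10.0), 5.0
                ),
            ),
            rn.NodeSpec("c2", 1.0, rn.BindingSpec("none", promoter_total=1.0)),
        ),
        inputs=("w",),
    )
    ic = rn.InterconnectionSpec(toggle_module, ctx, context_wiring={"w": "x1"})
    rep = rn.validate_interconnection(ic)
    assert not rep.mixing_zero
    assert not rep.scaling_zero
    # an unwired pair is load-free in both directions
    ic0 = rn.InterconnectionSpec(toggle_module, ctx)
    rep0 = rn.validate_interconnection(ic0)
    assert rep0.mixing_zero and rep0.scaling_zero


def test_interconnection_Q_matrices(toggle_ic):
    Q = toggle_ic.Q
    assert Q.shape == (2, 2)
    np.testing.assert_array_equal(Q, np.eye(2))
    assert toggle_ic.Qbar.shape == (0, 2)


def test_interconnection_wiring_must_resolve(toggle_module, load_context):
    with pytest.raises(ReferenceError_):
        rn.InterconnectionSpec(
            toggle_module, load_context, context_wiring={"u1": "nope"}
        )
    with pytest.raises(ReferenceError_):
        rn.InterconnectionSpec(
            toggle_module, load_context, context_wiring={"bad_input": "x1"}
        )


def test_interconnection_file_round_trip(tmp_path, toggle_module, load_context):
    rn.save_module(toggle_module, tmp_path / "toggle.yaml")
    rn.save_module(load_context, tmp_path / "ctx.yaml")
    (tmp_path / "ic.yaml").write_text(
        yaml.safe_dump(
            {
                "module": "toggle.yaml",
                "context": "ctx.yaml",
                "wiring": [
                    {"side": "context", "input": "u1", "node": "x1"},
                    {"side": "context", "input": "u2", "node": "x2"},
                ],
            }
        )
    )
    ic = rn.load_interconnection(tmp_path / "ic.yaml")
    assert ic.module.name == "toggle"
    assert ic.context_wiring == {"u1": "x1", "u2": "x2"}


def test_with_promoter_total_helper(toggle_module):
    m2 = with_promoter_total(toggle_module, "x1", 99.0)
    assert m2.node("x1").binding.promoter_total == 99.0
    assert m2.node("x2").binding.promoter_total == 25.0
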