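"""Shared fixtures: small canonical modules and cached case-study reports."""

import numpy as np
import pytest

import retronet as rn
from retronet.casestudies import run_study


def make_binding(rng: np.random.Generator) -> rn.BindingSpec:
    """Random legal BindingSpec with 1-2 parents in physiological ranges."""
    btype = rng.choice(["single", "independent", "competitive", "cooperative"])
    n_par = 1 if btype == "single" else 2
    ns = tuple(int(rng.integers(1, 5)) for _ in range(n_par))
    Ks = tuple(float(np.exp(rng.uniform(np.log(1.0), np.log(1000.0)))) ** n for n in ns)
    alphas = dict.fromkeys(("alpha0", "alpha1", "alpha2", "alpha12"), 0.0)
    for key in ("alpha0", "alpha1", "alpha2", "alpha12"):
        alphas[key] = float(np.exp(rng.uniform(np.log(1.0), np.log(600.0))))
    if btype == "competitive":
        alphas["alpha12"] = 0.0
    if btype == "cooperative":
        alphas["alpha2"] = 0.0
    return rn.BindingSpec(
        binding_type=str(btype),
        parents=tuple(f"p{i}" for i in range(n_par)),
        multimerization=ns,
        dissociation=Ks,
        promoter_total=float(np.exp(rng.uniform(np.log(2.0), np.log(600.0)))),
        production=rn.Production(**alphas),
    )


def random_parent_concs(rng: np.random.Generator, binding: rn.BindingSpec) -> np.ndarray:
    # around each parent's half-occupancy concentration, spanning 0.1x-10x
    half = np.array(
        [K ** (1.0 / n) for K, n in zip(binding.dissociation, binding.multimerization)]
    )
    return half * np.exp(rng.uniform(np.log(0.1), np.log(10.0), size=half.size))


@pytest.fixture(scope="session")
def autoreg_module() -> rn.ModuleSpec:
    """Single autoregulated node (monomeric self-repressor)."""
    return rn.ModuleSpec(
        "nar",
        (
            rn.NodeSpec(
                "x1",
                1.0,
                rn.BindingSpec(
                    "single", ("x1",), (1,), (100.0,), 50.0, rn.Production(alpha0=120.0)
                ),
                perturbable=True,
            ),
        ),
    )


@pytest.fixture(scope="session")
def toggle_module() -> rn.ModuleSpec:
    return rn.ModuleSpec(
        "toggle",
        (
            rn.NodeSpec(
                "x1",
                1.0,
                rn.BindingSpec("single", ("x2",), (2,), (900.0,), 25.0, rn.Production(alpha0=6.0)),
                perturbable=True,
            ),
            rn.NodeSpec(
                "x2",
                1.0,
                rn.BindingSpec("single", ("x1",), (2,), (900.0,), 25.0, rn.Production(alpha0=6.0)),
                perturbable=True,
            ),
        ),
    )


@pytest.fixture(scope="session")
def load_context() -> rn.ModuleSpec:
    """Two single-parent load nodes, one per toggle TF."""
    return rn.ModuleSpec(
        "homeostasis",
        (
            rn.NodeSpec(
                "y1",
                1.0,
                rn.BindingSpec("single", ("u1",), (2,), (900.0,), 300.0, rn.Production(alpha1=5.0)),
            ),
            rn.NodeSpec(
                "y2",
                1.0,
                rn.BindingSpec("single", ("u2",), (2,), (900.0,), 300.0, rn.Production(alpha1=5.0)),
            ),
        ),
        inputs=("u1", "u2"),
    )


@pytest.fixture(scope="session")
def toggle_ic(toggle_module, load_context) -> rn.InterconnectionSpec:
    return rn.InterconnectionSpec(
        toggle_module, load_context, context_wiring={"u1": "x1", "u2": "x2"}
    )


# case-study reports are expensive; compute once per session
@pytest.fixture(scope="session")
def negautoreg_report():
    return run_study("negautoreg")


@pytest.fixture(scope="session")
def combinatorial_report():
    return run_study("combinatorial")


@pytest.fixture(scope="session")
def clock_report():
    return run_study("clock")


@pytest.fixture(scope="session")
def toggle_report():
    return run_study("toggle")


@pytest.fixture(scope="session")
def sim_report():
    return run_study("sim")


@pytest.fixture(scope="session")
def suppression_report():
    return run_study("suppression")
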