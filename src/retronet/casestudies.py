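"""Scripted motif analyses demonstrating retroactivity effects.

Six studies, each a self-contained function returning a JSON-serializable
report:

``negautoreg``
    Negative autoregulation can *slow down* a gene's response: the Hill
    nonlinearity speeds it up, but the internal retroactivity premultiplier
    1/(1 + R) slows it down, and at high gene copy number the slowdown wins.
``combinatorial``
    Two TFs co-regulating one target become dynamically coupled through the
    shared promoter: a pulse applied to one parent produces a transient in
    the other parent (same sign under competitive binding, opposite sign
    under cooperative binding, none under independent binding) even though
    no regulatory path connects them.
``clock``
    An activator-repressor oscillator predicted to oscillate by the Hill
    model is quenched by internal retroactivity; adding DNA load on the
    repressor restores the limit cycle.
``toggle``
    A bistable toggle switch that flips under a short input pulse in
    isolation fails to flip when its context loads both TFs; a wider pulse
    restores switching, at slower speed.
``sim``
    Single-input motif: raising the autoregulated regulator's gene copy
    number (at fixed steady state) slows the module but shrinks both the
    robustness metric d and the response-time penalty upon connection.
``suppression``
    A periodically driven module whose output TF binds a mixed (competitive)
    promoter in its context: the context's dynamics leak into the module
    (mixing retroactivity), severely distorting its output; rewiring through
    an extra input node makes the mixing structurally zero.

Every default parameter carries a ``source`` annotation.  The studies are
parameterized in physiological E. coli ranges (concentrations in nM, time
in hours); each annotation states how the value was fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np

from .dynamics import (
    ReducedModel,
    detect_oscillation,
    find_steady_states,
    is_stable,
    response_time,
    simulate_reduced,
    steady_state,
)
from .errors import ValidationError
from .metrics import compare_connection, robustness_metric
from .netspec import (
    BindingSpec,
    InterconnectionSpec,
    ModuleSpec,
    NodeSpec,
    Production,
    validate_interconnection,
)
from .signals import pulse, sinusoid

__all__ = [
    "Param",
    "CaseStudyConfig",
    "DEFAULTS",
    "STUDIES",
    "run_negautoreg",
    "run_combinatorial",
    "run_clock",
    "run_toggle",
    "run_sim_motif",
    "run_suppression",
    "run_study",
]


@dataclass(frozen=True)
class Param:
    """A case-study parameter with an auditable provenance note."""

    value: float | tuple
    source: str

    def __post_init__(self) -> None:
        if not self.source or not str(self.source).strip():
            raise ValidationError("every case-study parameter requires a source note")


@dataclass(frozen=True)
class CaseStudyConfig:
    study: str
    params: Mapping[str, Param]
    variants: tuple[str, ...] = ()

    def value(self, name: str):
        return self.params[name].value

    def with_overrides(self, **overrides) -> "CaseStudyConfig":
        params = dict(self.params)
        for k, v in overrides.items():
            if k not in params:
                raise ValidationError(f"unknown parameter {k!r} for study {self.study!r}")
            params[k] = Param(v, "override")
        return replace(self, params=params)


_ASSUMED = "assumed: physiological range; "

DEFAULTS: dict[str, CaseStudyConfig] = {
    "negautoreg": CaseStudyConfig(
        "negautoreg",
        {
            "delta": Param(1.0, _ASSUMED + "protein lifetime of order one cell cycle"),
            "K": Param(1.0, _ASSUMED + "strong self-repression (tight operator)"),
            "alpha_pT": Param(
                1200.0,
                _ASSUMED + "production x copy-number product fixed across settings "
                "so that all regulated variants share the same steady state",
            ),
            "p_T_settings": Param(
                (10.0, 100.0, 600.0),
                _ASSUMED + "low/medium/high copy-number settings; production rate "
                "constant is alpha_pT/p_T for each",
            ),
            "fraction": Param(0.5, "response-time fraction (default, configurable)"),
            "t_end": Param(60.0, "simulation horizon [h], long enough for tail flatness"),
        },
    ),
    "combinatorial": CaseStudyConfig(
        "combinatorial",
        {
            "x_parent_ss": Param(
                30.0, _ASSUMED + "both parents expressed constitutively to 30 nM"
            ),
            "n_multimer": Param(4, _ASSUMED + "both parents bind as tetramers"),
            "p_T_target": Param(
                200.0,
                _ASSUMED + "abundant common target (dense-overlapping-regulon regime)",
            ),
            "alpha_target": Param(50.0, _ASSUMED + "active-state production of the target"),
            "pulse_height": Param(30.0, _ASSUMED + "perturbation doubling parent 1's production"),
            "pulse_start": Param(10.0, "pulse timing [h]"),
            "pulse_width": Param(3.0, "pulse width [h]"),
            "t_end": Param(260.0, "horizon [h]; slow post-pulse relaxation under load"),
            "p_T_sweep": Param((10.0, 20.0, 40.0), "doubling series for the load scaling check"),
        },
        variants=("independent", "competitive", "cooperative"),
    ),
    "clock": CaseStudyConfig(
        "clock",
        {
            "K_act": Param(25.0, _ASSUMED + "activator dimer, half-activation at 5 nM"),
            "K_rep": Param(
                160000.0, _ASSUMED + "repressor tetramer, half-repression at 20 nM"
            ),
            "p_T": Param(15.0, _ASSUMED + "low-copy plasmid (~7 copies/cell)"),
            "alpha_act_pT": Param(
                100.0, _ASSUMED + "activator production x copy product; basal fraction 4%"
            ),
            "alpha_rep_pT": Param(
                20.0, _ASSUMED + "repressor production x copy product; basal fraction 0.4%"
            ),
            "delta_act": Param(1.0, _ASSUMED + "activator decay"),
            "delta_rep": Param(
                0.3, _ASSUMED + "repressor decay; slower than activator as the "
                "oscillator design requires"
            ),
            "load_p_T": Param(
                50.0, _ASSUMED + "extra repressor binding sites restoring oscillation"
            ),
            "t_end": Param(400.0, "horizon [h], ~10 periods after transient"),
        },
        variants=("no-R", "with-R", "with-load"),
    ),
    "toggle": CaseStudyConfig(
        "toggle",
        {
            "K": Param(900.0, _ASSUMED + "both TFs bind as dimers, half-repression at 30 nM"),
            "p_T": Param(25.0, _ASSUMED + "medium-copy toggle plasmid"),
            "alpha0": Param(6.0, _ASSUMED + "unrepressed production; high state ~144 nM"),
            "delta": Param(1.0, _ASSUMED + "protein decay"),
            "context_p_T": Param(
                300.0, _ASSUMED + "high-copy downstream targets, one per toggle TF"
            ),
            "context_K": Param(900.0, _ASSUMED + "same operator affinity as the toggle"),
            "pulse_height": Param(150.0, _ASSUMED + "induction pulse on the low TF [nM/h]"),
            "narrow_width": Param(2.0, "narrow pulse [h]: flips the isolated toggle only"),
            "wide_width": Param(10.0, "wide pulse [h]: flips the connected toggle too"),
            "t_end": Param(80.0, "horizon [h]"),
        },
        variants=("isolated-narrow", "connected-narrow", "connected-wide"),
    ),
    "sim": CaseStudyConfig(
        "sim",
        {
            "delta": Param(1.0, _ASSUMED + "regulator decay"),
            "K": Param(1.0, _ASSUMED + "tight autorepression operator"),
            "alpha_pT": Param(
                1200.0, _ASSUMED + "production x copy product, fixed so the steady "
                "state is identical across the copy-number sweep"
            ),
            "p_T_sweep": Param((10.0, 60.0, 300.0), "copy-number sweep at fixed steady state"),
            "n_targets": Param(3, _ASSUMED + "three downstream operons"),
            "target_K": Param(50.0, _ASSUMED + "target operator affinity"),
            "load_levels": Param((10.0, 40.0, 120.0), "low/medium/high load [nM per target]"),
            "fraction": Param(0.5, "response-time fraction"),
            "t_end": Param(40.0, "horizon [h]"),
        },
    ),
    "suppression": CaseStudyConfig(
        "suppression",
        {
            "K_u": Param(50.0, _ASSUMED + "input activation of the module node"),
            "p_T_module": Param(10.0, _ASSUMED + "module node copy number"),
            "alpha_module": Param(60.0, _ASSUMED + "active production of the module node"),
            "interface_K": Param(100.0, _ASSUMED + "affinity of both TFs at the mixed promoter"),
            "interface_p_T": Param(600.0, _ASSUMED + "abundant interface promoter (high copy)"),
            "p_T_sweep": Param((0.0, 200.0, 600.0), "interface promoter sweep"),
            "u_mean": Param(40.0, "periodic drive mean [nM]"),
            "u_amplitude": Param(30.0, "periodic drive amplitude [nM]"),
            "u_period": Param(6.0, "periodic drive period [h]"),
            "u2_phase": Param(3.0, "phase shift of the context drive [h]"),
            "t_end": Param(48.0, "horizon [h], 8 drive periods"),
        },
        variants=("mixed", "rewired"),
    ),
}


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------


def _negautoreg_module(alpha: float, p_T: float, K: float, delta: float) -> ModuleSpec:
    # monomeric self-repressor: alpha1 = 0, basal alpha0 = alpha
    return ModuleSpec(
        "nar",
        (
            NodeSpec(
                "x1",
                delta,
                BindingSpec("single", ("x1",), (1,), (K,), p_T, Production(alpha0=alpha)),
                perturbable=True,
            ),
        ),
    )


def _constitutive_module(alpha: float, p_T: float, delta: float) -> ModuleSpec:
    return ModuleSpec(
        "unreg",
        (
            NodeSpec(
                "x1",
                delta,
                BindingSpec("none", promoter_total=p_T, production=Production(alpha0=alpha)),
            ),
        ),
    )


def _combinatorial_module(cfg: CaseStudyConfig, btype: str, p_T3: float) -> ModuleSpec:
    xss = cfg.value("x_parent_ss")
    n = int(cfg.value("n_multimer"))
    K = xss**n  # half occupancy exactly at the parents' steady state
    a = cfg.value("alpha_target")
    prod = {
        "independent": Production(alpha12=a),
        "competitive": Production(alpha1=a, alpha2=a),
        "cooperative": Production(alpha12=a),
    }[btype]
    return ModuleSpec(
        "comb",
        (
            NodeSpec(
                "x1",
                1.0,
                BindingSpec("none", promoter_total=2.0, production=Production(alpha0=xss / 2.0)),
                perturbable=True,
            ),
            NodeSpec(
                "x2",
                1.0,
                BindingSpec("none", promoter_total=2.0, production=Production(alpha0=xss / 2.0)),
            ),
            NodeSpec(
                "x3",
                1.0,
                BindingSpec(btype, ("x1", "x2"), (n, n), (K, K), p_T3, prod),
            ),
        ),
    )


def _clock_module(cfg: CaseStudyConfig, load_p_T: float = 0.0) -> ModuleSpec:
    p_T = cfg.value("p_T")
    a1A = cfg.value("alpha_act_pT") / p_T
    a1B = cfg.value("alpha_rep_pT") / p_T
    KA, KB = cfg.value("K_act"), cfg.value("K_rep")
    nodes = [
        NodeSpec(
            "A",
            cfg.value("delta_act"),
            BindingSpec(
                "competitive",
                ("A", "B"),
                (2, 4),
                (KA, KB),
                p_T,
                Production(alpha0=0.04 * a1A, alpha1=a1A),
            ),
        ),
        NodeSpec(
            "B",
            cfg.value("delta_rep"),
            BindingSpec("single", ("A",), (2,), (KA,), p_T, Production(alpha0=0.004 * a1B, alpha1=a1B)),
        ),
    ]
    if load_p_T > 0:
        nodes.append(
            NodeSpec(
                "C",
                1.0,
                BindingSpec("single", ("B",), (4,), (KB,), load_p_T, Production()),
            )
        )
    return ModuleSpec("clock", tuple(nodes))


def _toggle_module(cfg: CaseStudyConfig) -> ModuleSpec:
    K, p_T, a0, d = (cfg.value(k) for k in ("K", "p_T", "alpha0", "delta"))
    return ModuleSpec(
        "toggle",
        (
            NodeSpec(
                "x1", d, BindingSpec("single", ("x2",), (2,), (K,), p_T, Production(alpha0=a0)),
                perturbable=True,
            ),
            NodeSpec(
                "x2", d, BindingSpec("single", ("x1",), (2,), (K,), p_T, Production(alpha0=a0)),
                perturbable=True,
            ),
        ),
    )


def _toggle_context(cfg: CaseStudyConfig) -> ModuleSpec:
    pbar, K = cfg.value("context_p_T"), cfg.value("context_K")
    return ModuleSpec(
        "homeostasis",
        (
            NodeSpec("y1", 1.0, BindingSpec("single", ("u1",), (2,), (K,), pbar, Production(alpha1=5.0))),
            NodeSpec("y2", 1.0, BindingSpec("single", ("u2",), (2,), (K,), pbar, Production(alpha1=5.0))),
        ),
        inputs=("u1", "u2"),
    )


def _sim_module(cfg: CaseStudyConfig, p_T: float) -> ModuleSpec:
    alpha = cfg.value("alpha_pT") / p_T
    return ModuleSpec(
        "sim",
        (
            NodeSpec(
                "x",
                cfg.value("delta"),
                BindingSpec(
                    "single", ("x",), (1,), (cfg.value("K"),), p_T, Production(alpha0=alpha)
                ),
            ),
        ),
    )


def _sim_context(cfg: CaseStudyConfig, load: float) -> ModuleSpec:
    nodes = tuple(
        NodeSpec(
            f"y{i}",
            1.0,
            BindingSpec(
                "single", ("u",), (1,), (cfg.value("target_K"),), load, Production(alpha0=20.0)
            ),
        )
        for i in range(1, int(cfg.value("n_targets")) + 1)
    )
    return ModuleSpec("targets", nodes, inputs=("u",))


def _suppression_module(cfg: CaseStudyConfig) -> ModuleSpec:
    return ModuleSpec(
        "osc",
        (
            NodeSpec(
                "m1",
                1.0,
                BindingSpec(
                    "single",
                    ("u",),
                    (1,),
                    (cfg.value("K_u"),),
                    cfg.value("p_T_module"),
                    Production(alpha1=cfg.value("alpha_module")),
                ),
            ),
        ),
        inputs=("u",),
    )


def _suppression_context(cfg: CaseStudyConfig, pbar: float, rewired: bool) -> ModuleSpec:
    Ki = cfg.value("interface_K")
    driven = NodeSpec(
        "c2",
        1.0,
        BindingSpec(
            "single",
            ("u2",),
            (1,),
            (cfg.value("K_u"),),
            cfg.value("p_T_module"),
            Production(alpha1=cfg.value("alpha_module")),
        ),
    )
    if not rewired:
        mixed = NodeSpec(
            "c1",
            1.0,
            BindingSpec(
                "competitive", ("w", "c2"), (1, 1), (Ki, Ki), pbar, Production(alpha1=10.0)
            ),
        )
        return ModuleSpec("ctx", (mixed, driven), inputs=("w", "u2"))
    relay = NodeSpec(
        "w1",
        1.0,
        BindingSpec("single", ("w",), (1,), (Ki,), pbar, Production(alpha1=10.0)),
    )
    mixed = NodeSpec(
        "c1",
        1.0,
        BindingSpec(
            "competitive", ("w1", "c2"), (1, 1), (Ki, Ki), pbar, Production(alpha1=10.0)
        ),
    )
    return ModuleSpec("ctx", (relay, mixed, driven), inputs=("w", "u2"))


# --------------------------------------------------------------------------
# studies
# --------------------------------------------------------------------------


def run_negautoreg(cfg: CaseStudyConfig | None = None) -> dict:
    """Response-time comparison: unregulated vs autoregulated with/without R.

    The unregulated comparator's production rate is chosen per setting so
    that its steady state matches the regulated one.  Reports t_r for the
    three models at each copy-number setting.
    """
    cfg = cfg or DEFAULTS["negautoreg"]
    K, delta = cfg.value("K"), cfg.value("delta")
    phi, t_end = cfg.value("fraction"), cfg.value("t_end")
    settings = []
    for p_T in cfg.value("p_T_settings"):
        alpha = cfg.value("alpha_pT") / p_T
        reg = _negautoreg_module(alpha, p_T, K, delta)
        m_red = ReducedModel.from_spec(reg)
        m_hill = ReducedModel.from_spec(reg, mode="hill")
        x_ss = float(steady_state(m_red, guess=[cfg.value("alpha_pT") / delta / 10.0])[0])
        unreg = _constitutive_module(delta * x_ss / p_T, p_T, delta)
        m_un = ReducedModel.from_spec(unreg, mode="hill")
        t_r = {}
        for tag, m in (("unregulated", m_un), ("without_R", m_hill), ("with_R", m_red)):
            tr = simulate_reduced(m, [0.0], t_end=t_end, dt_out=0.002)
            t_r[tag] = response_time(tr, phi)
        settings.append({"alpha": alpha, "p_T": p_T, "x_ss": x_ss, **t_r})
    t_with = [s["with_R"] for s in settings]
    report = {
        "study": "negautoreg",
        "settings": settings,
        "checks": {
            "hill_speeds_up": all(s["without_R"] < s["unregulated"] for s in settings),
            "R_slows_down": all(s["with_R"] > s["without_R"] for s in settings),
            "t_with_R_increases_with_p_T": all(
                t_with[i] < t_with[i + 1] for i in range(len(t_with) - 1)
            ),
            "slower_than_unregulated_at_high_p_T": settings[-1]["with_R"]
            > settings[-1]["unregulated"],
        },
    }
    return report


def run_combinatorial(cfg: CaseStudyConfig | None = None) -> dict:
    """Pulse one parent, watch the other: coupling through the shared target."""
    cfg = cfg or DEFAULTS["combinatorial"]
    t_end = cfg.value("t_end")
    start, width = cfg.value("pulse_start"), cfg.value("pulse_width")
    per_type = {}
    for btype in ("independent", "competitive", "cooperative"):
        mod = _combinatorial_module(cfg, btype, cfg.value("p_T_target"))
        x0 = steady_state(
            ReducedModel.from_spec(mod), guess=[30.0, 30.0, 100.0]
        )
        pert = {"x1": pulse("d1", cfg.value("pulse_height"), start, width)}
        m = ReducedModel.from_spec(mod, perturbations=pert)
        tr = simulate_reduced(m, x0, t_end=t_end, dt_out=0.05)
        x2 = tr.column("x2")
        dev = x2 - x2[0]
        win = (tr.times >= start) & (tr.times <= start + width + 3.0)
        peak = float(dev[win][np.argmax(np.abs(dev[win]))])
        per_type[btype] = {
            "peak_deviation": peak,
            "recovery_rel": float(abs(x2[-1] - x2[0]) / x2[0]),
        }
    # load scaling: competitive transient grows at least linearly with p_T
    peaks = []
    for p_T3 in cfg.value("p_T_sweep"):
        mod = _combinatorial_module(cfg, "competitive", p_T3)
        x0 = steady_state(ReducedModel.from_spec(mod), guess=[30.0, 30.0, 100.0])
        m = ReducedModel.from_spec(
            mod,
            perturbations={"x1": pulse("d1", cfg.value("pulse_height"), start, width)},
        )
        tr = simulate_reduced(m, x0, t_end=start + width + 5.0, dt_out=0.05)
        peaks.append(float(np.max(tr.column("x2") - tr.column("x2")[0])))
    return {
        "study": "combinatorial",
        "per_type": per_type,
        "p_T_sweep": list(cfg.value("p_T_sweep")),
        "sweep_peaks": peaks,
        "checks": {
            "independent_flat": abs(per_type["independent"]["peak_deviation"]) < 1e-9,
            "competitive_same_sign": per_type["competitive"]["peak_deviation"] > 0,
            "cooperative_opposite_sign": per_type["cooperative"]["peak_deviation"] < 0,
            "adaptation": all(
                per_type[b]["recovery_rel"] < 1e-4
                for b in ("independent", "competitive", "cooperative")
            ),
            # more target DNA -> larger induced pulse (sublinear: the load also
            # damps the free excursion of the perturbed parent itself)
            "peak_grows_with_p_T": all(
                peaks[i + 1] > peaks[i] for i in range(len(peaks) - 1)
            ),
        },
    }


def run_clock(cfg: CaseStudyConfig | None = None) -> dict:
    """Oscillation verdicts for {no-R, with-R, with-load} clock variants."""
    cfg = cfg or DEFAULTS["clock"]
    t_end = cfg.value("t_end")
    verdicts, details = {}, {}
    for tag, mod, mode in (
        ("no-R", _clock_module(cfg), "hill"),
        ("with-R", _clock_module(cfg), "reduced"),
        ("with-load", _clock_module(cfg, cfg.value("load_p_T")), "reduced"),
    ):
        m = ReducedModel.from_spec(mod, mode=mode)
        tr = simulate_reduced(
            m, [1.0] * mod.n_nodes, t_end=t_end, dt_out=0.05, rtol=1e-9, atol=1e-11
        )
        v = detect_oscillation(tr, label="A")
        verdicts[tag] = v.verdict
        details[tag] = {"amplitude": v.amplitude, "period": v.period}
    return {
        "study": "clock",
        "verdicts": verdicts,
        "details": details,
        "checks": {
            "expected_verdicts": verdicts
            == {"no-R": "sustained", "with-R": "none", "with-load": "sustained"}
        },
    }


def run_toggle(cfg: CaseStudyConfig | None = None) -> dict:
    """Switching outcomes under narrow/wide pulses, isolated vs connected."""
    cfg = cfg or DEFAULTS["toggle"]
    mod = _toggle_module(cfg)
    ctx = _toggle_context(cfg)
    ic = InterconnectionSpec(mod, ctx, context_wiring={"u1": "x1", "u2": "x2"})
    iso = ReducedModel.from_spec(mod)
    conn = ReducedModel.from_spec(ic)
    stable_iso = [s for s in find_steady_states(iso) if is_stable(iso, s)]
    if len(stable_iso) != 2:
        raise ValidationError("toggle is not bistable with these parameters")
    hi = max(stable_iso, key=lambda s: s[0])  # x1-high state
    stable_conn = [s for s in find_steady_states(conn) if is_stable(conn, s)]
    z0 = min(stable_conn, key=lambda s: float(np.linalg.norm(s[:2] - hi)))
    t_end = cfg.value("t_end")
    height = cfg.value("pulse_height")

    def run(model, x0, width, pert_label):
        pert = {pert_label: pulse("d2", height, 2.0, width)}
        m = ReducedModel(model.network, "reduced", dict(model.signals), pert)
        tr = simulate_reduced(m, x0, t_end=t_end, dt_out=0.02)
        switched = bool(tr.states[-1, 1] > tr.states[-1, 0])
        return tr, switched

    narrow, wide = cfg.value("narrow_width"), cfg.value("wide_width")
    tr_iso_n, sw_iso_n = run(iso, hi, narrow, "x2")
    tr_conn_n, sw_conn_n = run(conn, z0, narrow, "toggle.x2")
    tr_conn_w, sw_conn_w = run(conn, z0, wide, "toggle.x2")
    tr_iso_w, sw_iso_w = run(iso, hi, wide, "x2")
    # switching speed: time for x2 to complete half its excursion (wide pulse)
    t_iso = response_time(tr_iso_w, 0.5, label="x2")
    t_conn = response_time(tr_conn_w, 0.5, label="toggle.x2")
    return {
        "study": "toggle",
        "outcomes": {
            "isolated-narrow": sw_iso_n,
            "connected-narrow": sw_conn_n,
            "connected-wide": sw_conn_w,
            "isolated-wide": sw_iso_w,
        },
        "switch_time_h": {"isolated-wide": t_iso, "connected-wide": t_conn},
        "checks": {
            "expected_outcomes": (sw_iso_n, sw_conn_n, sw_conn_w) == (True, False, True),
            "connected_switching_slower": t_conn > t_iso,
        },
    }


def run_sim_motif(cfg: CaseStudyConfig | None = None) -> dict:
    """Copy-number sweep at fixed steady state x three load levels."""
    cfg = cfg or DEFAULTS["sim"]
    phi, t_end = cfg.value("fraction"), cfg.value("t_end")
    p_Ts = cfg.value("p_T_sweep")
    loads = cfg.value("load_levels")
    iso_times = {}
    table = []
    for p_T in p_Ts:
        mod = _sim_module(cfg, p_T)
        red = ReducedModel.from_spec(mod)
        tr = simulate_reduced(red, [0.0], t_end=t_end, dt_out=0.005)
        iso_times[p_T] = response_time(tr, phi)
        x_ss = float(tr.states[-1, 0])
        for load in loads:
            ic = InterconnectionSpec(
                mod, _sim_context(cfg, load), context_wiring={"u": "x"}
            )
            conn = ReducedModel.from_spec(ic)
            v0 = [20.0] * int(cfg.value("n_targets"))
            trc = simulate_reduced(conn, [0.0] + v0, t_end=t_end, dt_out=0.005)
            t_conn = response_time(trc, phi, label=f"{mod.name}.x")
            box = {f"{mod.name}.x": (0.05 * x_ss, 1.5 * x_ss)}
            box.update(
                {
                    f"targets.y{i}": (1.0, 40.0)
                    for i in range(1, int(cfg.value("n_targets")) + 1)
                }
            )
            met = robustness_metric(ic, box, n_samples=64, seed=11)
            table.append(
                {
                    "p_T": p_T,
                    "load": load,
                    "t_isolated": iso_times[p_T],
                    "t_connected": t_conn,
                    "pct_increase": 100.0 * (t_conn - iso_times[p_T]) / iso_times[p_T],
                    "d": met.d,
                }
            )
    iso_seq = [iso_times[p] for p in p_Ts]

    def per_load(key):
        return {ld: [r[key] for r in table if r["load"] == ld] for ld in loads}

    pct, ds = per_load("pct_increase"), per_load("d")
    mono_dec = lambda seq: all(seq[i] > seq[i + 1] for i in range(len(seq) - 1))
    ordered_loads = all(
        pct[loads[i]][k] < pct[loads[i + 1]][k]
        for i in range(len(loads) - 1)
        for k in range(len(p_Ts))
    )
    return {
        "study": "sim",
        "isolated_t_r": {str(p): iso_times[p] for p in p_Ts},
        "table": table,
        "checks": {
            "isolated_slows_with_p_T": all(
                iso_seq[i] < iso_seq[i + 1] for i in range(len(iso_seq) - 1)
            ),
            "pct_decreases_with_p_T": all(mono_dec(pct[ld]) for ld in loads),
            "pct_ordered_across_loads": ordered_loads,
            "d_co_monotone": all(mono_dec(ds[ld]) for ld in loads),
        },
    }


def run_suppression(cfg: CaseStudyConfig | None = None) -> dict:
    """Severe distortion of a driven module by a mixed-promoter context."""
    cfg = cfg or DEFAULTS["suppression"]
    mean, amp, period = (cfg.value(k) for k in ("u_mean", "u_amplitude", "u_period"))
    sigs = {
        "u": sinusoid("u", mean, amp, period),
        "u2": sinusoid("u2", mean, amp, period, phase=cfg.value("u2_phase")),
    }
    t_end = cfg.value("t_end")
    sweep = []
    for pbar in cfg.value("p_T_sweep"):
        ic = InterconnectionSpec(
            _suppression_module(cfg), _suppression_context(cfg, pbar, rewired=False), context_wiring={"w": "m1"}
        )
        rep = validate_interconnection(ic)
        cr = compare_connection(
            ic,
            [0.0],
            [0.0] * ic.context.n_nodes,
            t_end=t_end,
            dt_out=0.02,
            signals=sigs,
            with_metric=False,
        )
        sweep.append({"interface_p_T": pbar, "sup_rel": cr.sup_rel, "mixing_zero": rep.mixing_zero})
    ic_rw = InterconnectionSpec(
        _suppression_module(cfg),
        _suppression_context(cfg, cfg.value("interface_p_T"), rewired=True),
        context_wiring={"w": "m1"},
    )
    rep_rw = validate_interconnection(ic_rw)
    cr_rw = compare_connection(
        ic_rw,
        [0.0],
        [0.0] * ic_rw.context.n_nodes,
        t_end=t_end,
        dt_out=0.02,
        signals=sigs,
        with_metric=False,
    )
    sups = [s["sup_rel"] for s in sweep]
    return {
        "study": "suppression",
        "sweep": sweep,
        "rewired": {"sup_rel": cr_rw.sup_rel, "mixing_zero": rep_rw.mixing_zero},
        "checks": {
            "zero_interface_coincides": sups[0] < 1e-6,
            "severe_distortion": sups[-1] > 0.10,
            "grows_with_interface_p_T": all(
                sups[i] < sups[i + 1] for i in range(len(sups) - 1)
            ),
            "mixed_has_mixing": not sweep[-1]["mixing_zero"],
            "rewired_mixing_zero": rep_rw.mixing_zero,
        },
    }


# --------------------------------------------------------------------------
# reduced-vs-full validation scenarios
# --------------------------------------------------------------------------


def master_scenario(study: str) -> dict:
    """Representative simulation setup per case study, used to validate the
    reduced model against the mass-action model.

    Returns a dict with ``spec`` (module or interconnection), ``x0`` (free
    TF initial condition), ``signals``, ``perturbations``, ``t_end``,
    ``dt_out``.  Horizons are moderate (one to a few characteristic times /
    periods) so that the comparison probes dynamics, not accumulated phase
    drift.
    """
    if study == "negautoreg":
        cfg = DEFAULTS["negautoreg"]
        p_T = cfg.value("p_T_settings")[-1]
        spec = _negautoreg_module(
            cfg.value("alpha_pT") / p_T, p_T, cfg.value("K"), cfg.value("delta")
        )
        return dict(spec=spec, x0=[0.0], signals={}, perturbations={}, t_end=15.0, dt_out=0.01)
    if study == "combinatorial":
        cfg = DEFAULTS["combinatorial"]
        spec = _combinatorial_module(cfg, "competitive", cfg.value("p_T_target"))
        x0 = steady_state(ReducedModel.from_spec(spec), guess=[30.0, 30.0, 100.0])
        pert = {"x1": pulse("d1", cfg.value("pulse_height"), 2.0, cfg.value("pulse_width"))}
        return dict(spec=spec, x0=list(x0), signals={}, perturbations=pert, t_end=20.0, dt_out=0.01)
    if study == "clock":
        cfg = DEFAULTS["clock"]
        spec = _clock_module(cfg, cfg.value("load_p_T"))
        return dict(
            spec=spec, x0=[1.0, 1.0, 1.0], signals={}, perturbations={}, t_end=60.0, dt_out=0.02
        )
    if study == "toggle":
        cfg = DEFAULTS["toggle"]
        mod = _toggle_module(cfg)
        ic = InterconnectionSpec(
            mod, _toggle_context(cfg), context_wiring={"u1": "x1", "u2": "x2"}
        )
        conn = ReducedModel.from_spec(ic)
        stable = [s for s in find_steady_states(conn) if is_stable(conn, s)]
        z0 = max(stable, key=lambda s: s[0])
        pert = {"toggle.x2": pulse("d2", cfg.value("pulse_height"), 2.0, cfg.value("wide_width"))}
        return dict(
            spec=ic, x0=list(z0), signals={}, perturbations=pert, t_end=40.0, dt_out=0.02
        )
    if study == "sim":
        cfg = DEFAULTS["sim"]
        mod = _sim_module(cfg, cfg.value("p_T_sweep")[1])
        ic = InterconnectionSpec(
            mod, _sim_context(cfg, cfg.value("load_levels")[1]), context_wiring={"u": "x"}
        )
        v0 = [20.0] * int(cfg.value("n_targets"))
        return dict(spec=ic, x0=[0.0] + v0, signals={}, perturbations={}, t_end=15.0, dt_out=0.01)
    if study == "suppression":
        cfg = DEFAULTS["suppression"]
        ic = InterconnectionSpec(
            _suppression_module(cfg),
            _suppression_context(cfg, cfg.value("interface_p_T"), rewired=False),
            context_wiring={"w": "m1"},
        )
        sigs = {
            "u": sinusoid("u", cfg.value("u_mean"), cfg.value("u_amplitude"), cfg.value("u_period")),
            "u2": sinusoid(
                "u2",
                cfg.value("u_mean"),
                cfg.value("u_amplitude"),
                cfg.value("u_period"),
                phase=cfg.value("u2_phase"),
            ),
        }
        return dict(
            spec=ic,
            x0=[0.0] * (1 + ic.context.n_nodes),
            signals=sigs,
            perturbations={},
            t_end=24.0,
            dt_out=0.01,
        )
    raise ValidationError(f"unknown case study {study!r}")


def reduced_full_discrepancy(study: str, epsilon: float = 1.0) -> float:
    """Sup-norm free-TF discrepancy between reduced and mass-action models,
    relative to each species' signal range (worst species reported).

    The mass-action model starts with complexes equilibrated at the reduced
    model's initial free-TF levels; ``epsilon`` widens the binding
    time-scale separation (the reduced model is its epsilon -> 0 limit).
    """
    from .mechanistic import build_full_model, simulate_full

    sc = master_scenario(study)
    spec, x0 = sc["spec"], sc["x0"]
    red_model = ReducedModel.from_spec(
        spec, signals=sc["signals"], perturbations=sc["perturbations"]
    )
    tr_red = simulate_reduced(
        red_model, x0, t_end=sc["t_end"], dt_out=sc["dt_out"], rtol=1e-9, atol=1e-11
    )
    full = build_full_model(spec, epsilon=epsilon)
    tr_full = simulate_full(
        full,
        x0,
        sc["signals"],
        t_end=sc["t_end"],
        dt_out=sc["dt_out"],
        perturbations=sc["perturbations"],
        rtol=1e-9,
        atol=1e-11,
    )
    n_free = red_model.network.n_species
    worst = 0.0
    for j in range(n_free):
        a = tr_red.states[:, j]
        b = tr_full.states[:, j]
        rng = max(float(a.max() - a.min()), 1e-3)
        worst = max(worst, float(np.abs(a - b).max()) / rng)
    return worst


STUDIES: dict[str, Callable[[CaseStudyConfig | None], dict]] = {
    "negautoreg": run_negautoreg,
    "combinatorial": run_combinatorial,
    "clock": run_clock,
    "toggle": run_toggle,
    "sim": run_sim_motif,
    "suppression": run_suppression,
}


def run_study(study: str, cfg: CaseStudyConfig | None = None) -> dict:
    if study not in STUDIES:
        raise ValidationError(f"unknown case study {study!r}; choose from {sorted(STUDIES)}")
    return STUDIES[study](cfg)
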