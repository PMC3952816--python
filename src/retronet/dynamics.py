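"""Reduced (quasi-steady-state) models: right-hand sides, simulation, analysis.

The reduced state is the vector of free TF concentrations.  Writing f for
the slow field H(x, u) - diag(delta) x + d(t), the reduced dynamics solve

    (I + J(x, u)) dx/dt = f(x, u, t) - Ju(x, u) du/dt

where J is the total-bound Jacobian assembled from the node retroactivities
of every promoter in the network and Ju its cross-Jacobian with respect to
exogenous inputs.  For an isolated module J is the internal retroactivity R;
for a module with inputs the forcing term carries the external retroactivity
S; for a wired module/context pair J additionally contains the scaling and
mixing blocks.  One engine covers all three tiers because they share the
same total-TF conservation identity: (I + J) dx/dt is the rate of change of
total (free plus bound) TF.

In ``hill`` mode the premultiplier and forcing are dropped, giving the
classical Hill-function model dx/dt = f.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

from . import _network as netw
from .errors import (
    AnalysisError,
    ConditioningError,
    ConfigurationError,
    ContractError,
    SolverError,
)
from .mechanistic import ATOL_DEFAULT, RTOL_DEFAULT, Trajectory
from .netspec import InterconnectionSpec, ModuleSpec
from .retroactivity import CONDITIONING_FLOOR
from .signals import InputSignal

__all__ = [
    "ReducedModel",
    "reduced_rhs_isolated",
    "reduced_rhs_with_input",
    "reduced_rhs_connected",
    "simulate_reduced",
    "steady_state",
    "find_steady_states",
    "response_time",
    "OscillationVerdict",
    "detect_oscillation",
]


@dataclass
class ReducedModel:
    """Reduced model of a module or a wired module/context pair.

    ``mode``: ``"reduced"`` (retroactivity premultiplier active) or
    ``"hill"`` (premultiplier forced to identity; the textbook model).
    """

    network: netw.Network
    mode: str = "reduced"
    signals: Mapping[str, InputSignal] = field(default_factory=dict)
    perturbations: Mapping[str, InputSignal] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("reduced", "hill"):
            raise ContractError(f"mode must be 'reduced' or 'hill', got {self.mode!r}")

    @classmethod
    def from_spec(
        cls,
        spec: ModuleSpec | InterconnectionSpec,
        mode: str = "reduced",
        signals: Mapping[str, InputSignal] | None = None,
        perturbations: Mapping[str, InputSignal] | None = None,
    ) -> "ReducedModel":
        net = (
            netw.from_interconnection(spec)
            if isinstance(spec, InterconnectionSpec)
            else netw.from_module(spec)
        )
        return cls(
            network=net,
            mode=mode,
            signals=dict(signals or {}),
            perturbations=dict(perturbations or {}),
        )

    @property
    def labels(self) -> tuple[str, ...]:
        return self.network.species

    def slow_field(self, t: float, z: np.ndarray) -> np.ndarray:
        uvals = netw.signal_values(self.network, self.signals, t)
        return netw.slow_field(self.network, t, z, uvals, self.perturbations)

    def rhs(self, t: float, z: np.ndarray) -> np.ndarray:
        net = self.network
        uvals = netw.signal_values(net, self.signals, t)
        f = netw.slow_field(net, t, z, uvals, self.perturbations)
        if self.mode == "hill":
            return f
        J, Ju = netw.reduced_matrices(net, np.maximum(z, 0.0), uvals)
        b = f
        if Ju.size:
            udot = np.array([self.signals[s].derivative(t) for s in net.signal_ids])
            b = f - Ju @ udot
        A = np.eye(net.n_species) + J
        try:
            out = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise ConditioningError(f"I + R singular at state {z}") from exc
        if not np.all(np.isfinite(out)):
            smin = np.linalg.svd(A, compute_uv=False)[-1]
            raise ConditioningError(f"premultiplier ill-conditioned (sigma_min={smin:.2e})")
        return out

    def premultiplier(self, t: float, z: np.ndarray) -> np.ndarray:
        uvals = netw.signal_values(self.network, self.signals, t)
        J, _ = netw.reduced_matrices(self.network, z, uvals)
        A = np.eye(self.network.n_species) + J
        smin = np.linalg.svd(A, compute_uv=False)[-1]
        if smin < CONDITIONING_FLOOR:
            raise ConditioningError(f"sigma_min(I + J) = {smin:.3e} below floor")
        return A


# -- functional surfaces ----------------------------------------------------


def reduced_rhs_isolated(
    spec: ModuleSpec,
    x: Sequence[float],
    t: float = 0.0,
    perturbations: Mapping[str, InputSignal] | None = None,
) -> np.ndarray:
    """dx/dt = (I + R(x))^{-1} (H(x) - diag(delta) x + d(t)) for a module
    without inputs (inputs, if declared, are held at zero)."""
    model = ReducedModel.from_spec(
        spec,
        signals={i: _zero_signal(i) for i in spec.inputs},
        perturbations=perturbations,
    )
    return model.rhs(t, np.asarray(x, dtype=float))


def reduced_rhs_with_input(
    spec: ModuleSpec,
    x: Sequence[float],
    u: Sequence[float],
    udot: Sequence[float],
    t: float = 0.0,
) -> np.ndarray:
    """dx/dt = (I + R)^{-1} (f - S(x, u) udot) at frozen input values."""
    u = np.asarray(u, dtype=float).reshape(-1)
    udot = np.asarray(udot, dtype=float).reshape(-1)
    if u.size != len(spec.inputs) or udot.size != len(spec.inputs):
        raise ConfigurationError(
            f"module has {len(spec.inputs)} inputs; got u size {u.size}, udot size {udot.size}"
        )
    signals = {
        sid: InputSignal(
            id=sid,
            value=(lambda tt, val=val: val),
            derivative=(lambda tt, d=d: d),
            shape="frozen",
            params={"value": float(val), "derivative": float(d)},
        )
        for sid, val, d in zip(spec.inputs, u, udot)
    }
    model = ReducedModel.from_spec(spec, signals=signals)
    return model.rhs(t, np.asarray(x, dtype=float))


def reduced_rhs_connected(
    ic: InterconnectionSpec,
    x: Sequence[float],
    v: Sequence[float],
    t: float = 0.0,
    signals: Mapping[str, InputSignal] | None = None,
    perturbations: Mapping[str, InputSignal] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint reduced dynamics (dx/dt, dv/dt) of a wired module/context pair."""
    model = ReducedModel.from_spec(ic, signals=signals or {}, perturbations=perturbations)
    z = np.concatenate(
        [np.asarray(x, float).reshape(-1), np.asarray(v, float).reshape(-1)]
    )
    dz = model.rhs(t, z)
    n = ic.module.n_nodes
    return dz[:n], dz[n:]


def _zero_signal(sid: str) -> InputSignal:
    return InputSignal(
        id=sid, value=lambda t: 0.0, derivative=lambda t: 0.0, shape="constant",
        params={"level": 0.0},
    )


# -- simulation -------------------------------------------------------------


def simulate_reduced(
    model: ReducedModel,
    x0: Sequence[float],
    t_end: float,
    dt_out: float = 0.05,
    t_start: float = 0.0,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
    method: str = "LSODA",
    max_step: float | None = None,
) -> Trajectory:
    """Integrate a reduced model; output on a uniform grid (same trajectory
    format as the mechanistic simulator).

    ``max_step`` defaults to 10 * dt_out so that short input features such
    as pulses cannot be stepped over when the system sits at an equilibrium.
    """
    x0 = np.asarray(x0, dtype=float).reshape(-1)
    if x0.size != model.network.n_species:
        raise ContractError(
            f"x0 size {x0.size} does not match state dimension {model.network.n_species}"
        )
    times = np.arange(t_start, t_end + 0.5 * dt_out, dt_out)
    sol = solve_ivp(
        model.rhs, (t_start, times[-1]), x0, method=method, t_eval=times,
        rtol=rtol, atol=atol, max_step=max_step if max_step else 10 * dt_out,
    )
    if not sol.success:
        raise SolverError(f"integration failed: {sol.message}")
    states = np.clip(sol.y.T, 0.0, None)
    return Trajectory(
        times=times,
        states=states,
        labels=model.labels,
        meta={
            "model": model.mode,
            "solver": method,
            "rtol": rtol,
            "atol": atol,
            "signals": {
                k: (v.to_dict() if v.shape not in ("custom", "frozen") else v.shape)
                for k, v in model.signals.items()
            },
        },
    )


# -- steady states ----------------------------------------------------------


def _state_scales(model: ReducedModel, t: float) -> np.ndarray:
    """Per-species production/decay scale alpha p_T / delta used to seed
    multistart grids."""
    net = model.network
    scales = np.full(net.n_species, 1.0)
    for prom in net.promoters:
        alpha_max = max(prom.binding.production.as_dict().values())
        scales[prom.owner] += alpha_max * prom.binding.promoter_total
    return scales / net.deltas


def steady_state(
    model: ReducedModel,
    guess: Sequence[float] | None = None,
    t: float = 0.0,
    tol: float = 1e-10,
) -> np.ndarray:
    """Solve f(x) = 0 (signals frozen at time ``t``).

    The retroactivity premultiplier does not move equilibria: with the
    conditioning guard in force, (I + J)^{-1} f = 0 iff f = 0, so the root
    is searched on the slow field directly.  With no ``guess``, multistart
    from a log-spaced grid returns the root nearest the origin.
    """
    roots = (
        [_solve_root(model, np.asarray(guess, float), t, tol)]
        if guess is not None
        else find_steady_states(model, t=t, tol=tol)
    )
    roots = [r for r in roots if r is not None]
    if not roots:
        raise SolverError("steady-state search did not converge")
    return roots[0]


def _solve_root(model, x0, t, tol):
    sol = root(lambda x: model.slow_field(t, np.maximum(x, 0.0)), x0, method="hybr", tol=tol)
    if not sol.success:
        return None
    x = np.maximum(sol.x, 0.0)
    if np.linalg.norm(model.slow_field(t, x)) > 1e-6 * max(1.0, np.linalg.norm(x)):
        return None
    return x


def find_steady_states(
    model: ReducedModel,
    t: float = 0.0,
    tol: float = 1e-10,
    n_grid: int = 5,
    max_starts: int = 200,
    seed: int = 0,
) -> list[np.ndarray]:
    """Multistart root search for all steady states (bistable systems).

    Starts on a log-spaced grid of ``n_grid`` points per dimension spanning
    [0.01, 10] times each species' production/decay scale; duplicate roots
    are merged at 1e-6 relative distance.  Roots are sorted by norm.
    """
    net = model.network
    scales = _state_scales(model, t)
    axes = [np.geomspace(0.01 * s, 10.0 * s, n_grid) for s in scales]
    n = net.n_species
    if n_grid**n <= max_starts:
        mesh = np.meshgrid(*axes, indexing="ij")
        starts = np.stack([m.ravel() for m in mesh], axis=1)
    else:
        rng = np.random.default_rng(seed)
        los = np.log([0.01 * s for s in scales])
        his = np.log([10.0 * s for s in scales])
        starts = np.exp(rng.uniform(los, his, size=(max_starts, n)))
    roots: list[np.ndarray] = []
    for x0 in starts:
        x = _solve_root(model, x0, t, tol)
        if x is None:
            continue
        for r in roots:
            if np.linalg.norm(x - r) <= 1e-4 * max(np.linalg.norm(r), 1e-6):
                break
        else:
            roots.append(x)
    roots.sort(key=lambda r: float(np.linalg.norm(r)))
    return roots


def is_stable(model: ReducedModel, x_star: np.ndarray, t: float = 0.0) -> bool:
    """Linear stability of an equilibrium of the reduced dynamics."""
    n = model.network.n_species
    J = np.empty((n, n))
    h = 1e-6 * np.maximum(np.abs(x_star), 1.0)
    for k in range(n):
        xp, xm = x_star.copy(), x_star.copy()
        xp[k] += h[k]
        xm[k] = max(xm[k] - h[k], 0.0)
        J[:, k] = (model.rhs(t, xp) - model.rhs(t, xm)) / (xp[k] - xm[k])
    return bool(np.all(np.linalg.eigvals(J).real < 0))


# -- trajectory analysis ----------------------------------------------------


def response_time(
    traj: Trajectory,
    fraction: float = 0.5,
    label: str | None = None,
    tail_fraction: float = 0.05,
    flatness_rtol: float = 0.02,
) -> float:
    """First time the species crosses ``x0 + fraction*(x_ss - x0)`` [h].

    ``x_ss`` is the mean over the trailing ``tail_fraction`` of the horizon,
    which must be flat to within ``flatness_rtol`` of the total displacement
    (otherwise the trajectory has not converged and AnalysisError is raised).
    Crossing location is linearly interpolated between samples.
    """
    if not 0 < fraction < 1:
        raise ContractError("fraction must be in (0, 1)")
    x = traj.column(label) if label else traj.states[:, 0]
    n_tail = max(int(len(x) * tail_fraction), 2)
    tail = x[-n_tail:]
    x0, x_ss = x[0], float(tail.mean())
    displacement = abs(x_ss - x0)
    if displacement < 1e-12:
        raise AnalysisError("no displacement; response time undefined")
    if tail.max() - tail.min() > flatness_rtol * displacement:
        raise AnalysisError("trajectory has not converged to a steady state")
    target = x0 + fraction * (x_ss - x0)
    sign = np.sign(x_ss - x0)
    crossed = sign * (x - target) >= 0
    idx = np.argmax(crossed)
    if not crossed[idx]:
        raise AnalysisError("trajectory never crosses the target fraction")
    if idx == 0:
        return float(traj.times[0])
    t0, t1 = traj.times[idx - 1], traj.times[idx]
    y0, y1 = x[idx - 1], x[idx]
    return float(t0 + (target - y0) / (y1 - y0) * (t1 - t0))


@dataclass(frozen=True)
class OscillationVerdict:
    verdict: str  # "sustained" | "damped" | "none"
    amplitude: float  # post-transient peak-to-peak [nM]
    period: float | None  # [h], from mean peak spacing

    def __bool__(self) -> bool:
        return self.verdict == "sustained"


def detect_oscillation(
    traj: Trajectory,
    transient_fraction: float = 0.5,
    amplitude_threshold: float = 0.05,
    label: str | None = None,
    n_windows: int = 3,
    decay_slack: float = 0.05,
) -> OscillationVerdict:
    """Classify a trajectory as sustained / damped / none.

    The first ``transient_fraction`` of the horizon is discarded.  The
    remainder is split into ``n_windows`` windows; the verdict is
    *sustained* iff every window's peak-to-peak amplitude exceeds
    ``amplitude_threshold`` times the whole-trajectory range and the window
    amplitudes do not decay by more than ``decay_slack`` relative per
    window; *damped* if oscillation peaks exist but amplitudes shrink;
    *none* otherwise.  The period estimate is the mean spacing of maxima.
    """
    x = traj.column(label) if label else traj.states[:, 0]
    n0 = int(len(x) * transient_fraction)
    if len(x) - n0 < 10:
        raise AnalysisError("trajectory too short after discarding the transient")
    seg = x[n0:]
    tseg = traj.times[n0:]
    full_range = float(x.max() - x.min())
    thresh = amplitude_threshold * full_range if full_range > 0 else 0.0
    amps = []
    for w in np.array_split(seg, n_windows):
        amps.append(float(w.max() - w.min()))
    peaks, _ = find_peaks(seg)
    period = None
    if len(peaks) >= 2:
        period = float(np.mean(np.diff(tseg[peaks])))
    amplitude = float(seg.max() - seg.min())
    oscillatory = len(peaks) >= 2 and amplitude > 0
    sustained = (
        oscillatory
        and all(a >= thresh for a in amps)
        and all(
            amps[i + 1] >= (1.0 - decay_slack) * amps[i] for i in range(len(amps) - 1)
        )
    )
    if sustained:
        return OscillationVerdict("sustained", amplitude, period)
    if oscillatory and amplitude >= thresh:
        return OscillationVerdict("damped", amplitude, period)
    return OscillationVerdict("none", amplitude, period)
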