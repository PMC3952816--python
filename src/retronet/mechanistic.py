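"""Full mass-action ODE model of a transcription network.

Species are the free TFs followed by every promoter occupancy state of every
node (empty promoter included).  Production and decay are the slow
reactions; reversible TF-promoter binding is fast, with off-rate
``k_off = K_OFF_DEFAULT / epsilon`` and on-rate ``k_on = k_off / K`` per
binding step so that the equilibrium constants are exactly the declared
dissociation constants.  Multimerization is lumped into one step
(n X + P <-> C), matching the occupancy algebra of the reduced model.

This model is the ground-truth oracle for every reduced-model claim: the
reduced model must converge to it as the binding time scale separates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _network as netw
from .errors import ContractError, SolverError
from .netspec import InterconnectionSpec, ModuleSpec
from .retroactivity import REACTION_CATALOG, STATE_CATALOG, qss_complexes, state_alphas, state_labels
from .signals import InputSignal

__all__ = [
    "K_OFF_DEFAULT",
    "Trajectory",
    "FullModel",
    "build_full_model",
    "equilibrated_state",
    "simulate_full",
    "total_tf_timeseries",
]

log = logging.getLogger(__name__)

#: Default unbinding rate [1/h] at epsilon = 1 (~1/s, the second-to-subsecond
#: time scale of TF-DNA binding).
K_OFF_DEFAULT = 3600.0

#: Default integrator tolerances [nM].
ATOL_DEFAULT = 1e-9
RTOL_DEFAULT = 1e-8


@dataclass(frozen=True)
class Trajectory:
    """Simulation output on a uniform grid: times [h] x species [nM]."""

    times: np.ndarray
    states: np.ndarray  # (n_times x n_species)
    labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.states.shape != (self.times.size, len(self.labels)):
            raise ContractError("trajectory shape does not match labels")
        if np.any(np.diff(self.times) <= 0):
            raise ContractError("trajectory times must be strictly increasing")

    def column(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]

    def to_csv(self, path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.states, columns=list(self.labels))
        df.insert(0, "time_h", self.times)
        df.to_csv(path, index=False)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(self.meta, indent=2, default=str)
        )

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            times=df["time_h"].to_numpy(),
            states=df.drop(columns="time_h").to_numpy(),
            labels=tuple(df.columns[1:]),
            meta=meta,
        )


@dataclass(frozen=True)
class _Reaction:
    reactant: int  # complex species index
    product: int
    parent_ref: tuple  # ("x", idx) or ("u", id)
    n: float  # multimer copies consumed
    k_on: float
    k_off: float


@dataclass(frozen=True)
class FullModel:
    """Mass-action model: species list, reactions, conservation structure."""

    network: netw.Network
    labels: tuple[str, ...]  # free TFs first, then complexes node by node
    complex_slices: tuple[slice, ...]  # one per promoter, into the full state
    reactions: tuple[_Reaction, ...]
    epsilon: float
    k_off_base: float

    @property
    def n_free(self) -> int:
        return self.network.n_species

    @property
    def n_species(self) -> int:
        return len(self.labels)

    def hash_key(self) -> str:
        import hashlib

        h = hashlib.sha256(repr((self.labels, self.epsilon, self.k_off_base)).encode())
        return h.hexdigest()[:12]


def build_full_model(
    spec: ModuleSpec | InterconnectionSpec, epsilon: float = 1.0, k_off: float = K_OFF_DEFAULT
) -> FullModel:
    """Instantiate the mass-action model of a module or wired pair.

    ``epsilon`` scales all binding rates by 1/epsilon: decreasing it widens
    the time-scale separation without moving any equilibrium.
    """
    if epsilon <= 0:
        raise ContractError("epsilon must be > 0")
    if isinstance(spec, InterconnectionSpec):
        net = netw.from_interconnection(spec)
    else:
        net = netw.from_module(spec)
    labels = list(net.species)
    slices: list[slice] = []
    reactions: list[_Reaction] = []
    koff = k_off / epsilon
    for prom in net.promoters:
        b = prom.binding
        start = len(labels)
        st_labels = state_labels(b)
        owner = net.species[prom.owner]
        labels.extend(f"{owner}:{sl}" for sl in st_labels)
        slices.append(slice(start, len(labels)))
        for s_r, s_p, j in REACTION_CATALOG[b.binding_type]:
            reactions.append(
                _Reaction(
                    reactant=start + s_r,
                    product=start + s_p,
                    parent_ref=prom.parent_refs[j],
                    n=float(b.multimerization[j]),
                    k_on=koff / b.dissociation[j],
                    k_off=koff,
                )
            )
    return FullModel(
        network=net,
        labels=tuple(labels),
        complex_slices=tuple(slices),
        reactions=tuple(reactions),
        epsilon=epsilon,
        k_off_base=k_off,
    )


def equilibrated_state(
    model: FullModel,
    x_free: Sequence[float],
    signals: Mapping[str, InputSignal] | None = None,
    t0: float = 0.0,
) -> np.ndarray:
    """Full state with complexes at binding equilibrium given free TF levels."""
    net = model.network
    x = np.asarray(x_free, dtype=float).reshape(-1)
    if x.size != net.n_species:
        raise ContractError(f"expected {net.n_species} free concentrations")
    uvals = netw.signal_values(net, signals or {}, t0)
    y = np.zeros(model.n_species)
    y[: net.n_species] = x
    for prom, sl in zip(net.promoters, model.complex_slices):
        res = qss_complexes(prom.binding, netw.parent_concentrations(prom, x, uvals))
        y[sl] = res.gamma
    return y


def _rhs(model: FullModel, signals, perturbations):
    net = model.network
    nf = net.n_species
    prom_alphas = [state_alphas(p.binding) for p in net.promoters]
    pert_idx = []
    if perturbations:
        for label, sig in perturbations.items():
            idx = net.species_index(label)
            if not net.perturbable[idx]:
                raise ContractError(f"species {label!r} is not flagged perturbable")
            pert_idx.append((idx, sig))

    def rhs(t, y):
        dy = np.zeros_like(y)
        uvals = netw.signal_values(net, signals, t)
        x = y[:nf]
        # slow: production from each occupancy state, decay of free TF
        dy[:nf] -= net.deltas * x
        for prom, sl, alphas in zip(net.promoters, model.complex_slices, prom_alphas):
            dy[prom.owner] += float(alphas @ y[sl])
        for idx, sig in pert_idx:
            dy[idx] += sig.value(t)
        # fast: reversible binding
        for r in model.reactions:
            kind, ref = r.parent_ref
            conc = x[ref] if kind == "x" else uvals[ref]
            flux = r.k_on * max(conc, 0.0) ** r.n * y[r.reactant] - r.k_off * y[r.product]
            dy[r.reactant] -= flux
            dy[r.product] += flux
            if kind == "x":
                dy[ref] -= r.n * flux
        return dy

    return rhs


def simulate_full(
    model: FullModel,
    x0: Sequence[float],
    signals: Mapping[str, InputSignal] | None = None,
    t_end: float = 10.0,
    dt_out: float = 0.05,
    perturbations: Mapping[str, InputSignal] | None = None,
    t_start: float = 0.0,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
    method: str = "LSODA",
    max_step: float | None = None,
) -> Trajectory:
    """Stiff integration of the mass-action model on a uniform output grid.

    ``x0`` is either the full state (free TFs + complexes) or just the free
    TF vector, in which case complexes start at their binding equilibrium.
    Promoter conservation is checked on every output sample.
    """
    signals = signals or {}
    y0 = np.asarray(x0, dtype=float).reshape(-1)
    if y0.size == model.n_free:
        y0 = equilibrated_state(model, y0, signals, t_start)
    if y0.size != model.n_species:
        raise ContractError(
            f"x0 must have {model.n_free} or {model.n_species} entries, got {y0.size}"
        )
    if np.any(y0 < 0):
        raise ContractError("initial state must be nonnegative")
    times = np.arange(t_start, t_end + 0.5 * dt_out, dt_out)
    rhs = _rhs(model, signals, perturbations)
    kwargs = dict(
        t_eval=times, rtol=rtol, atol=atol, max_step=max_step if max_step else 10 * dt_out
    )
    sol = solve_ivp(rhs, (t_start, times[-1]), y0, method=method, **kwargs)
    if not sol.success and method == "LSODA":
        # extreme binding stiffness (large multimer activities) can defeat
        # LSODA's step-size control; BDF is slower but more robust
        log.warning("LSODA failed (%s); retrying with BDF", sol.message)
        sol = solve_ivp(rhs, (t_start, times[-1]), y0, method="BDF", **kwargs)
    if not sol.success:
        raise SolverError(f"integration failed: {sol.message}")
    states = sol.y.T
    neg = states.min()
    clip_floor = -100 * atol
    if neg < clip_floor:
        raise SolverError(
            f"state went negative ({neg:.3e} nM) beyond tolerance; "
            "tighten rtol/atol"
        )
    if neg < 0:
        log.warning("clipping small negative concentrations (min %.3e nM)", neg)
        states = np.clip(states, 0.0, None)
    # conservation: complexes of each promoter must sum to p_T throughout
    for prom, sl in zip(model.network.promoters, model.complex_slices):
        p_T = prom.binding.promoter_total
        drift = np.abs(states[:, sl].sum(axis=1) - p_T).max()
        if drift > max(10 * atol, 10 * rtol * p_T):
            raise SolverError(
                f"promoter conservation drift {drift:.3e} nM at "
                f"{model.network.species[prom.owner]}"
            )
    return Trajectory(
        times=times,
        states=states,
        labels=model.labels,
        meta={
            "model": "full",
            "model_hash": model.hash_key(),
            "solver": method,
            "rtol": rtol,
            "atol": atol,
            "epsilon": model.epsilon,
            "k_off_base": model.k_off_base,
            "signals": {
                k: (v.to_dict() if v.shape != "custom" else "custom")
                for k, v in signals.items()
            },
        },
    )


def total_tf_timeseries(traj: Trajectory, model: FullModel) -> pd.DataFrame:
    """Total (free + promoter-bound) concentration of every dynamic TF.

    Bound amounts count multimerization: an n-multimer complex holds n
    copies of its TF.
    """
    net = model.network
    if traj.labels != model.labels:
        raise ContractError("trajectory does not match this model's species list")
    totals = traj.states[:, : net.n_species].copy()
    for prom, sl in zip(net.promoters, model.complex_slices):
        E = np.array(STATE_CATALOG[prom.binding.binding_type], dtype=float)
        for j, (kind, ref) in enumerate(prom.parent_refs):
            if kind != "x":
                continue
            copies = prom.binding.multimerization[j] * E[:, j]
            totals[:, ref] += traj.states[:, sl] @ copies
    df = pd.DataFrame(totals, columns=list(net.species))
    df.insert(0, "time_h", traj.times)
    return df
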