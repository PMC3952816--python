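"""Robustness-to-interconnection metric and isolated-vs-connected comparison.

For a module whose context applies only scaling retroactivity (zero mixing),
the connected reduced dynamics are dx/dt = (I + R + Sbar)^{-1} f while the
isolated dynamics are dx/dt = (I + R)^{-1} f.  The relative change of the
right-hand side upon interconnection is therefore bounded pointwise by the
operator norm ||(I + R + Sbar)^{-1} Sbar||_2, and over a state region by

    d = sup sigma_max(Sbar) / inf sigma_min(I + R),

the robustness-to-interconnection metric: small d means the context's load
is weak compared to the module's own stiffness, so trajectories barely move
upon interconnection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import qmc

from . import _network as netw
from .dynamics import ReducedModel, simulate_reduced
from .errors import AssumptionError, ContractError
from .mechanistic import Trajectory
from .netspec import InterconnectionSpec, validate_interconnection
from .retroactivity import interconnection_matrices
from .signals import InputSignal

__all__ = [
    "RobustnessReport",
    "ComparisonReport",
    "robustness_metric",
    "rhs_perturbation_check",
    "compare_connection",
]


@dataclass(frozen=True)
class RobustnessReport:
    """Robustness metric over a state region, with the pointwise profile."""

    region: str
    n_samples: int
    sup_sigma_max_Sbar: float
    inf_sigma_min_IplusR: float
    d: float
    pointwise_bound: np.ndarray  # ||(I+R+Sbar)^{-1} Sbar||_2 per sample
    conditioning_failures: int = 0

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "n_samples": self.n_samples,
            "sup_sigma_max_Sbar": self.sup_sigma_max_Sbar,
            "inf_sigma_min_IplusR": self.inf_sigma_min_IplusR,
            "d": self.d,
            "pointwise_bound_max": float(np.max(self.pointwise_bound))
            if self.pointwise_bound.size
            else 0.0,
            "conditioning_failures": self.conditioning_failures,
        }


def _require_no_mixing(ic: InterconnectionSpec) -> None:
    rep = validate_interconnection(ic)
    if not (rep.mixing_zero and rep.module_mixing_zero):
        raise AssumptionError(
            "the robustness metric assumes zero mixing retroactivity "
            "(no promoter may bind module and context TFs non-independently); "
            f"violations: {rep.notes}"
        )


def _sample_states(
    ic: InterconnectionSpec,
    region,
    n_samples: int,
    seed: int,
) -> tuple[np.ndarray, str]:
    n = ic.module.n_nodes + ic.context.n_nodes
    if isinstance(region, Trajectory):
        states = region.states[:, :n]
        return states, "trajectory"
    if isinstance(region, Mapping):
        labels = [f"{ic.module.name}.{i}" for i in ic.module.node_ids] + [
            f"{ic.context.name}.{i}" for i in ic.context.node_ids
        ]
        try:
            bounds = np.array([region[lab] for lab in labels], dtype=float)
        except KeyError as exc:
            raise ContractError(f"state box missing bounds for {exc}") from exc
        sampler = qmc.LatinHypercube(d=n, seed=seed)
        unit = sampler.random(n_samples)
        states = qmc.scale(unit, bounds[:, 0], bounds[:, 1])
        return states, "box"
    raise ContractError("region must be a state box mapping or a Trajectory")


def robustness_metric(
    ic: InterconnectionSpec,
    region,
    n_samples: int = 256,
    seed: int = 7,
    u_ext: Mapping[str, float] | None = None,
) -> RobustnessReport:
    """Evaluate d = sup sigma_max(Sbar) / inf sigma_min(I + R) over a region.

    ``region`` is either a mapping ``{qualified species label: (lo, hi)}``
    sampled by a seeded Latin hypercube, or a Trajectory whose states are
    used directly.  Requires structurally zero mixing retroactivity.
    """
    _require_no_mixing(ic)
    states, kind = _sample_states(ic, region, n_samples, seed)
    if states.size == 0:
        raise ContractError("empty state region")
    n = ic.module.n_nodes
    sup_smax, inf_smin = 0.0, np.inf
    profile = []
    failures = 0
    for z in states:
        mats = interconnection_matrices(ic, z[:n], z[n:], u_ext)
        IR = np.eye(n) + mats.R
        smin = np.linalg.svd(IR, compute_uv=False)[-1]
        smax = (
            np.linalg.svd(mats.Sbar, compute_uv=False)[0] if mats.Sbar.size else 0.0
        )
        sup_smax = max(sup_smax, float(smax))
        inf_smin = min(inf_smin, float(smin))
        try:
            G = np.linalg.solve(IR + mats.Sbar, mats.Sbar)
            profile.append(float(np.linalg.svd(G, compute_uv=False)[0]))
        except np.linalg.LinAlgError:
            failures += 1
            profile.append(np.nan)
    return RobustnessReport(
        region=kind,
        n_samples=len(states),
        sup_sigma_max_Sbar=sup_smax,
        inf_sigma_min_IplusR=float(inf_smin),
        d=sup_smax / float(inf_smin),
        pointwise_bound=np.asarray(profile),
        conditioning_failures=failures,
    )


def rhs_perturbation_check(
    ic: InterconnectionSpec,
    states: np.ndarray,
    u_ext: Mapping[str, float] | None = None,
    slack: float = 1e-9,
) -> int:
    """Count violations of the inequality chain

        ||dx_conn - dx_iso|| <= ||(I+R+Sbar)^{-1} Sbar|| ||dx_iso||
                             <= d ||dx_iso||

    over the given joint states (rows).  The first inequality is an
    algebraic identity of the two right-hand-side forms and doubles as a
    self-test of the matrix assembly; violations beyond ``slack``
    (relative) must be zero.
    """
    _require_no_mixing(ic)
    states = np.atleast_2d(np.asarray(states, dtype=float))
    n = ic.module.n_nodes
    net = netw.from_interconnection(ic)
    uvals = {sid: float((u_ext or {}).get(sid, 0.0)) for sid in net.signal_ids}
    # d over exactly these states
    sup_smax, inf_smin = 0.0, np.inf
    cache = []
    for z in states:
        mats = interconnection_matrices(ic, z[:n], z[n:], uvals)
        IR = np.eye(n) + mats.R
        smin = np.linalg.svd(IR, compute_uv=False)[-1]
        smax = np.linalg.svd(mats.Sbar, compute_uv=False)[0] if mats.Sbar.size else 0.0
        sup_smax, inf_smin = max(sup_smax, smax), min(inf_smin, smin)
        cache.append((mats, IR))
    d = sup_smax / inf_smin
    violations = 0
    for z, (mats, IR) in zip(states, cache):
        f = netw.slow_field(net, 0.0, z, uvals)[:n]
        dx_iso = np.linalg.solve(IR, f)
        dx_conn = np.linalg.solve(IR + mats.Sbar, f)
        lhs = np.linalg.norm(dx_conn - dx_iso)
        G = np.linalg.solve(IR + mats.Sbar, mats.Sbar)
        mid = np.linalg.norm(G, 2) * np.linalg.norm(dx_iso)
        rhs = d * np.linalg.norm(dx_iso)
        scale = max(np.linalg.norm(dx_iso), 1.0)
        if lhs > mid + slack * scale or mid > rhs + slack * scale:
            violations += 1
    return violations


@dataclass(frozen=True)
class ComparisonReport:
    """Isolated vs connected module trajectories plus the robustness metric."""

    isolated: Trajectory
    connected: Trajectory
    module_labels: tuple[str, ...]
    sup_abs: float
    sup_rel: float  # sup discrepancy / isolated range, per worst species
    l2_abs: float
    l2_rel: float
    metric: RobustnessReport | None = None

    def to_dict(self) -> dict:
        out = {
            "sup_abs_nM": self.sup_abs,
            "sup_rel": self.sup_rel,
            "l2_abs": self.l2_abs,
            "l2_rel": self.l2_rel,
        }
        if self.metric is not None:
            out["metric"] = self.metric.to_dict()
        return out


def trajectory_discrepancy(
    iso: Trajectory, conn: Trajectory, labels: Sequence[str]
) -> tuple[float, float, float, float]:
    """(sup_abs, sup_rel, l2_abs, l2_rel) over the given species.

    Relative values are normalized by each species' isolated-trajectory
    range (not pointwise values), so near-zero passages do not blow up the
    ratio; the worst species is reported.
    """
    if not np.allclose(iso.times, conn.times):
        raise ContractError("trajectories must share the time grid")
    sup_abs = l2_abs = sup_rel = l2_rel = 0.0
    dt = float(np.mean(np.diff(iso.times)))
    horizon = iso.times[-1] - iso.times[0]
    for la, lb in zip(labels, labels):
        a = iso.column(la)
        b = conn.column(lb)
        diff = np.abs(a - b)
        rng = max(float(a.max() - a.min()), 1e-12)
        sup = float(diff.max())
        l2 = float(np.sqrt(np.sum(diff**2) * dt / horizon))
        sup_abs = max(sup_abs, sup)
        l2_abs = max(l2_abs, l2)
        sup_rel = max(sup_rel, sup / rng)
        l2_rel = max(l2_rel, l2 / rng)
    return sup_abs, sup_rel, l2_abs, l2_rel


def compare_connection(
    ic: InterconnectionSpec,
    x0: Sequence[float],
    v0: Sequence[float],
    t_end: float,
    dt_out: float = 0.05,
    signals: Mapping[str, InputSignal] | None = None,
    perturbations: Mapping[str, InputSignal] | None = None,
    with_metric: bool = True,
    metric_seed: int = 7,
) -> ComparisonReport:
    """Simulate the module isolated and embedded in its context, from the
    same initial condition, and report discrepancy norms and (when the
    mixing retroactivity is structurally zero) the robustness metric
    evaluated along the connected trajectory.

    ``perturbations`` maps *module node ids* to perturbation signals; they
    are applied identically in both simulations.
    """
    signals = dict(signals or {})
    perturbations = dict(perturbations or {})
    iso_model = ReducedModel.from_spec(
        ic.module,
        signals={k: v for k, v in signals.items() if k in ic.module.inputs},
        perturbations=perturbations,
    )
    conn_model = ReducedModel.from_spec(
        ic,
        signals=signals,
        perturbations={f"{ic.module.name}.{k}": v for k, v in perturbations.items()},
    )
    iso = simulate_reduced(iso_model, x0, t_end=t_end, dt_out=dt_out)
    z0 = np.concatenate([np.asarray(x0, float), np.asarray(v0, float)])
    conn = simulate_reduced(conn_model, z0, t_end=t_end, dt_out=dt_out)
    # compare module species: unqualified in iso, qualified in conn
    n = ic.module.n_nodes
    sup_abs = sup_rel = l2_abs = l2_rel = 0.0
    dt = float(np.mean(np.diff(iso.times)))
    horizon = max(iso.times[-1] - iso.times[0], dt)
    for k, nid in enumerate(ic.module.node_ids):
        a = iso.column(nid)
        b = conn.states[:, k]
        diff = np.abs(a - b)
        rng = max(float(a.max() - a.min()), 1e-12)
        sup_abs = max(sup_abs, float(diff.max()))
        sup_rel = max(sup_rel, float(diff.max()) / rng)
        l2 = float(np.sqrt(np.sum(diff**2) * dt / horizon))
        l2_abs = max(l2_abs, l2)
        l2_rel = max(l2_rel, l2 / rng)
    metric = None
    if with_metric:
        rep = validate_interconnection(ic)
        if rep.mixing_zero and rep.module_mixing_zero:
            uvals = {
                sid: float(signals[sid].value(0.0)) if sid in signals else 0.0
                for sid in conn_model.network.signal_ids
            }
            metric = robustness_metric(
                ic, conn, n_samples=len(conn.times), seed=metric_seed, u_ext=uvals
            )
    return ComparisonReport(
        isolated=iso,
        connected=conn,
        module_labels=ic.module.node_ids,
        sup_abs=sup_abs,
        sup_rel=sup_rel,
        l2_abs=l2_abs,
        l2_rel=l2_rel,
        metric=metric,
    )
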