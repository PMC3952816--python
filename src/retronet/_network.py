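"""Flattened network representation shared by the mechanistic and reduced models.

A :class:`Network` is a module (or a wired module/context pair) with every
parent reference resolved to either a dynamic species index or an exogenous
signal id.  Both the mass-action model builder and the reduced right-hand
sides operate on this one structure, which guarantees that the two model
tiers describe the same chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigurationError
from .netspec import BindingSpec, InterconnectionSpec, ModuleSpec
from .retroactivity import hill_production, node_retroactivity, qss_complexes
from .signals import InputSignal

__all__ = [
    "ParentRef",
    "NetPromoter",
    "Network",
    "from_module",
    "from_interconnection",
    "slow_field",
    "reduced_matrices",
    "promoter_jacobian_blocks",
    "total_bound",
]

# ("x", species index) for a dynamic TF, ("u", signal id) for an exogenous input
ParentRef = tuple


@dataclass(frozen=True)
class NetPromoter:
    owner: int  # species index of the TF this promoter produces
    binding: BindingSpec
    parent_refs: tuple[ParentRef, ...]
    side: str  # "module" or "context"


@dataclass(frozen=True)
class Network:
    name: str
    species: tuple[str, ...]
    deltas: np.ndarray
    perturbable: tuple[bool, ...]
    promoters: tuple[NetPromoter, ...]
    signal_ids: tuple[str, ...]
    n_module: int  # species[:n_module] belong to the module side

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, label: str) -> int:
        return self.species.index(label)


def _resolve(spec: ModuleSpec, parent: str, offset: int, wiring_to_idx: Mapping[str, int]):
    if parent in spec.node_ids:
        return ("x", offset + spec.node_index(parent))
    if parent in wiring_to_idx:
        return ("x", wiring_to_idx[parent])
    return ("u", parent)


def _promoters(
    spec: ModuleSpec, offset: int, side: str, wiring_to_idx: Mapping[str, int]
) -> list[NetPromoter]:
    out = []
    for i, node in enumerate(spec.nodes):
        refs = tuple(
            _resolve(spec, p, offset, wiring_to_idx) for p in node.binding.parents
        )
        out.append(NetPromoter(owner=offset + i, binding=node.binding, parent_refs=refs, side=side))
    return out


def from_module(spec: ModuleSpec) -> Network:
    """Flatten a single module; unwired inputs stay exogenous signals."""
    return Network(
        name=spec.name,
        species=spec.node_ids,
        deltas=np.array([n.delta for n in spec.nodes]),
        perturbable=tuple(n.perturbable for n in spec.nodes),
        promoters=tuple(_promoters(spec, 0, "module", {})),
        signal_ids=tuple(spec.inputs),
        n_module=spec.n_nodes,
    )


def from_interconnection(ic: InterconnectionSpec) -> Network:
    """Flatten a wired module/context pair into one network.

    Species are qualified as ``<module name>.<node id>``; module species come
    first.  Wired inputs resolve to the feeding node's species index; unwired
    inputs remain exogenous signals under their raw input id.
    """
    mod, ctx = ic.module, ic.context
    species = tuple(f"{mod.name}.{nid}" for nid in mod.node_ids) + tuple(
        f"{ctx.name}.{nid}" for nid in ctx.node_ids
    )
    n = mod.n_nodes
    ctx_wiring = {inp: mod.node_index(node) for inp, node in ic.context_wiring.items()}
    mod_wiring = {inp: n + ctx.node_index(node) for inp, node in ic.module_wiring.items()}
    proms = _promoters(mod, 0, "module", mod_wiring) + _promoters(ctx, n, "context", ctx_wiring)
    signal_ids = tuple(
        dict.fromkeys(
            [i for i in mod.inputs if i not in ic.module_wiring]
            + [i for i in ctx.inputs if i not in ic.context_wiring]
        )
    )
    return Network(
        name=f"{mod.name}+{ctx.name}",
        species=species,
        deltas=np.concatenate(
            [[nd.delta for nd in mod.nodes], [nd.delta for nd in ctx.nodes]]
        ),
        perturbable=tuple(nd.perturbable for nd in mod.nodes)
        + tuple(nd.perturbable for nd in ctx.nodes),
        promoters=tuple(proms),
        signal_ids=signal_ids,
        n_module=n,
    )


def parent_concentrations(
    prom: NetPromoter, z: np.ndarray, uvals: Mapping[str, float]
) -> np.ndarray:
    concs = []
    for kind, ref in prom.parent_refs:
        if kind == "x":
            concs.append(max(z[ref], 0.0))
        else:
            try:
                concs.append(uvals[ref])
            except KeyError as exc:
                raise ConfigurationError(
                    f"no signal bound to input {ref!r}"
                ) from exc
    return np.asarray(concs, dtype=float)


def signal_values(
    net: Network, signals: Mapping[str, InputSignal], t: float
) -> dict[str, float]:
    out = {}
    for sid in net.signal_ids:
        if sid not in signals:
            raise ConfigurationError(f"no signal bound to input {sid!r}")
        out[sid] = max(float(signals[sid].value(t)), 0.0)
    return out


def slow_field(
    net: Network,
    t: float,
    z: np.ndarray,
    uvals: Mapping[str, float],
    perturbations: Mapping[str, InputSignal] | None = None,
) -> np.ndarray:
    """Slow vector field f = H(z, u) - diag(delta) z + d(t) in nM/h."""
    f = -net.deltas * z
    for prom in net.promoters:
        f[prom.owner] += hill_production(
            prom.binding, parent_concentrations(prom, z, uvals)
        )
    if perturbations:
        for label, sig in perturbations.items():
            idx = net.species_index(label)
            if not net.perturbable[idx]:
                raise ConfigurationError(
                    f"species {label!r} is not flagged perturbable"
                )
            f[idx] += sig.value(t)
    return f


def reduced_matrices(
    net: Network, z: np.ndarray, uvals: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Total-bound Jacobian J (n x n) and signal cross-Jacobian Ju (n x n_sig).

    J[j, k] = d(total TF j bound anywhere)/d(free TF k); Ju[j, s] likewise
    w.r.t. the exogenous signal s.  The reduced premultiplier is I + J and
    the input-derivative forcing is Ju @ udot.
    """
    n = net.n_species
    sig_index = {s: i for i, s in enumerate(net.signal_ids)}
    J = np.zeros((n, n))
    Ju = np.zeros((n, len(net.signal_ids)))
    for prom in net.promoters:
        b = prom.binding
        if b.n_parents == 0 or b.promoter_total == 0:
            continue
        R = node_retroactivity(b, parent_concentrations(prom, z, uvals)).R
        for j, (kj, rj) in enumerate(prom.parent_refs):
            if kj != "x":
                continue
            for k, (kk, rk) in enumerate(prom.parent_refs):
                if kk == "x":
                    J[rj, rk] += R[j, k]
                else:
                    Ju[rj, sig_index[rk]] += R[j, k]
    return J, Ju


def promoter_jacobian_blocks(
    net: Network, z: np.ndarray, uvals: Mapping[str, float]
) -> dict[str, np.ndarray]:
    """Total-bound Jacobians split by the side owning the promoter."""
    n = net.n_species
    blocks = {"module": np.zeros((n, n)), "context": np.zeros((n, n))}
    for prom in net.promoters:
        b = prom.binding
        if b.n_parents == 0 or b.promoter_total == 0:
            continue
        R = node_retroactivity(b, parent_concentrations(prom, z, uvals)).R
        J = blocks[prom.side]
        for j, (kj, rj) in enumerate(prom.parent_refs):
            if kj != "x":
                continue
            for k, (kk, rk) in enumerate(prom.parent_refs):
                if kk == "x":
                    J[rj, rk] += R[j, k]
    return blocks


def total_bound(net: Network, z: np.ndarray, uvals: Mapping[str, float]) -> np.ndarray:
    """Total promoter-bound amount of each dynamic TF at QSS, counting
    multimerization (n copies per bound n-multimer)."""
    bound = np.zeros(net.n_species)
    for prom in net.promoters:
        b = prom.binding
        if b.n_parents == 0 or b.promoter_total == 0:
            continue
        res = qss_complexes(b, parent_concentrations(prom, z, uvals))
        nr = node_retroactivity(b, parent_concentrations(prom, z, uvals))
        per_parent = nr.M @ res.gamma
        for j, (kind, ref) in enumerate(prom.parent_refs):
            if kind == "x":
                bound[ref] += per_parent[j]
    return bound
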