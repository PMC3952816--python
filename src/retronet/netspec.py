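"""Declarative network specifications.

A *node* is a transcriptional component: a promoter plus the gene expressing
one transcription factor (TF).  Parent TFs bind the promoter (as n-multimers,
in a single lumped step) and each promoter occupancy state produces the
node's TF at its own rate.  A *module* is a named set of nodes plus an
ordered list of external input TFs; an *interconnection* wires a module to a
context module by identifying inputs of one with nodes of the other.

Units are fixed package-wide: concentrations in nM, time in hours, and an
n-multimer dissociation constant carries units nM^n (binding is modeled as
n*X + P <-> C in one step).

Binding types at a promoter (at most two parents):

========================  =============================================
``none``                  constitutive, no parents
``single``                one parent
``independent``           two parents on separate sites; occupancies
                          factorize and neither influences the other
``competitive``           two parents competing for one site; states
                          P, C1, C2 only (no doubly bound complex)
``cooperative``           sequential binding: the FIRST listed parent
                          must bind before the second; states P, C1, C12
                          (the second parent cannot bind alone)
========================  =============================================
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import ConsistencyError, ReferenceError_, ValidationError

__all__ = [
    "BINDING_TYPES",
    "PARAMETER_RANGES",
    "Production",
    "BindingSpec",
    "NodeSpec",
    "ModuleSpec",
    "InterconnectionSpec",
    "InterconnectionReport",
    "load_module",
    "module_from_dict",
    "module_to_dict",
    "save_module",
    "load_interconnection",
    "generate_fixture",
    "validate_interconnection",
]

BINDING_TYPES = ("none", "single", "independent", "competitive", "cooperative")

#: Physiological parameter ranges for E. coli used by the fixture generator.
#: alpha: per-complex production rate constant [1/h]; a strong promoter/RBS
#: pair can reach several hundred proteins per hour per gene copy.
#: K_half: parent concentration at half occupancy [nM] (the dissociation
#: constant of an n-multimer is K_half**n in nM^n).
#: p_T: promoter (gene copy) concentration [nM]; 1 copy/cell ~ 2 nM, from
#: single-copy chromosomal insertion to high copy number plasmids.
#: delta: protein decay/dilution rate [1/h]; protein lifetime is on the order
#: of a cell cycle.
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (1.0, 600.0),
    "K_half": (1.0, 1000.0),
    "p_T": (2.0, 600.0),
    "delta": (0.3, 2.5),
}


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Production:
    """Per-occupancy-state production rate constants [1/h per nM promoter].

    ``alpha0``: empty promoter; ``alpha1``: first parent bound alone;
    ``alpha2``: second parent bound alone; ``alpha12``: both bound.
    """

    alpha0: float = 0.0
    alpha1: float = 0.0
    alpha2: float = 0.0
    alpha12: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha0": self.alpha0,
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "alpha12": self.alpha12,
        }


@dataclass(frozen=True)
class BindingSpec:
    """Promoter configuration of one node.

    ``parents`` is ordered; order is significant for cooperative binding
    (the first listed parent binds first).  ``multimerization[j]`` is the
    number of copies of parent j binding as one unit and
    ``dissociation[j]`` the corresponding dissociation constant in
    nM**multimerization[j].
    """

    binding_type: str
    parents: tuple[str, ...] = ()
    multimerization: tuple[int, ...] = ()
    dissociation: tuple[float, ...] = ()
    promoter_total: float = 0.0
    production: Production = field(default_factory=Production)

    def __post_init__(self) -> None:
        bt = self.binding_type
        if bt not in BINDING_TYPES:
            raise ValidationError(f"unknown binding type {bt!r}")
        expected = {"none": 0, "single": 1}.get(bt, 2)
        if len(self.parents) != expected:
            raise ConsistencyError(
                f"binding type {bt!r} requires {expected} parent(s), "
                f"got {len(self.parents)}"
            )
        if len(self.multimerization) != len(self.parents) or len(
            self.dissociation
        ) != len(self.parents):
            raise ConsistencyError(
                "multimerization and dissociation must have one entry per parent"
            )
        for n in self.multimerization:
            if int(n) != n or n < 1:
                raise ValidationError(f"multimerization factor must be an integer >= 1, got {n}")
        for K in self.dissociation:
            if not K > 0:
                raise ValidationError(f"dissociation constant must be > 0, got {K}")
        if self.promoter_total < 0:
            raise ValidationError(f"promoter_total must be >= 0, got {self.promoter_total}")
        p = self.production
        for name, a in p.as_dict().items():
            if a < 0:
                raise ValidationError(f"production rate {name} must be >= 0, got {a}")
        if bt == "competitive" and p.alpha12 != 0.0:
            raise ConsistencyError(
                "competitive binding has no doubly-bound complex: alpha12 must be 0"
            )
        if bt == "cooperative" and p.alpha2 != 0.0:
            raise ConsistencyError(
                "cooperative binding: the second parent cannot bind alone, alpha2 must be 0"
            )

    @property
    def n_parents(self) -> int:
        return len(self.parents)


@dataclass(frozen=True)
class NodeSpec:
    """One transcriptional component: id, decay rate [1/h], promoter binding."""

    id: str
    delta: float
    binding: BindingSpec
    perturbable: bool = False

    def __post_init__(self) -> None:
        if not self.id or not isinstance(self.id, str):
            raise ValidationError("node id must be a non-empty string")
        if not self.delta > 0:
            raise ValidationError(f"node {self.id!r}: decay rate delta must be > 0")


@dataclass(frozen=True)
class ModuleSpec:
    """A named set of nodes plus an ordered list of external input TF ids."""

    name: str
    nodes: tuple[NodeSpec, ...]
    inputs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"module {self.name!r}: duplicate node ids")
        if len(set(self.inputs)) != len(self.inputs):
            raise ValidationError(f"module {self.name!r}: duplicate input ids")
        clash = set(ids) & set(self.inputs)
        if clash:
            raise ValidationError(
                f"module {self.name!r}: ids used both as node and input: {sorted(clash)}"
            )
        known = set(ids) | set(self.inputs)
        for node in self.nodes:
            for p in node.binding.parents:
                if p not in known:
                    raise ReferenceError_(
                        f"module {self.name!r}: node {node.id!r} references "
                        f"unknown parent {p!r}"
                    )

    # -- index helpers -----------------------------------------------------

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(n.id for n in self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise ReferenceError_(f"module {self.name!r}: no node {node_id!r}")

    def node_index(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    @property
    def internal_parent_nodes(self) -> tuple[str, ...]:
        """Ids of nodes with at least one parent from inside the module."""
        ids = set(self.node_ids)
        return tuple(
            n.id for n in self.nodes if any(p in ids for p in n.binding.parents)
        )

    @property
    def input_parent_nodes(self) -> tuple[str, ...]:
        """Ids of nodes with at least one parent among the module inputs."""
        return tuple(
            n.id for n in self.nodes if any(p in self.inputs for p in n.binding.parents)
        )

    def selector_matrices(self, node_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Binary parent-selector matrices ``(V_i, W_i)`` of a node.

        Both have one row per parent (in declaration order); ``V_i`` has one
        column per module node, ``W_i`` one per module input.  Row j of the
        stacked pair contains exactly one 1, in ``V_i`` if parent j is an
        internal node and in ``W_i`` if it is an input, so that
        ``V_i @ x + W_i @ u`` reproduces the parent concentration vector.
        """
        node = self.node(node_id)
        n_par = node.binding.n_parents
        V = np.zeros((n_par, self.n_nodes))
        W = np.zeros((n_par, len(self.inputs)))
        for j, p in enumerate(node.binding.parents):
            if p in self.node_ids:
                V[j, self.node_index(p)] = 1.0
            else:
                W[j, self.inputs.index(p)] = 1.0
        return V, W


@dataclass(frozen=True)
class InterconnectionSpec:
    """A module embedded in a context module.

    ``context_wiring`` maps each wired context input id to the module node
    feeding it; ``module_wiring`` maps each wired module input id to the
    context node feeding it.  Unwired inputs must be bound to explicit
    signals at simulation time.
    """

    module: ModuleSpec
    context: ModuleSpec
    context_wiring: Mapping[str, str] = field(default_factory=dict)
    module_wiring: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for inp, node in self.context_wiring.items():
            if inp not in self.context.inputs:
                raise ReferenceError_(f"wiring: {inp!r} is not an input of the context")
            if node not in self.module.node_ids:
                raise ReferenceError_(f"wiring: {node!r} is not a node of the module")
        for inp, node in self.module_wiring.items():
            if inp not in self.module.inputs:
                raise ReferenceError_(f"wiring: {inp!r} is not an input of the module")
            if node not in self.context.node_ids:
                raise ReferenceError_(f"wiring: {node!r} is not a node of the context")

    @property
    def Q(self) -> np.ndarray:
        """Binary matrix (#context inputs x #module nodes): entry (j,k)=1 iff
        context input j is wired to module node k."""
        Q = np.zeros((len(self.context.inputs), self.module.n_nodes))
        for inp, node in self.context_wiring.items():
            Q[self.context.inputs.index(inp), self.module.node_index(node)] = 1.0
        return Q

    @property
    def Qbar(self) -> np.ndarray:
        """Binary matrix (#module inputs x #context nodes), the context-side
        counterpart of :attr:`Q`."""
        Q = np.zeros((len(self.module.inputs), self.context.n_nodes))
        for inp, node in self.module_wiring.items():
            Q[self.module.inputs.index(inp), self.context.node_index(node)] = 1.0
        return Q


# --------------------------------------------------------------------------
# (de)serialization
# --------------------------------------------------------------------------


def _binding_from_dict(d: Mapping, where: str) -> BindingSpec:
    if "type" not in d:
        raise ValidationError(f"{where}: binding block missing 'type'")
    parents_raw = d.get("parents", []) or []
    parents, ns, Ks = [], [], []
    for j, p in enumerate(parents_raw):
        try:
            parents.append(str(p["ref"]))
            ns.append(int(p.get("n", 1)))
            Ks.append(float(p["K"]))
        except KeyError as exc:
            raise ValidationError(f"{where}: parent {j} missing field {exc}") from exc
    prod_raw = d.get("production", {}) or {}
    unknown = set(prod_raw) - {"alpha0", "alpha1", "alpha2", "alpha12"}
    if unknown:
        raise ValidationError(f"{where}: unknown production keys {sorted(unknown)}")
    return BindingSpec(
        binding_type=str(d["type"]),
        parents=tuple(parents),
        multimerization=tuple(ns),
        dissociation=tuple(Ks),
        promoter_total=float(d.get("promoter_total", 0.0)),
        production=Production(**{k: float(v) for k, v in prod_raw.items()}),
    )


def module_from_dict(d: Mapping) -> ModuleSpec:
    if "name" not in d or "nodes" not in d:
        raise ValidationError("module requires 'name' and 'nodes'")
    nodes = []
    for nd in d["nodes"]:
        if "id" not in nd:
            raise ValidationError("node entry missing 'id'")
        where = f"node {nd['id']!r}"
        if "delta" not in nd:
            raise ValidationError(f"{where}: missing 'delta'")
        if "binding" not in nd:
            raise ValidationError(f"{where}: missing 'binding'")
        nodes.append(
            NodeSpec(
                id=str(nd["id"]),
                delta=float(nd["delta"]),
                binding=_binding_from_dict(nd["binding"], where),
                perturbable=bool(nd.get("perturbable", False)),
            )
        )
    return ModuleSpec(
        name=str(d["name"]),
        nodes=tuple(nodes),
        inputs=tuple(str(i) for i in d.get("inputs", []) or []),
    )


def module_to_dict(spec: ModuleSpec) -> dict:
    nodes = []
    for n in spec.nodes:
        b = n.binding
        nodes.append(
            {
                "id": n.id,
                "delta": n.delta,
                "perturbable": n.perturbable,
                "binding": {
                    "type": b.binding_type,
                    "parents": [
                        {"ref": p, "n": int(m), "K": float(K)}
                        for p, m, K in zip(b.parents, b.multimerization, b.dissociation)
                    ],
                    "promoter_total": b.promoter_total,
                    "production": b.production.as_dict(),
                },
            }
        )
    return {"name": spec.name, "nodes": nodes, "inputs": list(spec.inputs)}


def load_module(path) -> ModuleSpec:
    """Load and validate a module from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValidationError(f"{path}: top level must be a mapping")
    return module_from_dict(data)


def save_module(spec: ModuleSpec, path) -> None:
    path = Path(path)
    d = module_to_dict(spec)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(serialize_module(spec))


def serialize_module(spec: ModuleSpec) -> str:
    """Canonical YAML serialization (stable key order) of a module."""
    buf = io.StringIO()
    yaml.safe_dump(module_to_dict(spec), buf, sort_keys=True)
    return buf.getvalue()


def load_interconnection(path) -> InterconnectionSpec:
    """Load an interconnection file: keys ``module``, ``context`` (paths
    relative to the file, or inline module mappings) and ``wiring`` (list of
    ``{input, node, side}`` with side in {module, context})."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, Mapping):
        raise ValidationError(f"{path}: top level must be a mapping")

    def resolve(entry, what):
        if isinstance(entry, Mapping):
            return module_from_dict(entry)
        if isinstance(entry, str):
            return load_module(path.parent / entry)
        raise ValidationError(f"{path}: {what} must be a path or inline module")

    module = resolve(data.get("module"), "module")
    context = resolve(data.get("context"), "context")
    cw, mw = {}, {}
    for w in data.get("wiring", []) or []:
        try:
            side, inp, node = w["side"], w["input"], w["node"]
        except KeyError as exc:
            raise ValidationError(f"{path}: wiring entry missing {exc}") from exc
        if side == "context":
            cw[inp] = node
        elif side == "module":
            mw[inp] = node
        else:
            raise ValidationError(f"{path}: wiring side must be 'module' or 'context'")
    return InterconnectionSpec(module=module, context=context, context_wiring=cw, module_wiring=mw)


# --------------------------------------------------------------------------
# fixture generator
# --------------------------------------------------------------------------


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_fixture(seed: int, n_nodes: int, density: float) -> ModuleSpec:
    """Random module with parameters sampled log-uniformly from the
    physiological ranges in :data:`PARAMETER_RANGES`.

    ``density`` is the probability that a node is regulated at all; regulated
    nodes draw one or two parents uniformly from the node set (self-loops and
    cycles allowed), a legal binding type uniformly, and multimerization
    factors from {1, 2, 3, 4}.  Deterministic in ``seed``.
    """
    if n_nodes < 1:
        raise ValidationError("n_nodes must be >= 1")
    if not 0.0 <= density <= 1.0:
        raise ValidationError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"x{i + 1}" for i in range(n_nodes)]
    nodes = []
    for nid in ids:
        regulated = rng.random() < density
        alo, ahi = PARAMETER_RANGES["alpha"]
        if not regulated:
            binding = BindingSpec(
                binding_type="none",
                promoter_total=_log_uniform(rng, *PARAMETER_RANGES["p_T"]),
                production=Production(alpha0=_log_uniform(rng, alo, ahi)),
            )
        else:
            n_par = 1 if n_nodes == 1 else int(rng.integers(1, 3))
            if n_par == 1:
                btype = "single"
                parents = (ids[int(rng.integers(n_nodes))],)
            else:
                btype = str(rng.choice(["independent", "competitive", "cooperative"]))
                pair = rng.choice(n_nodes, size=2, replace=n_nodes < 2)
                parents = (ids[int(pair[0])], ids[int(pair[1])])
            ns = tuple(int(rng.integers(1, 5)) for _ in parents)
            Ks = tuple(
                _log_uniform(rng, *PARAMETER_RANGES["K_half"]) ** n for n in ns
            )
            alphas = {"alpha0": _log_uniform(rng, alo, ahi)}
            roles = ["alpha1"] if n_par == 1 else ["alpha1", "alpha2", "alpha12"]
            if btype == "competitive":
                roles.remove("alpha12")
            if btype == "cooperative":
                roles.remove("alpha2")
            for r in roles:
                # each occupied state is either silent or active
                alphas[r] = _log_uniform(rng, alo, ahi) if rng.random() < 0.5 else 0.0
            binding = BindingSpec(
                binding_type=btype,
                parents=parents,
                multimerization=ns,
                dissociation=Ks,
                promoter_total=_log_uniform(rng, *PARAMETER_RANGES["p_T"]),
                production=Production(**alphas),
            )
        nodes.append(
            NodeSpec(
                id=nid,
                delta=_log_uniform(rng, *PARAMETER_RANGES["delta"]),
                binding=binding,
                perturbable=bool(rng.random() < 0.5),
            )
        )
    return ModuleSpec(name=f"fixture-{seed}", nodes=tuple(nodes))


# --------------------------------------------------------------------------
# interconnection structure report
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class InterconnectionReport:
    """Structural guarantees readable from the wiring topology alone.

    ``mixing_zero``: the context's mixing retroactivity is identically zero
    (no context promoter couples module parents with context parents
    non-independently); ``scaling_zero``: the context places no load at all
    on module TFs.  ``module_mixing_zero``/``module_scaling_zero`` are the
    module-side counterparts (loads the module places on context TFs).
    """

    mixing_zero: bool
    scaling_zero: bool
    module_mixing_zero: bool
    module_scaling_zero: bool
    notes: tuple[str, ...] = ()


def _side_structure(
    receiver: ModuleSpec, wired_inputs: set[str]
) -> tuple[bool, bool, list[str]]:
    """Structure of the load ``receiver`` promoters place on the other side.

    ``wired_inputs``: receiver inputs that are fed by the other side's nodes.
    Returns (mixing_zero, scaling_zero, notes).
    """
    mixing_zero, scaling_zero = True, True
    notes: list[str] = []
    own = set(receiver.node_ids)
    for node in receiver.nodes:
        b = node.binding
        if b.promoter_total == 0:
            continue
        has_far = any(p in wired_inputs for p in b.parents)
        # only dynamic species on the receiver's side can be "mixed" with the
        # other side; unwired inputs are exogenous signals
        has_near = any(p in own for p in b.parents)
        if has_far:
            scaling_zero = False
            if has_near and b.binding_type != "independent":
                mixing_zero = False
                notes.append(
                    f"{receiver.name}.{node.id}: {b.binding_type} binding mixes "
                    "parents from both sides"
                )
    return mixing_zero, scaling_zero, notes


def validate_interconnection(ic: InterconnectionSpec) -> InterconnectionReport:
    """Report whether the scaling/mixing retroactivities are structurally zero.

    A context promoter contributes to the scaling retroactivity as soon as it
    binds a module TF, and to the mixing retroactivity only if it binds a
    module TF and a context TF at the same promoter non-independently.
    """
    mz, sz, n1 = _side_structure(ic.context, set(ic.context_wiring))
    mmz, msz, n2 = _side_structure(ic.module, set(ic.module_wiring))
    return InterconnectionReport(
        mixing_zero=mz,
        scaling_zero=sz,
        module_mixing_zero=mmz,
        module_scaling_zero=msz,
        notes=tuple(n1 + n2),
    )


def with_promoter_total(spec: ModuleSpec, node_id: str, p_T: float) -> ModuleSpec:
    """Return a copy of ``spec`` with one node's promoter total replaced."""
    nodes = tuple(
        replace(n, binding=replace(n.binding, promoter_total=float(p_T)))
        if n.id == node_id
        else n
        for n in spec.nodes
    )
    return replace(spec, nodes=nodes)
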