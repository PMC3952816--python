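"""Promoter occupancy at quasi-steady state and retroactivity matrices.

Binding of parent TFs to promoters is orders of magnitude faster than gene
expression, so on the expression time scale the promoter occupancy states sit
at the binding equilibrium determined by the instantaneous free parent
concentrations.  Writing ``a_j = x_j**n_j / K_j`` for the binding activity of
parent j (an n_j-multimer with dissociation constant K_j in nM**n_j), every
occupancy state s of the catalog carries the Boltzmann-like weight
``w_s = prod_j a_j**e_sj`` with binary exponents e_sj recording whether
parent j is bound in state s, and

    gamma_s = p_T * w_s / sum_t w_t .

This single partition-function form covers all four binding types; they
differ only in which states exist (competitive binding lacks the doubly
bound state, cooperative binding lacks the second-parent-only state).

The *retroactivity of a node* is the Jacobian of the total promoter-bound
parent amounts with respect to the free parent concentrations,

    R_i = M_i @ d(gamma)/d(x),

with M_i the multimer-count matrix (entry n_j if parent j is bound as an
n_j-multimer in state s).  R_i is dimensionless and quantifies how many
units of total TF must move to change the free concentration by one unit.
Module-level matrices are assembled by summing node retroactivities into
global coordinates using the parent-selector bookkeeping of the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConditioningError, ContractError, DomainError
from .netspec import BindingSpec, InterconnectionSpec, ModuleSpec

__all__ = [
    "STATE_CATALOG",
    "REACTION_CATALOG",
    "state_labels",
    "state_alphas",
    "QssResult",
    "NodeRetroactivity",
    "ModuleMatrices",
    "qss_complexes",
    "qss_newton",
    "hill_production",
    "node_retroactivity",
    "internal_retroactivity",
    "external_retroactivity",
    "interconnection_matrices",
    "CONDITIONING_FLOOR",
]

#: Minimum acceptable sigma_min(I + R); below this the premultiplier is
#: treated as singular.
CONDITIONING_FLOOR = 1e-12

#: Occupancy states per binding type as tuples of binary exponents over the
#: (ordered) parent list.  The first state is always the empty promoter.
STATE_CATALOG: dict[str, tuple[tuple[int, ...], ...]] = {
    "none": ((),),
    "single": ((0,), (1,)),
    "independent": ((0, 0), (1, 0), (0, 1), (1, 1)),
    "competitive": ((0, 0), (1, 0), (0, 1)),
    "cooperative": ((0, 0), (1, 0), (1, 1)),
}

#: Elementary reversible binding reactions per type, as (reactant state
#: index, product state index, parent index).  Independent binding forms a
#: closed thermodynamic cycle: the second-site rates do not depend on the
#: occupancy of the first site, so both paths to the doubly bound state
#: share the same equilibrium constants.
REACTION_CATALOG: dict[str, tuple[tuple[int, int, int], ...]] = {
    "none": (),
    "single": ((0, 1, 0),),
    "independent": ((0, 1, 0), (0, 2, 1), (1, 3, 1), (2, 3, 0)),
    "competitive": ((0, 1, 0), (0, 2, 1)),
    "cooperative": ((0, 1, 0), (1, 2, 1)),
}

_LABELS = {(): "P", (0,): "P", (1,): "C1", (0, 0): "P", (1, 0): "C1", (0, 1): "C2", (1, 1): "C12"}
_ALPHA_ROLE = {(): "alpha0", (0,): "alpha0", (1,): "alpha1", (0, 0): "alpha0",
               (1, 0): "alpha1", (0, 1): "alpha2", (1, 1): "alpha12"}


def state_labels(binding: BindingSpec) -> tuple[str, ...]:
    return tuple(_LABELS[e] for e in STATE_CATALOG[binding.binding_type])


def state_alphas(binding: BindingSpec) -> np.ndarray:
    """Production rate constant of each occupancy state, in catalog order."""
    prod = binding.production.as_dict()
    return np.array(
        [prod[_ALPHA_ROLE[e]] for e in STATE_CATALOG[binding.binding_type]]
    )


@dataclass(frozen=True)
class QssResult:
    """Binding equilibrium of one promoter given free parent concentrations."""

    labels: tuple[str, ...]
    gamma: np.ndarray  # state concentrations [nM], empty promoter first
    jacobian: np.ndarray  # d gamma / d parent_concs, (n_states x n_parents)

    @property
    def free_promoter(self) -> float:
        return float(self.gamma[0])


@dataclass(frozen=True)
class NodeRetroactivity:
    """Node retroactivity matrix and the multimer-count matrix behind it."""

    R: np.ndarray  # (n_parents x n_parents), d(total bound)/d(free)
    M: np.ndarray  # (n_parents x n_states), multimer counts


def _activities(binding: BindingSpec, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Binding activities a_j = x_j**n_j / K_j and their derivatives a'_j."""
    n = np.asarray(binding.multimerization, dtype=float)
    K = np.asarray(binding.dissociation, dtype=float)
    a = x**n / K
    # d/dx x**n = n x**(n-1); at x=0 this is 1/K for n=1 and 0 for n>1
    with np.errstate(divide="ignore", invalid="ignore"):
        da = np.where(x > 0, n * x ** (n - 1.0) / K, np.where(n == 1.0, 1.0 / K, 0.0))
    return a, da


def _check_parents(binding: BindingSpec, parent_concs) -> np.ndarray:
    x = np.asarray(parent_concs, dtype=float).reshape(-1)
    if x.size != binding.n_parents:
        raise ContractError(
            f"expected {binding.n_parents} parent concentration(s), got {x.size}"
        )
    if np.any(x < 0):
        raise DomainError(f"negative parent concentration: {x}")
    return x


def qss_complexes(binding: BindingSpec, parent_concs=()) -> QssResult:
    """Closed-form promoter occupancy states at binding equilibrium.

    Returns all states (empty promoter first) summing to ``promoter_total``,
    together with the analytic Jacobian of the state concentrations with
    respect to the free parent concentrations.
    """
    x = _check_parents(binding, parent_concs)
    states = STATE_CATALOG[binding.binding_type]
    p_T = binding.promoter_total
    if binding.n_parents == 0:
        return QssResult(
            labels=state_labels(binding),
            gamma=np.array([p_T]),
            jacobian=np.zeros((1, 0)),
        )
    a, da = _activities(binding, x)
    E = np.array(states, dtype=float)  # (n_states x n_parents)
    # w_s = prod_j a_j**e_sj with e in {0,1}: product over bound parents
    W = np.where(E > 0, a[None, :], 1.0).prod(axis=1)
    D = W.sum()
    gamma = p_T * W / D
    # dw_s/da_j = e_sj * prod_{k != j} a_k**e_sk
    dW = np.zeros((len(states), binding.n_parents))
    for j in range(binding.n_parents):
        others = np.where(
            np.delete(E, j, axis=1) > 0, np.delete(a, j)[None, :], 1.0
        ).prod(axis=1)
        dW[:, j] = E[:, j] * others
    dD = dW.sum(axis=0)
    dgamma_da = p_T * (dW * D - W[:, None] * dD[None, :]) / D**2
    jac = dgamma_da * da[None, :]
    return QssResult(labels=state_labels(binding), gamma=gamma, jacobian=jac)


def qss_newton(
    binding: BindingSpec,
    parent_concs=(),
    tol: float = 1e-12,
    max_iter: int = 200,
) -> QssResult:
    """Damped-Newton solve of the fast binding-flux fixed point.

    Independent numerical route to the same equilibrium as
    :func:`qss_complexes`: solves for the non-empty complex concentrations c
    such that the net flux of every elementary binding reaction drives
    ``dc/dt = 0``, with the empty promoter eliminated through conservation.
    Uses unit off-rates (the equilibrium is rate-independent) and a
    finite-difference Jacobian.  Intended as a cross-check oracle.
    """
    x = _check_parents(binding, parent_concs)
    states = STATE_CATALOG[binding.binding_type]
    reactions = REACTION_CATALOG[binding.binding_type]
    p_T = binding.promoter_total
    n_c = len(states) - 1
    if n_c == 0:
        return qss_complexes(binding, parent_concs)
    n = np.asarray(binding.multimerization, dtype=float)
    K = np.asarray(binding.dissociation, dtype=float)

    def residual(c: np.ndarray) -> np.ndarray:
        full = np.concatenate([[p_T - c.sum()], c])
        r = np.zeros(n_c)
        for s_r, s_p, j in reactions:
            flux = (x[j] ** n[j] / K[j]) * full[s_r] - full[s_p]
            if s_r > 0:
                r[s_r - 1] -= flux
            r[s_p - 1] += flux
        return r

    c = np.full(n_c, p_T / (n_c + 1.0))
    if p_T == 0:
        return QssResult(state_labels(binding), np.zeros(n_c + 1), np.zeros((n_c + 1, len(x))))
    # fluxes scale with the binding activities; the achievable residual floor does too
    a_max = float(np.max(x**n / K, initial=0.0))
    floor = tol * max(p_T, 1.0) * (1.0 + a_max)
    for _ in range(max_iter):
        r = residual(c)
        if np.max(np.abs(r)) < floor:
            break
        h = 1e-7 * max(p_T, 1.0)
        J = np.empty((n_c, n_c))
        for k in range(n_c):
            cp = c.copy()
            cp[k] += h
            J[:, k] = (residual(cp) - r) / h
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise ArithmeticError(f"Newton Jacobian singular, residual {r}") from exc
        lam = 1.0
        base = np.linalg.norm(r)
        for _ in range(60):
            trial = c + lam * step
            if np.all(trial >= -1e-300) and trial.sum() <= p_T * (1 + 1e-12):
                if np.linalg.norm(residual(trial)) < base:
                    break
            lam *= 0.5
        c = c + lam * step
    else:
        raise ArithmeticError(
            f"Newton did not converge; residual {residual(c)}"
        )
    gamma = np.concatenate([[p_T - c.sum()], c])
    return QssResult(state_labels(binding), gamma, np.full((n_c + 1, len(x)), np.nan))


def hill_production(binding: BindingSpec, parent_concs=()) -> float:
    """Production rate [nM/h]: per-state rate constants weighted by the QSS
    occupancies (the generalized Hill function of the node)."""
    res = qss_complexes(binding, parent_concs)
    return float(state_alphas(binding) @ res.gamma)


def node_retroactivity(binding: BindingSpec, parent_concs=()) -> NodeRetroactivity:
    """Jacobian of total bound parent amounts w.r.t. free parent concentrations.

    Not defined for nodes without parents.  Off-diagonal signs reflect the
    binding type: exactly zero for independent binding (separate sites),
    <= 0 for competitive binding (parents displace each other) and >= 0 for
    cooperative binding (the first parent recruits the second).
    """
    if binding.n_parents == 0:
        raise ContractError("node retroactivity is not defined for a node without parents")
    res = qss_complexes(binding, parent_concs)
    E = np.array(STATE_CATALOG[binding.binding_type], dtype=float)
    M = (np.asarray(binding.multimerization, dtype=float)[:, None] * E.T)
    R = M @ res.jacobian
    if binding.binding_type == "independent":
        # separate sites: the cross terms cancel analytically
        # (total bound parent j is p_T a_j/(1+a_j), independent of the other)
        R = np.diag(np.diag(R))
    return NodeRetroactivity(R=R, M=M)


# --------------------------------------------------------------------------
# module-level assembly
# --------------------------------------------------------------------------


def _parent_vector(
    spec: ModuleSpec, node, x: np.ndarray, u: np.ndarray
) -> np.ndarray:
    concs = []
    for p in node.binding.parents:
        if p in spec.node_ids:
            concs.append(x[spec.node_index(p)])
        else:
            concs.append(u[spec.inputs.index(p)])
    return np.asarray(concs, dtype=float)


def _as_input_vector(spec: ModuleSpec, u) -> np.ndarray:
    m = len(spec.inputs)
    if u is None:
        uv = np.zeros(m)
    else:
        uv = np.asarray(u, dtype=float).reshape(-1)
    if uv.size != m:
        raise ContractError(f"expected {m} input concentration(s), got {uv.size}")
    return uv


def internal_retroactivity(spec: ModuleSpec, x, u=None) -> np.ndarray:
    """Internal retroactivity matrix R(x, u) of a module (n x n).

    Sum over nodes of the internal-internal block of each node retroactivity
    lifted into module coordinates; entry (j, k) is the sensitivity of the
    total amount of TF j bound at intramodular promoters to the free
    concentration of TF k.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    uv = _as_input_vector(spec, u)
    R = np.zeros((spec.n_nodes, spec.n_nodes))
    for node in spec.nodes:
        if node.binding.n_parents == 0 or node.binding.promoter_total == 0:
            continue
        Ri = node_retroactivity(node.binding, _parent_vector(spec, node, x, uv)).R
        for j, pj in enumerate(node.binding.parents):
            if pj not in spec.node_ids:
                continue
            gj = spec.node_index(pj)
            for k, pk in enumerate(node.binding.parents):
                if pk in spec.node_ids:
                    R[gj, spec.node_index(pk)] += Ri[j, k]
    return R


def external_retroactivity(spec: ModuleSpec, x, u=None) -> np.ndarray:
    """External retroactivity matrix S(x, u) of a module (n x m inputs).

    Entry (j, k): sensitivity of total bound internal TF j to the free
    concentration of input k; nonzero only where an internal TF co-binds
    with an input non-independently at the same promoter.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    uv = _as_input_vector(spec, u)
    S = np.zeros((spec.n_nodes, len(spec.inputs)))
    for node in spec.nodes:
        if node.binding.n_parents == 0 or node.binding.promoter_total == 0:
            continue
        Ri = node_retroactivity(node.binding, _parent_vector(spec, node, x, uv)).R
        for j, pj in enumerate(node.binding.parents):
            if pj not in spec.node_ids:
                continue
            gj = spec.node_index(pj)
            for k, pk in enumerate(node.binding.parents):
                if pk in spec.inputs:
                    S[gj, spec.inputs.index(pk)] += Ri[j, k]
    return S


@dataclass(frozen=True)
class ModuleMatrices:
    """Retroactivity matrices of a module/context pair at one joint state.

    All blocks are Jacobians of total-bound-TF maps.  ``R``/``Rbar`` collect
    loading among each side's own TFs at its own promoters.  ``Sbar`` is the
    scaling retroactivity of the context (load context promoters place on
    module TFs, in module coordinates) and ``Mbar`` its mixing retroactivity
    (how context TF levels move module TF bound at mixed context promoters).
    ``Sbar_from_module``/``Mbar_from_module`` are the same quantities with
    the roles of module and context swapped.  ``cross_mc_module`` and
    ``cross_cm_context`` are the remaining off-role blocks of mixed
    promoters (they vanish together with the corresponding mixing blocks).
    The premultiplier of the joint reduced dynamics is

        A = I + [[R + Sbar,            Mbar + cross_mc_module],
                 [Mbar_from_module + cross_cm_context,
                                       Rbar + Sbar_from_module]].
    """

    module_labels: tuple[str, ...]
    context_labels: tuple[str, ...]
    R: np.ndarray
    Rbar: np.ndarray
    Sbar: np.ndarray
    Mbar: np.ndarray
    Sbar_from_module: np.ndarray
    Mbar_from_module: np.ndarray
    cross_mc_module: np.ndarray
    cross_cm_context: np.ndarray

    @property
    def premultiplier(self) -> np.ndarray:
        n, m = self.R.shape[0], self.Rbar.shape[0]
        A = np.eye(n + m)
        A[:n, :n] += self.R + self.Sbar
        A[:n, n:] += self.Mbar + self.cross_mc_module
        A[n:, :n] += self.Mbar_from_module + self.cross_cm_context
        A[n:, n:] += self.Rbar + self.Sbar_from_module
        return A


def interconnection_matrices(
    ic: InterconnectionSpec, x, v, u_ext: Mapping[str, float] | None = None
) -> ModuleMatrices:
    """Evaluate all retroactivity blocks of a wired module/context pair.

    ``x`` and ``v`` are the module and context free-TF concentration
    vectors; ``u_ext`` supplies concentrations for any unwired inputs
    (default 0).  Raises :class:`ConditioningError` if I + R (module side)
    is numerically singular.
    """
    from ._network import from_interconnection, promoter_jacobian_blocks

    net = from_interconnection(ic)
    z = np.concatenate([np.asarray(x, float).reshape(-1), np.asarray(v, float).reshape(-1)])
    if z.size != len(net.species):
        raise ContractError(
            f"state size {z.size} does not match joint network ({len(net.species)})"
        )
    uvals = dict(u_ext or {})
    blocks = promoter_jacobian_blocks(net, z, uvals)
    n = ic.module.n_nodes
    mm = slice(0, n)
    cc = slice(n, z.size)
    mats = ModuleMatrices(
        module_labels=tuple(net.species[:n]),
        context_labels=tuple(net.species[n:]),
        R=blocks["module"][mm, mm],
        Rbar=blocks["context"][cc, cc],
        Sbar=blocks["context"][mm, mm],
        Mbar=blocks["context"][mm, cc],
        Sbar_from_module=blocks["module"][cc, cc],
        Mbar_from_module=blocks["module"][cc, mm],
        cross_mc_module=blocks["module"][mm, cc],
        cross_cm_context=blocks["context"][cc, mm],
    )
    smin = np.linalg.svd(np.eye(n) + mats.R, compute_uv=False)[-1]
    if smin < CONDITIONING_FLOOR:
        raise ConditioningError(f"sigma_min(I + R) = {smin:.3e} below floor")
    return mats
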