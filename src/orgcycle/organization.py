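"""Chemical-organization predicates and enumeration.

A species set X is *closed* when no reaction applicable to X produces a
species outside X; *semi-self-maintaining* (SSM) when every species
consumed by an applicable reaction is also produced by one;
*self-maintaining* (SM) when a strictly positive flux vector v over the
applicable reactions R_X exists with non-negative net production
(N_X v >= 0 row-wise on X); and an *organization* when closed and SM.
Self-maintenance is decided by linear programming: strict positivity is
encoded as v >= 1, valid because N v >= 0 is invariant under scaling.

Organizations are the only possible supports of mass-action fixed points,
which is what ties this module to :mod:`orgcycle.dynamics`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from .network import (
    NetworkError,
    ReactionNetwork,
    applicable_reactions,
    largest_reactive_subset,
    stoichiometric_matrix,
)

__all__ = [
    "LPError",
    "SpeciesSetRecord",
    "HasseDiagram",
    "closure",
    "is_closed",
    "is_semi_self_maintaining",
    "is_self_maintaining",
    "is_organization",
    "analyze_set",
    "enumerate_closed_sets",
    "enumerate_organizations",
    "reactive_organizations",
    "hasse_diagram",
    "is_overproducible",
]

#: constraint-violation tolerance accepted after solving the SM feasibility LP
LP_TOL = 1e-9

#: default exhaustive-enumeration bound on |species|
ENUMERATION_BOUND = 22


class LPError(RuntimeError):
    """The LP solver failed for a reason other than infeasibility."""


@dataclass(frozen=True)
class SpeciesSetRecord:
    """A species subset with its computed flags and SM flux witness.

    ``flux_witness`` maps each applicable reaction id to a strictly
    positive rate; it is present exactly when the set is self-maintaining.
    """

    members: FrozenSet[str]
    closed: bool
    ssm: bool
    sm: bool
    reactive: bool
    flux_witness: Optional[Dict[str, float]] = None

    @property
    def organization(self) -> bool:
        return self.closed and self.sm

    def __len__(self) -> int:
        return len(self.members)


def closure(net: ReactionNetwork, X: Iterable[str]) -> FrozenSet[str]:
    """Smallest closed superset of X (least fixed point of product addition)."""
    Y = set(net.restricted_species(X))
    while True:
        added = False
        for r in net.reactions:
            if r.support <= Y and not (r.product <= Y):
                Y |= r.product
                added = True
        if not added:
            return frozenset(Y)


def is_closed(net: ReactionNetwork, X: Iterable[str]) -> bool:
    """True iff every reaction applicable to X produces only inside X."""
    X = net.restricted_species(X)
    return all(r.product <= X for r in net.reactions if r.support <= X)


def is_semi_self_maintaining(net: ReactionNetwork, X: Iterable[str]) -> bool:
    """True iff every species consumed within X is also produced within X."""
    X = net.restricted_species(X)
    rx = applicable_reactions(net, X)
    produced: Set[str] = set()
    for r in rx:
        produced |= r.product
    consumed: Set[str] = set()
    for r in rx:
        consumed |= r.support
    return consumed <= produced


def _witness_exact_ok(N: np.ndarray, v: np.ndarray) -> bool:
    """Rational re-check of an LP witness with exact arithmetic."""
    vf = [Fraction(float(x)).limit_denominator(10**9) for x in v]
    if any(x <= 0 for x in vf):
        return False
    rows, cols = N.shape
    for i in range(rows):
        acc = Fraction(0)
        for j in range(cols):
            acc += int(N[i, j]) * vf[j]
        if acc < 0:
            return False
    return True


def is_self_maintaining(
    net: ReactionNetwork, X: Iterable[str]
) -> Tuple[bool, Optional[Dict[str, float]]]:
    """Decide self-maintenance of X; return (flag, flux witness or None).

    Feasibility LP: variables v_r >= 1 for r in R_X (scale-invariant
    surrogate for v_r > 0), constraints N restricted to rows X and columns
    R_X applied as N_X v >= 0, zero objective.  An empty R_X is trivially
    self-maintaining with an empty witness.  Solver failures raise
    :class:`LPError`, distinct from a clean "infeasible".
    """
    X = net.restricted_species(X)
    rx = applicable_reactions(net, X)
    if not rx:
        return True, {}
    sm = stoichiometric_matrix(net)
    rows = sorted(X, key=net.species_index().get)
    cols = [r.id for r in rx]
    NX = sm.restrict(rows, cols)
    n = len(cols)
    res = linprog(
        c=np.zeros(n),
        A_ub=-NX,
        b_ub=np.zeros(len(rows)),
        bounds=[(1.0, None)] * n,
        method="highs",
    )
    if res.status == 2:  # infeasible
        return False, None
    if not res.success:
        raise LPError(f"LP solver failure (status {res.status}): {res.message}")
    v = np.asarray(res.x)
    viol = float(np.max(-(NX @ v), initial=0.0))
    if viol > LP_TOL and not _witness_exact_ok(NX, v):
        raise LPError(
            f"LP reported success but witness violates constraints by {viol:.2e}"
        )
    return True, dict(zip(cols, v.tolist()))


def is_organization(net: ReactionNetwork, X: Iterable[str]) -> bool:
    """Closed and self-maintaining."""
    X = net.restricted_species(X)
    return is_closed(net, X) and is_self_maintaining(net, X)[0]


def analyze_set(net: ReactionNetwork, X: Iterable[str]) -> SpeciesSetRecord:
    """Full record of flags (closed / SSM / SM / reactive) for one set."""
    X = net.restricted_species(X)
    sm, witness = is_self_maintaining(net, X)
    rec = SpeciesSetRecord(
        members=X,
        closed=is_closed(net, X),
        ssm=is_semi_self_maintaining(net, X),
        sm=sm,
        reactive=largest_reactive_subset(net, X) == X,
        flux_witness=witness,
    )
    if rec.sm and not rec.ssm:
        # theorem: self-maintenance implies semi-self-maintenance
        raise AssertionError(
            f"property violation: {sorted(X)} is SM but not SSM"
        )
    return rec


def enumerate_closed_sets(
    net: ReactionNetwork, max_species: int = ENUMERATION_BOUND
) -> List[FrozenSet[str]]:
    """All closed sets, by breadth-first closure expansion.

    Every closed set is reachable from closure(emptyset) by repeatedly
    adding one species and re-closing (closure is monotone, so the
    intermediate closures of subsets of a closed set C stay inside C).
    Complexity is O(#closed sets x |species| x closure cost); the
    ``max_species`` bound guards the exhaustive strategy.
    """
    if len(net.species) > max_species:
        raise NetworkError(
            f"{len(net.species)} species exceeds the exhaustive enumeration "
            f"bound {max_species}; verify candidate sets individually "
            "(offline workflow) instead"
        )
    start = closure(net, frozenset())
    seen: Set[FrozenSet[str]] = {start}
    queue: List[FrozenSet[str]] = [start]
    while queue:
        C = queue.pop()
        for s in net.species:
            if s in C:
                continue
            nxt = closure(net, C | {s})
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return sorted(seen, key=lambda S: (len(S), sorted(S)))


def enumerate_organizations(
    net: ReactionNetwork, max_species: int = ENUMERATION_BOUND
) -> List[SpeciesSetRecord]:
    """All organizations: closed sets filtered by the SM feasibility LP."""
    out = []
    for C in enumerate_closed_sets(net, max_species=max_species):
        rec = analyze_set(net, C)
        if rec.organization:
            out.append(rec)
    return out


def reactive_organizations(
    net: ReactionNetwork, max_species: int = ENUMERATION_BOUND
) -> List[SpeciesSetRecord]:
    """Organizations equal to their own largest reactive subset."""
    return [
        rec
        for rec in enumerate_organizations(net, max_species=max_species)
        if rec.reactive
    ]


@dataclass
class HasseDiagram:
    """Covering relation of the inclusion poset of a family of species sets."""

    nodes: List[FrozenSet[str]]
    edges: List[Tuple[FrozenSet[str], FrozenSet[str]]]  # (smaller, larger)

    def is_chain(self) -> bool:
        """True when the poset is totally ordered (a single chain)."""
        if len(self.nodes) <= 1:
            return True
        if len(self.edges) != len(self.nodes) - 1:
            return False
        ordered = sorted(self.nodes, key=len)
        return all(a < b for a, b in zip(ordered, ordered[1:]))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def to_dot(self) -> str:
        def label(S: FrozenSet[str]) -> str:
            return "{" + ",".join(sorted(S)) + "}" if S else "{}"

        lines = ["digraph hasse {", "  rankdir=BT;"]
        for node in self.nodes:
            lines.append(f'  "{label(node)}";')
        for small, big in self.edges:
            lines.append(f'  "{label(small)}" -> "{label(big)}";')
        lines.append("}")
        return "\n".join(lines)


def hasse_diagram(
    orgs: Sequence[SpeciesSetRecord | FrozenSet[str]],
) -> HasseDiagram:
    """Covering pairs (O1 strictly below O2 with nothing in between)."""
    sets = [o.members if isinstance(o, SpeciesSetRecord) else frozenset(o) for o in orgs]
    sets = sorted(set(sets), key=lambda S: (len(S), sorted(S)))
    edges = []
    for small, big in itertools.permutations(sets, 2):
        if not (small < big):
            continue
        if any(small < mid < big for mid in sets):
            continue
        edges.append((small, big))
    return HasseDiagram(nodes=sets, edges=edges)


def is_overproducible(net: ReactionNetwork, X: Iterable[str], s: str) -> bool:
    """Can species s be produced at strictly positive net rate within X?

    Same LP as self-maintenance with the extra constraint (N_X v)_s >= 1.
    Requires s in X; X is expected to be self-maintaining (otherwise the
    answer is False by infeasibility of the base constraints).
    """
    X = net.restricted_species(X)
    if s not in X:
        raise NetworkError(f"species {s!r} not in the candidate set")
    rx = applicable_reactions(net, X)
    if not rx:
        return False
    sm = stoichiometric_matrix(net)
    rows = sorted(X, key=net.species_index().get)
    cols = [r.id for r in rx]
    NX = sm.restrict(rows, cols)
    srow = rows.index(s)
    b_ub = np.zeros(len(rows))
    A_ub = -NX.astype(float).copy()
    b_ub[srow] = -1.0  # (N_X v)_s >= 1
    res = linprog(
        c=np.zeros(len(cols)),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(1.0, None)] * len(cols),
        method="highs",
    )
    if res.status == 2:
        return False
    if not res.success:
        raise LPError(f"LP solver failure (status {res.status}): {res.message}")
    return True
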