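"""Causal digraph, cycle enumeration, and the cycle/organization theorems.

Species s1 is *directly causally connected* to s2 when some reaction in
scope consumes s1 (s1 in its support) and produces s2 (s2 in its product);
a catalyst therefore induces a self-edge.  Cycles of a reaction network
are the cycles of this digraph; they are elementary (no repeated species),
counted up to rotation, and a self-loop counts as a length-1 "trivial"
cycle.  Edges are derived from the reactions applicable to the species set
under analysis, not the global reaction set, so cycle sets are relative to
the organization being analysed.

The central theorem implemented here: a reactive semi-self-maintaining set
T that strictly contains a closed set C must contain a cycle made of
species in T \\ C.  Its corollary: of two nested reactive organizations the
larger has strictly more cycles, and cycle-set containment implies set
containment — every organization is identified by its cycle set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .network import NetworkError, ReactionNetwork, applicable_reactions
from .organization import (
    SpeciesSetRecord,
    is_closed,
    is_semi_self_maintaining,
    reactive_organizations,
)
from .network import largest_reactive_subset

__all__ = [
    "Cycle",
    "CycleSet",
    "causal_graph",
    "contains_cycle",
    "enumerate_cycles",
    "new_cycles_between",
    "Lemma1Result",
    "PropertyViolation",
    "check_lemma1",
    "cycle_signature",
    "CorollaryReport",
    "check_corollary",
]


class PropertyViolation(AssertionError):
    """A proven structural property failed — an implementation bug."""


@dataclass(frozen=True, order=True)
class Cycle:
    """An elementary cycle, canonicalized by rotating the lexicographically
    smallest species to the front.  Length 1 means a self-edge."""

    species_sequence: Tuple[str, ...]

    @staticmethod
    def canonical(seq: Sequence[str]) -> "Cycle":
        seq = tuple(seq)
        if len(set(seq)) != len(seq):
            raise NetworkError(f"cycle {seq} repeats a species")
        k = seq.index(min(seq))
        return Cycle(species_sequence=seq[k:] + seq[:k])

    @property
    def length(self) -> int:
        return len(self.species_sequence)

    @property
    def trivial(self) -> bool:
        return self.length == 1

    def species(self) -> FrozenSet[str]:
        return frozenset(self.species_sequence)

    def __str__(self) -> str:
        return "(" + " -> ".join(self.species_sequence) + ")"


def causal_graph(net: ReactionNetwork, X: Iterable[str]) -> nx.DiGraph:
    """Directed graph over X: edge s1 -> s2 iff a reaction applicable to X
    has s1 in its support and s2 in its product.  Each edge carries the
    list of witnessing reaction ids in attribute ``reactions``."""
    X = net.restricted_species(X)
    g = nx.DiGraph()
    g.add_nodes_from(X)
    for r in applicable_reactions(net, X):
        for s1 in r.support:
            for s2 in r.product:
                if s2 not in X:
                    continue
                if g.has_edge(s1, s2):
                    g[s1][s2]["reactions"].append(r.id)
                else:
                    g.add_edge(s1, s2, reactions=[r.id])
    return g


def _graph_has_cycle(g: nx.DiGraph) -> bool:
    if any(g.has_edge(v, v) for v in g):
        return True
    return any(len(scc) > 1 for scc in nx.strongly_connected_components(g))


def contains_cycle(net: ReactionNetwork, X: Iterable[str]) -> bool:
    """True iff the causal graph over X has a self-edge or a nontrivial
    strongly connected component (linear time, Tarjan-style)."""
    return _graph_has_cycle(causal_graph(net, X))


@dataclass
class CycleSet:
    """Deterministically ordered elementary cycles, with a truncation flag.

    ``truncated`` is True when a length bound may have excluded longer
    cycles (the bound was below the largest nontrivial SCC size).
    """

    cycles: List[Cycle]
    truncated: bool = False

    def __iter__(self):
        return iter(self.cycles)

    def __len__(self):
        return len(self.cycles)

    def __getitem__(self, i):
        return self.cycles[i]

    def as_set(self) -> FrozenSet[Cycle]:
        return frozenset(self.cycles)


def enumerate_cycles(
    net: ReactionNetwork,
    X: Iterable[str],
    max_len: Optional[int] = None,
) -> CycleSet:
    """All elementary cycles of the causal graph over X (Johnson's
    algorithm), rotation-canonicalized, self-loops included, ordered by
    length then lexicographically."""
    g = causal_graph(net, X)
    found = {
        Cycle.canonical(c)
        for c in nx.simple_cycles(g, length_bound=max_len)
    }
    cycles = sorted(found, key=lambda c: (c.length, c.species_sequence))
    truncated = False
    if max_len is not None:
        biggest_scc = max(
            (len(s) for s in nx.strongly_connected_components(g)), default=0
        )
        truncated = max_len < biggest_scc
    return CycleSet(cycles=cycles, truncated=truncated)


def new_cycles_between(
    net: ReactionNetwork,
    O_small: Iterable[str],
    O_big: Iterable[str],
    max_len: Optional[int] = None,
) -> List[Cycle]:
    """Cycles of the causal graph over O_big lying entirely in O_big \\ O_small."""
    O_small = net.restricted_species(O_small)
    O_big = net.restricted_species(O_big)
    if not (O_small <= O_big):
        raise NetworkError("O_small must be contained in O_big")
    diff = O_big - O_small
    return [
        c
        for c in enumerate_cycles(net, O_big, max_len=max_len)
        if c.species() <= diff
    ]


def _extract_cycle(g: nx.DiGraph) -> Optional[Cycle]:
    """One elementary cycle of g (cheapest witness), or None."""
    for v in g:
        if g.has_edge(v, v):
            return Cycle.canonical((v,))
    for scc in nx.strongly_connected_components(g):
        if len(scc) > 1:
            sub = g.subgraph(scc)
            cyc = next(iter(nx.simple_cycles(sub)))
            return Cycle.canonical(cyc)
    return None


@dataclass
class Lemma1Result:
    """Outcome of the cycle-existence check for a (T, C) pair.

    Either the premises fail (with the failing ones named), or they hold
    and a witness cycle inside T \\ C is attached.  The combination
    "premises hold, no cycle" contradicts the theorem and raises
    :class:`PropertyViolation` instead of being returned.
    """

    premises_hold: bool
    failed_premises: List[str] = field(default_factory=list)
    witness: Optional[Cycle] = None


def check_lemma1(
    net: ReactionNetwork, T: Iterable[str], C: Iterable[str]
) -> Lemma1Result:
    """Verify: a reactive SSM set T strictly containing a closed set C
    contains a cycle among the species of T \\ C (edges from R_T)."""
    T = net.restricted_species(T)
    C = net.restricted_species(C)
    failed = []
    if largest_reactive_subset(net, T) != T:
        failed.append("T_not_reactive")
    if not is_semi_self_maintaining(net, T):
        failed.append("T_not_ssm")
    if not is_closed(net, C):
        failed.append("C_not_closed")
    if not (C < T):
        failed.append("no_strict_containment")
    if failed:
        return Lemma1Result(premises_hold=False, failed_premises=failed)
    g = causal_graph(net, T).subgraph(T - C)
    cyc = _extract_cycle(g)
    if cyc is None:
        raise PropertyViolation(
            f"premises hold for T={sorted(T)}, C={sorted(C)} but no cycle "
            "exists in T \\ C — implementation bug"
        )
    return Lemma1Result(premises_hold=True, witness=cyc)


def cycle_signature(
    net: ReactionNetwork, O: Iterable[str], max_len: Optional[int] = None
) -> FrozenSet[Cycle]:
    """The set of cycles identifying an organization."""
    return enumerate_cycles(net, O, max_len=max_len).as_set()


@dataclass
class CorollaryReport:
    """Pairwise check over the reactive organizations of one network.

    For every nested pair O1 < O2: the larger must gain at least one cycle
    supported on O2 \\ O1; for every pair, cycle-signature containment must
    imply set containment.  ``violations`` lists failures (each indicates
    an implementation bug, not a property of the network).
    """

    n_organizations: int
    pairs_checked: int
    violations: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def check_corollary(
    net: ReactionNetwork,
    orgs: Optional[Sequence[SpeciesSetRecord | FrozenSet[str]]] = None,
) -> CorollaryReport:
    if orgs is None:
        orgs = reactive_organizations(net)
    sets = [
        o.members if isinstance(o, SpeciesSetRecord) else frozenset(o)
        for o in orgs
    ]
    sigs = {S: cycle_signature(net, S) for S in sets}
    violations: List[str] = []
    pairs = 0
    for S1 in sets:
        for S2 in sets:
            if S1 == S2:
                continue
            pairs += 1
            if S1 < S2 and not new_cycles_between(net, S1, S2):
                violations.append(
                    f"nested pair {sorted(S1)} < {sorted(S2)} gained no cycle"
                )
            if sigs[S1] <= sigs[S2] and not (S1 <= S2):
                violations.append(
                    f"signature of {sorted(S1)} contained in {sorted(S2)}'s "
                    "but the sets are not nested"
                )
    return CorollaryReport(
        n_organizations=len(sets), pairs_checked=pairs, violations=violations
    )
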