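"""Reaction switch-off screens: which reactions are critical for an
organization, inside versus outside its cycles.

A reaction r applicable to an organization O is *critical* when O stops
being an organization in the network with r switched off.  Removing a
reaction can never break closure (fewer reactions produce fewer species),
so the decision reduces to one self-maintenance LP over R_O minus r —
closure is nonetheless re-verified at runtime as a cheap guard.

"Part of the cycle" is decided through strongly connected components of
the causal graph over O: a reaction belongs to the cycle structure when it
witnesses a self-edge or an edge inside a nontrivial SCC.  SCC membership
is the genome-scale-safe notion of cycle membership (elementary-cycle
enumeration does not scale; SCC computation is linear).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import networkx as nx

from .network import NetworkError, ReactionNetwork, applicable_reactions
from .organization import is_closed, is_self_maintaining
from .cycles import causal_graph

__all__ = [
    "KnockoutReport",
    "survives_knockout",
    "reaction_in_cycle",
    "cycle_reactions",
    "critical_reactions",
]


def survives_knockout(net: ReactionNetwork, O: Iterable[str], rid: str) -> bool:
    """True iff O is still an organization of the network without reaction rid.

    Requires O to be an organization and rid to be applicable to O
    (switching off an inapplicable reaction is a no-op and is reported as
    an error rather than silently returning True).
    """
    O = net.restricted_species(O)
    r = net.reaction(rid)  # KeyError on unknown id
    if not (r.support <= O):
        raise NetworkError(
            f"reaction {rid!r} is not applicable to the organization; "
            "switching it off is a no-op"
        )
    reduced = net.without_reactions([rid])
    if not is_closed(reduced, O):
        raise AssertionError(
            "closure was broken by removing a reaction — impossible"
        )
    return is_self_maintaining(reduced, O)[0]


def _cyclic_edges(net: ReactionNetwork, O: Iterable[str]) -> Set[Tuple[str, str]]:
    g = causal_graph(net, O)
    comp: Dict[str, int] = {}
    sizes: Dict[int, int] = {}
    for i, scc in enumerate(nx.strongly_connected_components(g)):
        sizes[i] = len(scc)
        for v in scc:
            comp[v] = i
    cyclic = set()
    for u, v in g.edges:
        if comp[u] == comp[v] and (u == v or sizes[comp[u]] > 1):
            cyclic.add((u, v))
    return cyclic


def reaction_in_cycle(net: ReactionNetwork, O: Iterable[str], rid: str) -> bool:
    """True iff rid witnesses a causal edge inside a common nontrivial SCC
    (or a self-edge) of the causal graph over O."""
    O = net.restricted_species(O)
    r = net.reaction(rid)
    if not (r.support <= O):
        return False
    cyclic = _cyclic_edges(net, O)
    return any(
        (s1, s2) in cyclic for s1 in r.support for s2 in (r.product & O)
    )


def cycle_reactions(net: ReactionNetwork, O: Iterable[str]) -> FrozenSet[str]:
    """Ids of all reactions applicable to O that are part of its cycle
    structure (SCC sense)."""
    O = net.restricted_species(O)
    cyclic = _cyclic_edges(net, O)
    out = set()
    for r in applicable_reactions(net, O):
        if any((s1, s2) in cyclic for s1 in r.support for s2 in (r.product & O)):
            out.add(r.id)
    return frozenset(out)


@dataclass
class KnockoutReport:
    """Per-reaction criticality verdicts for one organization, partitioned
    by cycle membership, with the tallies used to summarize a screen."""

    organization: FrozenSet[str]
    verdicts: Dict[str, bool]  # reaction id -> critical?
    in_cycle: FrozenSet[str]

    @property
    def in_cycle_total(self) -> int:
        return sum(1 for rid in self.verdicts if rid in self.in_cycle)

    @property
    def in_cycle_critical(self) -> int:
        return sum(
            1 for rid, crit in self.verdicts.items()
            if crit and rid in self.in_cycle
        )

    @property
    def out_cycle_total(self) -> int:
        return len(self.verdicts) - self.in_cycle_total

    @property
    def out_cycle_critical(self) -> int:
        return sum(
            1 for rid, crit in self.verdicts.items()
            if crit and rid not in self.in_cycle
        )

    def tallies(self) -> Dict[str, int]:
        return {
            "in_cycle_total": self.in_cycle_total,
            "in_cycle_critical": self.in_cycle_critical,
            "out_cycle_total": self.out_cycle_total,
            "out_cycle_critical": self.out_cycle_critical,
        }

    def as_frame(self):
        import pandas as pd

        rows = [
            {
                "reaction_id": rid,
                "in_cycle": rid in self.in_cycle,
                "critical": crit,
            }
            for rid, crit in sorted(self.verdicts.items())
        ]
        return pd.DataFrame(rows)


def critical_reactions(
    net: ReactionNetwork,
    O: Iterable[str],
    cycle_rids: Optional[Iterable[str]] = None,
) -> KnockoutReport:
    """Screen every reaction applicable to O for criticality.

    ``cycle_rids`` designates the cycle's constituting reactions; by
    default all SCC-cyclic reactions of O (see :func:`cycle_reactions`).
    """
    O = net.restricted_species(O)
    if cycle_rids is None:
        in_cycle = cycle_reactions(net, O)
    else:
        in_cycle = frozenset(cycle_rids)
    verdicts: Dict[str, bool] = {}
    for r in applicable_reactions(net, O):
        verdicts[r.id] = not survives_knockout(net, O, r.id)
    return KnockoutReport(organization=O, verdicts=verdicts, in_cycle=in_cycle)
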