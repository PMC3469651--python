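"""Reaction-network data model, multiset algebra, stoichiometry and file I/O.

A reaction network is an ordered list of species together with an ordered
list of reactions; each reaction is a pair of multisets (left/right hand
side) over the species, stored sparsely as ``{species_id: multiplicity}``
with strictly positive integer multiplicities.  A species occurring with the
same multiplicity on both sides (a catalyst) is legal and central to the
autocatalytic models shipped in :mod:`orgcycle.models`.

The plain-text dialect reads one reaction per line::

    r1: a + 2 b -> c      # irreversible
    r2: a <-> b           # reversible, expanded by split_reversible()
    r3: 0 -> a            # inflow (empty left hand side written "0")

Comments start with ``#``; blank lines are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "NetworkError",
    "ParseError",
    "Reaction",
    "ReactionNetwork",
    "StoichMatrix",
    "parse_network",
    "write_network",
    "read_sbml",
    "support",
    "product",
    "applicable_reactions",
    "stoichiometric_matrix",
    "largest_reactive_subset",
    "split_reversible",
]

_ID_RE = re.compile(r"^[^\s+]+$")
_TERM_RE = re.compile(r"^(\d+)?\s*(\S+)$")


class NetworkError(ValueError):
    """Invalid network structure (duplicate ids, unknown species, ...)."""


class ParseError(NetworkError):
    """Malformed reaction-list text; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _check_species_id(sid: str) -> str:
    if not sid or not _ID_RE.match(sid) or "->" in sid or sid == "0":
        raise NetworkError(f"invalid species id {sid!r}")
    return sid


@dataclass(frozen=True)
class Reaction:
    """One reaction: sparse lhs/rhs multisets over species ids.

    ``reversible`` marks a parsed ``<->`` reaction awaiting expansion;
    ``reversible_origin`` links the two directions of an already split pair.
    """

    id: str
    lhs: Dict[str, int] = field(default_factory=dict)
    rhs: Dict[str, int] = field(default_factory=dict)
    reversible: bool = False
    reversible_origin: Optional[str] = None

    def __post_init__(self):
        if not self.lhs and not self.rhs:
            raise NetworkError(f"reaction {self.id!r}: both sides empty")
        for side in (self.lhs, self.rhs):
            for sid, mult in side.items():
                _check_species_id(sid)
                if not isinstance(mult, (int, np.integer)) or mult <= 0:
                    raise NetworkError(
                        f"reaction {self.id!r}: multiplicity of {sid!r} "
                        f"must be a positive integer, got {mult!r}"
                    )

    @property
    def support(self) -> FrozenSet[str]:
        """Species present on the left hand side (a set, not a multiset)."""
        return frozenset(self.lhs)

    @property
    def product(self) -> FrozenSet[str]:
        """Species present on the right hand side (a set, not a multiset)."""
        return frozenset(self.rhs)

    def species(self) -> FrozenSet[str]:
        return self.support | self.product

    def reversed(self, rid: Optional[str] = None) -> "Reaction":
        return Reaction(
            id=rid or f"{self.id}_rev",
            lhs=dict(self.rhs),
            rhs=dict(self.lhs),
            reversible_origin=self.reversible_origin or self.id,
        )

    def __str__(self) -> str:
        def side(ms: Dict[str, int]) -> str:
            if not ms:
                return "0"
            return " + ".join(
                (f"{m} {s}" if m != 1 else s) for s, m in ms.items()
            )

        arrow = "<->" if self.reversible else "->"
        return f"{self.id}: {side(self.lhs)} {arrow} {side(self.rhs)}"


@dataclass(frozen=True)
class ReactionNetwork:
    """Ordered species list plus ordered reaction list.

    Species order is fixed at first mention; every matrix and vector in the
    package is indexed by this order so runs are reproducible.
    """

    species: Tuple[str, ...]
    reactions: Tuple[Reaction, ...]

    def __post_init__(self):
        seen: Set[str] = set()
        for s in self.species:
            _check_species_id(s)
            if s in seen:
                raise NetworkError(f"duplicate species id {s!r}")
            seen.add(s)
        rids: Set[str] = set()
        for r in self.reactions:
            if r.id in rids:
                raise NetworkError(f"duplicate reaction id {r.id!r}")
            rids.add(r.id)
            missing = r.species() - seen
            if missing:
                raise NetworkError(
                    f"reaction {r.id!r} mentions unknown species {sorted(missing)}"
                )

    @property
    def species_set(self) -> FrozenSet[str]:
        return frozenset(self.species)

    def species_index(self) -> Dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def without_reactions(self, rids: Iterable[str]) -> "ReactionNetwork":
        """Copy of the network with the given reactions switched off."""
        drop = set(rids)
        unknown = drop - {r.id for r in self.reactions}
        if unknown:
            raise NetworkError(f"unknown reaction ids {sorted(unknown)}")
        return ReactionNetwork(
            species=self.species,
            reactions=tuple(r for r in self.reactions if r.id not in drop),
        )

    def restricted_species(self, X: Iterable[str]) -> FrozenSet[str]:
        X = frozenset(X)
        unknown = X - self.species_set
        if unknown:
            raise NetworkError(f"unknown species {sorted(unknown)}")
        return X

    def __len__(self) -> int:
        return len(self.species)

    def __str__(self) -> str:
        return write_network(self)


@dataclass(frozen=True)
class StoichMatrix:
    """Integer stoichiometric matrix N with its row/column labels.

    ``N[i, j]`` is the rhs multiplicity minus the lhs multiplicity of
    species ``species[i]`` in reaction ``reaction_ids[j]``; a catalyst
    contributes zero.
    """

    matrix: np.ndarray
    species: Tuple[str, ...]
    reaction_ids: Tuple[str, ...]

    def __post_init__(self):
        assert self.matrix.shape == (len(self.species), len(self.reaction_ids))
        assert np.issubdtype(self.matrix.dtype, np.integer)

    def restrict(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        si = {s: i for i, s in enumerate(self.species)}
        ri = {r: j for j, r in enumerate(self.reaction_ids)}
        return self.matrix[np.ix_([si[s] for s in rows], [ri[r] for r in cols])]


# ---------------------------------------------------------------------------
# parsing / writing


def _parse_side(text: str, lineno: Optional[int]) -> Dict[str, int]:
    text = text.strip()
    if text == "0" or text == "":
        return {}
    out: Dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise ParseError(f"malformed term {term!r}", lineno)
        mult = int(m.group(1)) if m.group(1) else 1
        sid = m.group(2)
        if mult <= 0:
            raise ParseError(f"multiplicity must be positive in {term!r}", lineno)
        try:
            _check_species_id(sid)
        except NetworkError as exc:
            raise ParseError(str(exc), lineno) from exc
        out[sid] = out.get(sid, 0) + mult
    return out


def parse_network(text: str) -> ReactionNetwork:
    """Parse the plain-text reaction-list dialect into a validated network.

    Species are discovered in order of first mention (lhs before rhs,
    line by line).  Raises :class:`ParseError` with a line number on
    malformed input and :class:`NetworkError` on duplicate reaction ids.
    """
    species: List[str] = []
    seen: Set[str] = set()
    reactions: List[Reaction] = []
    rids: Set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ParseError("expected 'id: lhs -> rhs'", lineno)
        rid, body = line.split(":", 1)
        rid = rid.strip()
        if not rid or any(ch.isspace() for ch in rid):
            raise ParseError(f"invalid reaction id {rid!r}", lineno)
        if rid in rids:
            raise NetworkError(f"line {lineno}: duplicate reaction id {rid!r}")
        reversible = "<->" in body
        parts = body.split("<->" if reversible else "->")
        if len(parts) != 2:
            raise ParseError("expected exactly one '->' or '<->'", lineno)
        lhs = _parse_side(parts[0], lineno)
        rhs = _parse_side(parts[1], lineno)
        try:
            rxn = Reaction(id=rid, lhs=lhs, rhs=rhs, reversible=reversible)
        except NetworkError as exc:
            raise ParseError(str(exc), lineno) from exc
        reactions.append(rxn)
        rids.add(rid)
        for side in (lhs, rhs):
            for sid in side:
                if sid not in seen:
                    seen.add(sid)
                    species.append(sid)
    return ReactionNetwork(species=tuple(species), reactions=tuple(reactions))


def write_network(net: ReactionNetwork) -> str:
    """Serialize back to the plain-text dialect (inverse of parse_network)."""
    return "\n".join(str(r) for r in net.reactions) + "\n"


# ---------------------------------------------------------------------------
# SBML


def read_sbml(path: str, strict: bool = False) -> ReactionNetwork:
    """Read an SBML Level 2/3 core file as a bare reaction network.

    Only species, reactions and stoichiometries are used; kinetic laws,
    compartments and units are ignored, and boundary/constant species are
    mapped to ordinary species.  Reaction modifiers are treated as written
    catalysts (added to both sides with multiplicity 1).  Non-integer
    stoichiometries are scaled to integers by the least common multiple of
    their denominators (with a warning), or rejected when ``strict``.
    """
    import warnings
    from fractions import Fraction

    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ParseError(f"SBML error: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise ParseError("SBML document contains no model")

    species = tuple(
        model.getSpecies(i).getId() for i in range(model.getNumSpecies())
    )
    reactions: List[Reaction] = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)

        def side(refs) -> Dict[str, Fraction]:
            out: Dict[str, Fraction] = {}
            for ref in refs:
                st = ref.getStoichiometry()
                if st is None or (isinstance(st, float) and np.isnan(st)):
                    st = 1.0
                frac = Fraction(st).limit_denominator(10**6)
                if frac <= 0:
                    continue
                out[ref.getSpecies()] = out.get(ref.getSpecies(), Fraction(0)) + frac
            return out

        lhs = side(rx.getListOfReactants())
        rhs = side(rx.getListOfProducts())
        for j in range(rx.getNumModifiers()):
            mid = rx.getModifier(j).getSpecies()
            lhs[mid] = lhs.get(mid, Fraction(0)) + 1
            rhs[mid] = rhs.get(mid, Fraction(0)) + 1

        denoms = [v.denominator for v in (*lhs.values(), *rhs.values())]
        if any(d != 1 for d in denoms):
            if strict:
                raise NetworkError(
                    f"reaction {rx.getId()!r}: non-integer stoichiometry"
                )
            scale = int(np.lcm.reduce(denoms))
            warnings.warn(
                f"reaction {rx.getId()!r}: non-integer stoichiometry "
                f"scaled by {scale}",
                stacklevel=2,
            )
            lhs = {s: v * scale for s, v in lhs.items()}
            rhs = {s: v * scale for s, v in rhs.items()}
        reactions.append(
            Reaction(
                id=rx.getId(),
                lhs={s: int(v) for s, v in lhs.items()},
                rhs={s: int(v) for s, v in rhs.items()},
                reversible=rx.getReversible(),
            )
        )
    return ReactionNetwork(species=species, reactions=tuple(reactions))


# ---------------------------------------------------------------------------
# multiset algebra and derived objects


def support(r: Reaction) -> FrozenSet[str]:
    """Set of species on the left hand side (multiplicities ignored)."""
    return r.support


def product(r: Reaction) -> FrozenSet[str]:
    """Set of species on the right hand side (multiplicities ignored)."""
    return r.product


def applicable_reactions(net: ReactionNetwork, X: Iterable[str]) -> List[Reaction]:
    """Reactions applicable to X, i.e. those whose support lies inside X.

    Empty-support (inflow) reactions are applicable to every set, including
    the empty one.  Returned in network order.
    """
    X = net.restricted_species(X)
    return [r for r in net.reactions if r.support <= X]


def stoichiometric_matrix(net: ReactionNetwork) -> StoichMatrix:
    """N[s, r] = rhs multiplicity - lhs multiplicity; catalysts net to 0."""
    si = net.species_index()
    N = np.zeros((len(net.species), len(net.reactions)), dtype=np.int64)
    for j, r in enumerate(net.reactions):
        for s, m in r.lhs.items():
            N[si[s], j] -= m
        for s, m in r.rhs.items():
            N[si[s], j] += m
    return StoichMatrix(
        matrix=N,
        species=net.species,
        reaction_ids=tuple(r.id for r in net.reactions),
    )


def largest_reactive_subset(net: ReactionNetwork, X: Iterable[str]) -> FrozenSet[str]:
    """Greatest fixed point of "delete species that touch no applicable reaction".

    A set Y is reactive when every member occurs in support(r) or product(r)
    of some reaction applicable to Y itself.  Species that do not react
    within the set keep constant concentration and carry no dynamics, so
    analyses restrict to this largest reactive subset.
    """
    Y = set(net.restricted_species(X))
    while True:
        touched: Set[str] = set()
        for r in applicable_reactions(net, Y):
            touched |= r.support | r.product
        keep = Y & touched
        if keep == Y:
            return frozenset(Y)
        Y = keep


def split_reversible(net: ReactionNetwork) -> ReactionNetwork:
    """Replace every reversible reaction by an irreversible forward/reverse pair.

    The pair is tagged through ``reversible_origin`` so the two directions
    stay linked; networks without reversible reactions are returned as-is.
    """
    if not any(r.reversible for r in net.reactions):
        return net
    out: List[Reaction] = []
    for r in net.reactions:
        if not r.reversible:
            out.append(r)
            continue
        fwd = Reaction(
            id=f"{r.id}_fwd", lhs=dict(r.lhs), rhs=dict(r.rhs),
            reversible_origin=r.id,
        )
        out.append(fwd)
        out.append(
            Reaction(
                id=f"{r.id}_rev", lhs=dict(r.rhs), rhs=dict(r.lhs),
                reversible_origin=r.id,
            )
        )
    return ReactionNetwork(species=net.species, reactions=tuple(out))
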