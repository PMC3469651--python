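"""Built-in reaction-network fixtures and a seeded random-network generator.

The central fixture family is a generalized autocatalytic network: an
environment (external supply ``s``, internal food ``f``, degradation
product ``g``, waste ``w``) feeding a chain of catalysts ``c_1 .. c_n`` in
which each ``c_i`` catalyses the conversion of food into the next catalyst.
Closing the chain (``c_n`` catalyses production of ``c_1``) creates the
positive feedback cycle whose presence or absence decides whether the full
species set is a chemical organization and whether the mass-action dynamics
admit a strictly positive stable fixed point.

Six standard variants are exposed (``autocatalytic_case``):

====  ======  ===========================================
case  cycle   reversibility
====  ======  ===========================================
1     closed  none
2     open    none
3     closed  all chemical steps reversible
4     open    all chemical steps reversible
5     closed  all reversible except one designated step
6     open    all reversible except one designated step
====  ======  ===========================================

Reverse reactions are attached to the chemical transformations (supply,
food return, catalytic steps) and never to degradation/outflow steps:
reversing a degradation would re-create the catalysts from waste and void
the very distinction between open and closed variants, and reversing the
final outflow would add an inflow and a non-empty smallest organization.

The spindle assembly checkpoint (SAC) and spindle position checkpoint
(SPOC) models are instances of the same template with the catalysts renamed
to their biological identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .network import NetworkError, Reaction, ReactionNetwork, parse_network

__all__ = [
    "AutocatalyticSpec",
    "build_autocatalytic",
    "autocatalytic_case",
    "example_fig1",
    "build_sac",
    "build_spoc",
    "random_network",
    "FIXTURES",
    "get_fixture",
]

#: species ids used by the autocatalytic template environment
SUPPLY, FOOD, DEBRIS, WASTE = "s", "f", "g", "w"


@dataclass(frozen=True)
class AutocatalyticSpec:
    """Parameters of the generalized autocatalytic network family.

    n
        number of catalysts in the chain (>= 2).
    closed_cycle
        whether the feedback step (c_n catalyses production of c_1) exists.
    reversible
        ``"none"`` | ``"all"`` | ``"all_but_one"`` — which chemical steps
        receive reverse reactions.
    irreversible_step
        reaction id exempted in ``"all_but_one"`` mode; defaults to the
        cycle-closing catalytic step (or the last catalytic step when the
        cycle is open).
    lam
        rate constant of every reverse reaction (default 0.1).
    inflow, degradation
        rate constants of the supply step and of every decay step
        (defaults 2 and 1; the supply rate must exceed the food drain for a
        positive fixed point to exist at all).
    """

    n: int = 2
    closed_cycle: bool = True
    reversible: str = "none"
    irreversible_step: Optional[str] = None
    lam: float = 0.1
    inflow: float = 2.0
    degradation: float = 1.0

    def __post_init__(self):
        if self.n < 2:
            raise NetworkError(f"catalyst chain needs n >= 2, got {self.n}")
        if self.reversible not in ("none", "all", "all_but_one"):
            raise NetworkError(f"unknown reversible mode {self.reversible!r}")

    @property
    def catalysts(self) -> Tuple[str, ...]:
        return tuple(f"c{i}" for i in range(1, self.n + 1))

    def default_rates(self) -> Dict[str, float]:
        """Mass-action rate constants matching the construction."""
        rates: Dict[str, float] = {"supply": self.inflow, "freturn": 1.0}
        rates["sdecay"] = self.degradation
        ncat = self.n if self.closed_cycle else self.n - 1
        for i in range(1, ncat + 1):
            rates[f"cat{i}"] = 1.0
        for i in range(1, self.n + 1):
            rates[f"deg{i}"] = self.degradation
        rates["gout"] = 1.0
        rates["wout"] = self.degradation
        if self.reversible != "none":
            for rid in _reversible_ids(self):
                rates[f"{rid}_rev"] = self.lam
        return rates


def _reversible_ids(spec: AutocatalyticSpec) -> List[str]:
    ncat = spec.n if spec.closed_cycle else spec.n - 1
    ids = ["supply", "freturn"] + [f"cat{i}" for i in range(1, ncat + 1)]
    if spec.reversible == "all_but_one":
        exempt = spec.irreversible_step or f"cat{ncat}"
        if exempt not in ids:
            raise NetworkError(
                f"irreversible_step {exempt!r} is not a reversible-eligible "
                f"reaction (choose from {ids})"
            )
        ids.remove(exempt)
    return ids


def build_autocatalytic(
    spec: AutocatalyticSpec,
    catalyst_names: Optional[Tuple[str, ...]] = None,
) -> ReactionNetwork:
    """Build the generalized autocatalytic network for ``spec``.

    ``catalyst_names`` renames the catalysts c_1..c_n in order (used by the
    SAC/SPOC instantiations).
    """
    cats = catalyst_names or spec.catalysts
    if len(cats) != spec.n:
        raise NetworkError(
            f"need {spec.n} catalyst names, got {len(cats)}"
        )
    reactions: List[Reaction] = [
        # the supply species catalyses the import of food: the trivial cycle
        Reaction("supply", {SUPPLY: 1}, {SUPPLY: 1, FOOD: 1}),
        Reaction("freturn", {FOOD: 1}, {SUPPLY: 1}),
        # quadratic self-limitation (crowding) of the supply: without it the
        # linear supply/return loop has gain > 1 and no finite attractor
        # once the catalysts are gone
        Reaction("sdecay", {SUPPLY: 2}, {SUPPLY: 1}),
    ]
    ncat = spec.n if spec.closed_cycle else spec.n - 1
    for i in range(1, ncat + 1):
        nxt = cats[i % spec.n]
        reactions.append(
            Reaction(f"cat{i}", {FOOD: 1, cats[i - 1]: 1}, {cats[i - 1]: 1, nxt: 1})
        )
    for i in range(1, spec.n + 1):
        reactions.append(Reaction(f"deg{i}", {cats[i - 1]: 1}, {DEBRIS: 1}))
    reactions.append(Reaction("gout", {DEBRIS: 1}, {WASTE: 1}))
    reactions.append(Reaction("wout", {WASTE: 1}, {}))

    if spec.reversible != "none":
        by_id = {r.id: r for r in reactions}
        for rid in _reversible_ids(spec):
            reactions.append(by_id[rid].reversed())

    species = (SUPPLY, FOOD) + tuple(cats) + (DEBRIS, WASTE)
    return ReactionNetwork(species=species, reactions=tuple(reactions))


_CASES = {
    1: (True, "none"),
    2: (False, "none"),
    3: (True, "all"),
    4: (False, "all"),
    5: (True, "all_but_one"),
    6: (False, "all_but_one"),
}


def autocatalytic_case(case: int, n: int = 2, **kwargs) -> Tuple[ReactionNetwork, AutocatalyticSpec]:
    """The six standard variants; returns (network, spec)."""
    if case not in _CASES:
        raise NetworkError(f"case must be 1..6, got {case}")
    closed, rev = _CASES[case]
    spec = AutocatalyticSpec(n=n, closed_cycle=closed, reversible=rev, **kwargs)
    return build_autocatalytic(spec), spec


# ---------------------------------------------------------------------------
# small worked example

#: Worked example network: one catalytic self-loop (a), a 2-cycle (a, b),
#: one catalytic trivial cycle (c) and a 3-cycle (c, d, e) — four elementary
#: cycles in total.  r1's right hand side is the multiset {a, 2 b} whose
#: product *set* is {a, b}; the singleton {c} is closed because r3 also
#: needs b to be applicable.  This is a synthetic reconstruction: it is
#: built to exhibit exactly these documented features, not transcribed from
#: any published diagram.
_FIG1_TEXT = """
r1: a -> a + 2 b
r2: b -> a
r3: b + c -> c + d
r4: d -> e
r5: e -> c
"""


def example_fig1() -> ReactionNetwork:
    """Small worked example with exactly four elementary cycles."""
    return parse_network(_FIG1_TEXT)


# ---------------------------------------------------------------------------
# checkpoint models

#: catalyst renamings for the two mitotic checkpoint instantiations
SAC_SPECIES = ("OMad2", "Cdc20", "OMad2_star", "Cdc20_Mad2")
SPOC_SPECIES = ("Kin4", "Bfa1", "Kin4_star", "Bfa1_star", "SM")


def build_sac(closed_cycle: bool = True) -> ReactionNetwork:
    """Spindle assembly checkpoint model: the n=4 template with the
    catalysts renamed to O-Mad2, Cdc20, O-Mad2* and Cdc20:Mad2.

    ``closed_cycle=False`` removes the positive feedback (activation of
    O-Mad2 by Cdc20:Mad2), the variant in which the species decay.
    """
    spec = AutocatalyticSpec(n=4, closed_cycle=closed_cycle)
    return build_autocatalytic(spec, catalyst_names=SAC_SPECIES)


def build_spoc(closed_cycle: bool = True) -> ReactionNetwork:
    """Spindle position checkpoint model: the n=5 template with catalysts
    Kin4, Bfa1, Kin4*, Bfa1* and the SM signal closing the cycle."""
    spec = AutocatalyticSpec(n=5, closed_cycle=closed_cycle)
    return build_autocatalytic(spec, catalyst_names=SPOC_SPECIES)


# ---------------------------------------------------------------------------
# random networks for property tests


def random_network(
    n_species: int = 5,
    n_reactions: int = 6,
    max_arity: int = 2,
    p_inflow: float = 0.15,
    p_catalyst: float = 0.3,
    seed: int = 0,
) -> ReactionNetwork:
    """Seeded random reaction network for property-based testing.

    Each reaction draws up to ``max_arity`` reactant and product species
    (multiplicity 1 or 2), becomes an inflow (empty lhs) with probability
    ``p_inflow``, and with probability ``p_catalyst`` additionally carries a
    catalyst present on both sides.  The same seed always yields the same
    network.
    """
    if n_species <= 0 or n_reactions < 0:
        raise NetworkError("sizes must be positive")
    rng = np.random.default_rng(seed)
    species = tuple(f"s{i}" for i in range(n_species))
    reactions: List[Reaction] = []
    for j in range(n_reactions):
        lhs: Dict[str, int] = {}
        rhs: Dict[str, int] = {}
        if rng.random() >= p_inflow:
            for s in rng.choice(n_species, size=rng.integers(1, max_arity + 1), replace=False):
                lhs[species[s]] = int(rng.integers(1, 3))
        # empty rhs (outflow) kept rare but possible
        n_prod = int(rng.integers(0 if lhs else 1, max_arity + 1))
        for s in rng.choice(n_species, size=n_prod, replace=False):
            rhs[species[s]] = int(rng.integers(1, 3))
        if rng.random() < p_catalyst:
            cat = species[int(rng.integers(n_species))]
            lhs[cat] = lhs.get(cat, 0) + 1
            rhs[cat] = rhs.get(cat, 0) + 1
        if not lhs and not rhs:
            rhs[species[int(rng.integers(n_species))]] = 1
        reactions.append(Reaction(f"r{j}", lhs, rhs))
    return ReactionNetwork(species=species, reactions=tuple(reactions))


# ---------------------------------------------------------------------------
# fixture registry (used by the CLI)

FIXTURES = {
    "fig1": example_fig1,
    "case1": lambda: autocatalytic_case(1)[0],
    "case2": lambda: autocatalytic_case(2)[0],
    "case3": lambda: autocatalytic_case(3)[0],
    "case4": lambda: autocatalytic_case(4)[0],
    "case5": lambda: autocatalytic_case(5)[0],
    "case6": lambda: autocatalytic_case(6)[0],
    "sac": build_sac,
    "sac_open": lambda: build_sac(closed_cycle=False),
    "spoc": build_spoc,
    "spoc_open": lambda: build_spoc(closed_cycle=False),
}


def get_fixture(name: str) -> ReactionNetwork:
    try:
        return FIXTURES[name]()
    except KeyError:
        raise NetworkError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None


def fixture_rates(name: str) -> Dict[str, float]:
    """Mass-action rate constants matching a named fixture.

    Template-family fixtures get their spec's defaults (supply rate 2,
    decay 1, reverse rates 0.1); other fixtures use all-ones.
    """
    specs: Dict[str, AutocatalyticSpec] = {
        "case1": AutocatalyticSpec(n=2, closed_cycle=True),
        "case2": AutocatalyticSpec(n=2, closed_cycle=False),
        "case3": AutocatalyticSpec(n=2, closed_cycle=True, reversible="all"),
        "case4": AutocatalyticSpec(n=2, closed_cycle=False, reversible="all"),
        "case5": AutocatalyticSpec(n=2, closed_cycle=True, reversible="all_but_one"),
        "case6": AutocatalyticSpec(n=2, closed_cycle=False, reversible="all_but_one"),
        "sac": AutocatalyticSpec(n=4, closed_cycle=True),
        "sac_open": AutocatalyticSpec(n=4, closed_cycle=False),
        "spoc": AutocatalyticSpec(n=5, closed_cycle=True),
        "spoc_open": AutocatalyticSpec(n=5, closed_cycle=False),
    }
    if name in specs:
        return specs[name].default_rates()
    if name in FIXTURES:
        return {}
    raise NetworkError(f"unknown fixture {name!r}")
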