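"""Shared fixtures, hypothesis configuration and independent oracles."""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import List, Sequence, Tuple

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import orgcycle as oc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# small toy networks used across modules

TOY_CHAIN = "r1: a -> b\nr2: b -> c\n"
TOY_DECAY = "r1: a -> b\nr2: 2 b -> a\n"
TOY_INFLOW = "r1: 0 -> a\nr2: a -> 0\n"


@pytest.fixture
def toy_chain():
    return oc.parse_network(TOY_CHAIN)


@pytest.fixture
def toy_decay():
    return oc.parse_network(TOY_DECAY)


@pytest.fixture
def toy_inflow():
    return oc.parse_network(TOY_INFLOW)


@pytest.fixture
def fig1():
    return oc.example_fig1()


@pytest.fixture
def case1():
    net, spec = oc.autocatalytic_case(1, n=2)
    return net


# ---------------------------------------------------------------------------
# independent oracles

def fourier_motzkin_feasible(
    constraints: List[Tuple[Sequence[Fraction], Fraction]], n_vars: int
) -> bool:
    """Exact rational feasibility of {v : sum_j a_j v_j + b >= 0 for each row}.

    Plain Fourier-Motzkin elimination over Fractions; exponential but exact,
    used only on tiny systems as an oracle.
    """
    rows = [([Fraction(a) for a in coeffs], Fraction(b)) for coeffs, b in constraints]
    for k in range(n_vars):
        pos, neg, rest = [], [], []
        for coeffs, b in rows:
            a = coeffs[k]
            if a > 0:
                pos.append((coeffs, b))
            elif a < 0:
                neg.append((coeffs, b))
            else:
                rest.append((coeffs, b))
        new_rows = rest
        for (cp, bp) in pos:
            for (cn, bn) in neg:
                # eliminate v_k between cp.v + bp >= 0 and cn.v + bn >= 0
                scale_p, scale_n = -cn[k], cp[k]
                coeffs = [
                    scale_p * cp[j] + scale_n * cn[j] for j in range(n_vars)
                ]
                assert coeffs[k] == 0
                new_rows.append((coeffs, scale_p * bp + scale_n * bn))
        rows = new_rows
    return all(b >= 0 for _, b in rows)


def sm_oracle(net: oc.ReactionNetwork, X) -> bool:
    """Brute-force self-maintenance decision, independent of scipy.linprog.

    Feasibility of {v >= 1, N_X v >= 0} by exact Fourier-Motzkin
    elimination over the rationals.
    """
    X = net.restricted_species(X)
    rx = oc.applicable_reactions(net, X)
    if not rx:
        return True
    sm = oc.stoichiometric_matrix(net)
    rows = sorted(X)
    cols = [r.id for r in rx]
    NX = sm.restrict(rows, cols)
    n = len(cols)
    constraints: List[Tuple[List[Fraction], Fraction]] = []
    for i in range(NX.shape[0]):
        constraints.append(([Fraction(int(a)) for a in NX[i]], Fraction(0)))
    for j in range(n):
        unit = [Fraction(0)] * n
        unit[j] = Fraction(1)
        constraints.append((unit, Fraction(-1)))  # v_j - 1 >= 0
    return fourier_motzkin_feasible(constraints, n)


def dfs_has_cycle(edges, nodes) -> bool:
    """Exhaustive DFS cycle detection, independent of networkx SCC."""
    adj = {v: [] for v in nodes}
    for u, v in edges:
        adj[u].append(v)
    WHITE, GREY, BLACK = 0, 1, 2
    color = {v: WHITE for v in nodes}

    def visit(v) -> bool:
        color[v] = GREY
        for w in adj[v]:
            if color[w] == GREY:
                return True
            if color[w] == WHITE and visit(w):
                return True
        color[v] = BLACK
        return False

    return any(color[v] == WHITE and visit(v) for v in nodes)


def all_subsets(items):
    items = sorted(items)
    for r in range(len(items) + 1):
        yield from (frozenset(c) for c in itertools.combinations(items, r))
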