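"""Cycle enumeration and Wegscheider circuit conditions.

For a reversible mass-action network, detailed balance at a positive state
constrains the rate constants: around every cycle of the reaction graph the
product of forward constants must equal the product of backward constants
(the classical circuit conditions).  A cycle basis gives gamma = r - m + ell
independent such conditions; together with delta = m - ell - s
spanning-forest conditions on the equilibrium constants this yields the
classical count of r - s independent constraints on the constants.  Only the
circuit conditions are generated here; the spanning-forest conditions are
counted (delta), not constructed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import prod
from typing import Mapping

import networkx as nx

from .mixed_graph import CycleCapExceeded, CycleWitness
from .network import ReactionNetwork, summary

__all__ = [
    "CircuitCondition",
    "enumerate_cycles",
    "circuit_conditions",
    "condition_counts",
]

Edge = tuple[int, int]


def _canonical_cycle(cyc: list[int]) -> CycleWitness:
    """One representative per undirected elementary cycle.

    Rotate to the smallest vertex, then orient so the second vertex is
    smaller than the last; a cycle and its reversal collapse to the same
    witness (their circuit conditions coincide with sides swapped).
    """
    k = cyc.index(min(cyc))
    cyc = cyc[k:] + cyc[:k]
    if len(cyc) > 2 and cyc[-1] < cyc[1]:
        cyc = [cyc[0]] + cyc[:0:-1]
    return CycleWitness(tuple(cyc + [cyc[0]]))


def enumerate_cycles(net: ReactionNetwork, cap: int = 100_000) -> list[CycleWitness]:
    """All elementary cycles of length >= 3 of the underlying undirected graph.

    Each cycle is reported once, in canonical rotation and orientation, in a
    deterministic order (by length, then vertex sequence).  Reversible pairs
    are directed 2-cycles on which every cycle condition holds trivially, so
    they are excluded.  Raises :class:`CycleCapExceeded` past ``cap``.
    """
    g = net.undirected_graph()
    out = []
    for n, cyc in enumerate(nx.simple_cycles(g)):
        if n >= cap:
            raise CycleCapExceeded(f"more than {cap} elementary cycles")
        if len(cyc) >= 3:
            out.append(_canonical_cycle(cyc))
    out.sort(key=lambda w: (len(w), w.vertices))
    return out


@dataclass
class CircuitCondition:
    """One circuit condition: product of forward k's = product of backward k's.

    ``lhs``/``rhs`` list the directed edges whose constants appear on each
    side.  ``satisfied`` is filled in when constants are supplied;
    ``fundamental`` marks membership in a chosen cycle basis (an independent
    subset of size gamma — the full list is redundant but complete).
    """

    cycle: CycleWitness
    lhs: tuple[Edge, ...]
    rhs: tuple[Edge, ...]
    satisfied: bool | None = None
    fundamental: bool = False

    @staticmethod
    def from_cycle(cyc: CycleWitness) -> "CircuitCondition":
        steps = cyc.steps()
        return CircuitCondition(
            cycle=cyc,
            lhs=tuple(steps),
            rhs=tuple((b, a) for a, b in steps),
        )

    def evaluate(self, k: Mapping[Edge, object]) -> bool:
        lp = prod(Fraction(k[e]) for e in self.lhs)
        rp = prod(Fraction(k[e]) for e in self.rhs)
        return lp == rp

    def render(self, net: ReactionNetwork) -> str:
        def side(edges):
            return " * ".join(f"k({net.label(i)}->{net.label(j)})" for i, j in edges)
        return f"{side(self.lhs)} = {side(self.rhs)}"


def circuit_conditions(
    net: ReactionNetwork,
    k: Mapping[Edge, object] | None = None,
    cap: int = 100_000,
) -> tuple[list[CircuitCondition], int]:
    """All circuit conditions of a network, plus the independent count gamma.

    One condition per elementary cycle (a cycle and its reversal give the
    same condition with sides swapped; one representative is emitted).  When
    constants ``k`` are given, each condition's ``satisfied`` flag is
    evaluated exactly.  Conditions lying in a fundamental cycle basis of the
    underlying graph are marked; their number equals gamma.
    """
    cycles = enumerate_cycles(net, cap)
    conds = [CircuitCondition.from_cycle(c) for c in cycles]

    basis = {frozenset(frozenset(e) for e in _canonical_cycle(c).steps())
             for c in nx.cycle_basis(net.undirected_graph())}
    for cond in conds:
        key = frozenset(frozenset(e) for e in cond.cycle.steps())
        cond.fundamental = key in basis
        if k is not None:
            cond.satisfied = cond.evaluate(k)

    gamma = summary(net).gamma
    assert sum(c.fundamental for c in conds) == gamma
    return conds, gamma


def condition_counts(net: ReactionNetwork) -> tuple[int, int, int]:
    """(gamma, delta, r - s): circuit, spanning-forest, and total condition counts."""
    sm = summary(net)
    total = sm.r - sm.s
    assert sm.gamma + sm.delta == total
    return sm.gamma, sm.delta, total
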