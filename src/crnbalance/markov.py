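"""Balance in continuous-time Markov chains on countable lattices.

A CTMC with symmetric support (q(x,y) > 0 iff q(y,x) > 0) is the
Markov-chain analogue of a reversible reaction network: a measure mu is
*stationary* when, at every state, total outgoing probability flow
mu(x)q(x,y) equals total incoming flow (the analogue of complex balance),
and *reversible* when mu(x)q(x,y) = mu(y)q(y,x) on every transition (the
analogue of detailed balance).  The induced graph G_mu applies the same
trichotomy as for reaction networks to the flows, so a stationary measure
that is not reversible must exhibit a directed cycle or a bi-infinite
directed path in G_mu.

Infinite state spaces are handled through finite *windows*: balance is
asserted only on interior states (those whose every neighbor lies in the
window), and the bi-infinite-path witness is replaced by a window-limited
certificate — a directed path entering and leaving through the window
boundary.  Such a certificate is evidence on the window, not a proof about
the infinite graph.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Hashable, Iterable

from .balance import DEFAULT_RTOL, compare
from .kinetics import RateConstants
from .mixed_graph import MixedGraph, find_directed_cycle, is_edge_balanced
from .network import ReactionNetwork

__all__ = [
    "LatticeChain",
    "Measure",
    "Window",
    "stationarity_residuals",
    "reversibility_check",
    "induced_graph_mc",
    "theorem4_analysis",
    "Theorem4Report",
    "poisson_product_measure",
    "stochastic_mass_action_chain",
    "geometric_chain",
    "geometric_chain_stationary_measure",
    "geometric_chain_reversible_measure",
    "chain_from_network",
]

MCState = Hashable


@dataclass
class LatticeChain:
    """A CTMC given by a rate rule and a neighbor rule on a countable state set.

    ``rate(x, y)`` is the transition rate q(x, y); ``neighbors(x)`` returns
    the finite set of states reachable in one jump.  Symmetric support is
    required: q(x, y) > 0 iff q(y, x) > 0.
    """

    rate: Callable[[MCState, MCState], object]
    neighbors: Callable[[MCState], list[MCState]]
    dimension: int = 1

    def check_symmetric_support(self, states: Iterable[MCState]) -> None:
        for x in states:
            for y in self.neighbors(x):
                if (self.rate(x, y) > 0) != (self.rate(y, x) > 0):
                    raise ValueError(f"asymmetric support on transition {x} <-> {y}")


@dataclass
class Measure:
    """A sigma-finite measure given by a pointwise density on states."""

    density: Callable[[MCState], object]
    normalized: bool = False

    def __call__(self, x: MCState):
        v = self.density(x)
        if v < 0:
            raise ValueError(f"negative measure at {x}")
        return v


@dataclass
class Window:
    """A finite subset of the state space with its interior.

    A state is *interior* when all of its neighbors lie in the window;
    stationarity is only asserted on the interior, avoiding spurious
    truncation residuals at the boundary.
    """

    states: list[MCState]
    interior: list[MCState] = field(default=None)

    @staticmethod
    def build(chain: LatticeChain, states: Iterable[MCState]) -> "Window":
        states = list(states)
        sset = set(states)
        interior = [x for x in states if all(y in sset for y in chain.neighbors(x))]
        return Window(states=states, interior=interior)

    @staticmethod
    def box(chain: LatticeChain, lower: Iterable[int], upper: Iterable[int]) -> "Window":
        ranges = [range(lo, hi + 1) for lo, hi in zip(lower, upper)]
        return Window.build(chain, itertools.product(*ranges))

    def __contains__(self, x: MCState) -> bool:
        return x in set(self.states)


def stationarity_residuals(
    chain: LatticeChain, mu: Measure, window: Window
) -> dict[MCState, object]:
    """Per-interior-state residual: outgoing minus incoming probability flow.

    mu is stationary on the window iff all residuals vanish (within the
    comparison tolerance used downstream).
    """
    if not window.interior:
        raise ValueError("window has empty interior")
    res = {}
    for x in window.interior:
        out = sum(mu(x) * chain.rate(x, y) for y in chain.neighbors(x))
        inn = sum(mu(y) * chain.rate(y, x) for y in chain.neighbors(x))
        res[x] = out - inn
    return res


def is_stationary(
    chain: LatticeChain, mu: Measure, window: Window, rtol: float = DEFAULT_RTOL
) -> bool:
    for x in window.interior:
        out = sum(mu(x) * chain.rate(x, y) for y in chain.neighbors(x))
        inn = sum(mu(y) * chain.rate(y, x) for y in chain.neighbors(x))
        if compare(out, inn, rtol) != 0:
            return False
    return True


def reversibility_check(
    chain: LatticeChain, mu: Measure, window: Window, rtol: float = DEFAULT_RTOL
) -> tuple[bool, tuple[MCState, MCState] | None]:
    """Detailed balance mu(x)q(x,y) = mu(y)q(y,x) on every in-window transition."""
    sset = set(window.states)
    for x in window.states:
        for y in chain.neighbors(x):
            if y in sset and compare(mu(x) * chain.rate(x, y), mu(y) * chain.rate(y, x), rtol) != 0:
                return False, (x, y)
    return True, None


def induced_graph_mc(
    chain: LatticeChain, mu: Measure, window: Window, rtol: float = DEFAULT_RTOL
) -> MixedGraph:
    """The induced mixed graph G_mu restricted to the window.

    Undirected edge where the two probability flows agree, directed edge
    toward the larger flow.
    """
    sset = set(window.states)
    und, dirs = [], []
    seen = set()
    for x in window.states:
        for y in chain.neighbors(x):
            if y not in sset or frozenset((x, y)) in seen:
                continue
            seen.add(frozenset((x, y)))
            c = compare(mu(x) * chain.rate(x, y), mu(y) * chain.rate(y, x), rtol)
            if c == 0:
                und.append((x, y))
            elif c > 0:
                dirs.append((x, y))
            else:
                dirs.append((y, x))
    return MixedGraph(window.states, und, dirs)


@dataclass
class Theorem4Report:
    """Outcome of the stationary-implies-balanced-or-witnessed analysis.

    For a stationary measure whose induced graph is not edge-balanced, a
    witness is mandatory: either a directed cycle, or a window-limited
    directed path entering and leaving through the boundary (the finite
    surrogate for a bi-infinite directed path — a certificate on the window,
    not a proof on the infinite graph).
    """

    stationary: bool
    reversible: bool
    edge_balanced: bool
    witness_kind: str | None  # 'directed_cycle' | 'boundary_path' | None
    witness: object | None
    graph: MixedGraph


def _boundary_directed_path(g: MixedGraph, interior: set) -> list | None:
    """A maximal directed path whose both endpoints are non-interior states."""
    if not g.directed:
        return None
    start = sorted(g.directed, key=repr)[0]
    fwd = [start[0], start[1]]
    seen = set(fwd)
    while True:  # extend forward
        outs = [w for w in g.out_neighbors(fwd[-1]) if w not in seen]
        if not outs:
            break
        fwd.append(outs[0])
        seen.add(outs[0])
    while True:  # extend backward
        ins = [w for w in g.in_neighbors(fwd[0]) if w not in seen]
        if not ins:
            break
        fwd.insert(0, ins[0])
        seen.add(ins[0])
    if fwd[0] not in interior and fwd[-1] not in interior:
        return fwd
    return None


def theorem4_analysis(
    chain: LatticeChain, mu: Measure, window: Window, rtol: float = DEFAULT_RTOL
) -> Theorem4Report:
    """Check stationarity, then reversibility; produce the mandated witness.

    Raises on a non-stationary measure (the premise fails) and raises a
    consistency error if a stationary, non-reversible measure yields neither
    a directed cycle nor a boundary-to-boundary directed path — that
    combination is impossible on the interior of a window.
    """
    if not is_stationary(chain, mu, window, rtol):
        raise ValueError("measure is not stationary on the window interior")
    g = induced_graph_mc(chain, mu, window, rtol)
    rev, _ = reversibility_check(chain, mu, window, rtol)
    eb = is_edge_balanced(g)

    witness_kind, witness = None, None
    if not eb:
        cyc = find_directed_cycle(g)
        if cyc is not None:
            witness_kind, witness = "directed_cycle", cyc
        else:
            path = _boundary_directed_path(g, set(window.interior))
            if path is None:
                raise AssertionError(
                    "stationary non-reversible measure with neither a directed "
                    "cycle nor a boundary-to-boundary directed path"
                )
            witness_kind, witness = "boundary_path", path
    return Theorem4Report(
        stationary=True, reversible=rev, edge_balanced=eb,
        witness_kind=witness_kind, witness=witness, graph=g,
    )


# -- concrete chains and measures -----------------------------------------


def poisson_product_measure(c: Iterable[float]) -> Measure:
    """Product-form Poisson distribution with mean vector c > 0.

    density(x) = e^{-sum c} * prod c_i^{x_i} / x_i! — the stationary
    distribution of the stochastic mass-action system whenever the
    deterministic system is complex-balanced at c.
    """
    c = list(c)
    if any(ci <= 0 for ci in c):
        raise ValueError("Poisson means must be positive")
    norm = math.exp(-sum(c))

    def density(x):
        if any(xi < 0 for xi in x):
            return 0.0
        v = norm
        for ci, xi in zip(c, x):
            v *= ci ** xi / math.factorial(xi)
        return v

    return Measure(density=density, normalized=True)


def stochastic_mass_action_chain(net: ReactionNetwork, k: RateConstants) -> LatticeChain:
    """The CTMC of a reaction network under stochastic mass-action kinetics.

    States are molecule-count vectors over the network's species.  Firing
    the reaction i -> j moves the state by y(j) - y(i) with propensity
    k_ij * prod_s v_s! / (v_s - y(i)_s)!  (falling factorial); for networks
    with unary complexes this is k_ij times the source species count.
    Requires integer stoichiometry.
    """
    moves = []
    for (i, j) in net.edges:
        src = net.complexes[i]
        vec = net.reaction_vector(i, j)
        if any(Fraction(v).denominator != 1 for v in vec):
            raise ValueError("stochastic mass action requires integer stoichiometry")
        consume = [int(src.coefficient(sp)) for sp in net.species]
        delta = tuple(int(v) for v in vec)
        moves.append((consume, delta, k[(i, j)]))

    def propensity(consume, kij, v):
        p = kij
        for need, have in zip(consume, v):
            for t in range(need):
                p = p * (have - t)
            if have < need:
                return 0
        return p

    def rate(x, y):
        total = 0
        for consume, delta, kij in moves:
            if tuple(a + d for a, d in zip(x, delta)) == tuple(y):
                total += propensity(consume, kij, x)
        return total

    def neighbors(x):
        out = set()
        for consume, delta, kij in moves:
            y = tuple(a + d for a, d in zip(x, delta))
            if all(v >= 0 for v in y):
                # symmetric support: include y if either direction can fire
                out.add(y)
        return sorted(out)

    return LatticeChain(rate=rate, neighbors=neighbors, dimension=len(net.species))


def geometric_chain(q) -> LatticeChain:
    """Birth-death chain on the integers: q(x, x+1) = 2 q^{-|x|}, q(x, x-1) = q^{-|x|}.

    Rates grow away from the origin; the chain has no cycles beyond the
    trivial 2-cycles, yet carries two distinct stationary measures (so it is
    not positive recurrent): a non-reversible stationary distribution and a
    reversible measure that is normalizable exactly when q < 1/2.
    """
    q = Fraction(q)
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")

    def rate(x, y):
        if y == x + 1:
            return 2 * q ** (-abs(x))
        if y == x - 1:
            return q ** (-abs(x))
        return 0

    return LatticeChain(rate=rate, neighbors=lambda x: [x - 1, x + 1], dimension=1)


def geometric_chain_stationary_measure(q) -> Measure:
    """pi(x) = q^{|x|} (up to normalization): stationary but not reversible."""
    q = Fraction(q)
    return Measure(density=lambda x: q ** abs(x), normalized=False)


def geometric_chain_reversible_measure(q) -> Measure:
    """rho(x) = (2q)^x for x >= 0, (q/2)^{-x} for x < 0: reversible.

    Summable (hence normalizable to a distribution) precisely when q < 1/2.
    """
    q = Fraction(q)

    def density(x):
        return (2 * q) ** x if x >= 0 else (q / 2) ** (-x)

    return Measure(density=density, normalized=False)


def geometric_chain_reversible_normalizable(q) -> bool:
    """Whether the reversible measure has finite total mass (q < 1/2)."""
    q = Fraction(q)
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    return q < Fraction(1, 2)


def chain_from_network(net: ReactionNetwork, vertex_weight, edge_rate) -> LatticeChain:
    """Encode a finite network as a Markov chain on its vertex set.

    ``vertex_weight(i)`` plays the role of the measure mu(i) and
    ``edge_rate(i, j)`` the transition rate q(i, j); the induced graph of
    this chain under mu coincides with the reaction-network induced graph
    for rates r_ij = mu(i) q(i, j) — the dictionary between the two
    settings.
    """
    adjacency = {i: sorted({j for a, j in net.edges if a == i}) for i in range(net.n_vertices)}

    def rate(x, y):
        return edge_rate(x, y) if (x, y) in net.edges else 0

    return LatticeChain(rate=rate, neighbors=lambda x: adjacency[x], dimension=1)
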