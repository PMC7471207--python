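"""Simple mixed graphs and their balance structure.

A simple mixed graph G = (V, U, D) has undirected edges U and directed edges
D, with at most one edge of any kind between two vertices and no loops.  An
*edge* is balanced if it is undirected; a *vertex* is balanced if it has an
incoming directed edge exactly when it has an outgoing one.  The central
fact, proved constructively here, is that a finite vertex-balanced graph
that is not edge-balanced must contain a directed cycle — equivalently, a
vertex-balanced graph with no directed cycle is edge-balanced.

These notions drive everything downstream: a state of a reaction network (or
a measure on a Markov chain) is detailed-balanced exactly when its induced
mixed graph is edge-balanced, and complex-balanced/stationary implies vertex
balance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator

import networkx as nx

__all__ = [
    "MixedGraph",
    "CycleWitness",
    "is_edge_balanced",
    "is_vertex_balanced",
    "find_directed_cycle",
    "find_weakly_directed_cycle",
    "enumerate_mixed_graphs",
    "CycleCapExceeded",
]

Vertex = Hashable


class CycleCapExceeded(RuntimeError):
    """Cycle enumeration exceeded the configured cap; results would be partial."""


def _vkey(v: Vertex):
    # deterministic total order on arbitrary hashable labels
    return repr(v)


@dataclass(frozen=True)
class CycleWitness:
    """A cycle, stored as a closed vertex sequence v0, v1, ..., vk = v0.

    ``orientations[t]`` records how the t-th step was traversed: ``'u'`` for
    an undirected edge, ``'+'`` for a directed edge traversed forward,
    ``'-'`` for a directed edge traversed against its direction.
    """

    vertices: tuple[Vertex, ...]
    orientations: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        vs = self.vertices
        if len(vs) < 4 or vs[0] != vs[-1]:
            raise ValueError("cycle must be a closed sequence of >= 3 distinct vertices")
        if len(set(vs[:-1])) != len(vs) - 1:
            raise ValueError("cycle vertices must be distinct")
        if self.orientations and len(self.orientations) != len(vs) - 1:
            raise ValueError("one orientation flag per step")

    def __len__(self) -> int:
        return len(self.vertices) - 1

    def steps(self) -> list[tuple[Vertex, Vertex]]:
        return list(zip(self.vertices[:-1], self.vertices[1:]))

    @staticmethod
    def canonical(vertices: Iterable[Vertex], orientations: Iterable[str] = ()) -> "CycleWitness":
        """Canonical rotation: start at the minimal vertex, keep traversal order."""
        vs = list(vertices)
        if vs and vs[0] == vs[-1]:
            vs = vs[:-1]
        ori = list(orientations)
        k = min(range(len(vs)), key=lambda t: _vkey(vs[t]))
        vs2 = vs[k:] + vs[:k]
        ori2 = ori[k:] + ori[:k] if ori else []
        return CycleWitness(tuple(vs2 + [vs2[0]]), tuple(ori2))


@dataclass
class MixedGraph:
    """Simple mixed graph (V, U, D); U and D pairs are mutually exclusive."""

    vertices: set[Vertex]
    undirected: set[frozenset]
    directed: set[tuple[Vertex, Vertex]]

    def __init__(
        self,
        vertices: Iterable[Vertex] = (),
        undirected: Iterable = (),
        directed: Iterable[tuple[Vertex, Vertex]] = (),
    ):
        self.vertices = set(vertices)
        self.undirected = {frozenset(e) for e in undirected}
        self.directed = {tuple(e) for e in directed}
        for e in self.undirected:
            if len(e) != 2:
                raise ValueError(f"undirected loop or malformed edge {set(e)}")
            self.vertices |= e
        for a, b in self.directed:
            if a == b:
                raise ValueError(f"loop at {a!r}")
            self.vertices |= {a, b}
        for a, b in self.directed:
            pair = frozenset((a, b))
            if pair in self.undirected or (b, a) in self.directed:
                raise ValueError(f"multiple edges between {a!r} and {b!r}")

    # -- adjacency ---------------------------------------------------------

    def out_neighbors(self, v: Vertex) -> list[Vertex]:
        return sorted((b for a, b in self.directed if a == v), key=_vkey)

    def in_neighbors(self, v: Vertex) -> list[Vertex]:
        return sorted((a for a, b in self.directed if b == v), key=_vkey)

    def underlying(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(tuple(e) for e in self.undirected)
        g.add_edges_from(self.directed)
        return g

    def step_orientation(self, a: Vertex, b: Vertex) -> str:
        """'u' / '+' / '-' for traversing from a to b; raises if not adjacent."""
        if frozenset((a, b)) in self.undirected:
            return "u"
        if (a, b) in self.directed:
            return "+"
        if (b, a) in self.directed:
            return "-"
        raise KeyError(f"no edge between {a!r} and {b!r}")

    # -- export ------------------------------------------------------------

    def to_json(self) -> str:
        import json

        return json.dumps({
            "vertices": sorted(self.vertices, key=_vkey),
            "undirected": sorted([sorted(e, key=_vkey) for e in self.undirected]),
            "directed": sorted(self.directed, key=lambda e: (_vkey(e[0]), _vkey(e[1]))),
        })

    @classmethod
    def from_json(cls, text: str) -> "MixedGraph":
        import json

        d = json.loads(text)
        return cls(d["vertices"], d["undirected"], [tuple(e) for e in d["directed"]])

    def to_dot(self, name: str = "G") -> str:
        lines = [f"digraph {name} {{"]
        for v in sorted(self.vertices, key=_vkey):
            lines.append(f'  "{v}";')
        for e in sorted(self.undirected, key=lambda e: sorted(map(_vkey, e))):
            a, b = sorted(e, key=_vkey)
            lines.append(f'  "{a}" -> "{b}" [dir=none];')
        for a, b in sorted(self.directed, key=lambda e: (_vkey(e[0]), _vkey(e[1]))):
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)


def is_edge_balanced(g: MixedGraph) -> bool:
    """True iff every edge is undirected (D is empty)."""
    return not g.directed


def is_vertex_balanced(g: MixedGraph) -> tuple[bool, list[Vertex]]:
    """Check vertex balance; returns (verdict, sorted list of unbalanced vertices).

    A vertex is balanced when it has an incoming directed edge iff it has an
    outgoing one (undirected edges are ignored).
    """
    has_in = {b for _, b in g.directed}
    has_out = {a for a, _ in g.directed}
    bad = sorted(has_in ^ has_out, key=_vkey)
    return (not bad, bad)


def find_directed_cycle(g: MixedGraph) -> CycleWitness | None:
    """Find a directed cycle by the forward walk, or return None.

    Starting from each directed edge, repeatedly extend along outgoing
    directed edges (smallest head first) until a vertex repeats — on a
    vertex-balanced graph with D nonempty this always closes a cycle.  On
    general graphs the walk backtracks, so the search is complete: it returns
    a cycle iff one exists.
    """
    if not g.directed:
        return None
    # DFS over directed edges with an explicit stack (iterative, backtracking)
    color: dict[Vertex, int] = {}  # 0 absent/white, 1 on stack, 2 done
    for start, _ in sorted(g.directed, key=lambda e: (_vkey(e[0]), _vkey(e[1]))):
        if color.get(start, 0) == 2:
            continue
        path: list[Vertex] = [start]
        iters: list[Iterator[Vertex]] = [iter(g.out_neighbors(start))]
        color[start] = 1
        while path:
            try:
                nxt = next(iters[-1])
            except StopIteration:
                color[path.pop()] = 2
                iters.pop()
                continue
            c = color.get(nxt, 0)
            if c == 1:  # closes a directed cycle
                k = path.index(nxt)
                cyc = path[k:] + [nxt]
                return CycleWitness.canonical(cyc, ["+"] * (len(cyc) - 1))
            if c == 0:
                color[nxt] = 1
                path.append(nxt)
                iters.append(iter(g.out_neighbors(nxt)))
    return None


def _undirected_cycles(g: nx.Graph, cap: int) -> Iterator[list[Vertex]]:
    count = 0
    for cyc in nx.simple_cycles(g):
        if len(cyc) < 3:
            continue
        count += 1
        if count > cap:
            raise CycleCapExceeded(f"more than {cap} elementary cycles")
        yield cyc


def find_weakly_directed_cycle(g: MixedGraph, cap: int = 100_000) -> CycleWitness | None:
    """Find a weakly directed cycle (>= 1 directed edge, all agreeing), or None.

    Enumerates elementary cycles of the underlying undirected graph and checks
    each traversal orientation; a cycle whose directed edges all point with
    the traversal (or all against it) qualifies.  Raises
    :class:`CycleCapExceeded` beyond ``cap`` cycles rather than truncating.
    """
    for cyc in _undirected_cycles(g.underlying(), cap):
        closed = cyc + [cyc[0]]
        ori = [g.step_orientation(a, b) for a, b in zip(closed[:-1], closed[1:])]
        if "+" in ori and "-" not in ori:
            return CycleWitness.canonical(closed, ori)
        if "-" in ori and "+" not in ori:
            rev = list(reversed(closed))
            return CycleWitness.canonical(
                rev, [g.step_orientation(a, b) for a, b in zip(rev[:-1], rev[1:])]
            )
    return None


def enumerate_mixed_graphs(n: int) -> Iterator[MixedGraph]:
    """All simple mixed graphs on vertices 0..n-1.

    Each unordered pair independently takes one of four states: absent,
    undirected, or directed in either orientation — 4^(n(n-1)/2) graphs.
    Intended for exhaustive verification on small n.
    """
    pairs = list(itertools.combinations(range(n), 2))
    for assignment in itertools.product(range(4), repeat=len(pairs)):
        und, dirs = [], []
        for (a, b), state in zip(pairs, assignment):
            if state == 1:
                und.append((a, b))
            elif state == 2:
                dirs.append((a, b))
            elif state == 3:
                dirs.append((b, a))
        yield MixedGraph(range(n), und, dirs)
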