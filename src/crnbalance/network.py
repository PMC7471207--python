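"""Reversible reaction networks: data model, parsing, structural invariants.

A chemical reaction network is a finite simple directed graph whose vertices
carry *complexes* — formal nonnegative-rational combinations of species such
as ``A + 2 B``.  In the reversible setting studied here the graph is
symmetric: every reaction ``i -> j`` is accompanied by ``j -> i``.

The structural summary computes the classical indices of the field:

* ``m``      number of complexes (vertices)
* ``ell``    number of linkage classes (connected components)
* ``r``      number of reversible reactions (edge pairs)
* ``s``      stoichiometric rank, the rank of the span of reaction vectors
             ``y(j) - y(i)`` — computed in exact rational arithmetic
* ``gamma``  cycle rank (cyclomatic number) ``r - m + ell``
* ``delta``  deficiency ``m - ell - s``

with the identity ``gamma + delta = r - s``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import networkx as nx
import sympy

__all__ = [
    "Complex",
    "ReactionNetwork",
    "NetworkSummary",
    "NetworkParseError",
    "parse_network",
    "parse_complex",
    "summary",
]


class NetworkParseError(ValueError):
    """Malformed reaction text (stoichiometry, duplicates, irreversibility)."""


def _to_fraction(x) -> Fraction:
    if isinstance(x, float):
        return Fraction(x).limit_denominator(10**12)
    return Fraction(x)


@dataclass(frozen=True)
class Complex:
    """A formal sum of species with nonnegative rational coefficients.

    The empty complex (no species) is legal and prints as ``"0"``; it is the
    vertex used for exchange reactions with the environment.
    """

    coefficients: tuple[tuple[str, Fraction], ...]

    def __init__(self, coefficients: Mapping[str, object] | Iterable[tuple[str, object]]):
        items = dict(coefficients)
        cleaned = []
        for sp, c in items.items():
            c = _to_fraction(c)
            if c < 0:
                raise NetworkParseError(f"negative stoichiometric coefficient for {sp!r}")
            if c != 0:
                cleaned.append((sp, c))
        cleaned.sort(key=lambda t: t[0])
        object.__setattr__(self, "coefficients", tuple(cleaned))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sp for sp, _ in self.coefficients)

    def coefficient(self, sp: str) -> Fraction:
        for name, c in self.coefficients:
            if name == sp:
                return c
        return Fraction(0)

    def support(self) -> frozenset[str]:
        return frozenset(sp for sp, _ in self.coefficients)

    def vector(self, species: Iterable[str]) -> tuple[Fraction, ...]:
        return tuple(self.coefficient(sp) for sp in species)

    def is_empty(self) -> bool:
        return not self.coefficients

    def __str__(self) -> str:
        if not self.coefficients:
            return "0"
        parts = []
        for sp, c in self.coefficients:
            if c == 1:
                parts.append(sp)
            else:
                num = str(c) if c.denominator != 1 else str(c.numerator)
                parts.append(f"{num} {sp}")
        return " + ".join(parts)


_TERM_RE = re.compile(
    r"^\s*(?:(\d+(?:/\d+)?|\d*\.\d+)\s*\*?\s*)?([A-Za-z_][A-Za-z0-9_]*)\s*$"
)


def parse_complex(text: str) -> Complex:
    """Parse a formal sum like ``"A + 2 B"`` or ``"0"`` into a :class:`Complex`."""
    text = text.strip()
    if text == "0":
        return Complex({})
    coeffs: dict[str, Fraction] = {}
    for term in text.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise NetworkParseError(f"malformed stoichiometric term {term.strip()!r}")
        num, sp = m.groups()
        c = Fraction(num) if num else Fraction(1)
        coeffs[sp] = coeffs.get(sp, Fraction(0)) + c
    return Complex(coeffs)


@dataclass
class ReactionNetwork:
    """A reversible reaction network: symmetric simple directed graph + complexes.

    Vertices are indexed ``0..m-1``; ``complexes[i]`` is the complex ``y(i)``.
    ``edges`` holds ordered index pairs; in the default (reversible) setting
    the edge set is symmetric.  Complexes must be pairwise distinct.
    """

    species: list[str]
    complexes: list[Complex]
    edges: set[tuple[int, int]]
    reversible: bool = True

    def __post_init__(self) -> None:
        seen = set()
        for c in self.complexes:
            if c.coefficients in seen:
                raise NetworkParseError(f"duplicate complex {c}")
            seen.add(c.coefficients)
        m = len(self.complexes)
        for i, j in self.edges:
            if i == j:
                raise NetworkParseError(f"loop at vertex {i} ({self.complexes[i]})")
            if not (0 <= i < m and 0 <= j < m):
                raise NetworkParseError(f"edge ({i},{j}) references unknown vertex")
        if self.reversible:
            for i, j in self.edges:
                if (j, i) not in self.edges:
                    raise NetworkParseError(
                        f"irreversible reaction {self.complexes[i]} -> {self.complexes[j]} "
                        "in reversible mode (pass permissive=True to allow)"
                    )

    # -- structure ---------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.complexes)

    def vertex_of(self, c: Complex | str) -> int:
        if isinstance(c, str):
            c = parse_complex(c)
        return self.complexes.index(c)

    def label(self, i: int) -> str:
        return str(self.complexes[i])

    def reversible_pairs(self) -> list[tuple[int, int]]:
        """One orientation per reversible pair, lexicographic (i < j)."""
        return sorted({(min(i, j), max(i, j)) for i, j in self.edges})

    def undirected_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.reversible_pairs())
        return g

    def reaction_vector(self, i: int, j: int) -> tuple[Fraction, ...]:
        yi = self.complexes[i].vector(self.species)
        yj = self.complexes[j].vector(self.species)
        return tuple(b - a for a, b in zip(yi, yj))

    # -- serialization -----------------------------------------------------

    def to_text(self, constants: Mapping[tuple[int, int], object] | None = None) -> str:
        lines = []
        for i, j in self.reversible_pairs():
            line = f"{self.complexes[i]} <-> {self.complexes[j]}"
            if constants is not None:
                kf, kr = constants[(i, j)], constants[(j, i)]
                line += f", kf={kf}, kr={kr}"
            lines.append(line)
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "species": self.species,
                "complexes": [str(c) for c in self.complexes],
                "edges": sorted(self.edges),
                "reversible": self.reversible,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ReactionNetwork":
        d = json.loads(text)
        return cls(
            species=list(d["species"]),
            complexes=[parse_complex(c) for c in d["complexes"]],
            edges={tuple(e) for e in d["edges"]},
            reversible=d.get("reversible", True),
        )


_LINE_RE = re.compile(r"^(?P<lhs>[^<>,]+?)\s*(?P<arrow><->|->)\s*(?P<rhs>[^,]+?)\s*(?P<opts>,.*)?$")


def parse_network(
    text: str, permissive: bool = False
) -> tuple[ReactionNetwork, dict[tuple[int, int], Fraction] | None]:
    """Parse reaction text into a network, plus rate constants if present.

    Each nonblank, noncomment line reads ``LHS <-> RHS`` with an optional
    ``, kf=Q, kr=Q`` suffix; ``LHS``/``RHS`` are formal sums (``0`` for the
    empty complex).  ``#`` starts a comment.  Irreversible lines (``->``)
    are rejected unless ``permissive`` is set, in which case the returned
    network is suitable for structural summaries only.

    Returns ``(network, constants)`` where ``constants`` maps directed edges
    ``(i, j)`` to rate constants, or ``None`` if no line carried constants.
    """
    complexes: list[Complex] = []
    index: dict[tuple, int] = {}
    edges: set[tuple[int, int]] = set()
    constants: dict[tuple[int, int], Fraction] = {}
    saw_constants = False

    def vid(c: Complex) -> int:
        key = c.coefficients
        if key not in index:
            index[key] = len(complexes)
            complexes.append(c)
        return index[key]

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _LINE_RE.match(line)
        if not m:
            raise NetworkParseError(f"line {lineno}: cannot parse {line!r}")
        if m.group("arrow") == "->" and not permissive:
            raise NetworkParseError(
                f"line {lineno}: irreversible reaction in reversible mode"
            )
        lhs, rhs = parse_complex(m.group("lhs")), parse_complex(m.group("rhs"))
        if lhs == rhs:
            raise NetworkParseError(f"line {lineno}: loop reaction {lhs} <-> {rhs}")
        i, j = vid(lhs), vid(rhs)
        if (i, j) in edges:
            raise NetworkParseError(f"line {lineno}: duplicate reaction {lhs} <-> {rhs}")
        edges.add((i, j))
        if m.group("arrow") == "<->":
            edges.add((j, i))
        opts = m.group("opts")
        if opts:
            kv = dict(
                part.strip().split("=", 1) for part in opts.lstrip(",").split(",") if part.strip()
            )
            saw_constants = True
            if "kf" in kv:
                constants[(i, j)] = Fraction(kv["kf"])
            if "kr" in kv:
                constants[(j, i)] = Fraction(kv["kr"])

    species = sorted({sp for c in complexes for sp in c.species})
    net = ReactionNetwork(
        species=species,
        complexes=complexes,
        edges=edges,
        reversible=not permissive,
    )
    return net, (constants if saw_constants else None)


@dataclass(frozen=True)
class NetworkSummary:
    """Structural indices of a network, with the count identity asserted."""

    r: int
    m: int
    ell: int
    s: int
    gamma: int = field(init=False)
    delta: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma", self.r - self.m + self.ell)
        object.__setattr__(self, "delta", self.m - self.ell - self.s)
        if self.gamma < 0 or self.delta < 0:
            raise AssertionError("structural indices must be nonnegative")
        assert self.gamma + self.delta == self.r - self.s

    def as_dict(self) -> dict[str, int]:
        return {
            "r": self.r, "m": self.m, "ell": self.ell,
            "s": self.s, "gamma": self.gamma, "delta": self.delta,
        }


def stoichiometric_rank(net: ReactionNetwork) -> int:
    """Rank of the matrix of reaction vectors y(j)-y(i), exact over Q.

    One column per reversible pair (lexicographic orientation); the rank is
    orientation-invariant since flipping a column's sign preserves its span.
    """
    pairs = net.reversible_pairs()
    if not pairs or not net.species:
        return 0
    cols = [net.reaction_vector(i, j) for i, j in pairs]
    mat = sympy.Matrix([[sympy.Rational(c[k]) for c in cols] for k in range(len(net.species))])
    return mat.rank()


def summary(net: ReactionNetwork) -> NetworkSummary:
    """Compute (r, m, ell, s) and the derived gamma, delta for a network."""
    g = net.undirected_graph()
    return NetworkSummary(
        r=len(net.reversible_pairs()),
        m=net.n_vertices,
        ell=nx.number_connected_components(g),
        s=stoichiometric_rank(net),
    )
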