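"""The six balance predicates at a state, and the induced mixed graph.

For a reversible network with rate vector ``r`` evaluated at a state ``x``:

* detailed balance (DB):      r_ij = r_ji on every reversible reaction;
* complex balance (CB):       at every vertex, sum of outgoing rates equals
                              sum of incoming rates;
* formal balance (FB):        around every directed cycle, the product of
                              forward rates equals the product of backward
                              rates;
* strong cycle balance (sCycB): every cycle is either all-equal or carries
                              both a strictly forward and a strictly
                              backward edge;
* cycle balance (CycB):       no cycle has all its net rates strictly on
                              one side;
* weak complex balance (wCB): the induced graph is vertex-balanced.

The *induced graph* G_x places an undirected edge where forward and backward
rates are equal and a directed edge toward the larger rate.  The predicates
then translate to graph properties — DB iff G_x is edge-balanced, sCycB iff
G_x has no weakly directed cycle, CycB iff G_x has no directed cycle — and
:func:`classify` cross-checks the rate-level and graph-level answers, raising
:class:`ConsistencyError` on any disagreement (which would indicate a bug,
never bad input).  The headline result verified on every call: given CB (or
just wCB), DB, FB, sCycB and CycB are all equivalent; this holds for
arbitrary kinetics and for boundary states with zero rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational

from .cycle_conditions import enumerate_cycles
from .kinetics import RateVector
from .mixed_graph import (
    CycleWitness,
    MixedGraph,
    find_directed_cycle,
    find_weakly_directed_cycle,
    is_edge_balanced,
    is_vertex_balanced,
)
from .network import ReactionNetwork

__all__ = [
    "BalanceReport",
    "ConsistencyError",
    "induced_graph",
    "check_detailed_balance",
    "check_complex_balance",
    "check_formal_balance",
    "check_cycle_balance",
    "check_weak_complex_balance",
    "classify",
    "DEFAULT_RTOL",
]

DEFAULT_RTOL = 1e-9


class ConsistencyError(AssertionError):
    """A proven implication between balance predicates failed — internal bug."""


def compare(a, b, rtol: float = DEFAULT_RTOL) -> int:
    """Three-way comparison: -1, 0, +1 for a < b, a = b, a > b.

    Exact when both values are rational; otherwise equality means
    |a - b| <= rtol * max(1, |a|, |b|), so the trichotomy is exhaustive and
    exclusive.
    """
    if isinstance(a, Rational) and isinstance(b, Rational):
        return (a > b) - (a < b)
    a, b = float(a), float(b)
    if abs(a - b) <= rtol * max(1.0, abs(a), abs(b)):
        return 0
    return 1 if a > b else -1


def _compare_products(fwd: list, bwd: list, rtol: float) -> int:
    """Compare two products of nonnegative factors, zero- and overflow-safe."""
    fz, bz = any(f == 0 for f in fwd), any(b == 0 for b in bwd)
    if fz or bz:
        return (not fz) - (not bz)  # 0 vs 0 equal; zero side is smaller
    if all(isinstance(v, Rational) for v in fwd + bwd):
        pf = math.prod(map(Fraction, fwd))
        pb = math.prod(map(Fraction, bwd))
        return (pf > pb) - (pf < pb)
    lf = sum(math.log(float(v)) for v in fwd)
    lb = sum(math.log(float(v)) for v in bwd)
    if abs(lf - lb) <= rtol * max(1.0, abs(lf), abs(lb)) + len(fwd) * rtol:
        return 0
    return 1 if lf > lb else -1


def induced_graph(net: ReactionNetwork, r: RateVector, rtol: float = DEFAULT_RTOL) -> MixedGraph:
    """Build the induced mixed graph G_x on vertex indices.

    For each reversible pair: undirected edge when r_ij = r_ji (within the
    comparison rule), directed i -> j when r_ij > r_ji.  Simple by
    construction.
    """
    und, dirs = [], []
    for i, j in net.reversible_pairs():
        c = compare(r[(i, j)], r[(j, i)], rtol)
        if c == 0:
            und.append((i, j))
        elif c > 0:
            dirs.append((i, j))
        else:
            dirs.append((j, i))
    return MixedGraph(range(net.n_vertices), und, dirs)


def check_detailed_balance(
    net: ReactionNetwork, r: RateVector, rtol: float = DEFAULT_RTOL
) -> tuple[bool, tuple[int, int] | None]:
    """DB iff forward and backward rates agree on every pair; witness = bad edge."""
    for i, j in net.reversible_pairs():
        if compare(r[(i, j)], r[(j, i)], rtol) != 0:
            return False, (i, j)
    return True, None


def check_complex_balance(
    net: ReactionNetwork, r: RateVector, rtol: float = DEFAULT_RTOL
) -> tuple[bool, dict[int, object]]:
    """CB iff per-vertex out-flow equals in-flow; returns all residuals.

    The residual at vertex i is sum of outgoing minus sum of incoming rates.
    """
    residuals: dict[int, object] = {}
    balanced: dict[int, bool] = {}
    for v in range(net.n_vertices):
        out = sum(r[(i, j)] for i, j in net.edges if i == v)
        inn = sum(r[(i, j)] for i, j in net.edges if j == v)
        residuals[v] = out - inn
        balanced[v] = compare(out, inn, rtol) == 0
    return all(balanced.values()), residuals


def check_formal_balance(
    net: ReactionNetwork,
    r: RateVector,
    cycles: list[CycleWitness] | None = None,
    rtol: float = DEFAULT_RTOL,
) -> tuple[bool, list[dict]]:
    """FB iff forward and backward rate products agree around every cycle.

    2-cycles (the reversible pairs themselves) hold trivially and are not
    enumerated.  Zero rates are handled exactly: a zero forward product
    matches only a zero backward product.
    """
    if cycles is None:
        cycles = enumerate_cycles(net)
    results = []
    ok = True
    for cyc in cycles:
        fwd = [r[(a, b)] for a, b in cyc.steps()]
        bwd = [r[(b, a)] for a, b in cyc.steps()]
        c = _compare_products(fwd, bwd, rtol)
        results.append({"cycle": cyc, "forward": fwd, "backward": bwd, "equal": c == 0})
        ok = ok and c == 0
    return ok, results


def check_cycle_balance(
    net: ReactionNetwork,
    r: RateVector,
    cycles: list[CycleWitness] | None = None,
    strong: bool = False,
    rtol: float = DEFAULT_RTOL,
) -> tuple[bool, CycleWitness | None]:
    """Cycle balance (weak or strong); witness = first violating cycle.

    Strong (sCycB): every cycle is all-equal or has both a strict ``<`` and a
    strict ``>`` edge.  Weak (CycB): every cycle has some edge with
    r_ij <= r_ji and some with r_ij >= r_ji, i.e. its net rates are not all
    strictly one-sided.  Both conditions are invariant under cycle reversal,
    so one orientation per cycle suffices.
    """
    if cycles is None:
        cycles = enumerate_cycles(net)
    for cyc in cycles:
        signs = [compare(r[(a, b)], r[(b, a)], rtol) for a, b in cyc.steps()]
        if strong:
            if not (all(s == 0 for s in signs) or (1 in signs and -1 in signs)):
                return False, cyc
        else:
            if all(s == 1 for s in signs) or all(s == -1 for s in signs):
                return False, cyc
    return True, None


def check_weak_complex_balance(
    net: ReactionNetwork, r: RateVector, rtol: float = DEFAULT_RTOL
) -> tuple[bool, list[int]]:
    """wCB iff the induced graph is vertex-balanced; returns unbalanced vertices."""
    ok, bad = is_vertex_balanced(induced_graph(net, r, rtol))
    return ok, bad


@dataclass
class BalanceReport:
    """Verdicts of all six balance predicates at one state, with witnesses.

    ``witnesses`` holds per-verdict evidence for each failure: the unbalanced
    edge for DB, the residual vector for CB, the violating cycle and its
    products for FB, the one-sided cycle for CycB/sCycB, the unbalanced
    vertices for wCB.
    """

    db: bool
    cb: bool
    wcb: bool
    fb: bool
    scycb: bool
    cycb: bool
    witnesses: dict = field(default_factory=dict)
    rtol: float = DEFAULT_RTOL
    graph: MixedGraph | None = None

    def as_dict(self) -> dict:
        return {
            "db": self.db, "cb": self.cb, "wcb": self.wcb,
            "fb": self.fb, "scycb": self.scycb, "cycb": self.cycb,
            "rtol": self.rtol,
        }


def classify(
    net: ReactionNetwork,
    r: RateVector,
    rtol: float = DEFAULT_RTOL,
    positive_rates_assumed: bool | None = None,
) -> BalanceReport:
    """Run all six predicates, cross-check them through the induced graph,
    and assert every proven implication between them.

    Graph-level cross-checks: DB iff G_x edge-balanced; sCycB iff G_x has no
    weakly directed cycle; CycB iff G_x has no directed cycle; CB implies
    wCB.  Implications asserted on the verdicts: DB => CB, DB => FB,
    FB => CycB, sCycB => CycB, and FB => sCycB when all rates are positive
    (``positive_rates_assumed`` defaults to the observed positivity; pass
    True for kinetics obeying the support rule, where the implication also
    covers boundary states).  Finally, given CB or wCB, the four cycle-type
    predicates must coincide with DB.  Any violation raises
    :class:`ConsistencyError`.
    """
    cycles = enumerate_cycles(net)
    g = induced_graph(net, r, rtol)

    db, db_w = check_detailed_balance(net, r, rtol)
    cb, residuals = check_complex_balance(net, r, rtol)
    wcb, wcb_bad = check_weak_complex_balance(net, r, rtol)
    fb, fb_res = check_formal_balance(net, r, cycles, rtol)
    scycb, scycb_w = check_cycle_balance(net, r, cycles, strong=True, rtol=rtol)
    cycb, cycb_w = check_cycle_balance(net, r, cycles, strong=False, rtol=rtol)

    # graph-level equivalences
    if db != is_edge_balanced(g):
        raise ConsistencyError("DB vs edge balance of the induced graph")
    if scycb != (find_weakly_directed_cycle(g) is None):
        raise ConsistencyError("sCycB vs weakly directed cycles of the induced graph")
    if cycb != (find_directed_cycle(g) is None):
        raise ConsistencyError("CycB vs directed cycles of the induced graph")
    if cb and not wcb:
        raise ConsistencyError("CB must imply vertex balance of the induced graph")

    # implication chains on the verdicts
    if db and not cb:
        raise ConsistencyError("DB => CB violated")
    if db and not fb:
        raise ConsistencyError("DB => FB violated")
    if fb and not cycb:
        raise ConsistencyError("FB => CycB violated")
    if scycb and not cycb:
        raise ConsistencyError("sCycB => CycB violated")
    if positive_rates_assumed is None:
        positive_rates_assumed = all(v > 0 for v in r.values())
    if positive_rates_assumed and fb and not scycb:
        raise ConsistencyError("FB => sCycB violated for positive rates")

    # detailed balance = complex balance + cycle balance (and its variants)
    for premise, name in ((cb, "CB"), (wcb, "wCB")):
        if premise:
            if not (db == fb == scycb == cycb):
                raise ConsistencyError(
                    f"given {name}, DB/FB/sCycB/CycB must be equivalent; got "
                    f"db={db} fb={fb} scycb={scycb} cycb={cycb}"
                )

    witnesses: dict = {}
    if not db:
        witnesses["db"] = db_w
    if not cb:
        witnesses["cb"] = {v: res for v, res in residuals.items()
                           if compare(res, 0, rtol) != 0}
    if not wcb:
        witnesses["wcb"] = wcb_bad
    if not fb:
        witnesses["fb"] = [x for x in fb_res if not x["equal"]]
    if not scycb:
        witnesses["scycb"] = scycb_w
    if not cycb:
        witnesses["cycb"] = cycb_w

    return BalanceReport(
        db=db, cb=cb, wcb=wcb, fb=fb, scycb=scycb, cycb=cycb,
        witnesses=witnesses, rtol=rtol, graph=g,
    )
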