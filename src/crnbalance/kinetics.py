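"""Rate evaluation at a state: mass action, generalized, and user kinetics.

Mass action assigns the edge ``i -> j`` the rate ``k_ij * x^y(i)`` with the
monomial convention ``0^0 = 1`` (so exchange reactions from the empty complex
run at their constant rate).  Generalized (enzyme-type) kinetics factor as
``r_ij(x) = k_ij * g_ij(x) * f_i(x)`` with a symmetric edge factor
``g_ij = g_ji``; general kinetics are arbitrary nonnegative rate functions,
optionally checked against the support rule ``r_ij(x) > 0 iff
supp(y(i)) ⊆ supp(x)``.

Evaluation is exact (``Fraction``) whenever constants and state are rational;
comparison tolerances are owned by :mod:`crnbalance.balance`, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Callable, Mapping

from .network import ReactionNetwork

__all__ = [
    "State",
    "RateVector",
    "GeneralizedKinetics",
    "mass_action_rates",
    "general_rates",
    "db_constants_from_state",
    "monomial",
    "SupportViolation",
]

Edge = tuple[int, int]
State = Mapping[str, object]  # species name -> nonnegative number
RateConstants = Mapping[Edge, object]
RateVector = dict[Edge, object]


class SupportViolation(ValueError):
    """A rate function's sign disagrees with the support of its source complex."""


def _check_state(x: State) -> None:
    for sp, v in x.items():
        if v < 0:
            raise ValueError(f"negative concentration for {sp!r}: {v}")


def support(x: State) -> frozenset[str]:
    return frozenset(sp for sp, v in x.items() if v != 0)


def monomial(x: State, c, species=None):
    """x^y for a complex y: the product of x_sp^coeff, with 0^0 = 1.

    Exact when all inputs are rational and exponents are integral.
    """
    result: object = Fraction(1)
    exact = True
    for sp, coeff in c.coefficients:
        base = x.get(sp, 0)
        if base == 0:
            if coeff > 0:
                return Fraction(0) if exact else 0.0
            continue  # 0 exponent contributes factor 1
        if isinstance(base, Rational) and Fraction(coeff).denominator == 1:
            result = result * Fraction(base) ** int(coeff)
        else:
            result = float(result) * float(base) ** float(coeff)
            exact = False
    return result


def mass_action_rates(net: ReactionNetwork, k: RateConstants, x: State) -> RateVector:
    """Evaluate r_ij = k_ij * x^y(i) on every edge of the network."""
    _check_state(x)
    rates: RateVector = {}
    for (i, j) in net.edges:
        if (i, j) not in k:
            raise KeyError(f"missing rate constant for edge {net.label(i)} -> {net.label(j)}")
        kij = k[(i, j)]
        mono = monomial(x, net.complexes[i])
        if isinstance(kij, Rational) and isinstance(mono, Rational):
            rates[(i, j)] = Fraction(kij) * Fraction(mono)
        else:
            rates[(i, j)] = float(kij) * float(mono)
    return rates


def general_rates(
    net: ReactionNetwork,
    fns: Mapping[Edge, Callable[[State], object]],
    x: State,
    check_support: bool = False,
) -> RateVector:
    """Evaluate user-supplied rate functions at a state.

    With ``check_support`` on, enforces the general-kinetics sign rule:
    the rate on ``i -> j`` is positive exactly when every species of the
    source complex ``y(i)`` is present in ``x``.  Mass action satisfies this
    automatically; arbitrary user kinetics need not, so the flag defaults off.
    """
    _check_state(x)
    supp_x = support(x)
    rates: RateVector = {}
    for (i, j) in net.edges:
        val = fns[(i, j)](x)
        if val < 0:
            raise ValueError(
                f"negative rate {val} on edge {net.label(i)} -> {net.label(j)}"
            )
        if check_support:
            should_be_positive = net.complexes[i].support() <= supp_x
            if (val > 0) != should_be_positive:
                raise SupportViolation(
                    f"rate on {net.label(i)} -> {net.label(j)} is "
                    f"{'positive' if val > 0 else 'zero'} but supp(y(i)) "
                    f"{'⊆' if should_be_positive else '⊄'} supp(x)"
                )
        rates[(i, j)] = val
    return rates


@dataclass
class GeneralizedKinetics:
    """Factorized kinetics r_ij(x) = k_ij * g_ij(x) * f_i(x).

    In enzyme mode the edge factor is symmetric (g_ij = g_ji pointwise), so
    the net rate on a reversible pair factors as
    g_ij(x) * (k_ij f_i(x) - k_ji f_j(x)); with f_i(x) = x^y(i) this is
    generalized mass action.  Formal balance then depends only on the k's.
    """

    k: RateConstants
    f: Mapping[int, Callable[[State], object]]
    g: Mapping[Edge, Callable[[State], object]]

    def rates(self, net: ReactionNetwork, x: State) -> RateVector:
        _check_state(x)
        out: RateVector = {}
        for (i, j) in net.edges:
            out[(i, j)] = self.k[(i, j)] * self.g[(i, j)](x) * self.f[i](x)
        return out

    @classmethod
    def generalized_mass_action(
        cls, net: ReactionNetwork, k: RateConstants,
        g: Mapping[Edge, Callable[[State], object]] | None = None,
    ) -> "GeneralizedKinetics":
        """Enzyme-type kinetics: f_i(x) = x^y(i), symmetric g (default 1)."""
        if g is None:
            g = {e: (lambda x: Fraction(1)) for e in net.edges}
        for (i, j) in net.edges:
            if (j, i) not in g:
                raise ValueError("edge factor must be defined on both orientations")
        f = {i: (lambda x, c=net.complexes[i]: monomial(x, c)) for i in range(net.n_vertices)}
        return cls(k=k, f=f, g=g)


def db_constants_from_state(
    net: ReactionNetwork,
    x: State,
    forward_k: Mapping[tuple[int, int], object],
) -> dict[Edge, Fraction]:
    """Build mass-action constants making a given positive state detailed-balanced.

    For each reversible pair (i, j) with supplied forward constant k_ij, sets
    k_ji = k_ij * x^y(i) / x^y(j), so that k_ij x^y(i) = k_ji x^y(j) by
    construction.  Used as the ground-truth positive control in balance tests.
    """
    for sp in net.species:
        if x.get(sp, 0) <= 0:
            raise ValueError(f"state must be strictly positive; {sp!r} is {x.get(sp, 0)}")
    k: dict[Edge, Fraction] = {}
    for (i, j) in net.reversible_pairs():
        kf = Fraction(forward_k[(i, j)])
        if kf <= 0:
            raise ValueError("forward rate constants must be positive")
        mi = Fraction(monomial(x, net.complexes[i]))
        mj = Fraction(monomial(x, net.complexes[j]))
        k[(i, j)] = kf
        k[(j, i)] = kf * mi / mj
    return k
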