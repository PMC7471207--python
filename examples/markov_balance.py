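"""Stationary vs reversible measures of two continuous-time Markov chains.

First the stochastic mass-action triangle: its stationary distribution is
product-form Poisson with unit means, but it is not reversible — the induced
graph decomposes into directed 3-cycles.  Then a birth-death chain on the
integers with rates growing away from the origin: it carries two distinct
stationary measures, one non-reversible (whose induced graph is a directed
path through the whole window) and one reversible.
"""

from fractions import Fraction

from crnbalance import (
    Window,
    induced_graph_mc,
    make_fixture,
    reversibility_check,
    stationarity_residuals,
    theorem4_analysis,
)

# -- stochastic triangle ---------------------------------------------------
f2 = make_fixture("example2_chain")
w2 = Window.box(f2.chain, (0, 0, 0), (6, 6, 6))
pi = f2.measures["pi"]

res = stationarity_residuals(f2.chain, pi, w2)
print("triangle chain: max |residual| on interior =",
      max(abs(float(v)) for v in res.values()))
print("reversible:", reversibility_check(f2.chain, pi, w2)[0])
rep = theorem4_analysis(f2.chain, pi, w2)
print("witness:", rep.witness_kind, rep.witness.vertices)

# -- birth-death chain on Z ------------------------------------------------
f3 = make_fixture("example3_chain", q=Fraction(1, 3))
w3 = Window.build(f3.chain, range(-10, 11))

for name in ("pi", "rho"):
    mu = f3.measures[name]
    res = stationarity_residuals(f3.chain, mu, w3)
    rev, _ = reversibility_check(f3.chain, mu, w3)
    g = induced_graph_mc(f3.chain, mu, w3)
    print(f"birth-death {name}: stationary residuals all zero ="
          f" {all(v == 0 for v in res.values())}, reversible = {rev},"
          f" directed edges = {len(g.directed)}")

rep = theorem4_analysis(f3.chain, f3.measures["pi"], w3)
print("pi witness:", rep.witness_kind,
      f"{rep.witness[0]} -> ... -> {rep.witness[-1]}")

# A stationary measure whose induced graph is not edge-balanced must exhibit
# a directed cycle (triangle chain) or, on the integers where no cycles
# exist, a directed path leaving through both window boundaries — the
# finite-window certificate for a bi-infinite directed path.
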