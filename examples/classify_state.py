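"""Classify the balance of a mass-action state of the cyclic network.

Builds the reversible triangle A <-> B <-> C <-> A with rate constants
(k_AB, k_BA, k_BC, k_CB, k_CA, k_AC) = (2, 1, 2, 1, 2, 1), evaluates the
rates at x = (1, 1, 1), and runs all six balance predicates.
"""

from fractions import Fraction

from crnbalance import classify, mass_action_rates, parse_network

net, _ = parse_network("A <-> B\nB <-> C\nC <-> A")
v = net.vertex_of
k = {
    (v("A"), v("B")): 2, (v("B"), v("A")): 1,
    (v("B"), v("C")): 2, (v("C"), v("B")): 1,
    (v("C"), v("A")): 2, (v("A"), v("C")): 1,
}
x = {sp: Fraction(1) for sp in net.species}
rates = mass_action_rates(net, k, x)

report = classify(net, rates)
print("verdicts:", report.as_dict())
print("induced graph directed edges:",
      sorted((net.label(a), net.label(b)) for a, b in report.graph.directed))
print("violating cycle:", [net.label(u) for u in report.witnesses["cycb"].vertices])

# At x = (1,1,1) every vertex receives and emits total rate 3, so the state
# is complex-balanced; but each forward rate (2) beats its reverse (1), so it
# is not detailed-balanced, and the induced graph is the directed 3-cycle
# A -> B -> C -> A: exactly the cycle that cycle balance forbids.
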