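"""Directions of the net reactions in a flow reactor, read off the graph.

Puts the thermodynamically closed triangle A <-> B <-> C <-> A in a flow
reactor by adding exchange reactions A <-> 0 <-> C, and classifies a
complex-balanced but not detailed-balanced rate assignment.  The point of
the case study: every edge direction of the induced graph is forced by
graph-theoretic reasoning alone, without computing the equilibrium.
"""

from crnbalance import (
    circuit_conditions,
    classify,
    find_directed_cycle,
    is_vertex_balanced,
    make_fixture,
)

f = make_fixture("flow_network")
net = f.network

report = classify(net, f.rates)
print("verdicts:", report.as_dict())

g = report.graph
print("vertex-balanced:", is_vertex_balanced(g)[0])
print("net reaction directions:",
      sorted(f"{net.label(a)}->{net.label(b)}" for a, b in g.directed))

cycle = find_directed_cycle(g)
print("directed cycle:", " -> ".join(net.label(u) for u in cycle.vertices))

conds, gamma = circuit_conditions(net, f.constants)
print(f"{len(conds)} circuit conditions, {gamma} independent:")
for c in conds:
    print(f"  {c.render(net)}   satisfied={c.satisfied}")

# The rate assignment is complex-balanced (db=False, cb=True).  The triangle's
# circuit condition holds (the closed subnetwork obeys thermodynamics), so the
# triangle cannot be a directed cycle; complex balance at the vertex 0 then
# forces C -> 0 -> A, and the only consistent orientation of the rest is
# C <- A -> B -> C.  The directed cycles run through the exchange reactions.
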