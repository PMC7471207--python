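# crnbalance

Graph-theoretic balance analysis for reversible chemical reaction networks
and continuous-time Markov chains.

## The problem

A reversible reaction network is a finite simple symmetric directed graph
`G = (V, R)` whose vertices carry *complexes* `y(i) ∈ ℝⁿ≥` (formal sums of
species), together with a kinetics `r: R → (ℝⁿ≥ → ℝ≥)` assigning each
reaction a rate function.  An equilibrium `x` of the dynamics
`dx/dt = Σ_{i→j} (y(j) − y(i)) r_{ij}(x)` can be balanced at several levels:

* **detailed balance (DB):** `r_ij(x) = r_ji(x)` on every reversible pair;
* **complex balance (CB):** at every vertex, incoming and outgoing rate sums
  agree;
* **formal balance (FB):** around every directed cycle `C`,
  `∏_{ij∈C} r_ij(x) = ∏_{ij∈C} r_ji(x)`;
* **strong cycle balance (sCycB) / cycle balance (CycB):** inequality
  relaxations of FB — no cycle may have all its net rates strictly one-sided.

All of these are properties of the *induced mixed graph* `G_x`, which has an
undirected edge where forward and backward rates are equal and a directed
edge toward the larger rate: DB ⟺ `G_x` edge-balanced, CB ⟹ `G_x`
vertex-balanced, sCycB ⟺ no weakly directed cycle, CycB ⟺ no directed
cycle.  Because a finite vertex-balanced mixed graph with no directed cycle
has no directed edge at all (provable by a short constructive walk), one
obtains, for **arbitrary kinetics and boundary equilibria**:

> **detailed balance = complex balance + cycle balance.**

The same argument transfers verbatim to continuous-time Markov chains with
symmetric transition support, where probability flows `μ(x)q(x,y)` play the
role of rates: reversible measures correspond to detailed balance,
stationary measures to complex balance, and a stationary non-reversible
measure forces a directed cycle *or a bi-infinite directed path* in the
induced graph.

The package decides all six predicates at a state (exact rational arithmetic
whenever inputs are rational), constructs the induced graph and explicit
witnesses (violating edges, residuals, cycles, paths), generates the
Wegscheider circuit conditions on mass-action rate constants with their
independent count `γ = r − m + ℓ`, counts the `δ = m − ℓ − s`
spanning-forest conditions via the deficiency, and runs the corresponding
window-limited analysis for lattice Markov chains.  It is for modellers in
chemical reaction network theory and applied probability who want balance
verdicts *with machine-checked proofs attached*: every call to `classify`
re-asserts the full implication chain between the predicates and raises if
any proven implication fails.

## A worked example

The reversible cyclic network `A ⇌ B ⇌ C ⇌ A` with rate constants
`k_AB = k_BC = k_CA = 2` and `k_BA = k_CB = k_AC = 1` at `x = (1, 1, 1)`
(see `examples/classify_state.py`):

```
verdicts: {'db': False, 'cb': True, 'wcb': True, 'fb': False, 'scycb': False, 'cycb': False, 'rtol': 1e-09}
induced graph directed edges: [('A', 'B'), ('B', 'C'), ('C', 'A')]
violating cycle: ['A', 'B', 'C', 'A']
```

Every vertex emits and receives total rate 3, so the state is
complex-balanced; each forward rate (2) beats its reverse (1), so it is not
detailed-balanced — and the induced graph is exactly the directed 3-cycle
that cycle balance forbids.  Putting the triangle in a flow reactor
(`examples/flow_reactor.py`) adds exchange reactions `A ⇌ 0 ⇌ C`; with the
triangle's circuit condition `k_AB·k_BC·k_CA = k_AC·k_CB·k_BA` satisfied,
the only feasible induced graph is `C ← A → B → C` plus `C → 0 → A`, and the
directed cycles run through the exchange reactions:

```
net reaction directions: ['0->A', 'A->B', 'A->C', 'B->C', 'C->0']
directed cycle: A -> B -> C -> 0 -> A
3 circuit conditions, 2 independent:
  k(A->B) * k(B->C) * k(C->A) = k(B->A) * k(C->B) * k(A->C)   satisfied=True
  ...
```

`examples/markov_balance.py` runs the stochastic counterpart: the
product-form Poisson distribution with unit means is stationary for the
triangle's CTMC (max interior residual ~3e-17 on a 0..6 cube) but not
reversible, with a directed 3-cycle witness; a birth-death chain on ℤ with
rates `q(x, x±1) ∝ q^{−|x|}` carries two distinct stationary measures — one
non-reversible whose induced graph is a directed path spanning the window,
one reversible and normalizable exactly for `q < 1/2`.

A thin CLI mirrors the library:

```sh
crnbalance summary NETWORK.txt
crnbalance classify NETWORK.txt --state '{"A": 1, "B": 1, "C": 1}' --dot gx.dot
crnbalance wegscheider NETWORK.txt
crnbalance mc-check --chain example3 --measure pi --window 10
```

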