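# Methods

## Model and scope

The package treats a reversible reaction network as a finite simple
symmetric directed graph with complex-labelled vertices, together with a
rate vector evaluated at a fixed state.  Everything it decides — detailed
balance (DB), complex balance (CB), weak complex balance (wCB), formal
balance (FB), strong cycle balance (sCycB) and cycle balance (CycB) — is a
property of that rate vector, so the library is a *checker at a state*, not
an equilibrium solver: finding states with a given balance property, tree
constants for complex balance, and ODE/stochastic simulation are all out of
scope.  The Markov-chain side carries the identical notions over to
probability flows `μ(x)q(x,y)` on chains with symmetric transition support.

The central device is the induced mixed graph: undirected edge where the
two opposing rates (flows) are equal, directed edge toward the larger one.
Each predicate has both a direct arithmetic formulation and a
graph-theoretic one, and `classify` always computes both and compares them;
a disagreement, or the failure of any proven implication between the
predicates (DB ⟹ CB, DB ⟹ FB, FB ⟹ CycB, sCycB ⟹ CycB, FB ⟹ sCycB for
positive rates, and the four-way equivalence of DB/FB/sCycB/CycB given CB
or wCB), raises `ConsistencyError`.  These internal assertions are the
library's continuous self-test; they can only fire on an implementation
bug, never on unusual input, which is why the CLI maps them to a separate
exit code (3) from user errors (2).

## Numerical policy

* **Exact arithmetic whenever possible.**  Stoichiometric coefficients,
  states, rate constants and rates are `fractions.Fraction` unless the user
  supplies floats; the stoichiometric rank is computed over ℚ with sympy, so
  the deficiency `δ = m − ℓ − s` is exact and its nonnegativity is asserted,
  never rounded into.  One column per reversible pair is used for the
  stoichiometric matrix, oriented lexicographically; rank is invariant under
  flipping column signs, so the orientation choice is immaterial.
* **Float comparisons.**  When any operand is a float, equality means
  `|a − b| ≤ rtol · max(1, |a|, |b|)` with `rtol = 1e-9` by default.  This
  makes the trichotomy equal / greater / smaller exhaustive and exclusive,
  which the induced-graph construction requires.  The underlying theory is
  stated over exact reals and fixes no tolerance semantics; this rule is our
  decision and the tolerance used is recorded in every `BalanceReport`.
* **Cycle products.**  FB compares products of rates; in float mode the
  comparison happens in log space to avoid under/overflow, and zero factors
  are handled exactly (a zero forward product matches only a zero backward
  product).  In rational mode products are exact.
* **Boundary states.**  All predicates operate on nonnegative states; zero
  rates fall out of the same definitions (0 = 0 gives an undirected edge,
  0 < r a directed one).  The implication FB ⟹ sCycB needs positive rates
  in general; for kinetics obeying the support rule (mass action in
  particular) it extends to boundary states, which `classify` asserts when
  told the kinetics has that property (`positive_rates_assumed=True`).
  The monomial convention is `0^0 = 1`, so exchange reactions sourced at the
  empty complex run at their rate constant.

## Algorithms

* **Directed-cycle detection** follows the constructive argument behind the
  main theorem: walk forward along directed edges until a vertex repeats.
  On vertex-balanced graphs the walk cannot get stuck while directed edges
  remain; on general graphs the implementation backtracks (an iterative
  DFS), so it is complete either way.  Ties among outgoing edges are broken
  by a deterministic label order (repr-lexicographic — the proof picks
  arbitrarily), and reported cycles are rotated to start at their minimal
  vertex so tests compare deterministically.
* **Weakly directed cycles** (≥ 1 directed edge, all directed edges
  agreeing with one traversal orientation) are found by enumerating
  elementary cycles of the underlying undirected graph and checking both
  orientations per cycle.
* **Cycle enumeration** delegates to `networkx.simple_cycles` on the
  underlying undirected graph (Johnson-style blocking search, each
  elementary cycle once).  Reversible pairs are directed 2-cycles on which
  every cycle condition holds trivially; they are excluded.  A configurable
  cap (default 10⁵ cycles) raises loudly rather than truncating silently,
  since a truncated enumeration could turn "balanced" verdicts vacuous.
* **Circuit conditions.**  One condition per elementary cycle (a cycle and
  its reversal give the same condition with sides swapped, so one
  representative is emitted).  The independent count is the cycle rank
  `γ = r − m + ℓ`; conditions lying in a fundamental cycle basis
  (`networkx.cycle_basis`) are marked, giving an explicit independent
  subset alongside the complete redundant list.  The `δ` spanning-forest
  conditions on equilibrium constants are counted via the deficiency but
  not generated symbolically — they require equilibrium-constant algebra
  outside this package's graph-theoretic scope.

## Markov chains on windows

Countable state spaces are handled through finite windows.  A state is
*interior* when all its neighbors lie in the window, and stationarity is
asserted on interior states only, which eliminates spurious truncation
residuals.  Reversibility and the induced graph are computed on all
in-window transitions.  "Bi-infinite directed path" is undecidable from a
finite window, so the witness produced for a stationary, non-reversible
measure without directed cycles is a *window-limited certificate*: a
directed path entering and leaving through the window boundary.  It is
evidence on the window, not a proof about the infinite graph, and is
labelled as such in `Theorem4Report`.

Default windows are the 0..6 cube for the three-species triangle chain
(343 states, 219 interior — large enough that the cycle structure is
visible, small enough for exact-ish arithmetic in well under a second) and
−10..10 for the birth-death chain on ℤ.  Both are configurable.  Measures
are supplied as pointwise densities, never tabulated, so growing the window
needs no re-specification.

The stochastic mass-action chain assigns the reaction `i → j` the
propensity `k_ij · ∏_s v_s!/(v_s − y(i)_s)!` (falling factorials), which
for unary complexes reduces to `k_ij` times the source species count.  Only
three of the six transition-rate rules of the triangle chain are pinned
down by the published rates (`2a`, `b`, `a`); the remaining constants
(`2c`, `2b`, `c` pattern, i.e. `k = (2,1,2,1,2,1)` around the cycle) are a
**reconstruction**, chosen as the assignment that is complex- but not
detailed-balanced at `x = (1,1,1)` consistent with the three known rules.
The reconstruction is validated by its stated consequences — the unit-mean
product-form Poisson distribution is stationary on the window interior to
machine precision, and the induced graph decomposes into directed
3-cycles — rather than taken as ground truth.

## Synthetic instances

Randomized instances (module `fixtures`) drive the property suites:

* **mass_action** — random integer constants, random rational states, each
  species independently zeroed with probability 0.2 (default) to exercise
  boundary states;
* **db** — constants solved from a random positive state by
  `k_ji = k_ij x^{y(i)}/x^{y(j)}`, giving detailed balance by construction
  (the positive control: all six predicates must come out true);
* **cb_flow** — rates built as a symmetric random baseline plus
  superposed circulation flows along random cycles of the graph.  The
  result is complex-balanced by construction but detailed-balanced only
  when the flows cancel, so these instances probe exactly the gap between
  CB and DB that cycle balance measures.

Default sizes are 3 species, 4 complexes, spanning tree plus 2 extra
reversible pairs — small enough that thousands of instances classify in
seconds, large enough to contain up to ~10 elementary cycles and all the
mixed-graph phenomena on which the theory turns.  Instances are
reproducible bytewise from `(seed, config)` via a single `random.Random`
stream.  What these synthetic systems do *not* emulate: realistic
thermodynamic parameter ranges, conservation-law structure of specific
biochemical pathways, or kinetics outside mass action; passing tests show
the logical structure of the balance theory is implemented correctly, not
that any particular biological network is balanced.

The exhaustive mixed-graph check enumerates all `4^6 = 4096` simple mixed
graphs on four vertices (each vertex pair absent, undirected, or directed
either way) and confirms that every vertex-balanced graph without a
directed cycle is edge-balanced, with the directed-cycle finder producing
an explicit witness in every non-edge-balanced vertex-balanced case.

## Known limitations

* Verdicts at float states inherit the tolerance rule; rates closer than
  `rtol` are declared equal, which can flip a predicate for nearly-balanced
  systems.  Supply rationals for exact verdicts.
* Cycle-based predicates cost one pass over all elementary cycles, which is
  exponential in the worst case; the cap makes this fail loudly.
* Duplicate complexes on distinct vertices are rejected, although the
  general theory permits arbitrary vertex labellings; none of the intended
  use cases need them.
* Window-limited Markov analysis cannot certify anything about the infinite
  chain beyond the window; in particular "no directed cycle in the window"
  does not preclude cycles elsewhere.
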