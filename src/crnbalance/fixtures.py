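"""Built-in example systems and randomized instance generators.

The catalog carries the worked examples used throughout:

* ``triangle``       the reversible cyclic network A <-> B <-> C <-> A with
                     the rate constants (2,1,2,1,2,1) whose deterministic
                     system is complex- but not detailed-balanced at
                     x = (1,1,1);
* ``flow_network``   the triangle plus exchange reactions A <-> 0 <-> C
                     (the triangle in a flow reactor), with a complex- but
                     not detailed-balanced rate assignment built from
                     circulation flows;
* ``single_reaction``  the irreversible A + B -> C toy (structural use only);
* ``example2_chain`` the stochastic mass-action CTMC of the triangle, whose
                     stationary distribution is product-form Poisson with
                     unit means;
* ``example3_chain`` the birth-death chain on the integers with rates
                     2 q^{-|x|} up and q^{-|x|} down.

Each fixture validates its structural numbers (vertex/edge counts, gamma,
delta) at construction time.

Random instances come in three kinetics modes: plain mass action (arbitrary
constants and states), DB-by-construction (constants solved so a drawn
positive state is detailed-balanced — the positive control), and CB-flow
(rates assembled from circulation flows superposed on a symmetric baseline —
complex-balanced by construction, detailed-balanced only if all flows
cancel).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction

from .cycle_conditions import enumerate_cycles
from .kinetics import db_constants_from_state, mass_action_rates
from .markov import (
    LatticeChain,
    Measure,
    geometric_chain,
    geometric_chain_reversible_measure,
    geometric_chain_stationary_measure,
    poisson_product_measure,
    stochastic_mass_action_chain,
)
from .network import ReactionNetwork, parse_network, summary

__all__ = ["make_fixture", "RandomInstanceConfig", "random_instance", "FIXTURE_NAMES"]

TRIANGLE_TEXT = """\
# reversible cyclic network
A <-> B
B <-> C
C <-> A
"""

FLOW_NETWORK_TEXT = """\
# triangle in a flow reactor: exchange reactions with the environment
A <-> B
B <-> C
C <-> A
A <-> 0
0 <-> C
"""

SINGLE_REACTION_TEXT = "A + B -> C\n"

#: Rate constants of the stochastic triangle: three of the six transition
#: rules are fixed by the printed rates 2a, b, a; the rest are reconstructed
#: by requiring complex balance (not detailed balance) at x = (1,1,1) and
#: validated by their consequences (product-form Poisson stationary
#: distribution, induced graph decomposing into directed 3-cycles).
TRIANGLE_CONSTANTS_BY_LABEL = {
    ("A", "B"): 2, ("B", "A"): 1,
    ("B", "C"): 2, ("C", "B"): 1,
    ("C", "A"): 2, ("A", "C"): 1,
}


def _relabel(net: ReactionNetwork, by_label: dict) -> dict:
    return {(net.vertex_of(a), net.vertex_of(b)): Fraction(v) for (a, b), v in by_label.items()}


@dataclass
class Fixture:
    name: str
    network: ReactionNetwork | None = None
    constants: dict | None = None
    rates: dict | None = None
    state: dict | None = None
    chain: LatticeChain | None = None
    measures: dict[str, Measure] | None = None
    notes: str = ""


def _triangle() -> Fixture:
    net, _ = parse_network(TRIANGLE_TEXT)
    sm = summary(net)
    assert (sm.m, sm.ell, sm.s, sm.delta, sm.gamma) == (3, 1, 2, 0, 1)
    k = _relabel(net, TRIANGLE_CONSTANTS_BY_LABEL)
    x = {sp: Fraction(1) for sp in net.species}
    return Fixture(
        name="triangle", network=net, constants=k, state=x,
        rates=mass_action_rates(net, k, x),
        notes="CB but not DB at (1,1,1); single circuit condition 2*2*2 != 1*1*1",
    )


def _flow_network() -> Fixture:
    net, _ = parse_network(FLOW_NETWORK_TEXT)
    sm = summary(net)
    assert (sm.m, sm.ell, sm.s, sm.delta, sm.gamma) == (4, 1, 3, 0, 2)
    assert len(net.edges) == 10
    # CB non-DB rates: unit symmetric baseline + circulation flows
    # phi1 = 3 on 0->A->C->0 and phi2 = 1 on 0->A->B->C->0, chosen so the
    # triangle circuit condition (1+phi2)^2 = 1+phi1 holds.  Net directions:
    # 0->A, A->B, A->C, B->C, C->0 — every exchange edge strictly forward.
    phi1, phi2 = Fraction(3), Fraction(1)
    rates = {e: Fraction(1) for e in net.edges}
    for cycle_labels, phi in ((["0", "A", "C", "0"], phi1), (["0", "A", "B", "C", "0"], phi2)):
        ids = [net.vertex_of(lbl) for lbl in cycle_labels]
        for a, b in zip(ids[:-1], ids[1:]):
            rates[(a, b)] += phi
    x = {sp: Fraction(1) for sp in net.species}
    return Fixture(
        name="flow_network", network=net, rates=rates, state=x,
        constants=dict(rates),  # mass-action constants realizing these rates at x = 1
        notes="complex-balanced, not detailed-balanced; triangle circuit condition holds",
    )


def _single_reaction() -> Fixture:
    net, _ = parse_network(SINGLE_REACTION_TEXT, permissive=True)
    assert net.n_vertices == 2 and len(net.edges) == 1
    assert net.complexes[0].vector(net.species) == (1, 1, 0)
    assert net.complexes[1].vector(net.species) == (0, 0, 1)
    return Fixture(name="single_reaction", network=net,
                   notes="irreversible toy network; structural summaries only")


def _example2_chain() -> Fixture:
    tri = _triangle()
    chain = stochastic_mass_action_chain(tri.network, tri.constants)
    return Fixture(
        name="example2_chain", network=tri.network, constants=tri.constants,
        chain=chain, measures={"pi": poisson_product_measure([1.0, 1.0, 1.0])},
        notes="stochastic triangle; stationary product-form Poisson, not reversible",
    )


def _example3_chain(q=Fraction(1, 3)) -> Fixture:
    chain = geometric_chain(q)
    return Fixture(
        name="example3_chain", chain=chain,
        measures={
            "pi": geometric_chain_stationary_measure(q),
            "rho": geometric_chain_reversible_measure(q),
        },
        notes=f"birth-death chain on Z with q={q}; pi stationary non-reversible, rho reversible",
    )


_BUILDERS = {
    "triangle": _triangle,
    "flow_network": _flow_network,
    "single_reaction": _single_reaction,
    "example2_chain": _example2_chain,
    "example3_chain": _example3_chain,
}

FIXTURE_NAMES = tuple(_BUILDERS)


def make_fixture(name: str, **kwargs) -> Fixture:
    """Build a named fixture; raises KeyError for unknown names."""
    if name not in _BUILDERS:
        raise KeyError(f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}")
    return _BUILDERS[name](**kwargs)


# -- random instances ------------------------------------------------------


@dataclass
class RandomInstanceConfig:
    """Reproducible configuration for random kinetic systems.

    ``mode`` is one of ``"mass_action"``, ``"db"`` (constants solved so the
    drawn positive state is detailed-balanced) or ``"cb_flow"`` (rates from
    circulation flows: complex-balanced by construction).
    ``boundary_prob`` is the chance that each species is set to zero in
    mass-action mode, exercising boundary states.
    """

    seed: int
    n_species: int = 3
    n_vertices: int = 4
    extra_edges: int = 2
    mode: str = "mass_action"
    boundary_prob: float = 0.2
    max_flows: int = 3


@dataclass
class RandomInstance:
    config: RandomInstanceConfig
    network: ReactionNetwork
    rates: dict
    constants: dict | None = None
    state: dict | None = None


def _random_network(rng: random.Random, cfg: RandomInstanceConfig) -> ReactionNetwork:
    species = [f"S{i}" for i in range(cfg.n_species)]
    complexes = set()
    while len(complexes) < cfg.n_vertices:
        c = tuple(rng.randint(0, 2) for _ in species)
        complexes.add(c)
    complexes = sorted(complexes)
    m = len(complexes)
    # random spanning tree, then extra edges
    order = list(range(m))
    rng.shuffle(order)
    pairs = set()
    for t in range(1, m):
        a = order[t]
        b = order[rng.randrange(t)]
        pairs.add((min(a, b), max(a, b)))
    candidates = [(i, j) for i in range(m) for j in range(i + 1, m) if (i, j) not in pairs]
    rng.shuffle(candidates)
    pairs.update(candidates[: cfg.extra_edges])
    edges = set()
    for i, j in pairs:
        edges.add((i, j))
        edges.add((j, i))
    from .network import Complex

    return ReactionNetwork(
        species=species,
        complexes=[Complex(dict(zip(species, c))) for c in complexes],
        edges=edges,
    )


def random_instance(cfg: RandomInstanceConfig) -> RandomInstance:
    """Draw a reproducible random kinetic system and state (exact rationals)."""
    rng = random.Random(cfg.seed)
    net = _random_network(rng, cfg)

    if cfg.mode == "cb_flow":
        rates = {e: Fraction(rng.randint(1, 5)) for e in net.reversible_pairs()}
        rates = {**rates, **{(j, i): v for (i, j), v in rates.items()}}
        cycles = enumerate_cycles(net)
        n_flows = rng.randint(0, cfg.max_flows) if cycles else 0
        for _ in range(n_flows):
            cyc = rng.choice(cycles)
            phi = Fraction(rng.randint(0, 4))
            steps = cyc.steps() if rng.random() < 0.5 else [(b, a) for a, b in reversed(cyc.steps())]
            for a, b in steps:
                rates[(a, b)] += phi
        return RandomInstance(config=cfg, network=net, rates=rates)

    x = {sp: Fraction(rng.randint(1, 5), rng.randint(1, 3)) for sp in net.species}
    if cfg.mode == "db":
        fwd = {p: Fraction(rng.randint(1, 9)) for p in net.reversible_pairs()}
        k = db_constants_from_state(net, x, fwd)
    elif cfg.mode == "mass_action":
        k = {e: Fraction(rng.randint(1, 9)) for e in net.edges}
        for sp in net.species:
            if rng.random() < cfg.boundary_prob:
                x[sp] = Fraction(0)
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")
    rates = mass_action_rates(net, k, x)
    return RandomInstance(config=cfg, network=net, rates=rates, constants=k, state=x)
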