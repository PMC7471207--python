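"""Markov-chain balance: stationarity, reversibility, induced graphs."""

from fractions import Fraction

import math

import pytest

from crnbalance import (
    Measure,
    Window,
    induced_graph_mc,
    is_edge_balanced,
    is_vertex_balanced,
    poisson_product_measure,
    reversibility_check,
    stationarity_residuals,
    theorem4_analysis,
)
from crnbalance.markov import (
    LatticeChain,
    chain_from_network,
    geometric_chain,
    geometric_chain_reversible_normalizable,
)


@pytest.fixture(scope="module")
def ex2_window(example2):
    return Window.box(example2.chain, (0, 0, 0), (6, 6, 6))


@pytest.fixture(scope="module")
def ex3_window(example3):
    return Window.build(example3.chain, range(-10, 11))


class TestChainConstructors:
    def test_stochastic_triangle_matches_printed_rules(self, example2):
        q = example2.chain.rate
        assert q((3, 1, 2), (2, 2, 2)) == 6      # A -> B at rate 2a
        assert q((3, 1, 2), (4, 0, 2)) == 1      # B -> A at rate b
        assert q((3, 1, 2), (2, 1, 3)) == 3      # A -> C at rate a
        assert q((3, 1, 2), (3, 0, 3)) == 2      # B -> C at rate 2b
        assert q((3, 1, 2), (4, 1, 1)) == 4      # C -> A at rate 2c
        assert q((3, 1, 2), (3, 2, 1)) == 2      # C -> B at rate c

    def test_empty_state_has_no_transitions(self, example2):
        assert example2.chain.neighbors((0, 0, 0)) == []

    def test_geometric_chain_rates(self, example3):
        q = example3.chain.rate
        assert q(2, 3) == 18       # 2 * 3^2 at q = 1/3
        assert q(0, 1) == 2        # |x| = 0
        assert q(-2, -3) == 9
        assert q(0, 5) == 0        # only nearest neighbors

    def test_geometric_parameter_domain(self):
        for bad in (0, 1, Fraction(3, 2)):
            with pytest.raises(ValueError):
                geometric_chain(bad)

    def test_poisson_measure_values(self):
        mu = poisson_product_measure([1.0, 1.0, 1.0])
        assert mu((0, 0, 0)) == pytest.approx(math.exp(-3))
        assert mu((2, 1, 0)) == pytest.approx(math.exp(-3) / 2)
        # partial sums over growing cubes stay below 1 and converge to it
        totals = [
            sum(mu((a, b, c)) for a in range(n) for b in range(n) for c in range(n))
            for n in (4, 8, 16)
        ]
        assert totals == sorted(totals) and totals[-1] <= 1 + 1e-12
        assert totals[-1] == pytest.approx(1.0, abs=1e-10)

    def test_poisson_rejects_nonpositive_means(self):
        with pytest.raises(ValueError):
            poisson_product_measure([1.0, 0.0])


class TestStationarity:
    def test_poisson_is_stationary_for_triangle_chain(self, example2, ex2_window):
        res = stationarity_residuals(example2.chain, example2.measures["pi"], ex2_window)
        assert len(res) == len(ex2_window.interior) > 0
        assert max(abs(float(v)) for v in res.values()) < 1e-14

    def test_geometric_pi_is_stationary(self, example3, ex3_window):
        res = stationarity_residuals(example3.chain, example3.measures["pi"], ex3_window)
        assert all(v == 0 for v in res.values())  # exact rationals

    def test_uniform_measure_is_not_stationary(self, example3, ex3_window):
        uniform = Measure(density=lambda x: Fraction(1))
        res = stationarity_residuals(example3.chain, uniform, ex3_window)
        assert any(v != 0 for v in res.values())

    def test_empty_interior_rejected(self, example3):
        tiny = Window.build(example3.chain, [0, 1])
        with pytest.raises(ValueError):
            stationarity_residuals(example3.chain, example3.measures["pi"], tiny)


class TestReversibility:
    def test_rho_is_reversible(self, example3, ex3_window):
        ok, witness = reversibility_check(example3.chain, example3.measures["rho"], ex3_window)
        assert ok and witness is None

    def test_pi_is_not_reversible(self, example3, ex3_window):
        ok, (x, y) = reversibility_check(example3.chain, example3.measures["pi"], ex3_window)
        assert not ok and abs(x - y) == 1

    def test_symmetric_rates_uniform_measure(self):
        chain = LatticeChain(
            rate=lambda x, y: 1 if abs(x - y) == 1 else 0,
            neighbors=lambda x: [x - 1, x + 1],
        )
        w = Window.build(chain, range(0, 8))
        ok, _ = reversibility_check(chain, Measure(density=lambda x: 1), w)
        assert ok


class TestInducedGraph:
    def test_ex2_graph_fully_directed_into_3cycles(self, example2, ex2_window):
        g = induced_graph_mc(example2.chain, example2.measures["pi"], ex2_window)
        assert not g.undirected and g.directed
        # every directed edge with interior head closes a directed 3-cycle
        interior = set(ex2_window.interior)
        dirset = g.directed
        outs = {}
        for a, b in dirset:
            outs.setdefault(a, []).append(b)
        for (x, y) in dirset:
            if y not in interior:
                continue
            assert any((z, x) in dirset for z in outs.get(y, [])), (x, y)

    def test_ex3_pi_graph_is_spanning_directed_path(self, example3, ex3_window):
        g = induced_graph_mc(example3.chain, example3.measures["pi"], ex3_window)
        assert not g.undirected
        assert g.directed == {(x, x + 1) for x in range(-10, 10)}
        assert is_vertex_balanced(g)[0] is False  # window ends are unbalanced

    def test_ex3_rho_graph_is_edge_balanced(self, example3, ex3_window):
        g = induced_graph_mc(example3.chain, example3.measures["rho"], ex3_window)
        assert is_edge_balanced(g)


class TestTheorem4:
    def test_ex2_witness_is_directed_3cycle(self, example2, ex2_window):
        rep = theorem4_analysis(example2.chain, example2.measures["pi"], ex2_window)
        assert rep.stationary and not rep.reversible and not rep.edge_balanced
        assert rep.witness_kind == "directed_cycle" and len(rep.witness) == 3

    def test_ex3_pi_witness_spans_the_window(self, example3, ex3_window):
        rep = theorem4_analysis(example3.chain, example3.measures["pi"], ex3_window)
        assert rep.witness_kind == "boundary_path"
        assert rep.witness[0] == -10 and rep.witness[-1] == 10

    def test_ex3_rho_needs_no_witness(self, example3, ex3_window):
        rep = theorem4_analysis(example3.chain, example3.measures["rho"], ex3_window)
        assert rep.reversible and rep.edge_balanced and rep.witness_kind is None

    def test_non_stationary_measure_rejected(self, example3, ex3_window):
        with pytest.raises(ValueError):
            theorem4_analysis(example3.chain, Measure(density=lambda x: 1), ex3_window)


class TestNormalizability:
    @pytest.mark.parametrize(
        "q, expected",
        [(Fraction(2, 5), True), (Fraction(3, 5), False), (Fraction(1, 3), True)],
    )
    def test_rho_normalizable_iff_q_below_half(self, q, expected):
        assert geometric_chain_reversible_normalizable(q) is expected

    def test_two_distinct_stationary_measures(self, example3, ex3_window):
        """pi and rho are both stationary but differ: no positive recurrence."""
        for name in ("pi", "rho"):
            res = stationarity_residuals(example3.chain, example3.measures[name], ex3_window)
            assert all(v == 0 for v in res.values())
        pi, rho = example3.measures["pi"], example3.measures["rho"]
        ratios = {Fraction(pi(x)) / Fraction(rho(x)) for x in range(-3, 4)}
        assert len(ratios) > 1  # not proportional


class TestCorrespondenceWithReactionNetworks:
    def test_network_encoded_as_chain_gives_same_induced_graph(self, triangle):
        """mu(i) * q(i,j) = r_ij reproduces the reaction-network induced graph."""
        from crnbalance import induced_graph

        net, rates = triangle.network, triangle.rates
        chain = chain_from_network(net, lambda i: 1, lambda i, j: rates[(i, j)])
        w = Window.build(chain, range(net.n_vertices))
        g_mc = induced_graph_mc(chain, Measure(density=lambda i: Fraction(1)), w)
        g_rn = induced_graph(net, rates)
        assert g_mc.directed == g_rn.directed
        assert g_mc.undirected == g_rn.undirected
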