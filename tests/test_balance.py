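"""The six balance predicates, the induced graph, and their interplay."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crnbalance import (
    RandomInstanceConfig,
    check_complex_balance,
    check_cycle_balance,
    check_detailed_balance,
    check_formal_balance,
    classify,
    db_constants_from_state,
    find_directed_cycle,
    induced_graph,
    is_edge_balanced,
    is_vertex_balanced,
    mass_action_rates,
    parse_network,
    random_instance,
)
from crnbalance.balance import compare


def db_rates(net, seed=0):
    import random

    rng = random.Random(seed)
    x = {sp: Fraction(rng.randint(1, 5)) for sp in net.species}
    k = db_constants_from_state(net, x, {p: rng.randint(1, 9) for p in net.reversible_pairs()})
    return mass_action_rates(net, k, x)


class TestInducedGraph:
    def test_db_rates_give_all_undirected(self, triangle):
        net = triangle.network
        g = induced_graph(net, db_rates(net))
        assert is_edge_balanced(g) and len(g.undirected) == 3

    def test_triangle_reference_rates_give_directed_3cycle(self, triangle):
        g = induced_graph(triangle.network, triangle.rates)
        assert len(g.directed) == 3 and not g.undirected
        assert find_directed_cycle(g) is not None

    def test_flow_network_reference_graph(self, flow_network):
        """The feasible induced graph: C <- A -> B -> C plus C -> 0 -> A."""
        net = flow_network.network
        g = induced_graph(net, flow_network.rates)
        lbl = net.vertex_of
        assert g.directed == {
            (lbl("0"), lbl("A")), (lbl("A"), lbl("B")), (lbl("A"), lbl("C")),
            (lbl("B"), lbl("C")), (lbl("C"), lbl("0")),
        }
        assert is_vertex_balanced(g)[0]

    def test_asymmetric_network_rejected(self):
        net, _ = parse_network("A -> B", permissive=True)
        with pytest.raises(KeyError):
            induced_graph(net, {(0, 1): 1})


class TestDetailedBalance:
    def test_reference_triangle_fails_with_edge_witness(self, triangle):
        ok, witness = check_detailed_balance(triangle.network, triangle.rates)
        assert not ok and witness in triangle.network.edges

    def test_all_zero_rates_are_db(self, triangle):
        """A boundary equilibrium with empty support is detailed-balanced."""
        rates = {e: Fraction(0) for e in triangle.network.edges}
        assert check_detailed_balance(triangle.network, rates)[0]


class TestComplexBalance:
    def test_reference_triangle_is_cb(self, triangle):
        ok, residuals = check_complex_balance(triangle.network, triangle.rates)
        assert ok and all(v == 0 for v in residuals.values())

    def test_single_pair_imbalance_residual(self):
        net, _ = parse_network("A <-> B")
        i, j = net.vertex_of("A"), net.vertex_of("B")
        ok, residuals = check_complex_balance(net, {(i, j): 2, (j, i): 1})
        assert not ok and residuals[i] == 1 and residuals[j] == -1


class TestFormalBalance:
    def test_triangle_circuit_product(self, triangle):
        """FB on the triangle iff k_AB k_BC k_CA = k_AC k_CB k_BA: 8 != 1."""
        import math

        ok, per_cycle = check_formal_balance(triangle.network, triangle.rates)
        assert not ok
        [res] = per_cycle
        products = {math.prod(res["forward"]), math.prod(res["backward"])}
        assert products == {Fraction(8), Fraction(1)}

    def test_tree_network_vacuously_fb(self):
        net, _ = parse_network("A <-> B\nB <-> C")
        k = {e: Fraction(i + 2) for i, e in enumerate(sorted(net.edges))}
        ok, per_cycle = check_formal_balance(net, k)
        assert ok and per_cycle == []

    def test_zero_rates_on_cycle(self, triangle):
        """Zero forward product matches only a zero backward product."""
        net = triangle.network
        rates = {e: Fraction(1) for e in net.edges}
        a, b = net.vertex_of("A"), net.vertex_of("B")
        rates[(a, b)] = Fraction(0)
        assert not check_formal_balance(net, rates)[0]
        rates[(b, a)] = Fraction(0)
        assert check_formal_balance(net, rates)[0]


class TestCycleBalance:
    def test_reference_triangle_fails_both(self, triangle):
        net, r = triangle.network, triangle.rates
        assert not check_cycle_balance(net, r, strong=True)[0]
        assert not check_cycle_balance(net, r, strong=False)[0]

    def test_db_rates_pass_both(self, triangle):
        net = triangle.network
        r = db_rates(net)
        assert check_cycle_balance(net, r, strong=True)[0]
        assert check_cycle_balance(net, r, strong=False)[0]

    def test_mixed_signs_are_strongly_balanced(self, triangle):
        net = triangle.network
        lbl = net.vertex_of
        r = {e: Fraction(1) for e in net.edges}
        r[(lbl("A"), lbl("B"))] = Fraction(1, 2)   # A->B slower than B->A
        r[(lbl("B"), lbl("C"))] = Fraction(2)      # B->C faster than C->B
        ok, _ = check_cycle_balance(net, r, strong=True)
        assert ok

    def test_equal_rates_cycle_is_strong_but_onesided_is_not(self, triangle):
        net = triangle.network
        lbl = net.vertex_of
        # all three net rates weakly one-sided with one equality: CycB holds,
        # sCycB fails (no strict edge in the other direction)
        r = {e: Fraction(1) for e in net.edges}
        r[(lbl("A"), lbl("B"))] = Fraction(2)
        assert check_cycle_balance(net, r, strong=False)[0]
        assert not check_cycle_balance(net, r, strong=True)[0]


class TestClassify:
    def test_db_fixture_all_true(self, triangle):
        net = triangle.network
        rep = classify(net, db_rates(net))
        assert rep.db and rep.cb and rep.wcb and rep.fb and rep.scycb and rep.cycb
        assert rep.witnesses == {}

    def test_cb_non_db_equilibrium(self, flow_network):
        """CB without DB forces all cycle-type predicates false."""
        rep = classify(flow_network.network, flow_network.rates)
        assert rep.cb and rep.wcb
        assert not rep.db and not rep.fb and not rep.scycb and not rep.cycb
        assert "db" in rep.witnesses and "cycb" in rep.witnesses

    def test_float_rates_use_relative_tolerance(self, triangle):
        net = triangle.network
        r = {e: 1.0 + 1e-13 * i for i, e in enumerate(sorted(net.edges))}
        rep = classify(net, r)
        assert rep.db  # differences far below tolerance count as equal
        assert rep.rtol == 1e-9

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=120, deadline=None)
    def test_no_implication_violations_on_random_kinetics(self, seed):
        """Implication chains never break on random mass-action instances,
        including boundary states (classify raises internally otherwise)."""
        inst = random_instance(RandomInstanceConfig(seed=seed, mode="mass_action"))
        classify(inst.network, inst.rates, positive_rates_assumed=None)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=120, deadline=None)
    def test_cycb_equivalent_to_db_given_cb(self, seed):
        """On CB-by-construction flows, cycle balance holds iff detailed balance."""
        inst = random_instance(RandomInstanceConfig(seed=seed, mode="cb_flow"))
        rep = classify(inst.network, inst.rates)
        assert rep.cb
        assert rep.cycb == rep.db == rep.fb == rep.scycb

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=60, deadline=None)
    def test_boundary_mass_action_respects_support_implication(self, seed):
        """FB => sCycB also at boundary states under mass action."""
        inst = random_instance(
            RandomInstanceConfig(seed=seed, mode="mass_action", boundary_prob=0.5)
        )
        classify(inst.network, inst.rates, positive_rates_assumed=True)


class TestComparator:
    def test_rational_comparison_is_exact(self):
        a = Fraction(1, 3) + Fraction(1, 3) + Fraction(1, 3)
        assert compare(a, 1) == 0
        assert compare(Fraction(10**15), Fraction(10**15) + 1) == -1

    def test_float_trichotomy(self):
        assert compare(1.0, 1.0 + 1e-12) == 0
        assert compare(1.0, 1.0 + 1e-6) == -1
        assert compare(2.0, 1.0) == 1
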