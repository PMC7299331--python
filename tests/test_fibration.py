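import numpy as np
import pytest
from hypothesis import given, strategies as st

from fibercircuits import (
    GOLDEN_RATIO,
    DynamicsSpec,
    DriveSignal,
    NetworkIntegrityError,
    RegulatoryNetwork,
    branching_ratio,
    classify_fiber,
    frustration_count,
    input_tree,
    input_tree_classes,
    make_circuit,
    minimal_balanced_coloring,
    quotient_base,
    sat_classify,
    simulate,
    sync_error,
    trees_isomorphic,
)

from oracle_matchers import random_network


def fiber_sets(partition):
    return {frozenset(genes) for genes in partition.fibers.values()}


@pytest.fixture
def fibonacci_base():
    """Two-gene dual-feedback loop: self-loop on Y, X -> Y, Y -> X."""
    return RegulatoryNetwork(
        edges=[("Y", "Y", "-"), ("X", "Y", "-"), ("Y", "X", "-")]
    )


@pytest.fixture
def n2_base():
    """Two coupled autoregulators: branching ratio 2."""
    return RegulatoryNetwork(
        edges=[("X", "X", "+"), ("Y", "Y", "+"), ("X", "Y", "+"),
               ("Y", "X", "+")]
    )


class TestMinimalBalancedColoring:
    def test_ffl_has_no_symmetry(self, ffl):
        assert fiber_sets(minimal_balanced_coloring(ffl)) == {
            frozenset({"X"}), frozenset({"Y"}), frozenset({"Z"})
        }

    def test_sat_fff_fiber(self, sat_fff):
        assert fiber_sets(minimal_balanced_coloring(sat_fff)) == {
            frozenset({"X"}), frozenset({"Y", "Z"})
        }

    def test_edgeless_network_single_fiber(self):
        net = RegulatoryNetwork(genes=["a", "b", "c", "d"])
        assert fiber_sets(minimal_balanced_coloring(net)) == {
            frozenset({"a", "b", "c", "d"})
        }

    def test_signs_split_fibers(self):
        # two targets of the same regulator but with opposite signs
        net = RegulatoryNetwork(
            edges=[("Y", "Y", "-"), ("Y", "A", "+"), ("Y", "B", "-")]
        )
        assert fiber_sets(minimal_balanced_coloring(net)) == {
            frozenset({"Y", "B"}), frozenset({"A"})
        }

    def test_refinement_monotone_and_bounded(self):
        for seed in range(25):
            net = random_network(seed, n_min=5, n_max=10)
            p = minimal_balanced_coloring(net)
            assert p.rounds <= net.n_genes() + 1
            assert all(
                a <= b for a, b in zip(p.class_counts, p.class_counts[1:])
            )

    def test_empty_network(self):
        p = minimal_balanced_coloring(RegulatoryNetwork())
        assert p.coloring == {} and p.fibers == {}


class TestInputTree:
    def test_ar_loop_q_constant(self):
        net = RegulatoryNetwork(edges=[("Y", "Y", "-")])
        assert input_tree(net, "Y", 8).Q == [1] * 8

    def test_fibonacci_sequence(self, fibonacci_base):
        assert input_tree(fibonacci_base, "Y", 8).Q == [1, 2, 3, 5, 8, 13, 21, 34]

    def test_no_in_edges_dies_out(self, ffl):
        assert input_tree(ffl, "X", 5).Q == [1, 0, 0, 0, 0]

    def test_layers_match_counts_and_members(self, sat_fff):
        tree = input_tree(sat_fff, "Z", 4)
        assert [len(layer) for layer in tree.layers] == tree.Q[: len(tree.layers)]
        assert {g for g, _ in tree.layers[1]} == {"X", "Y"}

    def test_deep_counts_without_materialization(self, fibonacci_base):
        tree = input_tree(fibonacci_base, "Y", 41, max_nodes=1000)
        assert tree.truncated
        assert tree.Q[40] == tree.Q[39] + tree.Q[38]  # exact big integers

    def test_unknown_root_raises(self, ffl):
        with pytest.raises(KeyError):
            input_tree(ffl, "nope", 3)


class TestTreesIsomorphic:
    def test_sat_fff_y_z_isomorphic(self, sat_fff):
        d = 4
        ty = input_tree(sat_fff, "Y", d)
        tz = input_tree(sat_fff, "Z", d)
        tx = input_tree(sat_fff, "X", d)
        assert trees_isomorphic(ty, tz)
        assert not trees_isomorphic(tx, ty)
        assert trees_isomorphic(ty, ty)

    def test_depth_mismatch_rejected(self, sat_fff):
        with pytest.raises(ValueError):
            trees_isomorphic(
                input_tree(sat_fff, "Y", 3), input_tree(sat_fff, "Z", 4)
            )

    def test_across_networks(self, sat_fff):
        other = make_circuit("SAT_FFF", prefix="p_")
        a = input_tree(sat_fff, "Y", 4)
        b = input_tree(other, "p_Z", 4)
        assert trees_isomorphic(a, b)


class TestBranchingRatio:
    def test_canonical_values(self, fibonacci_base, n2_base):
        ar = RegulatoryNetwork(edges=[("Y", "Y", "-")])
        assert round(branching_ratio(ar, "Y", 40), 4) == 1.0
        assert round(branching_ratio(fibonacci_base, "Y", 41), 4) == 1.6180
        assert abs(branching_ratio(fibonacci_base, "Y", 41) - GOLDEN_RATIO) < 1e-6
        assert round(branching_ratio(n2_base, "Y", 20), 4) == 2.0

    def test_dead_tree_returns_zero(self, ffl):
        assert branching_ratio(ffl, "X", 10) == 0.0

    def test_q_recurrences_exact(self, fibonacci_base, n2_base):
        ar = RegulatoryNetwork(edges=[("Y", "Y", "-")])
        Q = input_tree(ar, "Y", 30).Q
        assert all(Q[t] == Q[t - 1] for t in range(1, 30))
        Q = input_tree(fibonacci_base, "Y", 30).Q
        assert all(Q[t] == Q[t - 1] + Q[t - 2] for t in range(2, 30))
        Q = input_tree(n2_base, "Y", 30).Q
        assert all(Q[t] == 2 * Q[t - 1] for t in range(1, 30))


class TestQuotientBase:
    def test_sat_fff_collapses_to_ar_plus_input(self, sat_fff):
        p = minimal_balanced_coloring(sat_fff)
        base = quotient_base(sat_fff, p)
        assert base.network.genes == {"X", "Y"}
        assert base.network.has_edge("X", "Y")
        assert base.network.has_edge("Y", "Y")
        assert not base.network.has_edge("Y", "X")
        assert all(m == 1 for m in base.multiplicity.values())

    def test_ffl_base_identical(self, ffl):
        p = minimal_balanced_coloring(ffl)
        base = quotient_base(ffl, p)
        assert base.network == ffl

    def test_singleton_ar_identity(self):
        net = RegulatoryNetwork(edges=[("Y", "Y", "-")])
        base = quotient_base(net, minimal_balanced_coloring(net))
        assert base.network == net

    def test_unbalanced_partition_rejected(self, ffl):
        from fibercircuits.fibration import FiberPartition

        bad = FiberPartition(
            coloring={"X": 0, "Y": 0, "Z": 1},
            fibers={0: {"X", "Y"}, 1: {"Z"}},
        )
        with pytest.raises(NetworkIntegrityError):
            quotient_base(ffl, bad)

    @pytest.mark.parametrize("kind", ["SAT_FFF", "UNSAT_FFF"])
    def test_base_reproduces_member_trajectory(self, kind):
        # simulating the collapsed base gives the synchronized fiber
        # trajectory of the full circuit
        net = make_circuit(kind)
        spec = DynamicsSpec(
            alpha=0.205, gamma={"X": 0.454, "Y": 0.454},
            k={"X": 0.5, "Y": 1.0},
        )
        drive = {"X": DriveSignal("constant", level=1.0)}
        full = simulate(net, spec, {"Y": 0.5, "Z": 0.5}, drive, T=400)
        base = quotient_base(net, minimal_balanced_coloring(net)).network
        small = simulate(base, spec, {"Y": 0.5}, drive, T=400)
        assert np.max(np.abs(full["Y"] - small["Y"])) == 0.0
        assert sync_error(full, "Y", "Z") == 0.0


class TestClassifyFiber:
    def test_sat_fff_class(self, sat_fff):
        p = minimal_balanced_coloring(sat_fff)
        fc = classify_fiber(sat_fff, {"Y", "Z"}, p)
        assert fc.label == "FFF |1,1>" and fc.ell == 1
        assert fc.n == pytest.approx(1.0)

    def test_isolated_ar_gene(self):
        net = RegulatoryNetwork(edges=[("Y", "Y", "-")])
        p = minimal_balanced_coloring(net)
        fc = classify_fiber(net, {"Y"}, p)
        assert fc.label == "AR |1,0>" and fc.ell == 0

    def test_fibonacci_class_and_recurrence(self, fibonacci_base):
        p = minimal_balanced_coloring(fibonacci_base)
        fc = classify_fiber(fibonacci_base, {"Y"}, p)
        assert fc.label == "Fibonacci"
        assert fc.n == pytest.approx(GOLDEN_RATIO, abs=1e-4)
        assert (fc.m, fc.d) == (1, 2)

    def test_n2_class(self, n2_base):
        p = minimal_balanced_coloring(n2_base)
        fc = classify_fiber(n2_base, {"X", "Y"}, p)
        assert fc.label == "n = 2"
        assert fc.m in (None, 0)


class TestFrustration:
    def test_unsat_fff_all_high_two_unsatisfied(self, unsat_fff):
        assert frustration_count(unsat_fff, {"X": 1, "Y": 1, "Z": 1}) == 2

    def test_sat_fff_all_high_satisfied(self, sat_fff):
        assert frustration_count(sat_fff, {"X": 1, "Y": 1, "Z": 1}) == 0
        assert sat_classify(sat_fff) == "SAT"

    def test_repressor_ar_is_frustrated(self):
        net = RegulatoryNetwork(edges=[("Y", "Y", "-")])
        assert sat_classify(net) == "UNSAT"

    def test_unsat_fff_classification(self, unsat_fff):
        assert sat_classify(unsat_fff) == "UNSAT"

    def test_unknown_sign_unsupported(self):
        net = RegulatoryNetwork(edges=[("A", "B", "?")])
        with pytest.raises(NetworkIntegrityError):
            frustration_count(net, {"A": 1, "B": 1})

    def test_too_large_for_exhaustive_search(self):
        net = RegulatoryNetwork(
            edges=[(f"g{i}", f"g{i+1}", "+") for i in range(24)]
        )
        with pytest.raises(ValueError):
            sat_classify(net)


class TestOracleEquivalence:
    """Fibers from refinement coincide with input-tree isomorphism classes."""

    def test_exhaustive_two_node_graphs_with_self_loops(self):
        from itertools import product

        from fibercircuits import Sign

        genes = ["a", "b"]
        positions = [(u, v) for u in genes for v in genes]
        states = (None, Sign.ACTIVATOR, Sign.REPRESSOR, Sign.UNKNOWN)
        for assignment in product(range(4), repeat=4):
            net = RegulatoryNetwork(genes=genes)
            for (u, v), s in zip(positions, assignment):
                if s:
                    net.add_edge(u, v, states[s])
            p = minimal_balanced_coloring(net)
            cls = input_tree_classes(net, 2)
            same_fiber = p.coloring["a"] == p.coloring["b"]
            same_tree = cls["a"] == cls["b"]
            assert same_fiber == same_tree, sorted(net.edges)

    @given(st.integers(0, 300))
    def test_random_graphs(self, seed):
        net = random_network(seed, n_min=4, n_max=7)
        p = minimal_balanced_coloring(net)
        cls = input_tree_classes(net, net.n_genes())
        genes = sorted(net.genes)
        for i, gi in enumerate(genes):
            for gj in genes[i + 1:]:
                assert (p.coloring[gi] == p.coloring[gj]) == (
                    cls[gi] == cls[gj]
                )
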