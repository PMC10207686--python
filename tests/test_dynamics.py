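"""STG generation, attractors, constant states, preservation guarantees."""

import dataclasses

import pytest

import bbereduce as bb
from bbereduce.dynamics import PARTIALLY_ASYNC, SYNCHRONOUS
from bbereduce.errors import SizeGuardError
from bbereduce.partitions import canonical_partition


class TestGenerateSTG:
    def test_toy_chain_synchronous(self, toy_chain):
        stg = bb.generate_stg(toy_chain)
        assert stg.n_states == 8
        edges = set(stg.edges())
        i110, i111 = int("110", 2), int("111", 2)
        assert (i110, i111) in edges and (i111, i110) in edges
        # synchronous: exactly one successor per state
        assert len(edges) == 8
        assert len({s for s, _ in edges}) == 8

    def test_single_identity_variable(self):
        stg = bb.generate_stg(bb.parse_bnet("a, a"))
        assert set(stg.edges()) == {(0, 0), (1, 1)}

    def test_tlr5_printed_edge(self, tlr5):
        stg = bb.generate_stg(tlr5)
        assert (int("10000", 2), int("11100", 2)) in set(stg.edges())

    def test_fully_async_blocks_give_out_degree_two(self):
        bn = bb.parse_bnet("a, b\nb, !a")
        k = bb.singleton_partition(bn)
        stg = bb.generate_stg(bn, PARTIALLY_ASYNC, sync_partition=k)
        assert len(stg.successors) == 2
        for s in range(4):
            assert len([t for src, t in stg.edges() if src == s]) == 2

    def test_maximal_sync_partition_equals_synchronous(self):
        bn = bb.random_bn(bb.GeneratorConfig(n=6, k=2, seed=3))
        sync = bb.generate_stg(bn)
        k = bb.maximal_partition(bn)
        pasync = bb.generate_stg(bn, PARTIALLY_ASYNC, sync_partition=k)
        assert len(pasync.successors) == 1
        assert (pasync.successors[0] == sync.successors[0]).all()

    def test_size_guard_refusal(self):
        bn = bb.random_bn(bb.GeneratorConfig(n=25, k=2, seed=0))
        with pytest.raises(SizeGuardError, match="24"):
            bb.generate_stg(bn)
        # but the cap is configurable
        small = bb.random_bn(bb.GeneratorConfig(n=5, k=2, seed=0))
        with pytest.raises(SizeGuardError):
            bb.generate_stg(small, max_vars=4)


class TestAttractors:
    def test_four_steady_states(self, four_steady):
        atts = bb.attractors(four_steady)
        assert len(atts) == 4
        assert all(a.steady_state for a in atts)
        assert {a.state_strings()[0] for a in atts} == {"000", "010", "100", "111"}

    def test_toy_chain_two_cycle(self, toy_chain):
        atts = bb.attractors(toy_chain)
        cycles = [a for a in atts if len(a) == 2]
        assert len(cycles) == 1
        assert set(cycles[0].state_strings()) == {"110", "111"}
        assert not cycles[0].steady_state

    def test_negation_network_has_no_steady_states(self):
        bn = bb.parse_bnet("a, !a\nb, !b")
        assert bb.attractors(bn, strategy="sat-steady") == []

    @pytest.mark.parametrize("seed", range(15))
    def test_sat_steady_agrees_with_explicit(self, seed):
        n = 6 + seed % 6
        bn = bb.random_bn(bb.GeneratorConfig(n=n, k=2, p=0.4, duplicates=1, seed=seed))
        explicit_steady = {
            a.states[0] for a in bb.attractors(bn) if a.steady_state
        }
        sat_steady = {a.states[0] for a in bb.attractors(bn, strategy="sat-steady")}
        assert sat_steady == explicit_steady

    def test_sat_steady_handles_free_inputs(self):
        # an identity input leaves the fixed-point formula unconstrained on it
        bn = bb.parse_bnet("a, a\nb, a & b")
        steady = {bb.BooleanNetwork.state_to_string(s) for s in bb.steady_states_sat(bn)}
        assert steady == {"00", "10", "11"}

    def test_synchronous_attractor_listed_as_cycle(self, toy_chain):
        (cycle,) = [a for a in bb.attractors(toy_chain) if len(a) == 2]
        assert cycle.state_strings() == ("110", "111")  # smallest first, then follow


class TestConstantStates:
    def test_merge_partition_has_four_constant_states(self, toy_chain, merge_x1x2):
        states = bb.constant_states(merge_x1x2, toy_chain.variables)
        assert [bb.BooleanNetwork.state_to_string(s) for s in states] == [
            "000",
            "001",
            "110",
            "111",
        ]

    def test_singletons_make_every_state_constant(self, toy_chain):
        singles = bb.singleton_partition(toy_chain)
        assert len(bb.constant_states(singles, toy_chain.variables)) == 8

    def test_maximal_partition_two_constant_states(self, tlr5):
        states = bb.constant_states(bb.maximal_partition(tlr5), tlr5.variables)
        assert [bb.BooleanNetwork.state_to_string(s) for s in states] == [
            "00000",
            "11111",
        ]


class TestCorrespondence:
    def test_toy_chain(self, toy_chain, merge_x1x2):
        res = bb.reduce(toy_chain, merge_x1x2)
        assert bb.verify_correspondence(toy_chain, res)

    def test_identity_quotient(self, toy_chain):
        res = bb.reduce(toy_chain, bb.singleton_partition(toy_chain))
        assert bb.verify_correspondence(toy_chain, res)

    @pytest.mark.parametrize("seed", range(25))
    def test_random_networks(self, seed):
        bn = bb.random_bn(bb.GeneratorConfig(n=8, k=2, p=0.5, duplicates=2, seed=seed))
        part = bb.coarsest_bbe(bn, bb.maximal_partition(bn))
        res = bb.reduce(bn, part)
        assert bb.verify_correspondence(bn, res)

    def test_detects_a_broken_quotient(self, toy_chain, merge_x1x2):
        """A deliberately wrong quotient function must fail the isomorphism check."""
        res = bb.reduce(toy_chain, merge_x1x2)
        broken_net = bb.BooleanNetwork(
            res.quotient.variables,
            {"x1": bb.Var("x3"), "x3": ~bb.Var("x3")},
        )
        broken = dataclasses.replace(res, quotient=broken_net)
        assert not bb.verify_correspondence(toy_chain, broken)

    @pytest.mark.parametrize("seed", range(8))
    def test_partially_async_correspondence(self, seed):
        """The square also commutes per synchronization block when ℋ refines 𝒦."""
        bn = bb.random_bn(bb.GeneratorConfig(n=6, k=2, p=0.5, duplicates=2, seed=seed))
        half = len(bn.variables) // 2
        k = canonical_partition(
            [bn.variables[:half], bn.variables[half:]], bn.variables
        )
        bn = dataclasses.replace(bn, sync_partition=k)
        part = bb.coarsest_bbe(bn, k)  # initial = 𝒦, result refines it
        res = bb.reduce(bn, part)
        assert res.quotient.sync_partition is not None
        assert bb.verify_correspondence(bn, res)

    def test_async_initial_partition_must_refine_sync_partition(self):
        bn = bb.random_bn(bb.GeneratorConfig(n=4, k=2, seed=0))
        k = bb.singleton_partition(bn)
        bn = dataclasses.replace(bn, sync_partition=k)
        from bbereduce.errors import PartitionError

        with pytest.raises(PartitionError, match="synchronization"):
            bb.coarsest_bbe(bn, bb.maximal_partition(bn))


class TestPreservation:
    def test_four_steady_classification(self, four_steady):
        part = canonical_partition([["x1", "x2"], ["x3"]], four_steady.variables)
        atts = bb.attractors(four_steady)
        preserved, dropped = bb.preserved_attractors(atts, part, four_steady.variables)
        assert {a.state_strings()[0] for a in preserved} == {"000", "111"}
        assert {a.state_strings()[0] for a in dropped} == {"010", "100"}

    def test_singleton_partition_preserves_everything(self, four_steady):
        atts = bb.attractors(four_steady)
        preserved, dropped = bb.preserved_attractors(
            atts, bb.singleton_partition(four_steady), four_steady.variables
        )
        assert len(preserved) == 4 and not dropped

    def test_toy_chain_cycle_survives_with_length_two(self, toy_chain, merge_x1x2):
        res = bb.reduce(toy_chain, merge_x1x2)
        qatts = bb.attractors(res.quotient)
        (cycle,) = [a for a in qatts if not a.steady_state]
        assert len(cycle) == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_quotient_attractors_are_exactly_preserved_projections(self, seed):
        """Reduction under-approximates: projections of constant-touching
        attractors, same lengths, nothing spurious."""
        n = 6 + seed % 7  # up to 12
        bn = bb.random_bn(bb.GeneratorConfig(n=n, k=2, p=0.5, duplicates=2, seed=seed))
        part = bb.coarsest_bbe(bn, bb.maximal_partition(bn))
        res = bb.reduce(bn, part)
        atts = bb.attractors(bn)
        qatts = bb.attractors(res.quotient)
        preserved, _ = bb.preserved_attractors(atts, part, bn.variables)
        # preserved attractors are entirely constant, so projection is total
        projections = {
            frozenset(bb.project_state(s, res) for s in a.states) for a in preserved
        }
        assert {a.state_set() for a in qatts} == projections
        assert len(qatts) <= len(atts)
        lengths = sorted(len(a) for a in preserved)
        assert sorted(len(a) for a in qatts) == lengths
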