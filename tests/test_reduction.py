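"""The backward-equivalence core: formula, SAT check, refinement loop, quotient."""

import random

import pytest
import sympy
from sympy.logic.inference import satisfiable

import bbereduce as bb
from bbereduce.errors import NonConstantStateError, NotBBEError
from bbereduce.partitions import canonical_partition

from _oracles import (
    as_block_sets,
    brute_force_coarsest_bbe,
    is_bbe_exhaustive,
)


def h1_partition(tlr5):
    return canonical_partition(
        [["TLR5"], ["TICAM1", "MyD88"], ["IRAK4", "PIK3AP1"]], tlr5.variables
    )


class TestFormula:
    def test_singleton_partition_gives_valid_formula(self, toy_chain):
        phi = bb.build_bbe_formula(toy_chain, bb.singleton_partition(toy_chain))
        assert satisfiable(sympy.Not(phi)) is False

    def test_is_partition_formula_falsifiable(self, tlr5, tlr5_is_partition):
        phi = bb.build_bbe_formula(tlr5, tlr5_is_partition)
        model = satisfiable(sympy.Not(phi))
        assert model is not False

    def test_refined_partition_formula_valid(self, tlr5):
        phi = bb.build_bbe_formula(tlr5, h1_partition(tlr5))
        assert satisfiable(sympy.Not(phi)) is False


class TestCheck:
    def test_is_partition_rejected_with_usable_witness(self, tlr5, tlr5_is_partition):
        ok, witness = bb.check_bbe(tlr5, tlr5_is_partition)
        assert not ok
        # the witness must be constant on the partition...
        values = dict(zip(tlr5.variables, witness.state))
        for block in tlr5_is_partition.blocks:
            assert len({values[v] for v in block}) == 1
        # ...its successor must be the synchronous step...
        assert witness.successor == bb.step(tlr5, witness.state)
        # ...and splitting on it must give exactly the refined partition,
        # whatever witness the solver returned.
        split = bb.split_blocks_by_witness(
            tlr5_is_partition, witness.next_values(), tlr5.variables
        )
        assert split == h1_partition(tlr5)

    def test_refined_partition_accepted(self, tlr5):
        assert bb.check_bbe(tlr5, h1_partition(tlr5)) == (True, None)

    def test_singletons_always_accepted(self, toy_chain, tlr5):
        for bn in (toy_chain, tlr5):
            assert bb.check_bbe(bn, bb.singleton_partition(bn)) == (True, None)

    def test_toy_chain_merge_accepted(self, toy_chain, merge_x1x2):
        assert bb.check_bbe(toy_chain, merge_x1x2) == (True, None)

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_exhaustive_state_sweep(self, seed):
        """SAT verdicts match a full 2^n constant-state sweep on random nets."""
        rng = random.Random(seed)
        n = rng.randint(3, 8)
        bn = bb.random_bn(bb.GeneratorConfig(n=n, k=2, p=0.5, duplicates=0, seed=seed))
        names = list(bn.variables)
        rng.shuffle(names)
        cut = rng.randint(1, n)
        blocks = [names[:cut]] + [[v] for v in names[cut:]]
        part = canonical_partition(blocks, bn.variables)
        ok, _ = bb.check_bbe(bn, part)
        assert ok == is_bbe_exhaustive(bn, [list(b) for b in part.blocks])


class TestCoarsest:
    def test_tlr5_from_input_separated(self, tlr5, tlr5_is_partition):
        assert bb.coarsest_bbe(tlr5, tlr5_is_partition) == h1_partition(tlr5)

    def test_toy_chain_from_maximal(self, toy_chain, merge_x1x2):
        assert bb.coarsest_bbe(toy_chain, bb.maximal_partition(toy_chain)) == merge_x1x2

    def test_singletons_are_a_fixed_point(self, tlr5):
        singles = bb.singleton_partition(tlr5)
        assert bb.coarsest_bbe(tlr5, singles) == singles

    def test_result_is_sound_and_refines_initial(self, tlr5, tlr5_is_partition):
        part = bb.coarsest_bbe(tlr5, tlr5_is_partition)
        assert bb.check_bbe(tlr5, part) == (True, None)
        assert bb.is_refinement(part, tlr5_is_partition)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_partition_enumeration(self, seed):
        n = 4 + seed % 4
        bn = bb.random_bn(bb.GeneratorConfig(n=n, k=2, p=0.5, duplicates=1, seed=seed))
        mine = bb.coarsest_bbe(bn, bb.maximal_partition(bn))
        assert as_block_sets(mine) == brute_force_coarsest_bbe(bn)

    @pytest.mark.parametrize("seed", range(10))
    def test_independent_of_variable_order(self, seed):
        """Shuffling declaration order permutes nothing but block naming."""
        bn = bb.random_bn(bb.GeneratorConfig(n=7, k=2, p=0.5, duplicates=2, seed=seed))
        base = as_block_sets(bb.coarsest_bbe(bn, bb.maximal_partition(bn)))
        rng = random.Random(seed)
        order = list(bn.variables)
        rng.shuffle(order)
        shuffled = bb.BooleanNetwork(tuple(order), dict(bn.functions))
        got = as_block_sets(bb.coarsest_bbe(shuffled, bb.maximal_partition(shuffled)))
        assert got == base

    @pytest.mark.parametrize("seed", range(10))
    def test_iteration_bound(self, seed):
        n = 8
        bn = bb.random_bn(bb.GeneratorConfig(n=n, k=2, p=0.5, duplicates=2, seed=seed))
        stats = {}
        bb.coarsest_bbe(bn, bb.maximal_partition(bn), stats=stats)
        assert stats["sat_checks"] <= n

    def test_block_count_monotone_in_initial_partition(self, tlr5):
        from_max = bb.coarsest_bbe(tlr5, bb.maximal_partition(tlr5))
        from_is = bb.coarsest_bbe(tlr5, bb.input_separated_partition(tlr5))
        assert from_max.n_blocks <= from_is.n_blocks <= tlr5.n


class TestQuotient:
    def test_toy_chain_quotient_function(self, toy_chain, merge_x1x2):
        res = bb.reduce(toy_chain, merge_x1x2)
        assert res.quotient.variables == ("x1", "x3")
        assert bb.semantic_equal(
            res.quotient.functions["x1"], bb.Var("x1") | ~bb.Var("x3")
        )
        assert res.block_to_representative[("x1", "x2")] == "x1"
        assert res.variable_to_block["x2"] == ("x1", "x2")

    def test_singleton_quotient_is_semantically_identical(self, toy_chain):
        res = bb.reduce(toy_chain, bb.singleton_partition(toy_chain))
        assert res.quotient.variables == toy_chain.variables
        for v in toy_chain.variables:
            assert bb.semantic_equal(res.quotient.functions[v], toy_chain.functions[v])

    def test_four_steady_quotient_substitutes_representative(self, four_steady):
        part = canonical_partition([["x1", "x2"], ["x3"]], four_steady.variables)
        res = bb.reduce(four_steady, part)
        assert bb.semantic_equal(res.quotient.functions["x1"], bb.Var("x1"))
        assert bb.semantic_equal(res.quotient.functions["x3"], bb.Var("x1"))

    def test_simplification_is_semantic_equality_checked(self, toy_chain, merge_x1x2):
        res = bb.reduce(toy_chain, merge_x1x2, simplify=True)
        assert bb.semantic_equal(
            res.quotient.functions["x1"], bb.Var("x1") | ~bb.Var("x3")
        )

    def test_non_bbe_partition_refused_with_witness(self, tlr5, tlr5_is_partition):
        with pytest.raises(NotBBEError) as exc:
            bb.reduce(tlr5, tlr5_is_partition)
        assert exc.value.witness.successor == bb.step(tlr5, exc.value.witness.state)


class TestProjectLift:
    def test_projection_example(self, toy_chain, merge_x1x2):
        res = bb.reduce(toy_chain, merge_x1x2)
        assert bb.project_state((1, 1, 0), res) == (1, 0)

    def test_non_constant_state_names_the_block(self, toy_chain, merge_x1x2):
        res = bb.reduce(toy_chain, merge_x1x2)
        with pytest.raises(NonConstantStateError, match="x1, x2"):
            bb.project_state((1, 0, 0), res)

    def test_lift_example(self, toy_chain, merge_x1x2):
        res = bb.reduce(toy_chain, merge_x1x2)
        assert bb.lift_state((1, 0), res) == (1, 1, 0)
        assert bb.lift_state((0, 0), res) == (0, 0, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_project_lift_round_trip(self, seed):
        bn = bb.random_bn(bb.GeneratorConfig(n=8, k=2, p=0.5, duplicates=2, seed=seed))
        part = bb.coarsest_bbe(bn, bb.maximal_partition(bn))
        res = bb.reduce(bn, part)
        rng = random.Random(seed)
        for _ in range(20):
            reduced = tuple(rng.randint(0, 1) for _ in range(res.quotient.n))
            assert bb.project_state(bb.lift_state(reduced, res), res) == reduced
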