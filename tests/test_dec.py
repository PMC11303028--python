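import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from paleorange.dec import (
    AncestralRangeModel,
    DECParams,
    _summaries,
    anagenetic_generator,
    clado_distribution,
)
from paleorange.geography import RangeStateSpace

from conftest import SINGLES, bound_tree, random_small_tree
from oracles import enum_loglik_and_marginals


class TestAnageneticGenerator:
    def test_adjacency_gates_expansion(self, space):
        Q = anagenetic_generator(space, DECParams(d=0.3, e=0.07))
        i = space.range_index({"NA"})
        assert Q[i, space.range_index({"NA", "EU"})] == pytest.approx(0.3)
        assert Q[i, space.range_index({"NA", "AF"})] == 0.0

    def test_expansion_counts_adjacent_occupied_areas(self, space):
        Q = anagenetic_generator(space, DECParams(d=0.3, e=0.07))
        # only NA is adjacent to EU within {SA, NA}
        assert Q[
            space.range_index({"SA", "NA"}), space.range_index({"SA", "NA", "EU"})
        ] == pytest.approx(0.3)
        # both NA and AF adjacent to EU within {NA, AF}
        assert Q[
            space.range_index({"NA", "AF"}), space.range_index({"NA", "EU", "AF"})
        ] == pytest.approx(0.6)

    def test_contraction_and_null(self, space):
        params = DECParams(d=0.3, e=0.07)
        Q = anagenetic_generator(space, params)
        assert Q[
            space.range_index({"NA", "EU"}), space.range_index({"NA"})
        ] == pytest.approx(0.07)
        assert Q[space.range_index({"NA"}), space.null_index] == pytest.approx(0.07)
        assert np.all(Q[space.null_index] == 0.0)  # absorbing

    def test_rows_sum_to_zero(self, space):
        Q = anagenetic_generator(space, DECParams(d=0.41, e=0.13))
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    @pytest.mark.parametrize("t", [0.01, 1.0, 100.0])
    def test_transition_rows_sum_to_one(self, space, t):
        Q = anagenetic_generator(space, DECParams(d=0.2, e=0.1))
        P = expm(Q * t)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10


class TestCladoDistribution:
    def test_singleton_without_jumps(self, space):
        cd = clado_distribution(space, DECParams(0.1, 0.1, 0.0))
        assert cd.table({"NA"}) == [
            (frozenset({"NA"}), frozenset({"NA"}), 1.0)
        ]

    def test_singleton_jump_weights(self, space):
        cd = clado_distribution(space, DECParams(0.1, 0.1, 0.5))
        tab = cd.table({"NA"})
        probs = {(tuple(sorted(l)), tuple(sorted(r))): p for l, r, p in tab}
        # sympatry 1/(1 + 4*0.5); each of the 4 ordered jumps 0.5/3
        assert probs[(("NA",), ("NA",))] == pytest.approx(1 / 3)
        assert probs[(("NA",), ("SA",))] == pytest.approx(0.5 / 3)
        assert probs[(("EU",), ("NA",))] == pytest.approx(0.5 / 3)
        assert len(tab) == 5

    def test_widespread_event_vocabulary(self, space):
        cd = clado_distribution(space, DECParams(0.1, 0.1, 0.0))
        tab = cd.table({"NA", "EU"})
        pairs = {(l, r) for l, r, _ in tab}
        na, eu, both = frozenset({"NA"}), frozenset({"EU"}), frozenset({"NA", "EU"})
        # subset sympatry both orderings + vicariance both orderings
        assert (na, both) in pairs and (both, na) in pairs
        assert (eu, both) in pairs and (both, eu) in pairs
        assert (na, eu) in pairs and (eu, na) in pairs
        assert all(p == pytest.approx(1 / 6) for _, _, p in tab)

    @pytest.mark.parametrize("j", [0.0, 0.3, 1.7])
    def test_probabilities_sum_to_one_per_state(self, space, j):
        cd = clado_distribution(space, DECParams(0.1, 0.1, j))
        sums = np.bincount(cd.anc, weights=cd.prob, minlength=space.n_states)
        assert np.abs(sums - 1.0).max() < 1e-12

    def test_zero_j_puts_no_mass_on_jumps(self, space):
        cd = clado_distribution(space, DECParams(0.1, 0.1, 0.0))
        for l, r, p in cd.table({"SA"}):
            assert l == r == frozenset({"SA"})


class TestLikelihood:
    def test_degenerate_rates_force_root_state(self, space):
        tree = bound_tree("(A:1,B:1);", {"A": {"NA"}, "B": {"NA"}})
        model = AncestralRangeModel(tree, state_space=space)
        assert model.loglike(DECParams(0, 0, 0)) == pytest.approx(np.log(1 / 14))

    def test_pruning_matches_enumeration(self, space, rng):
        for _ in range(8):
            tree = random_small_tree(rng, n_tips=3)
            params = DECParams(*rng.uniform(0.01, 1.0, 3))
            model = AncestralRangeModel(tree, state_space=space)
            lnl = model.loglike(params)
            ref_lnl, _ = enum_loglik_and_marginals(tree, space, params, model.root_prior)
            assert abs(lnl - ref_lnl) < 1e-8

    def test_decj_at_zero_j_equals_dec(self, space, rng):
        tree = random_small_tree(rng, n_tips=4)
        d, e = rng.uniform(0.01, 1.0, 2)
        dec = AncestralRangeModel(tree, model="DEC", state_space=space)
        decj = AncestralRangeModel(tree, model="DEC+J", state_space=space)
        assert dec.loglike(DECParams(d, e)) == decj.loglike(DECParams(d, e, 0.0))

    def test_invariant_to_child_swap(self, space):
        ranges = {"A": {"NA"}, "B": {"EU"}, "C": {"AF"}}
        t1 = bound_tree("((A:1,B:2):0.5,C:3);", ranges)
        t2 = bound_tree("(C:3,(B:2,A:1):0.5);", ranges)
        params = DECParams(0.2, 0.1, 0.4)
        l1 = AncestralRangeModel(t1, state_space=space).loglike(params)
        l2 = AncestralRangeModel(t2, state_space=space).loglike(params)
        assert l1 == pytest.approx(l2, abs=1e-12)

    def test_unbound_tip_raises(self, space):
        tree = bound_tree("(A:1,B:1);", {"A": {"NA"}, "B": {"NA"}})
        tree.tip("A").range_ = None
        with pytest.raises(Exception, match="A"):
            AncestralRangeModel(tree, state_space=space)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_pruning_equals_enumeration_property(self, space, seed):
        rng = np.random.default_rng(seed)
        tree = random_small_tree(rng)
        params = DECParams(rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(0, 2))
        model = AncestralRangeModel(tree, state_space=space)
        lnl = model.loglike(params)
        ref, _ = enum_loglik_and_marginals(tree, space, params, model.root_prior)
        assert abs(lnl - ref) < 1e-8


class TestMarginals:
    def test_state_probs_sum_to_one(self, space, rng):
        tree = random_small_tree(rng, n_tips=4)
        model = AncestralRangeModel(tree, state_space=space)
        prof = model.ancestral_marginals(DECParams(0.3, 0.1, 0.2))
        assert np.abs(prof.state_probs.sum(axis=1) - 1.0).max() < 1e-9

    def test_marginals_match_enumeration(self, space, rng):
        tree = random_small_tree(rng, n_tips=3)
        params = DECParams(0.25, 0.12, 0.6)
        model = AncestralRangeModel(tree, state_space=space)
        prof = model.ancestral_marginals(params)
        _, ref = enum_loglik_and_marginals(tree, space, params, model.root_prior)
        for node in tree.internal_nodes():
            got = prof.state_probs[prof.row(tree.clade_tips(node))]
            assert np.abs(got - ref[id(node)]).max() < 1e-8

    def test_split_and_inclusion_summaries(self, space):
        # 0.8 on {NA}, 0.2 on {NA,EU}: split NA 0.9 / EU 0.1,
        # inclusion NA 1.0 / EU 0.2
        probs = np.zeros((1, space.n_states))
        probs[0, space.range_index({"NA"})] = 0.8
        probs[0, space.range_index({"NA", "EU"})] = 0.2
        inclusion, split = _summaries(space, probs)
        by_area = dict(zip(space.areas, inclusion[0]))
        assert by_area["NA"] == pytest.approx(1.0)
        assert by_area["EU"] == pytest.approx(0.2)
        by_area = dict(zip(space.areas, split[0]))
        assert by_area["NA"] == pytest.approx(0.9)
        assert by_area["EU"] == pytest.approx(0.1)
        assert split[0].sum() == pytest.approx(1.0)

    def test_mirror_symmetric_tree_gives_mirrored_marginals(self, space):
        # mirror swaps SA<->AF and NA<->EU, which preserves the chain
        params = DECParams(0.3, 0.15, 0.4)
        t1 = bound_tree("((A:1,B:1):1,(C:1,D:1):1);",
                        {"A": {"SA"}, "B": {"NA"}, "C": {"EU"}, "D": {"AF"}})
        t2 = bound_tree("((A:1,B:1):1,(C:1,D:1):1);",
                        {"A": {"AF"}, "B": {"EU"}, "C": {"NA"}, "D": {"SA"}})
        mirror = {"SA": "AF", "NA": "EU", "EU": "NA", "AF": "SA"}
        p1 = AncestralRangeModel(t1, state_space=space).ancestral_marginals(params)
        p2 = AncestralRangeModel(t2, state_space=space).ancestral_marginals(params)
        root = frozenset("ABCD")
        incl1 = dict(zip(space.areas, p1.inclusion_for(root)))
        incl2 = dict(zip(space.areas, p2.inclusion_for(root)))
        for a in space.areas:
            assert incl1[a] == pytest.approx(incl2[mirror[a]], abs=1e-10)
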