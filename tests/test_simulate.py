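import numpy as np
import pytest

from paleorange.sampling import PreservationModel
from paleorange.simulate import (
    PRIOR_SUPPORTS,
    SimParams,
    SimulationError,
    draw_params_from_priors,
    oldest_record_area,
    pooled_event_rates,
    simulate_occurrences,
    simulate_tree,
)

from conftest import QUICK_SIM


class TestSimulateTree:
    def test_no_speciation_exhausts_attempts(self):
        params = SimParams(mu=0.0, delta=0.1, lambda1=0.0, lambda2=0.0, lambda3=0.0)
        with pytest.raises(SimulationError, match="5 attempts"):
            simulate_tree(params, 2, seed=1, max_attempts=5)

    def test_no_dispersal_keeps_every_tip_on_root_continent(self):
        params = SimParams(mu=0.1, delta=0.0, lambda1=0.5, lambda2=0.0, lambda3=0.0)
        res = simulate_tree(params, 20, seed=5, root_area="NA")
        assert all(t.range_ == frozenset({"NA"}) for t in res.tree.tips())

    def test_extant_count_hits_target_exactly(self, sim_result):
        assert len(sim_result.extant_tips()) == 50
        assert all(t.age == 0 for t in sim_result.tree.tips() if not t.extinct)

    def test_tree_is_binary_with_truth_ranges(self, sim_result):
        for node in sim_result.tree.internal_nodes():
            assert len(node.children) == 2
            assert node.range_ is not None and 1 <= len(node.range_) <= 2

    def test_pure_birth_has_no_extinct_tips(self):
        params = SimParams(mu=0.0, delta=0.2, lambda1=0.5, lambda2=0.1, lambda3=1.0)
        res = simulate_tree(params, 30, seed=9)
        assert res.extinct_tips() == []

    def test_extinct_tips_dated_with_last_continent(self, sim_result):
        extinct = [t for t in sim_result.tree.tips() if t.extinct]
        assert extinct, "fixture should contain fossil tips"
        for t in extinct:
            assert t.age > 0
            assert t.last_continent in ("SA", "NA", "EU", "AF")
            assert t.range_ == frozenset({t.last_continent})

    def test_branch_lengths_sum_to_lineage_time(self, sim_result):
        # lineage time integrates the stem too, which the tree drops
        expected = sim_result.total_lineage_time - sim_result.stem_time
        assert sim_result.tree.total_branch_length() == pytest.approx(
            expected, abs=1e-9
        )

    def test_same_seed_reproduces_tree(self):
        a = simulate_tree(QUICK_SIM, 15, seed=33)
        b = simulate_tree(QUICK_SIM, 15, seed=33)
        assert a.tree.tip_distances() == b.tree.tip_distances()
        assert a.counts == b.counts

    def test_range_size_capped_at_two(self, sim_result):
        for ev in sim_result.events:
            assert len(ev.source) <= 2
            for out in ev.outcome:
                assert len(out) <= 2

    def test_event_rate_recovery_single_vector(self):
        df = pooled_event_rates(QUICK_SIM, seed=77, min_events=4000)
        z = (df.realized_rate - df.nominal_rate) / df.nominal_se
        assert np.nanmax(np.abs(z)) < 3.0


class TestPriors:
    def test_supports_and_mean(self):
        rng = np.random.default_rng(6)
        draws = np.array(
            [list(draw_params_from_priors(rng).as_dict().values()) for _ in range(20_000)]
        )
        for k, (name, (lo, hi)) in enumerate(PRIOR_SUPPORTS.items()):
            assert draws[:, k].min() >= lo and draws[:, k].max() <= hi
        lam2 = draws[:, list(PRIOR_SUPPORTS).index("lambda2")]
        se = 0.25 / np.sqrt(12 * len(lam2))
        assert abs(lam2.mean() - 0.125) < 3 * se

    def test_same_seed_same_vector(self):
        assert draw_params_from_priors(99) == draw_params_from_priors(99)


class TestOccurrences:
    def _one_species_result(self, lifespan, rng=frozenset({"NA"})):
        from paleorange.simulate import SimulationResult
        from paleorange.trees import PhyloTree, Node

        # minimal container: only trajectories are consulted
        root = Node()
        root.add_child(Node("x", 1.0))
        root.add_child(Node("y", 1.0))
        tree = PhyloTree(root, validate=False)
        return SimulationResult(
            tree=tree, params=QUICK_SIM, seed=None, n_attempts=1, t_stop=lifespan,
            stem_time=0, total_lineage_time=lifespan, events=[], exposures={},
            counts={}, trajectories={"x": [(lifespan, 0.0, rng)]},
        )

    def test_zero_rates_give_empty_table(self):
        res = self._one_species_result(10.0)
        occ = simulate_occurrences(res, PreservationModel.homogeneous(0.0), seed=1)
        assert occ.empty

    def test_constant_rate_poisson_mean(self):
        q, L, n = 0.4, 10.0, 10_000
        res = self._one_species_result(L)
        res.trajectories = {f"s{i}": [(L, 0.0, frozenset({"NA"}))] for i in range(n)}
        occ = simulate_occurrences(res, PreservationModel.homogeneous(q), seed=2)
        mean = len(occ) / n
        se = np.sqrt(q * L / n)
        assert abs(mean - q * L) < 3 * se

    def test_two_stratum_mean(self):
        # rates q1 on ages < 5, q2 on ages >= 5; lifespan spans both
        q1, q2, n = 0.6, 0.1, 10_000
        model = PreservationModel(np.array([5.0]), np.full((2, 4), q1), factor=1.0)
        model.rates[1, :] = q2
        res = self._one_species_result(8.0)
        res.trajectories = {f"s{i}": [(8.0, 0.0, frozenset({"NA"}))] for i in range(n)}
        occ = simulate_occurrences(res, model, seed=3)
        expected = q1 * 5.0 + q2 * 3.0
        assert abs(len(occ) / n - expected) < 3 * np.sqrt(expected / n)

    def test_widespread_split_and_tagging(self):
        res = self._one_species_result(50.0, rng=frozenset({"NA", "EU"}))
        model = PreservationModel.homogeneous(1.0)
        occ = simulate_occurrences(res, model, seed=4)
        assert set(occ.continent) <= {"NA", "EU"}
        # split intensity: expect ~50 total, not ~100
        assert abs(len(occ) - 50) < 3 * np.sqrt(50)


class TestOldestRecord:
    def test_oldest_record_wins(self):
        import pandas as pd

        occ = pd.DataFrame(
            {"species": ["a", "b"], "age": [10.0, 8.0], "continent": ["NA", "EU"]}
        )
        assert oldest_record_area(occ) == ("NA",)

    def test_tie_reports_all(self):
        import pandas as pd

        occ = pd.DataFrame(
            {"species": ["a", "b"], "age": [9.0, 9.0], "continent": ["EU", "NA"]}
        )
        assert oldest_record_area(occ) == ("NA", "EU")

    def test_empty_group_is_an_error(self):
        import pandas as pd

        occ = pd.DataFrame({"species": ["a"], "age": [1.0], "continent": ["NA"]})
        with pytest.raises(ValueError):
            oldest_record_area(occ, group=["missing"])
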