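import numpy as np
import pytest

from paleorange.sampling import (
    PreservationModel,
    SamplingScenario,
    calibrate_factor,
    draw_included_set,
    draw_known_set,
    prune_to,
    species_detection_prob,
    tip_lifespan_segments,
)
from paleorange.simulate import simulate_tree
from paleorange.trees import TreeValidationError

from conftest import QUICK_SIM

NA = frozenset({"NA"})


def heterogeneous_model():
    # rich recent/NA record, poor elsewhere
    edges = np.array([5.0, 15.0])
    rates = np.array(
        [
            [0.05, 0.60, 0.20, 0.10],
            [0.02, 0.20, 0.10, 0.05],
            [0.01, 0.05, 0.03, 0.02],
        ]
    )
    return PreservationModel(edges, rates)


def synthetic_trajectories(n, rng):
    """Species with random lifespans scattered over strata and continents."""
    areas = ["SA", "NA", "EU", "AF"]
    out = {}
    for i in range(n):
        start = rng.uniform(0.5, 30.0)
        end = rng.uniform(0.0, start)
        out[f"sp{i}"] = [(start, end, frozenset({areas[rng.integers(4)]}))]
    return out


class TestDetectionProb:
    def test_zero_factor_means_undetectable(self):
        model = PreservationModel.homogeneous(0.5)
        assert species_detection_prob([(10.0, 0.0, NA)], model, factor=0.0) == 0.0

    def test_half_life_closed_form(self):
        # f*q*L = ln 2  ->  detection probability exactly 1/2
        q, L = 0.1, 10.0
        model = PreservationModel.homogeneous(q)
        f = np.log(2) / (q * L)
        assert species_detection_prob([(L, 0.0, NA)], model, factor=f) == pytest.approx(0.5)

    def test_matches_monte_carlo_occurrences(self, rng):
        model = heterogeneous_model()
        segments = [(20.0, 12.0, NA), (12.0, 3.0, frozenset({"NA", "EU"}))]
        p = species_detection_prob(segments, model, factor=1.0)
        lam = model.intensity_integral(segments)
        n = 10_000
        detected = rng.poisson(lam, size=n) > 0
        se = np.sqrt(p * (1 - p) / n)
        assert abs(detected.mean() - p) < 3 * se

    def test_negative_span_rejected(self):
        model = PreservationModel.homogeneous(0.1)
        with pytest.raises(ValueError):
            species_detection_prob([(1.0, 2.0, NA)], model)


class TestCalibrateFactor:
    def test_homogeneous_closed_form(self):
        q, L, target = 0.05, 8.0, 0.6
        model = PreservationModel.homogeneous(q)
        trajs = {f"s{i}": [(L, 0.0, NA)] for i in range(10)}
        f = calibrate_factor(model, trajs, target)
        assert f == pytest.approx(np.log(1 / (1 - target)) / (q * L), rel=1e-9)

    @pytest.mark.parametrize("target", [0.25, 0.5, 0.75])
    def test_postcondition_on_mean_probability(self, target, rng):
        model = heterogeneous_model()
        trajs = synthetic_trajectories(120, rng)
        f = calibrate_factor(model, trajs, target)
        probs = [species_detection_prob(s, model, factor=f) for s in trajs.values()]
        assert np.mean(probs) == pytest.approx(target, abs=1e-6)

    def test_objective_monotone_in_factor(self, rng):
        model = heterogeneous_model()
        trajs = synthetic_trajectories(50, rng)
        means = [
            np.mean([species_detection_prob(s, model, factor=f) for s in trajs.values()])
            for f in np.linspace(0.0, 5.0, 12)
        ]
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_all_zero_rates_unreachable(self):
        model = PreservationModel.homogeneous(0.0)
        with pytest.raises(ValueError, match="unreachable|zero"):
            calibrate_factor(model, {"a": [(5.0, 0.0, NA)]}, 0.5)

    def test_bad_target_rejected(self):
        model = PreservationModel.homogeneous(0.1)
        with pytest.raises(ValueError):
            calibrate_factor(model, {"a": [(5.0, 0.0, NA)]}, 1.0)


class TestKnownAndIncludedSets:
    def test_zero_factor_detects_nothing(self, rng):
        model = heterogeneous_model()
        trajs = synthetic_trajectories(40, rng)
        assert draw_known_set(trajs, model, seed=1, factor=0.0) == set()

    def test_same_seed_same_set(self, rng):
        model = heterogeneous_model()
        trajs = synthetic_trajectories(40, rng)
        f = calibrate_factor(model, trajs, 0.5)
        assert draw_known_set(trajs, model, 7, factor=f) == draw_known_set(
            trajs, model, 7, factor=f
        )

    def test_high_rate_stratum_enriched(self):
        # two equal-lifespan cohorts, one in a high-rate continent
        model = PreservationModel(
            np.array([]), np.array([[0.02, 0.5, 0.02, 0.02]])
        )
        trajs = {}
        for i in range(50):
            trajs[f"hi{i}"] = [(10.0, 0.0, NA)]
            trajs[f"lo{i}"] = [(10.0, 0.0, frozenset({"SA"}))]
        wins = 0
        for rep in range(100):
            known = draw_known_set(trajs, model, seed=rep, factor=1.0)
            hi = sum(1 for k in known if k.startswith("hi"))
            lo = sum(1 for k in known if k.startswith("lo"))
            wins += hi > lo
        assert wins > 90

    def test_included_equals_known_when_fractions_match(self):
        known = {"a", "b", "c"}
        out = draw_included_set(known, 12, 0.25, seed=1, frac_known=0.25)
        assert out == known

    def test_included_size_contract(self):
        known = set(f"s{i}" for i in range(30))
        out = draw_included_set(known, 100, 0.05, seed=2, frac_known=0.5)
        assert len(out) == 5 and out <= known

    def test_zero_fraction_empty(self):
        assert draw_included_set({"a", "b"}, 10, 0.0, seed=3) == set()

    def test_oversized_request_names_numbers(self):
        with pytest.raises(ValueError, match="25.*known set of 2|cannot include"):
            draw_included_set({"a", "b"}, 100, 0.25, seed=4, frac_known=0.5)

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            SamplingScenario(frac_known=0.25, frac_included=0.5)


class TestPruneTo:
    def test_keep_all_is_identity(self, sim_result):
        full = sim_result.tree
        pruned = prune_to(full, set(sim_result.extinct_tips()))
        assert pruned.tip_distances() == pytest.approx(full.tip_distances())

    def test_keep_none_leaves_extant_only(self, sim_result):
        pruned = prune_to(sim_result.tree, set())
        assert sorted(pruned.tip_names()) == sorted(sim_result.extant_tips())
        assert all(t.age == 0 for t in pruned.tips())

    def test_path_lengths_preserved(self, sim_result, rng):
        extinct = sorted(sim_result.extinct_tips())
        keep = set(rng.choice(extinct, size=len(extinct) // 2, replace=False))
        pruned = prune_to(sim_result.tree, keep)
        d_full = sim_result.tree.tip_distances()
        d_red = pruned.tip_distances()
        assert max(abs(d_full[k] - d_red[k]) for k in d_red) < 1e-9

    def test_mrca_ages_preserved(self, sim_result, rng):
        extinct = sorted(sim_result.extinct_tips())
        keep = set(rng.choice(extinct, size=len(extinct) // 3, replace=False))
        pruned = prune_to(sim_result.tree, keep)
        names = sorted(pruned.tip_names())
        pairs = [(names[i], names[-(i + 1)]) for i in range(0, min(10, len(names) // 2))]
        for a, b in pairs:
            assert pruned.mrca({a, b}).age == pytest.approx(
                sim_result.tree.mrca({a, b}).age, abs=1e-9
            )

    def test_unknown_species_rejected(self, sim_result):
        with pytest.raises(TreeValidationError):
            prune_to(sim_result.tree, {"not_a_tip"})

    def test_extant_tip_in_keep_set_rejected(self, sim_result):
        extant = sim_result.extant_tips()[0]
        with pytest.raises(TreeValidationError):
            prune_to(sim_result.tree, {extant})


class TestLifespanSegments:
    def test_terminal_branch_defines_span(self):
        from conftest import bound_tree

        tree = bound_tree("((A:1,B:2):1,C:3);", {"A": {"NA"}, "B": {"EU"}, "C": {"SA"}})
        segs = tip_lifespan_segments(tree)
        assert segs["A"] == [(2.0, 1.0, frozenset({"NA"}))]
        assert segs["C"] == [(3.0, 0.0, frozenset({"SA"}))]
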