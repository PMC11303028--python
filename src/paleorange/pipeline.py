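"""End-to-end simulation and empirical-style studies.

A simulation study runs the full chain: simulate a synthetic "pseudo-
empirical" target tree, draw candidate parameter vectors from the priors
and simulate one tree each, keep the k candidates with the smallest
ALE_max against the target's five summaries, subject each kept tree to a
grid of fossil-sampling scenarios (extant-only, random subsets, biased
subsets under the calibrated Poisson preservation model), fit the range
model on every reduced tree, and score accuracy against the simulation
truth.  An empirical-style study does the same on user-supplied trees,
scoring against the full-tree inference instead of a known truth.

Every stochastic stage receives an explicit child seed derived from the
master seed, so a rerun with the same configuration reproduces every
output exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .abc_select import ABCSummary, CRITERIA, select_trees, summary_stats
from .accuracy import (
    bin_and_summarize,
    evaluate_scenario,
    inclusion_profile,
    truth_profile,
)
from .dec import AncestralRangeModel, DECParams
from .predictability import PredictabilityResult, correlate_predictors
from .sampling import (
    PreservationModel,
    SamplingScenario,
    calibrate_factor,
    draw_included_set,
    draw_known_set,
    prune_to,
)
from .simulate import (
    SimParams,
    SimulationError,
    SimulationResult,
    draw_params_from_priors,
    simulate_tree,
)
from .trees import PhyloTree, write_newick

__all__ = [
    "ExperimentConfig",
    "StudyResult",
    "run_simulation_study",
    "run_empirical_style",
    "EXTANT_ONLY",
]

log = logging.getLogger("paleorange")

#: the no-fossil scenario (0% of extinct species included)
EXTANT_ONLY = SamplingScenario(frac_known=1.0, frac_included=0.0, mode="random")

_DEFAULT_SCENARIOS = (
    EXTANT_ONLY,
    SamplingScenario(frac_known=0.5, frac_included=0.25, mode="biased"),
)


@dataclass
class ExperimentConfig:
    """Configuration of a simulation study; JSON round-trippable."""

    target_params: SimParams = field(
        default_factory=lambda: SimParams(
            mu=0.2, delta=0.1, lambda1=0.3, lambda2=0.05, lambda3=0.5
        )
    )
    n_extant: int = 100
    n_candidates: int = 10_000
    k_keep: int = 20
    scenarios: Tuple[SamplingScenario, ...] = _DEFAULT_SCENARIOS
    model: str = "DEC+J"
    reference: str = "truth"  # "truth" or "inferred"
    bin_mode: str = "quantile"
    n_bins: int = 4
    n_restarts: int = 2
    seed: int = 1
    target_max_attempts: int = 500
    candidate_max_attempts: int = 3
    candidate_max_events: int = 20_000

    def __post_init__(self) -> None:
        if self.reference not in ("truth", "inferred"):
            raise ValueError("reference must be 'truth' or 'inferred'")
        if self.k_keep > self.n_candidates:
            raise ValueError("k_keep cannot exceed n_candidates")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["target_params"] = self.target_params.as_dict()
        d["scenarios"] = [dataclasses.asdict(s) for s in self.scenarios]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "target_params" in d:
            d["target_params"] = SimParams(**d["target_params"])
        if "scenarios" in d:
            d["scenarios"] = tuple(SamplingScenario(**s) for s in d["scenarios"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class StudyResult:
    config: ExperimentConfig
    records: pd.DataFrame
    summary: pd.DataFrame
    candidates: Optional[pd.DataFrame]
    predictability: Dict[str, PredictabilityResult]
    selected: List[SimulationResult]
    manifest: dict
    outdir: Optional[str] = None


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def scenario_included_set(
    result: SimulationResult, scenario: SamplingScenario, seed: int
) -> Tuple[Set[str], dict]:
    """Known and included fossil sets for one tree under one scenario.

    Biased mode calibrates the synthetic stratified preservation model to
    the scenario's known fraction and Bernoulli-samples detections; random
    mode treats every extinct species as known.  Returns the included set
    and a small diagnostics dict.
    """
    extinct = sorted(result.extinct_tips())
    info: dict = {"n_extinct": len(extinct), "mode": scenario.mode}
    if not extinct:
        return set(), info
    ss = np.random.SeedSequence(seed)
    s_known, s_incl = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    if scenario.mode == "biased" and scenario.frac_known < 1.0:
        trajs = {n: result.trajectories[n] for n in extinct}
        model = PreservationModel.synthetic_biased(result.tree.root_age)
        f = calibrate_factor(model, trajs, scenario.frac_known)
        known = draw_known_set(trajs, model, s_known, factor=f)
        info.update(factor=f, n_known=len(known))
    else:
        known = set(extinct)
        info.update(n_known=len(known))
    included = draw_included_set(
        known,
        len(extinct),
        scenario.frac_included,
        s_incl,
        frac_known=scenario.frac_known,
    )
    info.update(n_included=len(included))
    return included, info


def _evaluate_tree(
    result: SimulationResult,
    reference_profile,
    config: ExperimentConfig,
    tree_id: str,
    seed: int,
    ref_params: Optional[DECParams] = None,
) -> Tuple[pd.DataFrame, List[dict]]:
    frames = []
    infos = []
    n_extinct = len(result.extinct_tips())
    ss = np.random.SeedSequence(seed).spawn(len(config.scenarios))
    for scenario, sub in zip(config.scenarios, ss):
        t0 = time.perf_counter()
        included, info = scenario_included_set(result, scenario, _child_seed(sub))
        reduced = prune_to(result.tree, included)
        # when every fossil is back in, the reduced tree *is* the full tree
        # and the reference fit solves the identical ML problem: reuse it
        params = ref_params if (ref_params is not None and len(included) == n_extinct) else None
        recs = evaluate_scenario(
            result.tree,
            reference_profile,
            reduced,
            model=config.model,
            params=params,
            fit_kwargs={"n_restarts": config.n_restarts, "seed": _child_seed(sub)},
            tree_id=tree_id,
            scenario=scenario.label,
        )
        frames.append(recs)
        info.update(tree_id=tree_id, scenario=scenario.label)
        infos.append(info)
        log.info(
            "tree=%s scenario=%s n_tips=%d seed=%d wall=%.1fs",
            tree_id,
            scenario.label,
            reduced.n_tips,
            _child_seed(sub),
            time.perf_counter() - t0,
        )
    return pd.concat(frames, ignore_index=True), infos


def run_simulation_study(
    config: ExperimentConfig, outdir: Optional[str] = None
) -> StudyResult:
    """Simulate, select by ABC, subsample fossils, fit, and score accuracy."""
    root_ss = np.random.SeedSequence(config.seed)
    ss_target, ss_cand, ss_eval = root_ss.spawn(3)

    # 1. synthetic pseudo-empirical target
    target = simulate_tree(
        config.target_params,
        config.n_extant,
        seed=_child_seed(ss_target),
        max_attempts=config.target_max_attempts,
    )
    target_summary = summary_stats(target.tree)
    log.info("target tree: %d tips, root age %.2f Ma", target.tree.n_tips, target.tree.root_age)

    # 2. ABC rejection over prior draws
    cand_seeds = ss_cand.spawn(config.n_candidates)
    cand_results: List[Optional[SimulationResult]] = []
    cand_rows = []
    summaries: List[Optional[ABCSummary]] = []
    for i, cs in enumerate(cand_seeds):
        s1, s2 = cs.spawn(2)
        params = draw_params_from_priors(_child_seed(s1))
        row = {"candidate": i, **params.as_dict(), "seed": _child_seed(s2)}
        try:
            res = simulate_tree(
                params,
                config.n_extant,
                seed=_child_seed(s2),
                max_attempts=config.candidate_max_attempts,
                max_events=config.candidate_max_events,
            )
            summ = summary_stats(res.tree)
            row.update(status="ok", **summ.as_dict())
        except SimulationError:
            res, summ = None, None
            row.update(status="failed")
        cand_results.append(res)
        summaries.append(summ)
        cand_rows.append(row)
    selected_idx, report = select_trees(summaries, target_summary, config.k_keep)
    candidates = pd.concat([pd.DataFrame(cand_rows), report], axis=1)
    selected = [cand_results[i] for i in selected_idx]
    if any(s is None for s in selected):
        raise RuntimeError("ABC selected a failed candidate; increase n_candidates")

    # 3-4. scenarios, fits, accuracy
    frames = []
    sampling_info = []
    failures = []
    eval_seeds = ss_eval.spawn(len(selected))
    for k, (res, es) in enumerate(zip(selected, eval_seeds)):
        tree_id = f"sim{k:03d}"
        try:
            if config.reference == "truth":
                ref_profile = truth_profile(res.tree)
                ref_params = None
            else:
                full = AncestralRangeModel(res.tree, model=config.model).fit(
                    n_restarts=config.n_restarts, seed=_child_seed(es)
                )
                ref_profile = inclusion_profile(full.ancestral_marginals())
                ref_params = full.params
            recs, infos = _evaluate_tree(
                res, ref_profile, config, tree_id, _child_seed(es), ref_params
            )
            frames.append(recs)
            sampling_info.extend(infos)
        except Exception as exc:  # isolate per-tree failures
            log.error("tree %s failed: %s", tree_id, exc)
            failures.append({"tree_id": tree_id, "error": str(exc)})
    if not frames:
        raise RuntimeError(f"every tree failed: {failures}")
    records = pd.concat(frames, ignore_index=True)
    summary = bin_and_summarize(records, mode=config.bin_mode, n_bins=config.n_bins)

    predict = {
        scen.label: correlate_predictors(records[records["scenario"] == scen.label])
        for scen in config.scenarios
    }

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "n_selected": len(selected),
        "target_summary": target_summary.as_dict(),
        "sampling": sampling_info,
        "failures": failures,
    }
    out = StudyResult(
        config=config,
        records=records,
        summary=summary,
        candidates=candidates,
        predictability=predict,
        selected=selected,
        manifest=manifest,
        outdir=outdir,
    )
    if outdir is not None:
        _write_outputs(out)
    return out


def _write_outputs(result: StudyResult) -> None:
    outdir = result.outdir
    os.makedirs(outdir, exist_ok=True)
    result.records.to_csv(os.path.join(outdir, "records.tsv"), sep="\t", index=False)
    result.summary.to_csv(os.path.join(outdir, "summary.tsv"), sep="\t", index=False)
    if result.candidates is not None:
        result.candidates.to_csv(
            os.path.join(outdir, "candidates.tsv"), sep="\t", index=False
        )
    pred = {k: v.as_dict() for k, v in result.predictability.items()}
    with open(os.path.join(outdir, "predictability.json"), "w") as fh:
        json.dump(pred, fh, indent=2, sort_keys=True)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    tree_dir = os.path.join(outdir, "trees")
    os.makedirs(tree_dir, exist_ok=True)
    for k, res in enumerate(result.selected):
        write_newick(res.tree, os.path.join(tree_dir, f"sim{k:03d}.nwk"))


def run_empirical_style(
    trees: Sequence[PhyloTree],
    scenarios: Sequence[SamplingScenario] = (
        EXTANT_ONLY,
        SamplingScenario(1.0, 0.05, "random"),
        SamplingScenario(1.0, 0.25, "random"),
        SamplingScenario(1.0, 0.50, "random"),
    ),
    model: str = "DEC+J",
    n_restarts: int = 2,
    n_bins: int = 4,
    bin_mode: str = "quantile",
    seed: int = 1,
    outdir: Optional[str] = None,
) -> StudyResult:
    """Evaluate fossil-subsampling scenarios against the full-tree inference.

    ``trees`` are bound trees (ranges attached), e.g. a posterior sample.
    The reference for accuracy is the inference on each full tree, so the
    extant-only records quantify the *difference* fossils make rather than
    accuracy against an unknown truth.
    """
    cfg = ExperimentConfig(
        scenarios=tuple(scenarios),
        model=model,
        reference="inferred",
        n_restarts=n_restarts,
        n_bins=n_bins,
        bin_mode=bin_mode,
        seed=seed,
        n_candidates=1,
        k_keep=1,
    )
    root_ss = np.random.SeedSequence(seed)
    frames = []
    failures = []
    for k, (tree, es) in enumerate(zip(trees, root_ss.spawn(len(trees)))):
        tree_id = f"tree{k:03d}"
        try:
            full = AncestralRangeModel(tree, model=model).fit(
                n_restarts=n_restarts, seed=_child_seed(es)
            )
            ref_profile = inclusion_profile(full.ancestral_marginals())
            # wrap the bare tree in the minimal result the scenario code needs
            from .sampling import tip_lifespan_segments

            pseudo = SimulationResult(
                tree=tree,
                params=SimParams(0, 0, 0, 0, 0),
                seed=None,
                n_attempts=1,
                t_stop=tree.root_age,
                stem_time=0.0,
                total_lineage_time=tree.total_branch_length(),
                events=[],
                exposures={},
                counts={},
                trajectories=tip_lifespan_segments(tree),
            )
            recs, _ = _evaluate_tree(
                pseudo, ref_profile, cfg, tree_id, _child_seed(es), full.params
            )
            frames.append(recs)
        except Exception as exc:
            log.error("tree %s failed: %s", tree_id, exc)
            failures.append({"tree_id": tree_id, "error": str(exc)})
    if not frames:
        raise RuntimeError(f"every tree failed: {failures}")
    records = pd.concat(frames, ignore_index=True)
    summary = bin_and_summarize(records, mode=bin_mode, n_bins=n_bins)
    predict = {
        scen.label: correlate_predictors(records[records["scenario"] == scen.label])
        for scen in scenarios
    }
    manifest = {
        "package_version": __version__,
        "mode": "empirical-style",
        "seed": seed,
        "n_trees": len(trees),
        "failures": failures,
        "scenarios": [dataclasses.asdict(s) for s in scenarios],
    }
    out = StudyResult(
        config=cfg,
        records=records,
        summary=summary,
        candidates=None,
        predictability=predict,
        selected=[],
        manifest=manifest,
        outdir=outdir,
    )
    if outdir is not None:
        _write_outputs(out)
    return out
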