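"""Accuracy of ancestral-range estimates on reduced trees.

Every internal node (clade) of a reduced tree is matched to the smallest
clade of a reference tree containing the same species — the MRCA of its
retained tip set.  Accuracy on a continent is one minus the absolute
difference between the reference and estimated probabilities that the
continent belongs to the ancestral range; total accuracy is the product of
the four continental accuracies.  The reference is either the full-tree
inference (empirical mode) or the simulation truth (truth mode, where the
true node range gives inclusion probability 1 to member continents and 0
otherwise).  Per-tree bin means over node ages are summarized across trees
by their mean and shortest-interval 95% HPD.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dec import AncestralRangeModel, AncestryProfile, DECParams
from .geography import AREAS
from .trees import Node, PhyloTree
from .predictability import sampling_similarity

__all__ = [
    "match_clades",
    "node_accuracy",
    "truth_profile",
    "inclusion_profile",
    "continent_counts",
    "evaluate_scenario",
    "bin_and_summarize",
    "hpd_interval",
]


def _node_tipsets(tree: PhyloTree) -> List[Tuple[Node, FrozenSet[str]]]:
    sets: Dict[int, FrozenSet[str]] = {}
    out = []
    for node in tree.postorder():
        if node.is_tip:
            sets[id(node)] = frozenset((node.name,))
        else:
            sets[id(node)] = frozenset().union(*(sets[id(c)] for c in node.children))
        out.append((node, sets[id(node)]))
    return out


def match_clades(
    reduced_tree: PhyloTree, reference_tree: PhyloTree
) -> Dict[FrozenSet[str], Node]:
    """Map each reduced-tree clade to its MRCA node in the reference tree.

    The MRCA of a clade's tip set is the smallest reference clade
    containing those species (it may subtend additional, e.g. extinct,
    species).  Keys are the reduced clades' tip-name frozensets.
    """
    ref_sets = _node_tipsets(reference_tree)
    ref_tips = ref_sets[-1][1]
    mapping: Dict[FrozenSet[str], Node] = {}
    for node, tipset in _node_tipsets(reduced_tree):
        if node.is_tip:
            continue
        missing = tipset - ref_tips
        if missing:
            raise KeyError(
                f"reduced-tree species absent from reference: {sorted(missing)}"
            )
        best = None
        best_size = None
        for ref_node, ref_set in ref_sets:
            if tipset <= ref_set and (best is None or len(ref_set) < best_size):
                best, best_size = ref_node, len(ref_set)
        mapping[tipset] = best
    return mapping


def node_accuracy(
    p_ref: Sequence[float], p_est: Sequence[float]
) -> Tuple[np.ndarray, float]:
    """Per-continent accuracy ``1 - |p_ref - p_est|`` and their product."""
    p_ref = np.asarray(p_ref, dtype=float)
    p_est = np.asarray(p_est, dtype=float)
    if np.any((p_ref < 0) | (p_ref > 1) | (p_est < 0) | (p_est > 1)):
        raise ValueError("inclusion probabilities must lie in [0, 1]")
    cont = 1.0 - np.abs(p_ref - p_est)
    return cont, float(np.prod(cont))


def truth_profile(tree: PhyloTree, areas: Sequence[str] = AREAS) -> Dict[FrozenSet[str], np.ndarray]:
    """Simulation-truth inclusion probabilities (0/1) per clade of a tree."""
    profile: Dict[FrozenSet[str], np.ndarray] = {}
    for node, tipset in _node_tipsets(tree):
        if node.is_tip:
            continue
        if node.range_ is None:
            raise ValueError("tree has no recorded true node ranges")
        profile[tipset] = np.array(
            [1.0 if a in node.range_ else 0.0 for a in areas]
        )
    return profile


def inclusion_profile(profile: AncestryProfile) -> Dict[FrozenSet[str], np.ndarray]:
    """Clade -> per-continent inclusion probabilities from a fitted profile."""
    return {c: profile.inclusion[i] for i, c in enumerate(profile.clades)}


def continent_counts(
    reference_tree: PhyloTree, areas: Sequence[str] = AREAS
) -> Dict[FrozenSet[str], Tuple[np.ndarray, np.ndarray]]:
    """Per-clade (extant, all-species) presence counts per continent.

    A species adds one count to every continent of its range; extinct
    species are scored by their range at extinction.  Used as the
    sampling-similarity contingency table.
    """
    out: Dict[FrozenSet[str], Tuple[np.ndarray, np.ndarray]] = {}
    idx = {a: i for i, a in enumerate(areas)}
    tip_vec: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    for node in reference_tree.postorder():
        if node.is_tip:
            v = np.zeros(len(areas))
            for a in node.range_ or ():
                v[idx[a]] = 1.0
            tip_vec[id(node)] = (np.zeros(len(areas)) if node.extinct else v, v)
        else:
            ext = sum((tip_vec[id(c)][0] for c in node.children), np.zeros(len(areas)))
            allsp = sum((tip_vec[id(c)][1] for c in node.children), np.zeros(len(areas)))
            tip_vec[id(node)] = (ext, allsp)
            out[reference_tree.clade_tips(node)] = (ext, allsp)
    return out


def evaluate_scenario(
    reference_tree: PhyloTree,
    reference_profile: Dict[FrozenSet[str], np.ndarray],
    reduced_tree: PhyloTree,
    model: str = "DEC+J",
    params: Optional[DECParams] = None,
    fit_kwargs: Optional[dict] = None,
    tree_id: str = "tree",
    scenario: str = "scenario",
    similarity: bool = True,
) -> pd.DataFrame:
    """Fit the range model on a reduced tree and score it against a reference.

    ``reference_profile`` maps reference-tree clades to per-continent
    inclusion probabilities (simulation truth or a full-tree inference).
    If ``params`` is given the fit is skipped and marginals are computed at
    those rates.  Returns one row per internal node of the reduced tree.
    """
    arm = AncestralRangeModel(reduced_tree, model=model)
    if params is None:
        res = arm.fit(**(fit_kwargs or {}))
        fitted, llf, converged = res.params, res.llf, res.converged
        profile = res.ancestral_marginals()
    else:
        fitted, converged = params, True
        profile = arm.ancestral_marginals(params)
        llf = profile.loglik
    est = inclusion_profile(profile)
    mapping = match_clades(reduced_tree, reference_tree)
    counts = continent_counts(reference_tree) if similarity else {}
    rows = []
    for clade, ref_node in mapping.items():
        ref_key = reference_tree.clade_tips(ref_node)
        if ref_key not in reference_profile:
            continue  # e.g. the reduced clade maps onto a reference tip
        p_ref = reference_profile[ref_key]
        p_est = est[clade]
        cont, total = node_accuracy(p_ref, p_est)
        sim_p = np.nan
        if similarity and ref_key in counts:
            ext, allsp = counts[ref_key]
            if ext.sum() > 0 and allsp.sum() > 0:
                sim_p = sampling_similarity(ext, allsp)
        row = {
            "tree_id": tree_id,
            "scenario": scenario,
            "clade_size": len(clade),
            "ref_clade_size": len(ref_key),
            "age_Ma": ref_node.age,
            "total_accuracy": total,
            "sampling_similarity_p": sim_p,
            "d": fitted.d,
            "e": fitted.e,
            "j": fitted.j,
            "loglik": llf,
            "converged": converged,
        }
        for a, v in zip(AREAS, cont):
            row[f"acc_{a}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Binning and cross-tree summaries
# ---------------------------------------------------------------------------

def hpd_interval(samples: Sequence[float], mass: float = 0.95) -> Tuple[float, float]:
    """Shortest interval containing ``mass`` of the sample."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    k = max(int(np.ceil(mass * n)), 1)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 + np.arange(n - k + 1)] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def bin_and_summarize(
    records: pd.DataFrame,
    mode: str = "quantile",
    n_bins: int = 4,
    value: str = "total_accuracy",
    edges: Optional[Sequence[float]] = None,
    mass: float = 0.95,
) -> pd.DataFrame:
    """Per-tree bin means of accuracy over node age, summarized across trees.

    ``mode='quantile'`` bins each tree's node ages by its own quantiles
    (the comparison the simulations call for, since root ages differ);
    ``mode='absolute'`` uses the supplied common ``edges`` in Ma.  Empty
    bins are reported as missing, never as zero.  Returns one row per
    (scenario, bin) with mean-of-per-tree-means and the 95% HPD across
    trees.
    """
    if mode not in ("quantile", "absolute"):
        raise ValueError("mode must be 'quantile' or 'absolute'")
    if mode == "absolute" and edges is None:
        raise ValueError("absolute mode needs explicit bin edges")
    df = records.copy()
    bins = pd.Series(0, index=df.index, dtype=int)
    for _, idx in df.groupby(["tree_id", "scenario"]).groups.items():
        ages = df.loc[idx, "age_Ma"]
        if mode == "quantile":
            ranks = ages.rank(method="first") - 1
            bins.loc[idx] = np.minimum(
                (ranks / len(ages) * n_bins).astype(int), n_bins - 1
            )
        else:
            bins.loc[idx] = np.searchsorted(
                np.asarray(edges, dtype=float), ages.to_numpy(), side="right"
            )
    df["age_bin"] = bins
    per_tree = (
        df.groupby(["scenario", "tree_id", "age_bin"])[value].mean().reset_index()
    )
    rows = []
    for (scen, b), grp in per_tree.groupby(["scenario", "age_bin"]):
        vals = grp[value].to_numpy()
        lo, hi = hpd_interval(vals, mass)
        rows.append(
            {
                "scenario": scen,
                "age_bin": int(b),
                "n_trees": len(vals),
                "mean": float(vals.mean()),
                "hpd_low": lo,
                "hpd_high": hi,
            }
        )
    return pd.DataFrame(rows)
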