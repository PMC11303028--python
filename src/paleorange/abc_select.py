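"""Summary statistics and ABC rejection for choosing plausible simulated trees.

Five summaries characterize each simulated tree: total tree length, root
height, the fraction of species still extant, the number of extant species
occupying two continents, and the fraction of sister-species pairs
(cherries) whose members are single-continent endemics on different
continents (extinct members scored by the continent they last occupied).
Candidates are ranked by the largest absolute log error (ALE_max) of the
five summaries against a target, and the k best are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .trees import PhyloTree

__all__ = ["ABCSummary", "summary_stats", "ale", "select_trees", "CRITERIA"]

CRITERIA = (
    "tree_length",
    "root_height",
    "frac_extant",
    "n_extant_two_continents",
    "frac_split_sisters",
)

#: summaries that are counts and receive the +0.5 continuity offset at zero
_COUNT_LIKE = {"n_extant_two_continents", "frac_split_sisters"}


@dataclass(frozen=True)
class ABCSummary:
    tree_length: float
    root_height: float
    frac_extant: float
    n_extant_two_continents: int
    frac_split_sisters: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in CRITERIA], dtype=float)

    def as_dict(self) -> Dict[str, float]:
        return {c: getattr(self, c) for c in CRITERIA}


def summary_stats(tree: PhyloTree) -> ABCSummary:
    """The five ABC summaries of a simulated (or empirical) tree.

    Tree length includes the branches of extinct subtrees.  The sister-pair
    criterion is computed over cherries — tip pairs that are mutual
    sisters — scoring an extinct member solely by its last-occupied
    continent; it requires ``last_continent`` on extinct tips.
    """
    tips = tree.tips()
    n_tips = len(tips)
    extant = [t for t in tips if not t.extinct]
    n_split = 0
    n_cherries = 0
    for node in tree.internal_nodes():
        a, b = node.children
        if not (a.is_tip and b.is_tip):
            continue
        n_cherries += 1
        areas = []
        for t in (a, b):
            if t.extinct:
                if t.last_continent is None:
                    raise ValueError(
                        f"extinct tip {t.name} lacks a last-occupied continent"
                    )
                areas.append(frozenset((t.last_continent,)))
            else:
                if t.range_ is None:
                    raise ValueError(f"tip {t.name} has no range bound")
                areas.append(t.range_)
        if len(areas[0]) == 1 and len(areas[1]) == 1 and areas[0] != areas[1]:
            n_split += 1
    return ABCSummary(
        tree_length=tree.total_branch_length(),
        root_height=tree.root_age,
        frac_extant=len(extant) / n_tips,
        n_extant_two_continents=sum(
            1 for t in extant if t.range_ is not None and len(t.range_) >= 2
        ),
        frac_split_sisters=n_split / n_cherries,
    )


def ale(r_emp: float, r_sim: float) -> float:
    """Absolute log error ``|ln(r_emp / r_sim)|`` between two summaries."""
    if r_emp <= 0 or r_sim <= 0:
        raise ValueError(
            f"ALE requires positive values, got ({r_emp}, {r_sim}); "
            "offset zero-valued counts before calling"
        )
    return abs(float(np.log(r_emp / r_sim)))


def _offset_pair(emp: float, sim: float, criterion: str) -> Tuple[float, float]:
    # Continuity correction: zero counts make the log error undefined, so
    # when either side of a count-like summary is zero both get +0.5.
    if criterion in _COUNT_LIKE and (emp <= 0 or sim <= 0):
        return emp + 0.5, sim + 0.5
    return emp, sim


def ale_profile(candidate: ABCSummary, target: ABCSummary) -> np.ndarray:
    """ALE for each of the five criteria (count zeros offset by +0.5)."""
    out = np.empty(len(CRITERIA))
    for k, c in enumerate(CRITERIA):
        emp, sim = _offset_pair(getattr(target, c), getattr(candidate, c), c)
        out[k] = ale(emp, sim)
    return out


def select_trees(
    candidate_summaries: Sequence[ABCSummary],
    empirical_summary: ABCSummary,
    k: int,
) -> Tuple[List[int], pd.DataFrame]:
    """Indices of the k candidates with smallest ALE_max (ties by index).

    Returns the selected indices (best first) and a DataFrame with the
    per-criterion ALEs and ALE_max for every candidate.  Candidates whose
    summary is None (failed simulations) rank last with infinite ALE_max.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = len(candidate_summaries)
    if k > n:
        raise ValueError(f"cannot select {k} of {n} candidates")
    ales = np.full((n, len(CRITERIA)), np.inf)
    for i, cand in enumerate(candidate_summaries):
        if cand is not None:
            ales[i] = ale_profile(cand, empirical_summary)
    ale_max = ales.max(axis=1)
    order = np.lexsort((np.arange(n), ale_max))
    selected = [int(i) for i in order[:k]]
    report = pd.DataFrame(ales, columns=[f"ale_{c}" for c in CRITERIA])
    report["ale_max"] = ale_max
    report["rank"] = np.empty(n, dtype=int)
    report.loc[order, "rank"] = np.arange(n)
    report["selected"] = report["rank"] < k
    return selected, report
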