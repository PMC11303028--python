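"""Predictors of accuracy loss: node age and sampling similarity.

When fossils are omitted, the accuracy of an ancestral-range estimate
should degrade more for older nodes and for clades whose extant species
have a different geographic spread than the clade as a whole.  *Sampling
similarity* quantifies the latter as the p-value of a Fisher exact test
comparing, per clade, the per-continent species counts among extant
species against those among all (extant plus extinct) species: a high
p-value means the extant species are a geographically representative
sample.  Per tree, accuracy is rank-correlated with both predictors and
their strengths are compared by a paired t-test across trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "sampling_similarity",
    "fisher_exact_rxc",
    "correlate_predictors",
    "compare_predictors",
    "PredictabilityResult",
    "PairedTestResult",
]

#: p-values within this relative slack of the observed table probability
#: count as "as or more extreme" (guards against float round-off in the
#: standard two-sided probability-mass criterion).
_REL_EPS = 1e-7


def _row_log_prob(x: np.ndarray, col_totals: np.ndarray, r1: int) -> np.ndarray:
    """Log multivariate-hypergeometric pmf of first-row vectors ``x``."""
    n = col_totals.sum()
    const = -(gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
    terms = (
        gammaln(col_totals + 1)
        - gammaln(x + 1)
        - gammaln(col_totals - x + 1)
    ).sum(axis=-1)
    return terms + const


def _enumerate_first_rows(col_totals: np.ndarray, r1: int) -> np.ndarray:
    """All first rows of 2xc tables with the given margins."""
    rows: List[List[int]] = [[]]
    remaining = col_totals.sum()
    for c in col_totals:
        remaining -= c
        new_rows = []
        for prefix in rows:
            used = sum(prefix)
            lo = max(0, r1 - used - remaining)
            hi = min(c, r1 - used)
            for x in range(lo, hi + 1):
                new_rows.append(prefix + [x])
        rows = new_rows
    return np.array(rows, dtype=int)


def fisher_exact_rxc(
    table: Sequence[Sequence[float]],
    exact_threshold: int = 200,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided Fisher exact test for a 2xc contingency table.

    Exact enumeration of all tables with the observed margins when the
    grand total is at most ``exact_threshold``; otherwise Monte-Carlo with
    ``n_mc`` tables drawn from the multivariate hypergeometric null.  The
    two-sided p-value sums the probabilities of all tables no more likely
    than the observed one.  Zero-count columns are dropped (they carry no
    information and break the enumeration); a table with a single
    informative column has p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2 x c")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] < 2 or t[0].sum() == 0 or t[1].sum() == 0:
        return 1.0
    col_totals = t.sum(axis=0)
    r1 = int(t[0].sum())
    obs_lp = float(_row_log_prob(t[0].astype(float), col_totals, r1))
    cutoff = obs_lp + np.log1p(_REL_EPS)
    if t.sum() <= exact_threshold:
        X = _enumerate_first_rows(col_totals, r1)
        lp = _row_log_prob(X, col_totals, r1)
        return float(np.exp(lp[lp <= cutoff]).sum())
    rng = np.random.default_rng(seed)
    X = rng.multivariate_hypergeometric(col_totals, r1, size=n_mc)
    lp = _row_log_prob(X, col_totals, r1)
    return float(np.mean(lp <= cutoff))


def sampling_similarity(
    extant_counts: Sequence[float],
    all_counts: Sequence[float],
    **kwargs,
) -> float:
    """Fisher exact p-value that extant and all-species counts per
    continent are draws from the same distribution."""
    return fisher_exact_rxc(
        np.vstack([extant_counts, all_counts]), **kwargs
    )


@dataclass
class PredictabilityResult:
    per_tree: pd.DataFrame  # columns: tree_id, rho_age, rho_similarity
    median_rho_age: float
    median_rho_similarity: float
    range_rho_age: Tuple[float, float]
    range_rho_similarity: Tuple[float, float]
    paired_test: "PairedTestResult"

    def as_dict(self) -> dict:
        return {
            "median_rho_age": self.median_rho_age,
            "median_rho_similarity": self.median_rho_similarity,
            "range_rho_age": list(self.range_rho_age),
            "range_rho_similarity": list(self.range_rho_similarity),
            "paired_t": self.paired_test.statistic,
            "paired_p": self.paired_test.pvalue,
            "n_trees": int(len(self.per_tree)),
        }


@dataclass
class PairedTestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


def correlate_predictors(
    records: pd.DataFrame,
    method: str = "spearman",
    value: str = "total_accuracy",
) -> PredictabilityResult:
    """Per-tree correlation of accuracy with node age and sampling similarity.

    ``records`` needs columns ``tree_id``, ``age_Ma``,
    ``sampling_similarity_p`` and the accuracy column.  Trees with fewer
    than 3 usable nodes, or with constant accuracy (undefined rank
    correlation), are recorded as missing and excluded from the medians.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for tree_id, grp in records.groupby("tree_id"):
        acc = grp[value].to_numpy(dtype=float)
        age = grp["age_Ma"].to_numpy(dtype=float)
        simp = grp["sampling_similarity_p"].to_numpy(dtype=float)
        ok = np.isfinite(acc) & np.isfinite(age)
        rho_age = rho_sim = np.nan
        if ok.sum() >= 3 and np.ptp(acc[ok]) > 0:
            if np.ptp(age[ok]) > 0:
                rho_age = float(corr(acc[ok], age[ok]).statistic)
            ok_s = ok & np.isfinite(simp)
            if ok_s.sum() >= 3 and np.ptp(acc[ok_s]) > 0 and np.ptp(simp[ok_s]) > 0:
                rho_sim = float(corr(acc[ok_s], simp[ok_s]).statistic)
        rows.append(
            {"tree_id": tree_id, "rho_age": rho_age, "rho_similarity": rho_sim}
        )
    per_tree = pd.DataFrame(rows)
    ra = per_tree["rho_age"].dropna()
    rs = per_tree["rho_similarity"].dropna()
    both = per_tree.dropna()
    test = (
        compare_predictors(both["rho_age"].to_numpy(), both["rho_similarity"].to_numpy())
        if len(both) >= 2
        else PairedTestResult(np.nan, np.nan, True)
    )
    return PredictabilityResult(
        per_tree=per_tree,
        median_rho_age=float(ra.median()) if len(ra) else np.nan,
        median_rho_similarity=float(rs.median()) if len(rs) else np.nan,
        range_rho_age=(float(ra.min()), float(ra.max())) if len(ra) else (np.nan, np.nan),
        range_rho_similarity=(float(rs.min()), float(rs.max())) if len(rs) else (np.nan, np.nan),
        paired_test=test,
    )


def compare_predictors(
    rho_age: Sequence[float],
    rho_similarity: Sequence[float],
    absolute: bool = True,
) -> PairedTestResult:
    """Paired t-test of predictor strengths across trees.

    By default the *absolute* correlations are compared (age correlates
    negatively with accuracy, similarity positively, so signed values are
    not commensurable).  Conventions for degenerate inputs: identical
    paired vectors give t = 0, p = 1; a nonzero constant difference (zero
    variance) is reported as p -> 0 with a degeneracy flag.
    """
    a = np.asarray(rho_age, dtype=float)
    b = np.asarray(rho_similarity, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with >= 2 pairs")
    if absolute:
        a, b = np.abs(a), np.abs(b)
    diff = a - b
    if np.allclose(diff, 0.0):
        return PairedTestResult(0.0, 1.0)
    if np.isclose(diff.std(ddof=1), 0.0):
        return PairedTestResult(np.sign(diff.mean()) * np.inf, 0.0, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTestResult(float(res.statistic), float(res.pvalue))
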