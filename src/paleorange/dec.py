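"""DEC and DEC+J likelihoods, ML fitting and marginal ancestral ranges.

The dispersal–extinction–cladogenesis (DEC) model describes range evolution
along a time-calibrated tree with two coupled processes:

* **anagenetic** (along branches): a continuous-time Markov chain over
  ranges in which a range expands into an adjacent area at rate
  ``d × (number of occupied areas adjacent to the target)`` and loses an
  occupied area at rate ``e`` per area; a singleton range contracts into an
  absorbing null state at rate ``e``;
* **cladogenetic** (at nodes): at each speciation the ancestral range is
  partitioned between the daughters by narrow sympatry, subset sympatry or
  vicariance (all weight 1), and — under DEC+J — founder-event "jump"
  dispersal into an adjacent unoccupied area with weight ``j``.  Weights
  are normalized per ancestral state; DEC is the ``j = 0`` submodel.

Fossil tips need no special treatment: a tip observed at age ``t > 0``
simply terminates its branch early, and its conditional likelihood is an
indicator at the observed range.

The public surface follows the Model/Results convention:
``AncestralRangeModel(tree).fit()`` returns an
:class:`AncestralRangeResults` carrying fitted rates, the log-likelihood
and marginal ancestral-range reconstructions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import minimize

from .geography import AREAS, Range, RangeStateSpace
from .trees import PhyloTree, TreeValidationError

__all__ = [
    "DECParams",
    "CladoEventDistribution",
    "AncestryProfile",
    "AncestralRangeModel",
    "AncestralRangeResults",
    "anagenetic_generator",
    "clado_distribution",
    "tree_loglik",
    "ancestral_marginals",
    "fit_ml",
    "NonFiniteLikelihoodError",
]


class NonFiniteLikelihoodError(ValueError):
    """Raised when the pruning recursion produces a non-finite partial."""


@dataclass(frozen=True)
class DECParams:
    """Rates of the DEC/DEC+J model, per Ma.

    d : range-expansion (dispersal) rate per adjacent area pair
    e : per-area range-loss rate
    j : jump-dispersal cladogenetic weight (0 under plain DEC)
    """

    d: float
    e: float
    j: float = 0.0

    def __post_init__(self) -> None:
        for f in ("d", "e", "j"):
            v = getattr(self, f)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f} must be finite and >= 0, got {v}")

    def as_array(self, with_j: bool = True) -> np.ndarray:
        return np.array([self.d, self.e, self.j] if with_j else [self.d, self.e])


def anagenetic_generator(space: RangeStateSpace, params: DECParams) -> np.ndarray:
    """Instantaneous rate matrix over the state space (null included, absorbing)."""
    n = space.n_states
    Q = np.zeros((n, n))
    for i, S in enumerate(space.states):
        if len(S) < space.max_range_size:
            reachable = frozenset().union(*(space.neighbors(a) for a in S)) - S
            for a in reachable:
                k = sum(1 for b in S if space.is_adjacent(a, b))
                Q[i, space.index[S | {a}]] = params.d * k
        if len(S) > 1:
            for a in S:
                Q[i, space.index[S - {a}]] = params.e
        else:
            Q[i, space.null_index] = params.e
    Q[np.arange(n), np.arange(n)] -= Q.sum(axis=1)
    return Q


class CladoEventDistribution:
    """Per-ancestral-state distribution over ordered daughter-range pairs.

    Stored as flat parallel arrays ``(anc, left, right, prob)`` over state
    indices; probabilities sum to 1 within each ancestral state.
    """

    def __init__(
        self,
        space: RangeStateSpace,
        anc: np.ndarray,
        left: np.ndarray,
        right: np.ndarray,
        prob: np.ndarray,
    ) -> None:
        self.space = space
        self.anc = anc
        self.left = left
        self.right = right
        self.prob = prob

    def table(self, state: Range) -> List[Tuple[Range, Range, float]]:
        """Event triples ``(left_range, right_range, probability)`` for a state."""
        i = self.space.range_index(state)
        sel = self.anc == i
        st = self.space.states

        def rng(k: int) -> Range:
            return st[k] if k < self.space.null_index else frozenset()

        return [
            (rng(l), rng(r), p)
            for l, r, p in zip(self.left[sel], self.right[sel], self.prob[sel])
        ]

    def as_tensor(self) -> np.ndarray:
        """Dense ``(anc, left, right) -> prob`` tensor (for small-scale checks)."""
        n = self.space.n_states
        C = np.zeros((n, n, n))
        C[self.anc, self.left, self.right] = self.prob
        return C


def clado_distribution(space: RangeStateSpace, params: DECParams) -> CladoEventDistribution:
    """Build the cladogenetic event distribution.

    Event weights: narrow sympatry, subset sympatry (both orderings) and
    vicariance with at least one singleton daughter (both orderings) each
    weight 1; jump dispersal into each adjacent unoccupied area weights
    ``j`` per ordering.  Weights are normalized within each ancestral
    state.  The null state deterministically yields two null daughters so
    the arrays cover the whole space (it never receives posterior mass).
    """
    j = params.j
    anc: List[int] = []
    left: List[int] = []
    right: List[int] = []
    prob: List[float] = []
    for i, S in enumerate(space.states):
        events: List[Tuple[int, int, float]] = []
        if len(S) == 1:
            events.append((i, i, 1.0))
        else:
            for a in space.sort_areas(S):
                ia = space.index[frozenset((a,))]
                events.append((ia, i, 1.0))
                events.append((i, ia, 1.0))
            members = space.sort_areas(S)
            # all ordered splits (A, S\A); keep those with a singleton part
            for mask in range(1, 2 ** len(members) - 1):
                A = frozenset(m for k, m in enumerate(members) if mask >> k & 1)
                B = S - A
                if min(len(A), len(B)) == 1:
                    events.append((space.index[A], space.index[B], 1.0))
        if j > 0:
            targets = frozenset().union(*(space.neighbors(a) for a in S)) - S
            for a in space.sort_areas(targets):
                ia = space.index[frozenset((a,))]
                events.append((i, ia, j))
                events.append((ia, i, j))
        total = sum(w for _, _, w in events)
        for l, r, w in events:
            anc.append(i)
            left.append(l)
            right.append(r)
            prob.append(w / total)
    anc.append(space.null_index)
    left.append(space.null_index)
    right.append(space.null_index)
    prob.append(1.0)
    return CladoEventDistribution(
        space,
        np.asarray(anc, dtype=np.intp),
        np.asarray(left, dtype=np.intp),
        np.asarray(right, dtype=np.intp),
        np.asarray(prob, dtype=float),
    )


# ---------------------------------------------------------------------------
# Indexed tree and pruning
# ---------------------------------------------------------------------------

class _IndexedTree:
    """Flat postorder arrays for the pruning recursion."""

    def __init__(self, tree: PhyloTree, space: RangeStateSpace) -> None:
        nodes = tree.postorder()
        self.nodes = nodes
        self.n = len(nodes)
        idx = {id(n): i for i, n in enumerate(nodes)}
        self.is_tip = np.array([n.is_tip for n in nodes])
        self.lengths = np.array([n.length for n in nodes])
        self.left = np.full(self.n, -1, dtype=np.intp)
        self.right = np.full(self.n, -1, dtype=np.intp)
        self.parent = np.full(self.n, -1, dtype=np.intp)
        self.tip_state = np.full(self.n, -1, dtype=np.intp)
        for i, n in enumerate(nodes):
            if n.is_tip:
                if n.range_ is None:
                    raise TreeValidationError(
                        f"tip {n.name} has no range bound; call bind_ranges first"
                    )
                try:
                    self.tip_state[i] = space.range_index(n.range_)
                except ValueError as exc:
                    raise TreeValidationError(f"tip {n.name}: {exc}") from exc
            else:
                l, r = n.children
                self.left[i], self.right[i] = idx[id(l)], idx[id(r)]
                self.parent[idx[id(l)]] = i
                self.parent[idx[id(r)]] = i
        self.root = self.n - 1
        self.internal = np.flatnonzero(~self.is_tip)


def _transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """``exp(Q t)`` for every branch length, via eigendecomposition.

    The 15x15 generator is dense and generically diagonalizable; a single
    eigendecomposition turns every branch into two small matmuls.  If the
    reconstruction is poorly conditioned (near-defective Q) the routine
    falls back to a per-branch Padé expm.
    """
    n = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        E = np.exp(np.outer(lengths, w))
        P = np.einsum("ij,bj,jk->bik", V, E, Vinv).real
        err = np.abs(P.sum(axis=2) - 1.0).max()
        if not np.isfinite(err) or err > 1e-8 or P.min() < -1e-8:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        P = np.empty((len(lengths), n, n))
        cache: Dict[float, np.ndarray] = {}
        for b, t in enumerate(lengths):
            if t not in cache:
                cache[t] = sla.expm(Q * t)
            P[b] = cache[t]
    np.clip(P, 0.0, None, out=P)
    return P


def _uniform_root_prior(space: RangeStateSpace) -> np.ndarray:
    prior = np.zeros(space.n_states)
    prior[: space.n_observable] = 1.0 / space.n_observable
    return prior


def _pruning(
    itree: _IndexedTree,
    space: RangeStateSpace,
    P: np.ndarray,
    clado: Optional[CladoEventDistribution],
    root_prior: np.ndarray,
    keep_partials: bool = False,
):
    """Felsenstein pruning with cladogenetic mixing; returns lnL (and partials)."""
    n_states = space.n_states
    D = np.zeros((itree.n, n_states))
    Dtop = np.zeros((itree.n, n_states))
    logs = np.zeros(itree.n)
    for i in range(itree.n):
        if itree.is_tip[i]:
            v = np.zeros(n_states)
            v[itree.tip_state[i]] = 1.0
        else:
            l, r = itree.left[i], itree.right[i]
            if clado is None:
                v = Dtop[l] * Dtop[r]
            else:
                contrib = clado.prob * Dtop[l, clado.left] * Dtop[r, clado.right]
                v = np.bincount(clado.anc, weights=contrib, minlength=n_states)
            logs[i] = logs[l] + logs[r]
        m = v.max()
        if not np.isfinite(m) or m <= 0.0:
            node = itree.nodes[i]
            raise NonFiniteLikelihoodError(
                f"zero or non-finite partial likelihood at node "
                f"{node.name or f'postorder index {i}'}"
            )
        logs[i] += np.log(m)
        D[i] = v / m
        Dtop[i] = P[i] @ D[i]
    like = float(root_prior @ D[itree.root])
    if like <= 0 or not np.isfinite(like):
        raise NonFiniteLikelihoodError("non-positive likelihood at the root")
    lnl = np.log(like) + logs[itree.root]
    if keep_partials:
        return lnl, D, Dtop
    return lnl


@dataclass
class AncestryProfile:
    """Marginal ancestral-range reconstruction for the internal nodes.

    ``state_probs[k]`` is the posterior over range states for internal node
    ``k`` (keyed by its clade — the frozenset of descendant tip names).
    ``inclusion[k, c]`` is P(area c is part of the ancestral range);
    ``split[k, c]`` divides widespread mass equally among member areas, the
    convention used when a single number per continent is plotted.
    """

    space: RangeStateSpace
    clades: List[FrozenSet[str]]
    ages: np.ndarray
    state_probs: np.ndarray
    inclusion: np.ndarray
    split: np.ndarray
    loglik: float

    def __post_init__(self) -> None:
        self._by_clade = {c: i for i, c in enumerate(self.clades)}

    def row(self, clade: FrozenSet[str]) -> int:
        return self._by_clade[clade]

    def inclusion_for(self, clade: FrozenSet[str]) -> np.ndarray:
        return self.inclusion[self._by_clade[clade]]

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        cols["clade_size"] = [len(c) for c in self.clades]
        cols["clade_hash"] = [
            format(hash(tuple(sorted(c))) & 0xFFFFFFFF, "08x") for c in self.clades
        ]
        cols["age_Ma"] = self.ages
        for s in range(self.space.n_observable):
            cols[f"P[{self.space.label(s)}]"] = self.state_probs[:, s]
        for a_i, a in enumerate(self.space.areas):
            cols[f"incl_{a}"] = self.inclusion[:, a_i]
        for a_i, a in enumerate(self.space.areas):
            cols[f"split_{a}"] = self.split[:, a_i]
        return pd.DataFrame(cols)


def _summaries(space: RangeStateSpace, probs: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    n_areas = len(space.areas)
    member = np.zeros((space.n_states, n_areas))
    for i, S in enumerate(space.states):
        for a in S:
            member[i, space.area_index(a)] = 1.0
    sizes = np.maximum(member.sum(axis=1), 1.0)
    inclusion = probs @ member
    split = probs @ (member / sizes[:, None])
    return inclusion, split


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class AncestralRangeModel:
    """DEC / DEC+J range-evolution model on a tree with optional fossil tips.

    Parameters
    ----------
    tree : PhyloTree
        Binary tree with tip ranges bound (extant and fossil tips alike).
    model : {"DEC", "DEC+J"}
        Whether the jump-dispersal weight ``j`` is estimated (DEC+J) or
        fixed at 0 (DEC).
    state_space : RangeStateSpace, optional
        Defaults to the four-continent chain with ranges up to size 3.
    root_prior : {"uniform"} or array, optional
        Prior over root states; default uniform over observable states
        (no conditioning on survival).
    cladogenesis : {"full", "none"}
        "none" disables cladogenetic mixing (daughters inherit the parent
        state); useful for purely anagenetic analyses and diagnostics.
    """

    #: optimizer box constraints, per Ma
    BOUNDS = {"d": (1e-8, 5.0), "e": (1e-8, 5.0), "j": (0.0, 3.0)}

    def __init__(
        self,
        tree: PhyloTree,
        model: str = "DEC+J",
        state_space: Optional[RangeStateSpace] = None,
        root_prior=None,
        cladogenesis: str = "full",
    ) -> None:
        if model not in ("DEC", "DEC+J"):
            raise ValueError("model must be 'DEC' or 'DEC+J'")
        if cladogenesis not in ("full", "none"):
            raise ValueError("cladogenesis must be 'full' or 'none'")
        self.tree = tree
        self.model = model
        self.space = state_space or RangeStateSpace(AREAS, max_range_size=3)
        self.cladogenesis = cladogenesis
        if root_prior is None or (isinstance(root_prior, str) and root_prior == "uniform"):
            self.root_prior = _uniform_root_prior(self.space)
        else:
            rp = np.asarray(root_prior, dtype=float)
            if rp.shape != (self.space.n_states,) or rp[self.space.null_index] != 0:
                raise ValueError(
                    "root_prior must have one entry per state with zero on null"
                )
            self.root_prior = rp / rp.sum()
        self._itree = _IndexedTree(tree, self.space)

    @classmethod
    def from_files(
        cls,
        newick_path,
        geography_path,
        tip_ages: Optional[Dict[str, float]] = None,
        **kwargs,
    ) -> "AncestralRangeModel":
        from .trees import bind_ranges, read_geography, read_newick

        tree = read_newick(newick_path, tip_ages=tip_ages)
        bind_ranges(tree, read_geography(geography_path))
        return cls(tree, **kwargs)

    # -- likelihood ------------------------------------------------------
    def _prepare(self, params: DECParams):
        Q = anagenetic_generator(self.space, params)
        P = _transition_matrices(Q, self._itree.lengths)
        clado = (
            clado_distribution(self.space, params)
            if self.cladogenesis == "full"
            else None
        )
        return P, clado

    def loglike(self, params: DECParams) -> float:
        """Log-likelihood of the tip ranges under the given rates."""
        if self.model == "DEC" and params.j != 0:
            raise ValueError("DEC requires j = 0")
        P, clado = self._prepare(params)
        return float(_pruning(self._itree, self.space, P, clado, self.root_prior))

    def _neg_loglike_vec(self, x: np.ndarray) -> float:
        params = DECParams(x[0], x[1], x[2] if len(x) > 2 else 0.0)
        try:
            return -self.loglike(params)
        except NonFiniteLikelihoodError:
            return 1e10

    def fit(
        self,
        n_restarts: int = 5,
        seed: int = 0,
        start: Optional[DECParams] = None,
        gtol: float = 1e-6,
    ) -> "AncestralRangeResults":
        """Bounded multi-start quasi-Newton ML fit; deterministic given seed."""
        if self.tree.n_tips < 3:
            raise TreeValidationError("fitting requires at least 3 tips")
        with_j = self.model == "DEC+J"
        names = ("d", "e", "j") if with_j else ("d", "e")
        bounds = [self.BOUNDS[k] for k in names]
        rng = np.random.default_rng(seed)
        starts: List[np.ndarray] = []
        if start is not None:
            starts.append(start.as_array(with_j))
        while len(starts) < max(n_restarts, 1):
            x0 = np.array(
                [10 ** rng.uniform(-3, 0) for _ in ("d", "e")]
                + ([rng.uniform(0.0, 1.0)] if with_j else [])
            )
            starts.append(x0)
        best = None
        any_success = False
        for x0 in starts:
            res = minimize(
                self._neg_loglike_vec,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"gtol": gtol, "maxiter": 500},
            )
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        params = DECParams(
            best.x[0], best.x[1], best.x[2] if with_j else 0.0
        )
        return AncestralRangeResults(
            model=self,
            params=params,
            llf=-float(best.fun),
            converged=any_success,
            n_restarts=len(starts),
        )

    def ancestral_marginals(self, params: DECParams) -> AncestryProfile:
        """Marginal ancestral-range posteriors at every internal node.

        Combines the standard down-pass (pruning) partials with an up-pass
        that conditions each node on all data outside its subtree.
        """
        itree = self._itree
        space = self.space
        P, clado = self._prepare(params)
        lnl, D, Dtop = _pruning(
            itree, space, P, clado, self.root_prior, keep_partials=True
        )
        n_states = space.n_states
        Out = np.zeros((itree.n, n_states))
        Out[itree.root] = self.root_prior
        order = itree.internal[::-1]  # root first (postorder reversed)
        for i in order:
            out = Out[i]
            l, r = itree.left[i], itree.right[i]
            if clado is None:
                gl = out * Dtop[r]
                gr = out * Dtop[l]
            else:
                wl = clado.prob * out[clado.anc] * Dtop[r, clado.right]
                gl = np.bincount(clado.left, weights=wl, minlength=n_states)
                wr = clado.prob * out[clado.anc] * Dtop[l, clado.left]
                gr = np.bincount(clado.right, weights=wr, minlength=n_states)
            for child, g in ((l, gl), (r, gr)):
                oc = g @ P[child]
                m = oc.max()
                Out[child] = oc / m if m > 0 else oc
        rows = itree.internal
        probs = D[rows] * Out[rows]
        probs /= probs.sum(axis=1, keepdims=True)
        inclusion, split = _summaries(space, probs)
        clades = [self.tree.clade_tips(itree.nodes[i]) for i in rows]
        ages = np.array([itree.nodes[i].age for i in rows])
        return AncestryProfile(
            space=space,
            clades=clades,
            ages=ages,
            state_probs=probs,
            inclusion=inclusion,
            split=split,
            loglik=float(lnl),
        )


@dataclass
class AncestralRangeResults:
    """Fitted DEC/DEC+J rates and derived reconstructions."""

    model: AncestralRangeModel
    params: DECParams
    llf: float
    converged: bool
    n_restarts: int

    def ancestral_marginals(self) -> AncestryProfile:
        if not hasattr(self, "_profile"):
            self._profile = self.model.ancestral_marginals(self.params)
        return self._profile

    @property
    def n_params(self) -> int:
        return 3 if self.model.model == "DEC+J" else 2

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.llf

    def params_dict(self) -> Dict[str, float]:
        return {"d": self.params.d, "e": self.params.e, "j": self.params.j}

    def save_params(self, path) -> None:
        payload = {
            "model": self.model.model,
            "loglik": self.llf,
            "aic": self.aic,
            "converged": self.converged,
            **self.params_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def summary(self) -> str:
        lines = [
            "Ancestral range model results",
            "=" * 46,
            f"Model:            {self.model.model}",
            f"No. tips:         {self.model.tree.n_tips}"
            f"  (fossil: {sum(t.extinct for t in self.model.tree.tips())})",
            f"Log-likelihood:   {self.llf:.4f}",
            f"AIC:              {self.aic:.4f}",
            f"Converged:        {self.converged}  ({self.n_restarts} restarts)",
            "-" * 46,
            f"{'param':<10}{'estimate':>12}    unit",
            f"{'d':<10}{self.params.d:>12.6f}    expansions /pair /Ma",
            f"{'e':<10}{self.params.e:>12.6f}    area losses /Ma",
        ]
        if self.model.model == "DEC+J":
            lines.append(f"{'j':<10}{self.params.j:>12.6f}    jump weight")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional wrappers (thin aliases over the Model object)
# ---------------------------------------------------------------------------

def tree_loglik(
    tree: PhyloTree,
    space: RangeStateSpace,
    params: DECParams,
    root_prior=None,
) -> float:
    return AncestralRangeModel(
        tree, model="DEC+J", state_space=space, root_prior=root_prior
    ).loglike(params)


def ancestral_marginals(
    tree: PhyloTree,
    space: RangeStateSpace,
    params: DECParams,
    root_prior=None,
) -> AncestryProfile:
    return AncestralRangeModel(
        tree, model="DEC+J", state_space=space, root_prior=root_prior
    ).ancestral_marginals(params)


def fit_ml(
    tree: PhyloTree,
    space: Optional[RangeStateSpace] = None,
    model: str = "DEC+J",
    n_restarts: int = 5,
    seed: int = 0,
) -> Tuple[DECParams, float]:
    res = AncestralRangeModel(tree, model=model, state_space=space).fit(
        n_restarts=n_restarts, seed=seed
    )
    return res.params, res.llf
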