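"""Independent oracles used by the test suite.

These deliberately avoid the package's computational paths: transition
probabilities come from scipy's Padé expm (not the eigendecomposition),
likelihoods from explicit joint enumeration over internal-node states (not
pruning), correlations from rank arithmetic, and the paired t from its
closed form.
"""

from __future__ import annotations

import itertools
from math import comb
from typing import Dict

import numpy as np
from scipy.linalg import expm

from paleorange.dec import anagenetic_generator, clado_distribution


def enum_loglik_and_marginals(tree, space, params, root_prior):
    """Joint enumeration over all internal-node state assignments."""
    Q = anagenetic_generator(space, params)
    C = clado_distribution(space, params).as_tensor()
    nodes = tree.postorder()
    P = {id(n): expm(Q * n.length) for n in nodes}
    internal = [n for n in nodes if not n.is_tip]
    tipstate = {id(n): space.range_index(n.range_) for n in nodes if n.is_tip}
    n = space.n_states
    M = {}
    for v in internal:
        l, r = v.children
        M[id(v)] = np.einsum("alr,lx,ry->axy", C, P[id(l)], P[id(r)])
    total = 0.0
    marg = {id(v): np.zeros(n) for v in internal}
    ids = [id(v) for v in internal]
    for assign in itertools.product(range(n), repeat=len(internal)):
        amap = dict(zip(ids, assign))
        term = root_prior[amap[id(tree.root)]]
        if term == 0.0:
            continue
        for v in internal:
            l, r = v.children
            sl = amap[id(l)] if not l.is_tip else tipstate[id(l)]
            sr = amap[id(r)] if not r.is_tip else tipstate[id(r)]
            term *= M[id(v)][amap[id(v)], sl, sr]
            if term == 0.0:
                break
        if term == 0.0:
            continue
        total += term
        for v in internal:
            marg[id(v)][amap[id(v)]] += term
    return np.log(total), {k: v / total for k, v in marg.items()}


def naive_spearman(x, y):
    """Spearman rho via explicit mid-ranks and the Pearson formula."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def paired_t_closed_form(a, b):
    """Textbook paired t statistic and two-sided p-value."""
    from scipy.stats import t as tdist

    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2 * tdist.sf(abs(t), n - 1)
    return t, p


def fisher_2x2_exact(table):
    """Two-sided 2x2 Fisher p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x):
        if x < 0 or x > c1 or r1 - x < 0 or r1 - x > n - c1:
            return 0.0
        return comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1)

    p_obs = prob(a)
    return sum(p for x in range(0, min(r1, c1) + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-9))


def mrca_by_parent_walk(tree, names):
    """MRCA via intersected root-paths (independent of subset scans)."""
    paths = []
    for name in names:
        node = tree.tip(name)
        chain = []
        while node is not None:
            chain.append(id(node))
            node = node.parent
        paths.append(chain)
    common = set(paths[0])
    for chain in paths[1:]:
        common &= set(chain)
    # deepest common ancestor = first element of any root-path in the set
    for nid in paths[0]:
        if nid in common:
            target = nid
            break
    for node in tree.postorder():
        if id(node) == target:
            return node
    raise AssertionError("unreachable")
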