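"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by a different algorithmic route than the
package (explicit path walking, branch enumeration, projection-matrix
partition, exhaustive enumeration) so agreement is meaningful.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def root_path(tip):
    """List of (node, branch length) pairs from a tip up to the root."""
    path = []
    node = tip
    while node.parent is not None:
        path.append((node, node.length or 0.0))
        node = node.parent
    return path


def path_sum_distance(tree, name_a: str, name_b: str) -> float:
    """Cophenetic distance by explicitly walking both root paths and
    cancelling the shared suffix above the common ancestor."""
    tips = {t.name: t for t in tree.tips()}
    pa = root_path(tips[name_a])
    pb = root_path(tips[name_b])
    ids_a = [id(n) for n, _ in pa]
    shared = {id(n) for n, _ in pb} & set(ids_a)
    dist = sum(l for n, l in pa if id(n) not in shared)
    dist += sum(l for n, l in pb if id(n) not in shared)
    return dist


def unifrac_branch_enumeration(tree, a: dict, b: dict, normalized=True) -> float:
    """Weighted UniFrac by enumerating every branch and recomputing its
    descendant tip set from scratch."""
    raw = 0.0
    for node in tree.traverse(include_self=False):
        desc = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        fa = sum(a[n] for n in desc)
        fb = sum(b[n] for n in desc)
        raw += (node.length or 0.0) * abs(fa - fb)
    if not normalized:
        return raw
    denom = 0.0
    for tip in tree.tips():
        d = sum(l for _, l in root_path(tip))
        denom += d * (a[tip.name] + b[tip.name])
    return raw / denom


def pseudo_f_projection(d: np.ndarray, labels) -> tuple[float, float]:
    """PERMANOVA pseudo-F via the Gower-centered matrix and the hat-matrix
    trace partition (McArdle-Anderson route)."""
    labels = np.asarray(labels)
    n = len(labels)
    a = -0.5 * d.astype(float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    groups = np.unique(labels)
    x = np.column_stack([(labels == g_).astype(float) for g_ in groups])
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    ss_between = np.trace(h @ g @ h)
    ss_total = np.trace(g)
    ss_within = ss_total - ss_between
    k = len(groups)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total


def ranksum_exact_p(x, y, alternative="two_sided") -> float:
    """Exact Wilcoxon rank-sum p-value by full enumeration of all
    assignments of the pooled ranks to the first sample (no ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1  # no ties assumed
    rx = ranks[: len(x)].sum()
    n, nx = len(pooled), len(x)
    all_ranks = np.arange(1, n + 1)
    sums = np.array([sum(c) for c in combinations(all_ranks, nx)])
    total = comb(n, nx)
    if alternative == "less":
        return (sums <= rx).sum() / total
    if alternative == "greater":
        return (sums >= rx).sum() / total
    p = 2 * min((sums <= rx).sum(), (sums >= rx).sum()) / total
    return min(p, 1.0)


def bh_stepup(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up pass."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted
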