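"""Tree-based quantities for strain phylogenies.

Trees are :class:`skbio.TreeNode` objects (rooted, branch lengths in
substitutions/site or arbitrary units). This module computes cophenetic
(patristic) distances, Faith's phylogenetic diversity, weighted UniFrac,
and performs PD-targeted synthetic-community (SynCom) design.

Conventions
-----------
* Faith's PD is root-inclusive: the minimal subtree connecting the chosen
  tips is extended to the root, so every branch on each tip's root path is
  counted. Pass ``include_root=False`` for the root-exclusive variant.
* Weighted UniFrac defaults to the normalized variant
  ``sum_b l_b |A_b - B_b| / sum_j d_j (A_j + B_j)`` with ``A_b`` the
  fraction of sample A descending from branch ``b`` and ``d_j`` the
  root-to-tip distance of tip ``j``. Pass ``normalized=False`` for the raw
  branch-length-weighted sum.
* Multifurcations are accepted as-is.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import FormatError

__all__ = [
    "read_newick",
    "write_newick",
    "cophenetic_distances",
    "faith_pd",
    "weighted_unifrac",
    "design_syncoms",
    "SynComDesign",
]


def read_newick(source) -> TreeNode:
    """Read a rooted tree from a Newick file path, handle, or string."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        source = io.StringIO(source)
    return TreeNode.read(source, format="newick")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(path, format="newick")


def _check_tips(tree: TreeNode) -> list:
    tips = list(tree.tips())
    names = [t.name for t in tips]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"duplicate tip labels: {dupes}")
    if len(tips) < 2:
        raise FormatError("tree must have at least 2 tips")
    return tips


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between all tips.

    ``d(x, y)`` is the sum of branch lengths on the unique x-to-y path;
    the diagonal is zero.
    """
    _check_tips(tree)
    return tree.tip_tip_distances()


def faith_pd(tree: TreeNode, tips, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of a tip subset.

    Sum of branch lengths of the minimal subtree connecting ``tips``;
    root-inclusive by default (the subtree is grafted onto the root, so a
    single tip has PD equal to its root-to-tip distance).
    """
    tips = list(tips)
    if not tips:
        raise ValueError("tip subset must be non-empty")
    _check_tips(tree)
    index = {t.name: t for t in tree.tips()}
    unknown = [t for t in tips if t not in index]
    if unknown:
        raise ValueError(f"unknown tip(s): {unknown}")

    branches = set()  # nodes whose parent edge is counted
    for name in tips:
        node = index[name]
        while node.parent is not None:
            if id(node) in branches:
                break
            branches.add(id(node))
            node = node.parent

    if not include_root and len(tips) > 1:
        # drop edges above the most recent common ancestor of the subset
        mrca = tree.lca([index[t] for t in tips])
        node = mrca
        while node.parent is not None:
            branches.discard(id(node))
            node = node.parent

    total = 0.0
    for node in tree.traverse(include_self=False):
        if id(node) in branches:
            total += node.length or 0.0
    return total


def _as_proportions(tree_tips, abundances) -> np.ndarray:
    """Coerce a mapping/Series/array of per-tip proportions to tree order."""
    names = [t.name for t in tree_tips]
    if hasattr(abundances, "get") or hasattr(abundances, "keys"):
        missing = [n for n in names if n not in abundances]
        if missing:
            raise ValueError(f"abundances missing tips: {missing}")
        vec = np.asarray([float(abundances[n]) for n in names])
    else:
        vec = np.asarray(abundances, dtype=float)
        if vec.shape != (len(names),):
            raise ValueError(
                f"expected {len(names)} per-tip proportions, got shape {vec.shape}"
            )
    if (vec < 0).any():
        raise ValueError("negative abundance")
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1 (got {vec.sum():.12g})")
    return vec


def weighted_unifrac(tree: TreeNode, abundances_a, abundances_b,
                     normalized: bool = True) -> float:
    """Abundance-weighted UniFrac distance between two communities.

    Accumulates ``l_b * |A_b - B_b|`` over every branch ``b``, where ``X_b``
    is the fraction of sample X assigned to tips descending from ``b``.
    With ``normalized=True`` (default) the sum is divided by
    ``D = sum_j d_j (A_j + B_j)`` (``d_j`` = root-to-tip distance), which
    bounds the distance in [0, 1].
    """
    tips = _check_tips(tree)
    a = _as_proportions(tips, abundances_a)
    b = _as_proportions(tips, abundances_b)

    tip_pos = {id(t): i for i, t in enumerate(tips)}
    raw = 0.0
    denom = 0.0
    # postorder pass: fraction of each sample under every branch
    frac = {}  # id(node) -> (A_b, B_b)
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = tip_pos[id(node)]
            fa, fb = a[i], b[i]
        else:
            fa = sum(frac[id(c)][0] for c in node.children)
            fb = sum(frac[id(c)][1] for c in node.children)
        frac[id(node)] = (fa, fb)
        if node.parent is not None:
            length = node.length or 0.0
            raw += length * abs(fa - fb)

    if not normalized:
        return raw
    for i, tip in enumerate(tips):
        d = 0.0
        node = tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        denom += d * (a[i] + b[i])
    if denom == 0.0:
        return 0.0
    return raw / denom


@dataclass(frozen=True)
class SynComDesign:
    """A designed community: member tips and their Faith's PD."""

    members: tuple
    pd: float


def design_syncoms(tree: TreeNode, pool, size: int, n_communities: int,
                   objective: str = "spread", seed: int = 0,
                   n_candidates: int = 10_000) -> list[SynComDesign]:
    """Choose strain subsets with targeted phylogenetic diversity.

    Candidate subsets of ``pool`` of the given ``size`` are sampled at
    random (exhaustively when the pool is small enough, at most
    ``n_candidates`` subsets otherwise) and ranked by Faith's PD according
    to ``objective``:

    * ``"maximize"`` — the ``n_communities`` highest-PD subsets,
    * ``"minimize"`` — the lowest-PD subsets,
    * ``"spread"`` — subsets evenly spaced across the sampled PD range,
      returned in non-decreasing PD order.

    Deterministic for a given ``seed``.
    """
    pool = list(pool)
    if size > len(pool):
        raise ValueError(f"size {size} exceeds pool size {len(pool)}")
    if objective not in ("maximize", "minimize", "spread"):
        raise ValueError(f"unknown objective: {objective!r}")

    n_total = math.comb(len(pool), size)
    if n_total <= 100_000:
        candidates = [tuple(c) for c in itertools.combinations(sorted(pool), size)]
    else:
        rng = np.random.default_rng(seed)
        seen = set()
        candidates = []
        while len(candidates) < min(n_candidates, n_total):
            sub = tuple(sorted(rng.choice(pool, size=size, replace=False)))
            if sub not in seen:
                seen.add(sub)
                candidates.append(sub)

    scored = sorted(
        (SynComDesign(sub, faith_pd(tree, sub)) for sub in candidates),
        key=lambda d: (d.pd, d.members),
    )
    n_communities = min(n_communities, len(scored))
    if objective == "maximize":
        picked = scored[-n_communities:]
    elif objective == "minimize":
        picked = scored[:n_communities]
    else:
        if n_communities == 1:
            picked = [scored[0]]
        else:
            idx = np.linspace(0, len(scored) - 1, n_communities).round().astype(int)
            picked = [scored[i] for i in sorted(set(idx))]
    return picked
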