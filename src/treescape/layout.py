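"""Tree layout algorithms: rectangular, circular, and unrooted equal-angle.

All three operate directly on the balanced-parentheses tree using iterative
preorder/postorder passes (no recursion, so 10^5-tip trees are fine) and
return a :class:`LayoutResult` of abstract Cartesian coordinates — any
"y grows downward" convention is applied at render time only.

Branch-length modes: ``actual`` uses stored lengths, substituting 0 for an
*absent* length (with a warning — topology is preserved, depth is not
invented); ``unit`` gives every edge length 1, the standard alternative when
branch-length distortion of clade size is a concern.

Layout rules
------------
rectangular
    Tips take y = 0..n_tips-1 in the order tips appear left-to-right;
    an internal node's y is the arithmetic mean of its children's y; x
    accumulates branch length from x(root) = 0. Per-internal-node vertical
    connector segments span the children's y extremes.
circular
    Tip k of n takes angle start_angle + 2*pi*k/n; an internal node's angle
    is the mean of its children's angles; radius accumulates branch length
    from radius(root) = 0. Per-internal-node arcs sit at the node's own
    radius and span its children's angle extremes.
unrooted equal-angle
    The root sits at the origin owning the full sector [0, 2*pi); every
    child subtree receives a contiguous sub-sector proportional to its tip
    count (tree order, counterclockwise) and is placed at its branch length
    from the parent along the bisector of its sector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bptree import BalancedParenTree

__all__ = ["LayoutResult", "rectangular_layout", "circular_layout",
           "unrooted_equal_angle_layout"]

TWO_PI = 2.0 * np.pi


@dataclass
class LayoutResult:
    """Per-node 2-D coordinates plus layout-specific connector geometry.

    Arrays are indexed by 0-based preorder rank; ``positions`` maps rank to
    the node's opening position in the BP vector; ``tip_ranks`` lists tip
    ranks in left-to-right tip order.
    """

    kind: str
    branch_mode: str
    positions: np.ndarray
    x: np.ndarray
    y: np.ndarray
    tip_ranks: np.ndarray
    radius: np.ndarray | None = None
    angle: np.ndarray | None = None
    vlines: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    arcs: dict[int, tuple[float, float, float]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.x.size


def _edge_lengths(tree: BalancedParenTree, branch_mode: str) -> np.ndarray:
    """Per-node (preorder) edge length toward the parent; root entry is 0."""
    if branch_mode not in ("actual", "unit"):
        raise ValueError("branch_mode must be 'actual' or 'unit'")
    n = tree.n_nodes
    if branch_mode == "unit":
        ell = np.ones(n)
    else:
        raw = tree.lengths
        absent = sum(1 for v in raw[1:] if v is None)
        if absent:
            warnings.warn(
                f"{absent} absent branch length(s) substituted with 0 in "
                "'actual' mode; use branch_mode='unit' for uniform depth",
                stacklevel=3)
        ell = np.array([0.0 if v is None else float(v) for v in raw])
    ell[0] = 0.0  # the root edge never contributes to depth
    return ell


def _topology(tree: BalancedParenTree):
    """Preorder parent-rank array and postorder rank sequence."""
    pre = tree.preorder_positions()
    rank_of = {int(p): r for r, p in enumerate(pre)}
    parent_rank = np.full(tree.n_nodes, -1, dtype=np.int64)
    for r, p in enumerate(pre[1:], start=1):
        parent_rank[r] = rank_of[tree.parent(int(p))]
    post_ranks = np.array([rank_of[int(p)] for p in tree.postorder_positions()],
                          dtype=np.int64)
    tip_ranks = np.array([rank_of[int(p)] for p in tree.tip_positions()],
                         dtype=np.int64)
    is_tip = np.zeros(tree.n_nodes, dtype=bool)
    is_tip[tip_ranks] = True
    return parent_rank, post_ranks, tip_ranks, is_tip


def _accumulate_depth(parent_rank: np.ndarray, ell: np.ndarray) -> np.ndarray:
    depth = np.zeros(parent_rank.size)
    for r in range(1, parent_rank.size):  # preorder: parent precedes child
        depth[r] = depth[parent_rank[r]] + ell[r]
    return depth


def _mean_of_children(parent_rank, post_ranks, is_tip, tip_values, tip_ranks):
    """Postorder fold: tips get ``tip_values``; internals the child mean.

    Also returns per-internal (min, max) of the direct children's values.
    """
    n = parent_rank.size
    val = np.zeros(n)
    val[tip_ranks] = tip_values
    acc_sum = np.zeros(n)
    acc_cnt = np.zeros(n, dtype=np.int64)
    acc_min = np.full(n, np.inf)
    acc_max = np.full(n, -np.inf)
    for r in post_ranks:
        if not is_tip[r]:
            val[r] = acc_sum[r] / acc_cnt[r]
        pr = parent_rank[r]
        if pr >= 0:
            acc_sum[pr] += val[r]
            acc_cnt[pr] += 1
            acc_min[pr] = min(acc_min[pr], val[r])
            acc_max[pr] = max(acc_max[pr], val[r])
    return val, acc_min, acc_max


def rectangular_layout(tree: BalancedParenTree,
                       branch_mode: str = "actual") -> LayoutResult:
    ell = _edge_lengths(tree, branch_mode)
    parent_rank, post_ranks, tip_ranks, is_tip = _topology(tree)
    x = _accumulate_depth(parent_rank, ell)
    tip_y = np.arange(tip_ranks.size, dtype=float)
    y, ymin, ymax = _mean_of_children(parent_rank, post_ranks, is_tip,
                                      tip_y, tip_ranks)
    vlines = {int(r): (float(x[r]), float(ymin[r]), float(ymax[r]))
              for r in range(tree.n_nodes) if not is_tip[r]}
    return LayoutResult(kind="rectangular", branch_mode=branch_mode,
                        positions=tree.preorder_positions(), x=x, y=y,
                        tip_ranks=tip_ranks, vlines=vlines)


def circular_layout(tree: BalancedParenTree, branch_mode: str = "actual",
                    start_angle: float = 0.0) -> LayoutResult:
    ell = _edge_lengths(tree, branch_mode)
    parent_rank, post_ranks, tip_ranks, is_tip = _topology(tree)
    radius = _accumulate_depth(parent_rank, ell)
    n_tips = tip_ranks.size
    tip_angles = np.mod(start_angle + TWO_PI * np.arange(n_tips) / n_tips,
                        TWO_PI)
    angle, amin, amax = _mean_of_children(parent_rank, post_ranks, is_tip,
                                          tip_angles, tip_ranks)
    x = radius * np.cos(angle)
    y = radius * np.sin(angle)
    arcs = {int(r): (float(radius[r]), float(amin[r]), float(amax[r]))
            for r in range(tree.n_nodes) if not is_tip[r]}
    return LayoutResult(kind="circular", branch_mode=branch_mode,
                        positions=tree.preorder_positions(), x=x, y=y,
                        tip_ranks=tip_ranks, radius=radius, angle=angle,
                        arcs=arcs)


def unrooted_equal_angle_layout(tree: BalancedParenTree,
                                branch_mode: str = "actual") -> LayoutResult:
    """Equal-angle layout: sectors proportional to subtree tip counts.

    The root is treated as an interior vertex placed at the origin, even for
    rooted input.
    """
    ell = _edge_lengths(tree, branch_mode)
    parent_rank, post_ranks, tip_ranks, is_tip = _topology(tree)
    n = tree.n_nodes
    pre = tree.preorder_positions()
    tip_counts = np.array([tree.subtree_tip_count(int(p)) for p in pre],
                          dtype=float)
    x = np.zeros(n)
    y = np.zeros(n)
    angle = np.zeros(n)  # bisector direction of each node's sector
    sector_start = np.zeros(n)
    sector_width = np.zeros(n)
    sector_start[0] = 0.0
    sector_width[0] = TWO_PI
    rank_of = {int(p): r for r, p in enumerate(pre)}
    stack = [0]
    while stack:
        r = stack.pop()
        pos = int(pre[r])
        cursor = sector_start[r]
        for child_pos in tree.children(pos):
            cr = rank_of[child_pos]
            w = sector_width[r] * tip_counts[cr] / tip_counts[r]
            mid = cursor + w / 2.0
            sector_start[cr] = cursor
            sector_width[cr] = w
            angle[cr] = mid
            x[cr] = x[r] + ell[cr] * np.cos(mid)
            y[cr] = y[r] + ell[cr] * np.sin(mid)
            cursor += w
            stack.append(cr)
    return LayoutResult(kind="unrooted", branch_mode=branch_mode,
                        positions=tree.preorder_positions(), x=x, y=y,
                        tip_ranks=tip_ranks, angle=angle)
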