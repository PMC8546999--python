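"""Succinct balanced-parentheses (BP) rooted tree.

A rooted tree with ``n`` nodes is stored as a length-``2n`` bit vector in
which every node contributes one opening and one matching closing
parenthesis; the subtree of a node is exactly the parenthesis interval it
delimits.  Node names and (optional) branch lengths are carried in preorder
arrays.  All navigation queries — ``parent``, ``first_child``,
``next_sibling``, ``is_leaf``, ``open``/``close`` matching, preorder and
postorder ``select``, subtree tip counts — are answered in O(1) from plain
prefix-sum index arrays built once at construction.  Space-optimal o(n)
rank/select structures are deliberately not used: the contract here is the
BP navigation algebra, not bit-level succinctness.

Nodes are addressed by their **opening position** in the bit vector (the
root is always position 0).  ``parent(root)`` returns the sentinel ``-1``.

A plain :class:`PointerTree` (parent/children records) is provided as the
construction scaffold for the parser and, in the test suite, as the naive
oracle every BP primitive is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROOT_SENTINEL = -1


@dataclass
class PointerNode:
    name: str = ""
    length: float | None = None
    parent: int = ROOT_SENTINEL
    children: list[int] = field(default_factory=list)


class PointerTree:
    """Ordinary pointer-based rooted tree (construction scaffold / oracle)."""

    def __init__(self) -> None:
        self.nodes: list[PointerNode] = []
        self.root: int = ROOT_SENTINEL

    def add_node(self, name: str = "", length: float | None = None,
                 parent: int = ROOT_SENTINEL) -> int:
        nid = len(self.nodes)
        self.nodes.append(PointerNode(name=name, length=length, parent=parent))
        if parent == ROOT_SENTINEL:
            if self.root != ROOT_SENTINEL:
                raise ValueError("pointer tree already has a root")
            self.root = nid
        else:
            self.nodes[parent].children.append(nid)
        return nid

    def n_nodes(self) -> int:
        return len(self.nodes)

    def subtree_tip_counts(self) -> list[int]:
        """Tip count below (and including) every node, computed iteratively."""
        counts = [0] * len(self.nodes)
        for nid in self.postorder():
            node = self.nodes[nid]
            if not node.children:
                counts[nid] = 1
            else:
                counts[nid] = sum(counts[c] for c in node.children)
        return counts

    def preorder(self) -> list[int]:
        order: list[int] = []
        if self.root == ROOT_SENTINEL:
            return order
        stack = [self.root]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(reversed(self.nodes[nid].children))
        return order

    def postorder(self) -> list[int]:
        order: list[int] = []
        if self.root == ROOT_SENTINEL:
            return order
        stack: list[tuple[int, int]] = [(self.root, 0)]
        while stack:
            nid, ci = stack[-1]
            children = self.nodes[nid].children
            if ci < len(children):
                stack[-1] = (nid, ci + 1)
                stack.append((children[ci], 0))
            else:
                order.append(nid)
                stack.pop()
        return order


class BalancedParenTree:
    """Immutable balanced-parentheses tree with O(1) navigation primitives.

    Parameters
    ----------
    bits
        Boolean sequence of length 2n, ``True`` for an opening parenthesis.
    names
        Per-node name strings in preorder (empty string = unnamed).
    lengths
        Per-node branch length in preorder; ``None`` marks an *absent*
        length, which is distinct from ``0.0``. Lengths must be >= 0.
    """

    def __init__(self, bits, names, lengths) -> None:
        bits = np.asarray(bits, dtype=bool)
        if bits.ndim != 1 or bits.size == 0 or bits.size % 2:
            raise ValueError("bits must be a non-empty even-length 1-D sequence")
        if not bits[0]:
            raise ValueError("position 0 must be an opening parenthesis")
        excess = np.cumsum(np.where(bits, 1, -1))
        if excess[-1] != 0 or excess[:-1].min() < 1:
            raise ValueError("parenthesis sequence is not balanced (single root)")
        n = int(bits.sum())
        if len(names) != n or len(lengths) != n:
            raise ValueError("names/lengths must have one entry per node")
        for ln in lengths:
            if ln is not None and (not np.isfinite(ln) or ln < 0):
                raise ValueError(f"branch lengths must be finite and >= 0, got {ln!r}")
        self._bits = bits
        self._names = list(names)
        self._lengths = list(lengths)
        self._n = n
        self._build_index()

    # -- index construction -------------------------------------------------

    def _build_index(self) -> None:
        bits = self._bits
        m = bits.size
        close_of = np.full(m, -1, dtype=np.int64)
        open_of = np.full(m, -1, dtype=np.int64)
        parent_open = np.full(m, ROOT_SENTINEL, dtype=np.int64)
        post_pos: list[int] = []
        stack: list[int] = []
        blist = bits.tolist()
        for p, b in enumerate(blist):
            if b:
                if stack:
                    parent_open[p] = stack[-1]
                stack.append(p)
            else:
                o = stack.pop()
                close_of[o] = p
                open_of[p] = o
                post_pos.append(o)
        self._close_of = close_of
        self._open_of = open_of
        self._parent_open = parent_open
        self._post_pos = np.asarray(post_pos, dtype=np.int64)
        # preorder rank of opening position p = (# opens at positions <= p) - 1
        self._open_cum = np.cumsum(bits.astype(np.int64))
        self._open_pos = np.flatnonzero(bits).astype(np.int64)
        post_rank = np.full(m, -1, dtype=np.int64)
        post_rank[self._post_pos] = np.arange(1, self._n + 1)
        self._post_rank = post_rank
        leaf = np.zeros(m, dtype=np.int64)
        leaf[:-1] = bits[:-1] & ~bits[1:]
        self._leaf_cum = np.concatenate([[0], np.cumsum(leaf)])
        self._tip_pos = np.flatnonzero(leaf).astype(np.int64)

    # -- basic accessors -----------------------------------------------------

    @property
    def bits(self) -> np.ndarray:
        return self._bits.copy()

    @property
    def n_nodes(self) -> int:
        return self._n

    @property
    def n_tips(self) -> int:
        return int(self._tip_pos.size)

    @property
    def root(self) -> int:
        return 0

    def _check_open(self, i: int) -> None:
        if not (0 <= i < self._bits.size and self._bits[i]):
            raise IndexError(f"position {i} is not an opening parenthesis")

    def preorder_rank(self, i: int) -> int:
        """0-based preorder rank of the node opened at position ``i``."""
        self._check_open(i)
        return int(self._open_cum[i]) - 1

    def name(self, i: int) -> str:
        return self._names[self.preorder_rank(i)]

    def length(self, i: int) -> float | None:
        return self._lengths[self.preorder_rank(i)]

    @property
    def names(self) -> list[str]:
        """Node names in preorder."""
        return list(self._names)

    @property
    def lengths(self) -> list[float | None]:
        """Branch lengths in preorder (None = absent)."""
        return list(self._lengths)

    # -- navigation (all O(1)) ----------------------------------------------

    def parent(self, i: int) -> int:
        self._check_open(i)
        return int(self._parent_open[i])

    def first_child(self, i: int) -> int:
        """Opening position of the first child, or -1 for a leaf."""
        self._check_open(i)
        j = i + 1
        return j if self._bits[j] else -1

    def next_sibling(self, i: int) -> int:
        """Opening position of the next sibling, or -1 if ``i`` is last."""
        self._check_open(i)
        j = int(self._close_of[i]) + 1
        if j < self._bits.size and self._bits[j]:
            return j
        return -1

    def is_leaf(self, i: int) -> bool:
        self._check_open(i)
        return not self._bits[i + 1]

    def close(self, i: int) -> int:
        self._check_open(i)
        return int(self._close_of[i])

    def open(self, j: int) -> int:
        """Matching opening position of the closing parenthesis at ``j``."""
        if not (0 <= j < self._bits.size) or self._bits[j]:
            raise IndexError(f"position {j} is not a closing parenthesis")
        return int(self._open_of[j])

    def preorder_select(self, k: int) -> int:
        """Opening position of the k-th node in preorder (1-based)."""
        if not 1 <= k <= self._n:
            raise IndexError(f"preorder rank {k} out of range 1..{self._n}")
        return int(self._open_pos[k - 1])

    def postorder_select(self, k: int) -> int:
        """Opening position of the k-th node in postorder (1-based)."""
        if not 1 <= k <= self._n:
            raise IndexError(f"postorder rank {k} out of range 1..{self._n}")
        return int(self._post_pos[k - 1])

    def postorder_rank(self, i: int) -> int:
        """1-based postorder rank of the node opened at position ``i``."""
        self._check_open(i)
        return int(self._post_rank[i])

    def subtree_tip_count(self, i: int) -> int:
        self._check_open(i)
        c = int(self._close_of[i])
        return int(self._leaf_cum[c + 1] - self._leaf_cum[i])

    def children(self, i: int) -> list[int]:
        out = []
        c = self.first_child(i)
        while c != -1:
            out.append(c)
            c = self.next_sibling(c)
        return out

    # -- traversals / tip helpers -------------------------------------------

    def preorder_positions(self) -> np.ndarray:
        return self._open_pos.copy()

    def postorder_positions(self) -> np.ndarray:
        return self._post_pos.copy()

    def tip_positions(self) -> np.ndarray:
        """Opening positions of tips in left-to-right order."""
        return self._tip_pos.copy()

    def tip_names(self) -> list[str]:
        return [self._names[self.preorder_rank(int(p))] for p in self._tip_pos]

    def descendant_tip_positions(self, i: int) -> np.ndarray:
        """Opening positions of all tips in the subtree of ``i`` (inclusive)."""
        self._check_open(i)
        c = int(self._close_of[i])
        lo = np.searchsorted(self._tip_pos, i, side="left")
        hi = np.searchsorted(self._tip_pos, c, side="right")
        return self._tip_pos[lo:hi]

    def descendant_tip_names(self, i: int) -> list[str]:
        return [self._names[self.preorder_rank(int(p))]
                for p in self.descendant_tip_positions(i)]

    def find_name(self, name: str) -> int:
        """Opening position of the unique node named ``name``; KeyError if none."""
        try:
            rank = self._names.index(name)
        except ValueError:
            raise KeyError(f"no node named {name!r} in tree") from None
        return int(self._open_pos[rank])

    # -- conversions ---------------------------------------------------------

    def to_pointer(self) -> PointerTree:
        pt = PointerTree()
        bp_to_pt: dict[int, int] = {}
        for pos in self._open_pos:
            pos = int(pos)
            par = int(self._parent_open[pos])
            rank = int(self._open_cum[pos]) - 1
            nid = pt.add_node(name=self._names[rank],
                              length=self._lengths[rank],
                              parent=bp_to_pt[par] if par != ROOT_SENTINEL
                              else ROOT_SENTINEL)
            bp_to_pt[pos] = nid
        return pt

    @classmethod
    def from_pointer(cls, pt: PointerTree) -> "BalancedParenTree":
        if pt.root == ROOT_SENTINEL:
            raise ValueError("pointer tree is empty")
        bits: list[bool] = []
        names: list[str] = []
        lengths: list[float | None] = []
        stack: list[tuple[int, int]] = [(pt.root, 0)]
        while stack:
            nid, ci = stack[-1]
            node = pt.nodes[nid]
            if ci == 0:
                bits.append(True)
                names.append(node.name)
                lengths.append(node.length)
            if ci < len(node.children):
                stack[-1] = (nid, ci + 1)
                stack.append((node.children[ci], 0))
            else:
                bits.append(False)
                stack.pop()
        return cls(np.asarray(bits, dtype=bool), names, lengths)

    # -- structural operations ----------------------------------------------

    def shear(self, keep) -> "BalancedParenTree":
        """Restrict the tree to the tips named in ``keep``.

        Internal nodes that retain at least one kept descendant tip survive,
        including nodes left with a single child (unifurcations are kept, with
        their names and lengths untouched — they may carry metadata used for
        coloring). Relative sibling order is preserved.
        """
        keep = set(keep)
        tipset = set(self.tip_names())
        if not (keep & tipset):
            missing = sorted(keep - tipset)[:5]
            raise ValueError(
                "none of the requested tips occur in the tree; "
                f"missing names include {missing}")
        m = self._bits.size
        kept_tip = np.zeros(m + 1, dtype=np.int64)
        for p in self._tip_pos:
            p = int(p)
            if self._names[int(self._open_cum[p]) - 1] in keep:
                kept_tip[p + 1] = 1
        kt_cum = np.cumsum(kept_tip)
        keep_mask = np.zeros(m, dtype=bool)
        keep_node = np.zeros(self._n, dtype=bool)
        for rank, p in enumerate(self._open_pos):
            p = int(p)
            c = int(self._close_of[p])
            if kt_cum[c + 1] - kt_cum[p] > 0:
                keep_mask[p] = True
                keep_mask[c] = True
                keep_node[rank] = True
        new_bits = self._bits[keep_mask]
        new_names = [nm for nm, k in zip(self._names, keep_node) if k]
        new_lengths = [ln for ln, k in zip(self._lengths, keep_node) if k]
        return BalancedParenTree(new_bits, new_names, new_lengths)

    def sort_siblings(self, order: str = "descending") -> "BalancedParenTree":
        """Reorder sibling clades by subtree tip count (stable on ties)."""
        if order not in ("ascending", "descending"):
            raise ValueError("order must be 'ascending' or 'descending'")
        pt = self.to_pointer()
        counts = pt.subtree_tip_counts()
        reverse = order == "descending"
        for node in pt.nodes:
            if len(node.children) > 1:
                node.children.sort(key=lambda c: counts[c], reverse=reverse)
        return BalancedParenTree.from_pointer(pt)

    # -- comparison ----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BalancedParenTree):
            return NotImplemented
        return (np.array_equal(self._bits, other._bits)
                and self._names == other._names
                and self._lengths == other._lengths)

    def __repr__(self) -> str:
        return (f"<BalancedParenTree with {self._n} nodes "
                f"({self.n_tips} tips)>")
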