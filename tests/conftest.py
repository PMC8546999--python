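"""Shared fixtures and naive oracles for the test suite.

The oracles here deliberately re-derive every quantity from the plain
pointer-tree representation (parent/children records), independently of the
balanced-parentheses index arrays they are used to check.
"""

import datetime

import pytest

from treescape import generate_fixture, read_newick
from treescape.bptree import ROOT_SENTINEL, BalancedParenTree, PointerTree


@pytest.fixture
def small_community():
    """20-tip tree + 10-sample table + metadata, fixed seed."""
    nw, table, sample_md, feature_md = generate_fixture(20, 10, 0.3, seed=7)
    return read_newick(nw), table, sample_md, feature_md


def random_tree(seed: int, max_tips: int = 50) -> BalancedParenTree:
    import numpy as np
    rng = np.random.default_rng(seed)
    n_tips = int(rng.integers(2, max_tips + 1))
    nw, *_ = generate_fixture(n_tips, 2, 0.5, seed=seed + 1)
    return read_newick(nw)


# ---------------------------------------------------------------------------
# pointer-tree oracles
# ---------------------------------------------------------------------------

def oracle_navigation(pt: PointerTree):
    """Answer every navigation query naively from parent/children records.

    Returns dicts keyed by *pointer node id*; because ``to_pointer`` emits
    nodes in preorder, pointer id k corresponds to BP preorder rank k.
    """
    parent = {i: n.parent for i, n in enumerate(pt.nodes)}
    first_child = {i: (n.children[0] if n.children else -1)
                   for i, n in enumerate(pt.nodes)}
    next_sibling = {}
    for i, n in enumerate(pt.nodes):
        for a, b in zip(n.children, n.children[1:]):
            next_sibling[a] = b
        if n.children:
            next_sibling[n.children[-1]] = -1
    next_sibling[pt.root] = -1
    is_leaf = {i: not n.children for i, n in enumerate(pt.nodes)}
    tip_counts = dict(enumerate(pt.subtree_tip_counts()))
    return {"parent": parent, "first_child": first_child,
            "next_sibling": next_sibling, "is_leaf": is_leaf,
            "subtree_tip_count": tip_counts,
            "preorder": pt.preorder(), "postorder": pt.postorder()}


def oracle_shear(pt: PointerTree, keep: set) -> PointerTree:
    """Filter a pointer tree to tips in ``keep`` plus their ancestors."""
    keep_node = [False] * len(pt.nodes)
    for nid in pt.postorder():
        node = pt.nodes[nid]
        if not node.children:
            keep_node[nid] = node.name in keep
        else:
            keep_node[nid] = any(keep_node[c] for c in node.children)
    out = PointerTree()
    mapping = {}
    for nid in pt.preorder():
        if not keep_node[nid]:
            continue
        node = pt.nodes[nid]
        par = node.parent
        mapping[nid] = out.add_node(
            name=node.name, length=node.length,
            parent=mapping[par] if par != ROOT_SENTINEL else ROOT_SENTINEL)
    return out


def oracle_sliding_windows(records, window_days, min_records):
    """Brute-force (location, start-date) double loop over dated records.

    ``records`` is a list of (record_id, iso_date, location). Returns
    {community_sample_id: frozenset of record ids}.
    """
    by_loc = {}
    for rid, iso, loc in records:
        by_loc.setdefault(loc, []).append(
            (datetime.date.fromisoformat(iso), rid))
    out = {}
    for loc, recs in by_loc.items():
        days = [d for d, _ in recs]
        start = min(days)
        while start <= max(days):
            end = start + datetime.timedelta(days=window_days - 1)
            members = frozenset(r for d, r in recs if start <= d <= end)
            if len(members) >= min_records:
                out[f"{loc}@{start.isoformat()}"] = members
            start += datetime.timedelta(days=1)
    return out
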