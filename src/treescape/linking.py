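"""Bidirectional sample <-> tree-node linking and longitudinal frames.

Implements the logic behind paired tree/ordination views: selecting samples
highlights every tip present in them plus every internal node whose tip set
is fully covered; clicking a node returns all samples containing any of its
descendant tips; biplot arrows resolve to tree nodes by exact name match;
and longitudinal data turn into ordered animation frames whose per-group
unique-feature sets are pairwise disjoint by construction. The sliding
window builder converts dated, located records (e.g. pathogen genomes) into
a community feature table, one community sample per (location, window)
passing a minimum-occupancy threshold.

Node identities in :class:`Selection` are 1-based postorder ranks of the
tree the selection was computed against; convert with
``tree.postorder_select`` / ``tree.postorder_rank``.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .bptree import BalancedParenTree
from .community import MISSING_CATEGORY, PresenceIndex
from .io_formats import MISSING, FeatureTable, MetadataTable

__all__ = ["Selection", "samples_to_nodes", "node_to_samples",
           "summarize_selection", "resolve_biplot_arrow", "FrameSeries",
           "build_frames", "sliding_window_communities"]


@dataclass
class Selection:
    """A linked selection propagated between ordination and tree views."""

    origin: str  # "samples" | "node" | "feature_arrow"
    sample_ids: set[str] = field(default_factory=set)
    node_ids: set[int] = field(default_factory=set)  # 1-based postorder ranks
    label: str = ""


def samples_to_nodes(sample_ids, presence: PresenceIndex,
                     tree: BalancedParenTree, *,
                     tips_only: bool = False) -> Selection:
    """Tree nodes present in the selected samples.

    The result contains every tip whose feature occurs in at least one
    selected sample and — unless ``tips_only`` — every internal node all of
    whose descendant tips are such tips, so fully covered clades highlight
    as a whole.
    """
    sample_ids = set(sample_ids)
    unknown = sample_ids - set(presence.sample_to_features)
    if unknown:
        raise KeyError(f"unknown sample id(s): {sorted(unknown)[:5]}")
    covered: set[str] = set()
    for s in sample_ids:
        covered |= presence.features_of(s)
    node_ids: set[int] = set()
    m = tree.bits.size
    marked = np.zeros(m + 1, dtype=np.int64)
    for p in tree.tip_positions():
        p = int(p)
        if tree.name(p) in covered:
            marked[p + 1] = 1
            node_ids.add(tree.postorder_rank(p))
    if not tips_only:
        cum = np.cumsum(marked)
        for p in tree.preorder_positions():
            p = int(p)
            if tree.is_leaf(p):
                continue
            c = tree.close(p)
            hit = int(cum[c + 1] - cum[p])
            if hit > 0 and hit == tree.subtree_tip_count(p):
                node_ids.add(tree.postorder_rank(p))
    return Selection(origin="samples", sample_ids=sample_ids,
                     node_ids=node_ids)


def node_to_samples(node_id: int, tree: BalancedParenTree,
                    presence: PresenceIndex) -> Selection:
    """All samples containing any descendant tip of the node (postorder rank)."""
    pos = tree.postorder_select(node_id)
    samples: set[str] = set()
    for tip in tree.descendant_tip_names(pos):
        samples |= presence.samples_of(tip)
    return Selection(origin="node", sample_ids=samples, node_ids={node_id},
                     label=tree.name(pos))


def summarize_selection(selection: Selection, sample_md: MetadataTable,
                        field_name: str) -> dict[str, int]:
    """Category -> sample count over the selection; missing pooled."""
    values = sample_md.categorical(field_name)
    counts: dict[str, int] = {}
    for s in selection.sample_ids:
        cat = values.get(s, MISSING)
        cat = cat if cat != MISSING else MISSING_CATEGORY
        counts[cat] = counts.get(cat, 0) + 1
    return counts


def resolve_biplot_arrow(feature_id: str, ordination, tree: BalancedParenTree,
                         ) -> int:
    """Postorder rank of the tree node matching a biplot arrow's feature id."""
    if ordination.feature_coords is None:
        raise ValueError("ordination has no biplot (feature) coordinates")
    if feature_id not in set(ordination.feature_ids):
        raise KeyError(f"feature {feature_id!r} has no biplot arrow")
    pos = tree.find_name(feature_id)  # exact string match; names are unique
    return tree.postorder_rank(pos)


@dataclass
class FrameSeries:
    """Ordered animation frames with per-trajectory unique feature sets."""

    gradient_field: str
    trajectory_field: str
    frame_keys: list[str]
    frame_samples: dict[str, dict[str, set[str]]]  # frame -> traj -> samples
    frame_unique: dict[str, dict[str, set[str]]]   # frame -> traj -> features


def build_frames(sample_md: MetadataTable, gradient_field: str,
                 trajectory_field: str, presence: PresenceIndex) -> FrameSeries:
    """Frames along the gradient; per-frame per-trajectory unique features.

    A feature is *unique* to trajectory g within a frame when it occurs in
    g's samples but in no other trajectory's samples of the same frame.
    Frames are ordered numerically when the gradient column is numeric,
    lexicographically otherwise; samples missing either field are skipped.
    """
    grad = sample_md.column(gradient_field)
    traj = sample_md.categorical(trajectory_field)
    numeric = sample_md.column_types[gradient_field] == "numeric"
    groups: dict[str, dict[str, set[str]]] = {}
    keys: dict[str, float | str] = {}
    for s in sample_md.ids:
        g = grad.get(s)
        t = traj.get(s, MISSING)
        if t == MISSING or g is None:
            continue
        if numeric:
            if np.isnan(g):
                continue
            key = repr(float(g))
            keys[key] = float(g)
        else:
            if g == MISSING:
                continue
            key = str(g)
            keys[key] = key
        groups.setdefault(key, {}).setdefault(t, set()).add(s)
    frame_keys = sorted(groups, key=lambda k: keys[k])
    frame_samples: dict[str, dict[str, set[str]]] = {}
    frame_unique: dict[str, dict[str, set[str]]] = {}
    for fk in frame_keys:
        frame_samples[fk] = groups[fk]
        feats = {t: set().union(*(presence.features_of(s) for s in ss))
                 if ss else set()
                 for t, ss in groups[fk].items()}
        uniq: dict[str, set[str]] = {}
        for t, fs in feats.items():
            others: set[str] = set()
            for t2, fs2 in feats.items():
                if t2 != t:
                    others |= fs2
            uniq[t] = fs - others
        frame_unique[fk] = uniq
    return FrameSeries(gradient_field=gradient_field,
                       trajectory_field=trajectory_field,
                       frame_keys=frame_keys, frame_samples=frame_samples,
                       frame_unique=frame_unique)


def sliding_window_communities(record_md: MetadataTable, date_field: str,
                               location_field: str, window_days: int,
                               min_records: int, *,
                               rename_map: dict[str, str] | None = None,
                               ) -> FeatureTable:
    """Aggregate dated records into per-(location, window) community samples.

    Per location, a window of ``window_days`` days slides one day at a time
    over the location's observed date range; window starting at day d covers
    [d, d + window_days - 1]. A community sample is emitted iff at least
    ``min_records`` records fall inside, and it contains each such record
    once (presence). Sample ids are ``"<location>@<window start ISO date>"``;
    the output table has records as features. ``rename_map`` merges location
    labels (e.g. boroughs into one city) before windowing.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if min_records < 1:
        raise ValueError("min_records must be >= 1")
    dates_raw = record_md.categorical(date_field) \
        if record_md.column_types[date_field] == "categorical" \
        else record_md.column(date_field).astype(str)
    locs = record_md.categorical(location_field)
    rename_map = rename_map or {}
    per_loc: dict[str, list[tuple[datetime.date, str]]] = {}
    for rid in record_md.ids:
        raw = dates_raw.get(rid, MISSING)
        loc = locs.get(rid, MISSING)
        if raw == MISSING or loc == MISSING:
            raise ValueError(f"record {rid!r} lacks a date or location")
        try:
            day = datetime.date.fromisoformat(str(raw))
        except ValueError:
            raise ValueError(
                f"record {rid!r} has unparseable date {raw!r}") from None
        per_loc.setdefault(rename_map.get(loc, loc), []).append((day, rid))
    sample_ids: list[str] = []
    columns: list[list[str]] = []
    for loc in sorted(per_loc):
        recs = sorted(per_loc[loc])
        days = [d for d, _ in recs]
        d0, d1 = days[0], days[-1]
        start = d0
        while start <= d1:
            end = start + datetime.timedelta(days=window_days - 1)
            members = [rid for d, rid in recs if start <= d <= end]
            if len(members) >= min_records:
                sample_ids.append(f"{loc}@{start.isoformat()}")
                columns.append(members)
            start += datetime.timedelta(days=1)
    if not sample_ids:
        # no window met the occupancy threshold
        return FeatureTable([], [], sp.csr_matrix((0, 0)))
    used = set().union(*columns)
    feature_ids = [rid for rid in record_md.ids if rid in used]
    feat_col = {rid: c for c, rid in enumerate(feature_ids)}
    mat = sp.lil_matrix((len(sample_ids), len(feature_ids)))
    for r, members in enumerate(columns):
        for rid in members:
            mat[r, feat_col[rid]] = 1.0
    return FeatureTable(sample_ids, feature_ids, mat.tocsr())
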