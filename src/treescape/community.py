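"""Joining the tree with the feature table and metadata.

Presence indexing, per-tip stacked-barplot proportions, numeric aggregation
of sample metadata onto features (e.g. mean pH of the samples a feature
occurs in, or log10 occurrence counts), quantile-based sample subsetting,
upward propagation of uniform feature metadata, and collapsing of maximal
uniform clades.

Tips are matched to table features by name. Tips absent from the table get
an empty barplot payload (the default shear removes them anyway); table
features absent from the tree are ignored with a warning unless
``strict=True``. Missing categorical values are pooled under the reserved
label ``"__missing__"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bptree import BalancedParenTree
from .io_formats import MISSING, FeatureTable, MetadataTable

__all__ = ["PresenceIndex", "build_presence", "BarplotLayer",
           "tip_category_proportions", "feature_numeric_aggregate",
           "subset_samples_middle_fraction", "propagate_uniform_metadata",
           "collapse_uniform_clades", "CollapsedClade", "MISSING_CATEGORY"]

MISSING_CATEGORY = "__missing__"


@dataclass
class PresenceIndex:
    """Transposed pair of membership maps derived from positive table entries."""

    feature_to_samples: dict[str, set[str]]
    sample_to_features: dict[str, set[str]]

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.feature_to_samples.values())

    def samples_of(self, feature: str) -> set[str]:
        return self.feature_to_samples.get(feature, set())

    def features_of(self, sample: str) -> set[str]:
        return self.sample_to_features.get(sample, set())


def build_presence(table: FeatureTable) -> PresenceIndex:
    """Index value > 0 memberships in both directions."""
    f2s: dict[str, set[str]] = {}
    s2f: dict[str, set[str]] = {}
    coo = table.matrix.tocoo()
    for r, c in zip(coo.row, coo.col):
        s = table.sample_ids[r]
        f = table.feature_ids[c]
        f2s.setdefault(f, set()).add(s)
        s2f.setdefault(s, set()).add(f)
    return PresenceIndex(f2s, s2f)


@dataclass
class BarplotLayer:
    """One tip-aligned barplot ring/column.

    ``payload`` maps tip name to either a category->proportion dict
    (``categorical_stacked``; proportions sum to 1 for tips present in >= 1
    sample, empty dict otherwise) or an optional float
    (``numeric``; None for tips with no value).
    """

    kind: str  # "categorical_stacked" | "numeric"
    field_name: str
    payload: dict[str, object]
    palette: str = "discrete"
    numeric_encoding: str = "both"  # color | length | both
    diverging: bool = False

    def categories(self) -> list[str]:
        cats: set[str] = set()
        for v in self.payload.values():
            if isinstance(v, dict):
                cats.update(v)
        return sorted(cats)


def _check_features_in_tree(tree: BalancedParenTree, presence: PresenceIndex,
                            strict: bool) -> None:
    tips = set(tree.tip_names())
    orphans = sorted(set(presence.feature_to_samples) - tips)
    if orphans:
        msg = (f"{len(orphans)} table feature(s) absent from the tree "
               f"(e.g. {orphans[:5]})")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + "; ignored", stacklevel=3)


def tip_category_proportions(tree: BalancedParenTree, presence: PresenceIndex,
                             sample_md: MetadataTable, field_name: str,
                             *, strict: bool = False) -> BarplotLayer:
    """Stacked per-tip proportions of containing samples, by category.

    For tip t occurring in sample set S(t): proportion(c) =
    |{s in S(t) : md(s) = c}| / |S(t)|. Samples with a missing field value
    are pooled under ``"__missing__"``.
    """
    values = sample_md.categorical(field_name)
    if MISSING_CATEGORY in set(values):
        raise ValueError(
            f"category label {MISSING_CATEGORY!r} is reserved for missing "
            f"values but occurs in column {field_name!r}")
    _check_features_in_tree(tree, presence, strict)
    payload: dict[str, object] = {}
    for tip in tree.tip_names():
        samples = presence.samples_of(tip)
        if not samples:
            payload[tip] = {}
            continue
        counts: dict[str, int] = {}
        for s in samples:
            cat = values.get(s, MISSING)
            cat = cat if cat != MISSING else MISSING_CATEGORY
            counts[cat] = counts.get(cat, 0) + 1
        total = len(samples)
        payload[tip] = {c: k / total for c, k in sorted(counts.items())}
    return BarplotLayer(kind="categorical_stacked", field_name=field_name,
                        payload=payload)


def feature_numeric_aggregate(presence: PresenceIndex,
                              sample_md: MetadataTable, field_name: str,
                              stat: str = "mean") -> pd.Series:
    """Aggregate a numeric sample column over each feature's sample set.

    ``mean``/``median`` are taken over the containing samples with a
    non-missing field value; ``count_log10`` is log10 of the number of
    samples the feature occurs in (no field filtering — it counts
    occurrence, not field coverage). Features with no contributing samples
    are missing (NaN).
    """
    if stat not in ("mean", "median", "count_log10"):
        raise ValueError("stat must be 'mean', 'median' or 'count_log10'")
    values = sample_md.numeric(field_name)
    out: dict[str, float] = {}
    for feat, samples in presence.feature_to_samples.items():
        if stat == "count_log10":
            out[feat] = float(np.log10(len(samples))) if samples else np.nan
            continue
        vals = [values[s] for s in samples
                if s in values.index and not np.isnan(values[s])]
        if not vals:
            out[feat] = np.nan
        elif stat == "mean":
            out[feat] = float(np.mean(vals))
        else:
            out[feat] = float(np.median(vals))
    return pd.Series(out, name=f"{field_name}_{stat}", dtype=float)


def subset_samples_middle_fraction(sample_md: MetadataTable, field_name: str,
                                   keep_fraction: float,
                                   *, mode: str = "quantile") -> set[str]:
    """Samples inside the central ``keep_fraction`` of a numeric column.

    Missing-valued samples are dropped first. With ``mode="quantile"``
    (default) the cutoffs are the ((1-f)/2) and (1-(1-f)/2) empirical
    quantiles (linear interpolation) — an outlier-robust reading of "the
    middle f of the range". ``mode="span"`` instead cuts at those fractions
    of the observed min-max span. Bounds are inclusive.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    values = sample_md.numeric(field_name).dropna()
    if values.empty:
        raise ValueError(f"all values of {field_name!r} are missing")
    tail = (1.0 - keep_fraction) / 2.0
    arr = values.to_numpy(dtype=float)
    if mode == "quantile":
        lo, hi = np.quantile(arr, [tail, 1.0 - tail], method="linear")
    elif mode == "span":
        mn, mx = arr.min(), arr.max()
        lo = mn + tail * (mx - mn)
        hi = mx - tail * (mx - mn)
    else:
        raise ValueError("mode must be 'quantile' or 'span'")
    return set(values.index[(arr >= lo) & (arr <= hi)])


_MIXED = object()  # sentinel: conflicting values below this node


def propagate_uniform_metadata(tree: BalancedParenTree,
                               feature_md: MetadataTable,
                               field_name: str) -> dict[int, str | None]:
    """Per-node value (keyed by opening position) if uniform below, else None.

    A tip carries its own metadata value (None when missing). An internal
    node carries value v iff at least one descendant tip has a non-missing
    value and every such tip agrees on v; tips with missing values are
    tolerated.
    """
    col = feature_md.column(field_name)
    if feature_md.column_types[field_name] == "numeric":
        raw = {i: (None if np.isnan(v) else repr(v)) for i, v in col.items()}
    else:
        raw = {i: (None if v == MISSING else v) for i, v in col.items()}
    state: dict[int, object] = {}
    for p in tree.postorder_positions():
        p = int(p)
        if tree.is_leaf(p):
            state[p] = raw.get(tree.name(p))
        else:
            agg: object = None
            for c in tree.children(p):
                s = state[c]
                if s is None:
                    continue
                if agg is None:
                    agg = s
                elif agg is not s and agg != s:
                    agg = _MIXED
            state[p] = agg
    return {p: (None if s is _MIXED or s is None else s)  # type: ignore
            for p, s in state.items()}


@dataclass
class CollapsedClade:
    """A maximal metadata-uniform clade marked for single-wedge drawing."""

    position: int  # opening position of the collapsed internal node
    name: str
    value: str
    tip_count: int


def collapse_uniform_clades(tree: BalancedParenTree,
                            node_values: dict[int, str | None],
                            *, exclude: set[str] = frozenset(),
                            ) -> list[CollapsedClade]:
    """Maximal internal nodes with a uniform propagated value.

    A node is collapsed iff it is internal, has a non-missing propagated
    value, its name is not in ``exclude``, and none of its ancestors is
    itself collapsed (so collapsed tip sets are disjoint). Excluding a node
    exposes the maximal uniform nodes strictly inside it.
    """
    exclude = set(exclude)
    out: list[CollapsedClade] = []
    collapsed_pos: set[int] = set()
    suppressed: set[int] = set()  # positions with a collapsed ancestor
    for p in tree.preorder_positions():
        p = int(p)
        parent = tree.parent(p)
        if parent in suppressed or parent in collapsed_pos:
            suppressed.add(p)
            continue
        if tree.is_leaf(p):
            continue
        value = node_values.get(p)
        if value is not None and tree.name(p) not in exclude:
            collapsed_pos.add(p)
            out.append(CollapsedClade(position=p, name=tree.name(p),
                                      value=value,
                                      tip_count=tree.subtree_tip_count(p)))
    return out
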