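"""Readers, writers, and fixture generation for the standard input formats.

Covers: Newick trees (parsed straight into :class:`~treescape.bptree.
BalancedParenTree`), dense TSV feature tables (features as rows — the common
dense convention — with an ``orient`` switch), BIOM-HDF5 v2.1 tables behind
an optional format flag, TSV metadata with numeric/categorical column
inference, the sectioned ordination-results text format (via scikit-bio),
and a seeded random-fixture generator producing trees, sparse tables and
metadata of controllable size.

Newick dialect: quoted labels with ``''`` escaping; ``[...]`` comments are
skipped; underscores are kept verbatim (no space substitution); internal
labels are names, not support values; a missing branch length is recorded as
*absent* (``None``), never as 0. Parse errors carry the character offset at
which they were detected.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .bptree import ROOT_SENTINEL, BalancedParenTree, PointerTree

__all__ = [
    "NewickParseError", "read_newick", "write_newick",
    "FeatureTable", "read_table", "write_table",
    "MetadataTable", "read_metadata", "write_metadata",
    "Ordination", "read_ordination", "write_ordination",
    "generate_fixture", "generate_record_fixture", "generate_ordination",
]


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

class NewickParseError(ValueError):
    """Malformed Newick input.

    ``offset`` is the 1-based character position at which the problem was
    detected (one past the end of the text for truncated input).
    """

    def __init__(self, message: str, index: int) -> None:
        self.offset = index + 1
        super().__init__(f"{message} at offset {self.offset}")


_UNQUOTED_STOP = set("(),:;[]'")
_NUMBER_RE = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")


def _skip_blanks(text: str, i: int) -> int:
    n = len(text)
    while i < n:
        c = text[i]
        if c in " \t\r\n":
            i += 1
        elif c == "[":
            j = text.find("]", i + 1)
            if j == -1:
                raise NewickParseError("unterminated '[' comment", i)
            i = j + 1
        else:
            break
    return i


def _read_label(text: str, i: int) -> tuple[str, int]:
    if text[i] == "'":
        start = i
        i += 1
        parts: list[str] = []
        n = len(text)
        while True:
            j = text.find("'", i)
            if j == -1:
                raise NewickParseError("unterminated quoted label", start)
            parts.append(text[i:j])
            if j + 1 < n and text[j + 1] == "'":  # '' escapes a literal quote
                parts.append("'")
                i = j + 2
            else:
                return "".join(parts), j + 1
    j = i
    n = len(text)
    while j < n and text[j] not in _UNQUOTED_STOP and text[j] not in " \t\r\n":
        j += 1
    return text[i:j], j


def read_newick(text: str, *, allow_duplicate_names: bool = False) -> BalancedParenTree:
    """Parse a single ``;``-terminated Newick statement into a BP tree.

    Raises :class:`NewickParseError` (with a character offset) on unbalanced
    parentheses, trailing garbage, negative branch lengths, or empty input.
    Duplicate non-empty node names are an error unless
    ``allow_duplicate_names`` is set, in which case repeats are auto-suffixed
    ``_2``, ``_3``, ... to keep table joins unambiguous.
    """
    n = len(text)
    i = _skip_blanks(text, 0)
    if i >= n:
        raise NewickParseError("empty Newick input", i)
    pt = PointerTree()
    cur = pt.add_node()
    stack: list[int] = []
    terminated = False
    while True:
        c = text[i]
        if c == "(":
            stack.append(cur)
            cur = pt.add_node(parent=stack[-1])
            i += 1
        elif c == ",":
            if not stack:
                raise NewickParseError("',' outside parentheses", i)
            cur = pt.add_node(parent=stack[-1])
            i += 1
        elif c == ")":
            if not stack:
                raise NewickParseError("unbalanced ')'", i)
            cur = stack.pop()
            i += 1
        elif c == ";":
            if stack:
                raise NewickParseError(
                    f"{len(stack)} unclosed '(' before ';'", i)
            i += 1
            terminated = True
            break
        elif c == ":":
            if pt.nodes[cur].length is not None:
                raise NewickParseError("second branch length for one node", i)
            i = _skip_blanks(text, i + 1)
            m = _NUMBER_RE.match(text, i)
            if m is None:
                raise NewickParseError("expected a branch length", i)
            value = float(m.group())
            if value < 0:
                raise NewickParseError(f"negative branch length {m.group()}", i)
            pt.nodes[cur].length = value
            i = m.end()
        else:
            if pt.nodes[cur].name or pt.nodes[cur].length is not None:
                raise NewickParseError("unexpected second label", i)
            label, i = _read_label(text, i)
            pt.nodes[cur].name = label
        i = _skip_blanks(text, i)
        if i >= n and not terminated:
            raise NewickParseError("unexpected end of input", n)
    i = _skip_blanks(text, i)
    if i < n:
        raise NewickParseError("trailing characters after ';'", i)

    seen: dict[str, int] = {}
    for node in pt.nodes:
        if not node.name:
            continue
        if node.name in seen:
            if not allow_duplicate_names:
                raise NewickParseError(
                    f"duplicate node name {node.name!r}", 0)
            seen[node.name] += 1
            node.name = f"{node.name}_{seen[node.name]}"
            seen[node.name] = 1
        else:
            seen[node.name] = 1
    return BalancedParenTree.from_pointer(pt)


def _format_label(name: str) -> str:
    if name and any(ch in _UNQUOTED_STOP or ch in " \t\r\n" for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _format_length(value: float) -> str:
    # repr() of a Python float is the shortest round-trip representation
    return repr(float(value))


def write_newick(tree: BalancedParenTree) -> str:
    """Serialize to one Newick statement; parse(write(t)) == t exactly."""
    pt = tree.to_pointer()
    out: list[str] = []
    stack: list[tuple[int, int]] = [(pt.root, 0)]
    while stack:
        nid, ci = stack[-1]
        node = pt.nodes[nid]
        if node.children:
            if ci == 0:
                out.append("(")
            if ci < len(node.children):
                if ci > 0:
                    out.append(",")
                stack[-1] = (nid, ci + 1)
                stack.append((node.children[ci], 0))
                continue
            out.append(")")
        out.append(_format_label(node.name))
        if node.length is not None:
            out.append(":" + _format_length(node.length))
        stack.pop()
    out.append(";")
    return "".join(out)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

class FeatureTable:
    """Sparse samples x features count table with string ids on both axes.

    Zeros are never stored; all values are finite and >= 0; ids are unique
    and non-empty within each axis.
    """

    def __init__(self, sample_ids, feature_ids, matrix) -> None:
        sample_ids = [str(s) for s in sample_ids]
        feature_ids = [str(f) for f in feature_ids]
        for axis, ids in (("sample", sample_ids), ("feature", feature_ids)):
            if any(not x for x in ids):
                raise ValueError(f"empty {axis} id")
            dup = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dup):
                raise ValueError(f"duplicate {axis} id {dup[0]!r}")
        matrix = sp.csr_matrix(matrix, dtype=float, copy=True)
        if matrix.shape != (len(sample_ids), len(feature_ids)):
            raise ValueError("matrix shape does not match id lists")
        if matrix.nnz and (not np.all(np.isfinite(matrix.data))
                           or matrix.data.min() < 0):
            raise ValueError("table values must be finite and non-negative")
        matrix.eliminate_zeros()
        self.sample_ids = sample_ids
        self.feature_ids = feature_ids
        self.matrix = matrix
        self._srow = {s: r for r, s in enumerate(sample_ids)}
        self._fcol = {f: c for c, f in enumerate(feature_ids)}

    @property
    def nnz(self) -> int:
        return int(self.matrix.nnz)

    def value(self, sample: str, feature: str) -> float:
        return float(self.matrix[self._srow[sample], self._fcol[feature]])

    def to_dense(self) -> pd.DataFrame:
        """Dense features x samples frame (the canonical TSV orientation)."""
        return pd.DataFrame(self.matrix.toarray().T,
                            index=pd.Index(self.feature_ids, name="#FeatureID"),
                            columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (self.sample_ids == other.sample_ids
                and self.feature_ids == other.feature_ids
                and (self.matrix != other.matrix).nnz == 0)

    def __repr__(self) -> str:
        return (f"<FeatureTable {len(self.sample_ids)} samples x "
                f"{len(self.feature_ids)} features, {self.nnz} stored>")


def read_table(path, format: str = "tsv", *, orient: str = "features") -> FeatureTable:
    """Read a feature table from dense TSV (default) or BIOM-HDF5 v2.1.

    TSV orientation ``features`` (canonical) means features as rows and a
    header row of sample ids; ``samples`` transposes.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                         keep_default_na=False, comment=None)
        if orient == "samples":
            df = df.T
        elif orient != "features":
            raise ValueError("orient must be 'features' or 'samples'")
        if df.isin([""]).any().any():
            raise ValueError("ragged or empty cells in table TSV")
        try:
            values = df.astype(float)
        except ValueError as exc:
            raise ValueError(f"non-numeric table cell: {exc}") from None
        return FeatureTable(list(df.columns), list(df.index),
                            sp.csr_matrix(values.to_numpy().T))
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown table format {format!r}")


def write_table(table: FeatureTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        table.to_dense().to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown table format {format!r}")


def _read_biom(path) -> FeatureTable:
    import h5py

    with h5py.File(path, "r") as f:
        feature_ids = [x.decode() if isinstance(x, bytes) else str(x)
                       for x in f["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x)
                      for x in f["sample/ids"][:]]
        g = f["observation/matrix"]
        obs_by_sample = sp.csr_matrix(
            (g["data"][:], g["indices"][:], g["indptr"][:]),
            shape=(len(feature_ids), len(sample_ids)))
    return FeatureTable(sample_ids, feature_ids, obs_by_sample.T.tocsr())


def _write_biom(table: FeatureTable, path) -> None:
    import h5py

    obs = table.matrix.T.tocsr()  # features x samples
    smp = table.matrix.tocsr()    # samples x features
    with h5py.File(path, "w") as f:
        f.attrs["id"] = "No Table ID"
        f.attrs["type"] = "OTU table"
        f.attrs["format-url"] = "http://biom-format.org"
        f.attrs["format-version"] = (2, 1)
        f.attrs["generated-by"] = "treescape"
        f.attrs["creation-date"] = datetime.datetime.now().isoformat()
        f.attrs["shape"] = (len(table.feature_ids), len(table.sample_ids))
        f.attrs["nnz"] = table.nnz
        for group, ids, mat in (("observation", table.feature_ids, obs),
                                ("sample", table.sample_ids, smp)):
            g = f.create_group(group)
            g.create_dataset("ids", data=np.array(ids, dtype="S"))
            gm = g.create_group("matrix")
            gm.create_dataset("data", data=mat.data.astype(float))
            gm.create_dataset("indices", data=mat.indices.astype(np.int32))
            gm.create_dataset("indptr", data=mat.indptr.astype(np.int32))
            g.create_group("metadata")
            g.create_group("group-metadata")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

MISSING = ""  # raw representation of a missing cell in metadata TSV


class MetadataTable:
    """Identifier-keyed metadata with per-column numeric/categorical typing.

    A column is *numeric* when every non-missing cell parses as a real
    number; otherwise it is *categorical*. Missing cells (empty strings) are
    representable in both.
    """

    def __init__(self, raw: pd.DataFrame) -> None:
        raw = raw.fillna(MISSING).astype(str)
        if raw.index.has_duplicates:
            dup = raw.index[raw.index.duplicated()][0]
            raise ValueError(f"duplicate metadata identifier {dup!r}")
        self._raw = raw
        self.column_types: dict[str, str] = {}
        for col in raw.columns:
            vals = raw[col][raw[col] != MISSING]
            numeric = len(vals) > 0 and vals.map(_parses_float).all()
            self.column_types[col] = "numeric" if numeric else "categorical"

    @property
    def ids(self) -> list[str]:
        return list(self._raw.index)

    @property
    def columns(self) -> list[str]:
        return list(self._raw.columns)

    def _require(self, column: str, kind: str | None = None) -> None:
        if column not in self._raw.columns:
            raise KeyError(f"no metadata column {column!r}")
        if kind is not None and self.column_types[column] != kind:
            raise ValueError(
                f"column {column!r} is {self.column_types[column]}, "
                f"expected {kind}")

    def numeric(self, column: str) -> pd.Series:
        """Float series (NaN = missing) for a numeric column."""
        self._require(column, "numeric")
        return pd.to_numeric(self._raw[column].replace({MISSING: None}))

    def categorical(self, column: str) -> pd.Series:
        """String series ('' = missing) for a categorical column."""
        self._require(column, "categorical")
        return self._raw[column].copy()

    def column(self, column: str) -> pd.Series:
        self._require(column)
        if self.column_types[column] == "numeric":
            return self.numeric(column)
        return self.categorical(column)

    def to_frame(self) -> pd.DataFrame:
        return self._raw.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetadataTable):
            return NotImplemented
        return self._raw.equals(other._raw)

    def __repr__(self) -> str:
        return (f"<MetadataTable {len(self._raw)} ids x "
                f"{len(self._raw.columns)} columns>")


def _parses_float(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def read_metadata(path) -> MetadataTable:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     keep_default_na=False)
    df.index = df.index.astype(str)
    return MetadataTable(df)


def write_metadata(md: MetadataTable, path) -> None:
    df = md.to_frame()
    df.index.name = df.index.name or "#ID"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Ordination results
# ---------------------------------------------------------------------------

@dataclass
class Ordination:
    """Per-sample coordinates of a low-dimensional sample embedding.

    ``feature_ids``/``feature_coords`` hold biplot arrow coordinates when the
    file has a species section. ``proportion_explained`` entries lie in
    [0, 1]; every coordinate block shares the same axis count.
    """

    sample_ids: list[str]
    sample_coords: np.ndarray
    proportion_explained: np.ndarray
    feature_ids: list[str] | None = None
    feature_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_coords = np.asarray(self.sample_coords, dtype=float)
        self.proportion_explained = np.asarray(self.proportion_explained,
                                               dtype=float)
        k = self.sample_coords.shape[1]
        if self.proportion_explained.shape != (k,):
            raise ValueError("proportion_explained length != number of axes")
        pe = self.proportion_explained
        if np.any((pe < 0) | (pe > 1)):
            raise ValueError("proportion explained must lie in [0, 1]")
        if (self.feature_coords is None) != (self.feature_ids is None):
            raise ValueError("feature ids and coords must come together")
        if self.feature_coords is not None:
            self.feature_coords = np.asarray(self.feature_coords, dtype=float)
            if self.feature_coords.shape[1] != k:
                raise ValueError("feature coordinate axis count mismatch")

    @property
    def n_axes(self) -> int:
        return self.sample_coords.shape[1]


def read_ordination(path) -> Ordination:
    """Read the sectioned ordination-results text format (scikit-bio)."""
    from skbio.stats.ordination import OrdinationResults

    try:
        res = OrdinationResults.read(str(path))
    except Exception as exc:
        raise ValueError(f"malformed ordination file: {exc}") from exc
    feats = res.features
    return Ordination(
        sample_ids=[str(s) for s in res.samples.index],
        sample_coords=res.samples.to_numpy(),
        proportion_explained=np.nan_to_num(
            res.proportion_explained.to_numpy(), nan=0.0),
        feature_ids=None if feats is None else [str(f) for f in feats.index],
        feature_coords=None if feats is None else feats.to_numpy(),
    )


def write_ordination(ord_: Ordination, path) -> None:
    from skbio.stats.ordination import OrdinationResults

    k = ord_.n_axes
    axes = [f"PC{i + 1}" for i in range(k)]
    res = OrdinationResults(
        "PCoA", "Principal Coordinate Analysis",
        eigvals=pd.Series(ord_.proportion_explained, index=axes),
        samples=pd.DataFrame(ord_.sample_coords, index=ord_.sample_ids,
                             columns=axes),
        features=None if ord_.feature_coords is None else pd.DataFrame(
            ord_.feature_coords, index=ord_.feature_ids, columns=axes),
        proportion_explained=pd.Series(ord_.proportion_explained, index=axes),
    )
    res.write(str(path))


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def generate_fixture(n_tips: int, n_samples: int, density: float, seed: int,
                     *, feature_coverage: float = 1.0,
                     multifurcation_prob: float = 0.2,
                     ) -> tuple[str, FeatureTable, MetadataTable, MetadataTable]:
    """Random tree + sparse table + metadata, byte-identical per seed.

    The tree is grown by sequential random coalescence of the tip lineages
    (mostly binary joins, occasional trifurcations) with exponential branch
    lengths of mean 0.1 substitutions/site — a scale typical of 16S gene
    trees. Table features are a subset of the tree tips (``feature_coverage``
    controls how large); per-(sample, feature) presence is Bernoulli with
    probability ``density`` and positive integer counts. Sample metadata
    carries a categorical ``group``, numeric ``ph`` (uniform in the 4–9 range
    typical of environmental surveys), integer ``timepoint`` and categorical
    ``location``; feature metadata carries a categorical ``phylum`` and a
    numeric ``score``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)

    # sequential random coalescence over integer node handles
    children_of: dict[int, list[int]] = {}
    lengths: dict[int, float] = {}
    node_names: dict[int, str] = {i: f"t{i + 1}" for i in range(n_tips)}
    active = list(range(n_tips))
    next_id = n_tips
    internal_count = 0
    while len(active) > 1:
        k = 3 if (len(active) > 2
                  and rng.random() < multifurcation_prob) else 2
        picked: list[int] = []
        for _ in range(k):
            j = int(rng.integers(len(active)))
            picked.append(active[j])
            active[j] = active[-1]
            active.pop()
        internal_count += 1
        nid = next_id
        next_id += 1
        node_names[nid] = f"i{internal_count}"
        children_of[nid] = picked
        for c in picked:
            lengths[c] = float(rng.exponential(0.1))
        active.append(nid)
    root = active[0]

    parent_of: dict[int, int] = {}
    for par, kids in children_of.items():
        for c in kids:
            parent_of[c] = par
    pt = PointerTree()
    mapping: dict[int, int] = {}
    stack = [root]
    while stack:
        nid = stack.pop()
        mapping[nid] = pt.add_node(
            name=node_names[nid], length=lengths.get(nid),
            parent=ROOT_SENTINEL if nid == root else mapping[parent_of[nid]])
        stack.extend(reversed(children_of.get(nid, [])))
    tree = BalancedParenTree.from_pointer(pt)
    newick = write_newick(tree)

    n_feat = max(1, int(round(feature_coverage * n_tips)))
    feature_ids = [f"t{i + 1}" for i in range(n_feat)]
    sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    mask = rng.random((n_samples, n_feat)) < density
    counts = rng.integers(1, 100, size=(n_samples, n_feat))
    table = FeatureTable(sample_ids, feature_ids,
                         sp.csr_matrix(np.where(mask, counts, 0).astype(float)))

    groups = np.array(["A", "B", "C"])[rng.integers(0, 3, n_samples)]
    ph = np.round(rng.uniform(4.0, 9.0, n_samples), 2)
    timepoint = rng.integers(1, 5, n_samples)
    location = np.array(["X", "Y"])[rng.integers(0, 2, n_samples)]
    sample_md = MetadataTable(pd.DataFrame(
        {"group": groups, "ph": [f"{v:.2f}" for v in ph],
         "timepoint": timepoint.astype(str), "location": location},
        index=pd.Index(sample_ids, name="#SampleID")))

    phyla = np.array(["Firmicutes", "Proteobacteria", "Bacteroidetes"])
    feature_md = MetadataTable(pd.DataFrame(
        {"phylum": phyla[rng.integers(0, 3, n_feat)],
         "score": [f"{v:.4f}" for v in rng.normal(0.0, 1.0, n_feat)]},
        index=pd.Index(feature_ids, name="#FeatureID")))
    return newick, table, sample_md, feature_md


def generate_record_fixture(n_records: int, seed: int, *,
                            locations: tuple[str, ...] = ("Italy", "San Diego",
                                                          "New York"),
                            start: str = "2020-03-01",
                            span_days: int = 30) -> MetadataTable:
    """Record-level metadata (id, ISO date, location) for sliding windows.

    Emulates per-genome collection metadata of a longitudinal survey: each
    record gets a uniform-random collection date within ``span_days`` of
    ``start`` and a random location.
    """
    rng = np.random.default_rng(seed)
    t0 = datetime.date.fromisoformat(start)
    offsets = rng.integers(0, span_days, n_records)
    locs = np.asarray(locations)[rng.integers(0, len(locations), n_records)]
    ids = [f"r{i + 1}" for i in range(n_records)]
    dates = [(t0 + datetime.timedelta(days=int(d))).isoformat()
             for d in offsets]
    return MetadataTable(pd.DataFrame(
        {"date": dates, "location": locs},
        index=pd.Index(ids, name="#RecordID")))


def generate_ordination(sample_ids, seed: int, *, n_axes: int = 3,
                        feature_ids=None) -> Ordination:
    """Random ordination (and optional biplot arrows) over the given ids."""
    rng = np.random.default_rng(seed)
    pe = rng.random(n_axes)
    pe = np.sort(pe)[::-1]
    pe = pe / pe.sum()
    sample_ids = list(sample_ids)
    coords = rng.normal(0.0, 1.0, (len(sample_ids), n_axes))
    fc = None
    if feature_ids is not None:
        feature_ids = list(feature_ids)
        fc = rng.normal(0.0, 1.0, (len(feature_ids), n_axes))
    return Ordination(sample_ids, coords, pe, feature_ids, fc)
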