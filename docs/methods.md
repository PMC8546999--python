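# Methods

This note documents the models, algorithms, numerical choices and
limitations behind treescape, in the order data flows through the package.

## Succinct tree model

A rooted tree with `n` nodes is encoded as a balanced-parentheses (BP) bit
vector of length `2n`: a preorder walk emits an opening bit when a node is
entered and a closing bit when it is left, so every subtree is a
contiguous, balanced parenthesis interval. Nodes are addressed by their
opening position; names and optional branch lengths live in preorder
arrays. Validity requires the running excess (opens minus closes) to stay
≥ 1 everywhere before the final position and to end at 0 — this enforces a
single root as well as balance, and is re-checked after every structural
operation.

Navigation — `parent`, `first_child`, `next_sibling`, `is_leaf`,
`open`/`close` matching, `preorder_select`, `postorder_select`,
`subtree_tip_count` — is answered in O(1) from plain index arrays (matching
positions, parent positions, cumulative open and leaf counts) built in one
O(n) pass at construction. This is a deliberate trade: the package needs
the BP *navigation algebra* and its locality (shearing and tip counting are
interval arithmetic), not bit-level `o(n)`-space rank/select structures.
The structure is immutable; every structural operation returns a new tree,
and node identity across operations is by name (names are unique by
construction) or by recomputed postorder rank.

`parent(root)` returns the sentinel `-1`, as do `first_child` of a leaf and
`next_sibling` of a last child. Branch lengths must be finite and
non-negative; a *missing* length is `None` and is never conflated with 0.

### Shearing

`shear(keep)` restricts the tree to the tips named in `keep`: a node
survives iff its subtree contains at least one kept tip (computed with one
cumulative sum over a kept-tip indicator, then one interval query per
node). Internal nodes left with a single child are **retained**, with their
names and lengths untouched: such nodes often carry taxonomy or other
metadata used for coloring, and collapsing them would silently discard it.
No path compression or length summing is performed. Sibling order is
preserved; requesting only absent tips is an error that names up to five of
the missing ids.

### Sibling sorting

`sort_siblings` orders each node's children by subtree tip count,
ascending or descending, with a stable sort so ties keep their input
order. It is idempotent and preserves the multiset of (name, length,
subtree tip count).

## Newick dialect

The parser is a single-pass, iterative recursive-descent reader that
builds the BP representation directly. Accepted dialect: multifurcations;
empty labels; internal labels treated as *names* (not support values);
quoted labels with `''` escaping; `[...]` comments skipped; underscores
kept verbatim (no space substitution). Duplicate non-empty names are an
error by default — they would make table joins and biplot-arrow resolution
ambiguous — with an opt-in `allow_duplicate_names` that suffixes repeats
`_2`, `_3`, …. Negative branch lengths are rejected, not clamped, so
upstream problems surface instead of distorting layouts.

Parse errors carry a **1-based** character offset (one past the end for
truncated input). The writer emits shortest-round-trip floating point
(`repr`), quotes labels only when needed, and omits absent lengths, so
`read(write(t)) == t` exactly; this identity is property-tested against
500 generated trees and cross-checked against scikit-bio's independent
Newick parser on fixtures.

## Layouts

All layouts are iterative (explicit stacks / linear passes), so recursion
depth never limits tree size; a 100,000-tip tree lays out in well under a
minute on one core.

Branch-length modes: `actual` uses stored lengths and substitutes 0 for an
absent length with a warning — preserving topology without inventing
depth — while `unit` gives every edge length 1. The choice can drastically
change the perceived size of clades; both modes are first-class.

- **Rectangular.** Tips take `y = 0..n_tips−1` in left-to-right order;
  an internal node's `y` is the arithmetic mean of its children's `y`;
  `x` accumulates branch lengths from `x(root) = 0`. Per-internal-node
  vertical connector segments span the children's `y` extremes.
- **Circular.** Tip `k` of `n` takes angle `θ_k = start + 2πk/n` (exactly
  equally spaced; the consecutive gap is `2π/n` by construction); the
  internal-node angle is the **mean of its children's angles** (not the
  midpoint of the tip-span extremes — the mean weights balanced clades
  toward their mass, and ties cannot occur because tips are distinct
  nodes); radius accumulates branch length from 0 at the root. Arcs sit at
  each internal node's radius and span its children's angle extremes.
- **Unrooted equal-angle.** The root is treated as an interior vertex at
  the origin owning the sector `[0, 2π)`; each child subtree receives a
  contiguous sub-sector proportional to its tip count (tree order,
  counterclockwise, starting at angle 0) and is placed at its branch
  length from its parent along the bisector of its sector. Sector widths
  therefore partition the parent sector exactly; the suite asserts closure
  to 1e-9. Equal-daylight refinement and radial layouts are out of scope.

## Community joins

Presence is strict positivity (`value > 0`) of the sparse samples ×
features table; zeros are never stored, and the feature→samples and
sample→features maps are transposes of each other by construction.

- **Stacked tip barplots.** For tip `t` occurring in sample set `S(t)`,
  `proportion(c) = |{s ∈ S(t) : md(s) = c}| / |S(t)|`; proportions sum to
  1 whenever `S(t)` is non-empty. Samples missing the field are pooled
  under the reserved label `__missing__` (a collision with a real category
  is an error). Tips absent from the table get an empty payload — never an
  error, since the default shear removes them anyway. Table features
  absent from the tree warn and are ignored (a `strict` flag errors
  instead), mirroring exploratory-tool forgiveness.
- **Numeric aggregation.** `mean` and `median` are taken over the
  containing samples with a non-missing field value; `count_log10` is
  log10 of the *occurrence* count `|S(t)|` with no field filtering,
  because it measures how widely a feature occurs, not field coverage.
- **Middle-fraction subsetting.** "The middle f of the range" is
  implemented as the `((1−f)/2)` and `(1−(1−f)/2)` empirical quantiles
  with linear interpolation, inclusive bounds, after dropping
  missing-valued samples. The quantile reading is the default because the
  purpose of the operation is outlier removal, which min–max fractions do
  not serve when outliers stretch the span; `mode="span"` provides the
  min–max reading.
- **Propagation and collapsing.** A tip carries its own metadata value;
  an internal node carries value `v` iff ≥ 1 descendant tip has a
  non-missing value and all such tips agree (missing-tolerant). Collapsing
  returns the *maximal* uniform internal nodes — no collapsed ancestor —
  so collapsed tip sets are disjoint; an exclusion list keeps named nodes
  open and exposes the maximal uniform clades strictly inside them.

## Linking and animation

Selecting samples highlights every tip whose feature occurs in ≥ 1
selected sample **plus** every internal node all of whose descendant tips
are such tips, so fully covered clades highlight as a whole (a
`tips_only` flag restricts to tips). The reverse direction returns the
union of `S(t)` over a node's descendant tips. These are adjoint: any tip
is recovered by selecting the samples that contain it. Selections carry
1-based postorder ranks, which are stable for a given tree and cheap to
map to/from opening positions.

Animation frames are the distinct values of a *gradient* column (numeric
sort when the column is numeric, lexicographic otherwise); within a frame,
samples group by a *trajectory* column, and a feature is unique to a
trajectory iff it occurs in that trajectory's samples and no other
trajectory's samples of the same frame — pairwise disjoint by
construction, and asserted.

**Sliding windows.** Dated records are partitioned by location (after an
optional rename map that merges labels, e.g. boroughs into one city) and a
window of `w` days advances **one day at a time** — the maximal-overlap
reading of "sliding" — over each location's observed date range; the
window starting at day `d` covers `[d, d + w − 1]` inclusive. A community
sample is emitted iff ≥ `min_records` records fall inside, containing each
record once (presence, not abundance: a strain is either observed in the
window or not). Sample ids are `<location>@<window start ISO date>`. The
implementation is tested for exact equality against a brute-force
(location, start-date) double loop.

## Rendering

SVG output is a pure function of (layout, colors, collapsed clades,
layers, style): no timestamps, no hashed ids, fixed float formatting —
identical inputs give byte-identical files, which makes golden tests and
diffs meaningful. Layers draw innermost-first in list order; each tip with
a non-empty payload contributes one `bar-group` element; each layer
contributes a legend listing exactly the categories it drew. Barplots
require tip alignment and are therefore rejected (not silently dropped)
on the unrooted layout at the library level; the CLI warns and drops them.
Collapsed clades render as labeled triangles/wedges spanning their tips.

Discrete colors come from a 12-color colorblind-safe palette; beyond 12
categories the least frequent pool into "Other" (cap and label
configurable). Continuous maps are matplotlib's perceptually uniform
`viridis` (sequential) and `RdBu` (diverging, with a defined midpoint —
default the data mid-range, typically set to 0 for signed statistics);
both are monotone in the data value, and a degenerate scale (all values
equal) maps to the colormap midpoint.

## Synthetic data

The fixture generator grows trees by sequential random coalescence
(binary joins with a 20% chance of a ternary join while ≥ 3 lineages
remain) with exponential branch lengths of mean 0.1 — a scale typical of
16S gene trees. Tables draw per-(sample, feature) Bernoulli presence at a
requested density with positive integer counts; features are a prefix of
the tips (`feature_coverage` controls overlap with the tree). Sample
metadata provides a 3-level categorical `group`, numeric `ph` uniform on
the 4–9 range typical of environmental surveys, integer `timepoint` and
2-level `location`; feature metadata a 3-level `phylum` and a standard
normal `score`. The record generator emits ISO dates uniform over a
configurable span across three locations. Everything is driven by one
`numpy` `Generator` seed and is byte-identical per seed.

What the generator does *not* emulate: phylogenetic signal in the table
(presence is independent of the tree), realistic abundance distributions
(no zero inflation or overdispersion), metadata correlated with topology,
or epidemic-like temporal clustering of record dates. Passing tests
therefore demonstrate the correctness of the *algorithms* under controlled
conditions, not biological realism of any inference.

## Problem sizes

The default suite checks oracle equivalence on 200 trees (≤ 50 tips),
round-trips on 500 trees (≤ 64 tips), shearing on 100 tree/set pairs,
barplot conservation at 1,000 tips × 200 samples, sliding windows on 50
record fixtures, and one full parse + three layouts + barplot pipeline at
100,000 tips — sizes chosen so the whole suite runs in well under a minute
apart from the large-tree smoke (a few seconds itself), while still
exercising every code path at a scale where indexing mistakes would
surface.

## Known limitations

- BP indexes use O(n) words, not succinct o(n) bits; trees are immutable
  (no dynamic BP updates).
- BIOM-HDF5 support reads/writes the v2.1 layout directly via h5py and
  ignores embedded observation/sample metadata groups.
- Taxonomy strings are plain categorical values; no rank parsing.
- The renderer is static SVG only; interactive/browser rendering and QZV
  packaging are non-goals.
- Ordination files are consumed, never computed (no UniFrac/PCoA here).
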