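# treescape

**treescape** is the computational engine of a community-data-aware
phylogenetic tree visualizer. It is aimed at microbiome, metabolome and
other 'omics analyses in which a tree (a phylogeny, a molecular cladogram,
a functional hierarchy) must be viewed *in the context of* a samples ×
features table, sample/feature metadata, and an ordination of the samples —
at the scale of reference trees with hundreds of thousands of nodes.

It provides, as a library plus two small CLI tools:

- **Succinct tree storage.** Trees are held in a balanced-parentheses (BP)
  encoding: a 2n-bit vector in which each node is an open/close pair and a
  subtree is a parenthesis interval. Navigation (`parent`, `first_child`,
  `next_sibling`, `open`/`close` matching, preorder/postorder `select`,
  subtree tip counts) is O(1) via prefix-sum index arrays.
- **Tree shearing** to the features present in a table (the default when a
  table is supplied, and the standard preprocessing step for community
  data), plus sibling sorting by subtree tip count.
- **Three layouts** — rectangular, circular, and unrooted *equal-angle*
  (each subtree receives an angular sector proportional to its tip count) —
  with `actual` and `unit` branch-length modes.
- **Barplot statistics**: per-tip stacked proportions of containing samples
  stratified by a categorical column (e.g. sample type), and numeric
  aggregation of sample metadata onto features (e.g. mean pH of the samples
  a feature occurs in, log10 occurrence counts), with quantile-based sample
  subsetting for outlier removal.
- **Linked views**: selecting samples highlights the tips they contain plus
  every fully covered clade; clicking a node returns all samples containing
  its descendant tips; biplot arrows resolve to named nodes; longitudinal
  metadata become ordered animation frames with per-group unique-feature
  sets.
- **Sliding-window community construction**: dated, located records (e.g.
  pathogen genomes) are aggregated into one community sample per
  (location, window) that meets a minimum occupancy — the input for
  phylogenetically informed ordination of longitudinal data.
- **Deterministic SVG export** of any layout with node coloring, collapsed
  uniform clades, stacked/numeric barplot rings or columns, and legends.

## Worked example

```python
import treescape as ts

# seeded synthetic study: 8-tip tree, 4 samples, table covering 5 tips
nw, table, sample_md, feature_md = ts.generate_fixture(
    n_tips=8, n_samples=4, density=0.5, seed=1, feature_coverage=5/8)
tree = ts.read_newick(nw)
sheared = tree.shear(set(table.feature_ids))
print("tips after shear:", sheared.n_tips)

presence = ts.build_presence(table)
layer = ts.tip_category_proportions(sheared, presence, sample_md, "group")
for tip, props in layer.payload.items():
    print(f"  {tip}: " + ", ".join(f"{c}={p:.2f}" for c, p in props.items()))

sel = ts.samples_to_nodes({"s1"}, presence, sheared)
print("nodes highlighted by selecting s1:", sorted(sel.node_ids))
```

prints

```
tips after shear: 5
  t5: A=0.33, B=0.67
  t2:
  t4: B=1.00
  t1: A=1.00
  t3: A=0.50, B=0.50
nodes highlighted by selecting s1: [1, 3, 4]
```

Reading: shearing keeps the 5 of 8 tips that occur in the table. Tip `t5`
occurs in three samples, two of which belong to metadata group `B`, so its
stacked bar is 1/3 `A` and 2/3 `B`; `t2` occurs in no sample and gets no
bar. Selecting sample `s1` highlights nodes `1`, `3` and `4` (postorder
ranks): the two tips `s1` contains plus their common ancestor, whose clade
is fully covered by the selection.

The same pipeline is available from a shell:

```sh
community-plot --tree tree.nwk --table table.tsv \
    --sample-metadata samples.tsv --barplot-field group -o out/
# out/plot.svg, out/summary.json (node/tip/sample counts after shearing), out/run.log
tree-plot --tree tree.nwk --feature-metadata features.tsv \
    --color-field phylum --layout circular -o out2/
```

Add `--no-shear` to keep tips absent from the table.

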