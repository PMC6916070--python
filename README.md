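# mullerkit

Muller plots, origin-time dendrograms, and clone-tree exports for clonal
evolution data.

When a population is sampled repeatedly over time — a simulated tumor, a
serially passaged xenograft, an evolving microbial culture — its genetic
composition is naturally summarized as a *clone tree* (each clone arose by
mutation within its parent) plus a clone × time matrix of sizes or
frequencies.  `mullerkit` turns that structure into the field's standard
pictures and exchange formats:

* **Muller plots** — stacked polygons where band thickness at time *t* is the
  clone's abundance and descendants are drawn nested inside their ancestor's
  band, so a new genotype visibly *emerges from within* the clone it arose in;
* **origin-time dendrograms** ("evograms") — a tree view whose x axis is each
  clone's origin time (first time its abundance is positive), giving a
  quantitative read on when each expansion started;
* **exports** — Newick (branch lengths = origin-time differences), Graphviz
  DOT, edge lists, and long/wide CSV tables;
* **parsers** for subclonal-reconstruction outputs: PhyloWGS summary JSON
  (cumulative cellular prevalences, one or all candidate trees), CALDER
  proportion-matrix + DOT solutions, and a generic clone-frequency table
  covering ClonEvol-style exports;
* **animations** — per-time-point frames of a growing Muller plot or
  dendrogram, with fixed axes, optionally assembled into a GIF;
* a seeded **branching-logistic simulator** so everything above is testable
  without any external data.

## The layout model

Given a clone forest with abundances `n_c(t)`, define the subtree total
`S_c(t) = n_c(t) + Σ_{d ∈ children(c)} S_d(t)`.  Each clone occupies a band of
height `S_c(t)`; inside it, half of the clone's own mass pads the bottom, its
children stack contiguously in the middle (in canonical order), and the other
half pads the top:

```
lower_child1(t) = lower_c(t) + n_c(t)/2
upper_c(t)      = lower_c(t) + n_c(t)/2 + Σ S_child(t) + n_c(t)/2
```

Painting bands ancestors-first leaves exactly `n_c(t)` of each clone visible,
so summed visible thickness equals the population total (or 1 on frequency
scale) at every time — a conservation property the test suite checks to
1e-9 against an independent brute-force oracle.  Clone ordering is
deterministic: depth-first preorder with siblings sorted by origin time, then
total mass, then id.  Optional grid refinement interpolates trajectories
(linear or monotone cubic) with clone wedges pinned to zero before emergence.

## Worked example

```python
import mullerkit as mk

h = mk.CloneHistory(
    clone_ids=["A", "B"],
    parent_of={"A": None, "B": "A"},
    times=[0, 1, 2],
    sizes=[[10, 8, 6], [0, 2, 4]],   # B emerges inside A at t=1
)
f = mk.normalize_frequencies(h)
layout = mk.compute_bands(f)
print(layout.bands["A"])
print(layout.bands["B"])
print(mk.to_newick(h))
```

prints

```
(array([0., 0., 0.]), array([1., 1., 1.]))
(array([0.5, 0.4, 0.3]), array([0.5, 0.6, 0.7]))
(B:1)A:0;
```

Clone A is the whole population (band `[0, 1]` at every time).  B's band is
centered inside A and widens from zero thickness at t=0 to 0.4 at t=2 —
read `upper − lower`: 0.0, 0.2, 0.4, exactly B's frequency.  The Newick
string records that B arose 1 time unit after A.
`mk.render_muller(layout, f, out_path="muller.svg")` draws the figure;
`mk.filter_clones(h, 0.2)` merges clones that never reach 20% frequency into
their parents without changing any column total.

The same pipeline runs from the shell:

```bash
mullerkit simulate --out-dir demo --seed 5
mullerkit muller --input demo/history_long.csv --scale frequency \
    --threshold 0.2 --out demo/muller.svg --layout-csv demo/layout.csv
mullerkit evogram --input demo/history_long.csv \
    --out demo/evogram.svg --newick demo/tree.nwk --dot demo/tree.dot
mullerkit animate --input demo/history_long.csv --out-dir demo/frames \
    --gif demo/muller.gif
```

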