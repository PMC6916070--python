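# Methods

## Data model

A `CloneHistory` is a forest of clones (each clone has at most one parent;
multiple roots are allowed and no artificial super-root is ever added to the
data), a strictly increasing numeric time axis, and a clone × time matrix of
non-negative abundances on one of two scales: `size` (absolute counts) or
`frequency` (each column sums to at most 1).  Categorical sample labels —
e.g. an originating tumor `T` followed by xenograft passages `X1, X2, …` —
are mapped to consecutive integers 0..m−1 in declared (or first-appearance)
order and retained for axis annotation, since serial passages are an ordered
pseudo-time, not a metric one.

Long tables are the sparse exchange shape, so missing (clone, time) pairs
are zero-filled rather than rejected; contradictions (two parents for one
clone, duplicate observations with different values, parent cycles) are
errors.  `read_long∘to_long` and `read_wide∘to_wide` are exact identities,
property-tested on simulated histories.

## Muller band layout

The layout convention, chosen here and stated explicitly so outputs are
reproducible:

* a clone's band height is its subtree total `S_c(t)`;
* the clone's own mass is split **half below / half above** its children,
  which are stacked **contiguously** in the middle.  The half-split is the
  symmetric convention under which a genotype emerges from *within* its
  ancestor's polygon rather than along one edge;
* vertical order is depth-first preorder with roots and siblings sorted by
  origin time, ties broken by total summed mass (descending), then id.
  Painting in preorder (ancestors first) leaves exactly the clone's own mass
  visible.

Bands are accumulated sequentially (lower pad, children, upper pad) rather
than as `lower + subtree`, so boundary values are plain running sums of
half-masses; an independent test oracle recomputes them as cumulative sums
of the flattened half-entry sequence, and the two agree to 1e-12 on every
labeled forest with up to 5 clones (1441 topologies).

Degenerate inputs are handled geometrically rather than rejected: an
all-zero clone gets a zero-height band; an all-zero column gets zero-height
bands for every clone.  `root_gap` (default 0, same units as the scale)
inserts white space between root bands.

### Grid refinement and emergence

Observed trajectories are often coarse.  `refine_grid` subdivides each
interval into `points_per_interval` equal steps and interpolates each
clone's trajectory either linearly or with a shape-preserving monotone cubic
(PCHIP).  PCHIP was chosen over unconstrained splines because it cannot
overshoot between points — negative abundances would otherwise appear
between a zero and a small positive observation; any residual negatives are
clipped and, on frequency scale, each refined column is renormalized to
sum 1 as a second guard.

A clone first observed positive at `t_j` must rise from zero somewhere in
`(t_{j−1}, t_j]`.  The emergence anchor is `t_{j−1}` by default
(`previous_point`: the wedge opens at the last observed zero) or the
interval midpoint (`midpoint`, opt-in, giving sharper wedges); values are
pinned to exactly zero before the anchor and ramp linearly from the anchor
to the first positive observation.  Both conventions exist in prior
visualization practice; neither is canonical.

## Origin-time dendrogram and exports

A clone's origin time is the first time point with positive abundance
(never-positive clones are flagged and drawn at the last time point).  The
dendrogram places nodes at x = origin time and y = the Muller clone order,
so the two views are visually consistent; edges are elbows (vertical
connector at the parent's x, horizontal run at the child's y).  Node sizes
map to the clone's *maximum* abundance over the time course — a stated
choice; mean or final abundance would be equally defensible.

Newick branch lengths are origin-time differences (a root's length is its
origin minus the first time point): the tree is time-styled, not a genetic
distance tree.  A child observed before its parent — possible in noisy
reconstructions — is kept and warned about, never silently reordered.
Forests are wrapped under an artificial zero-length root for Newick only.
DOT output uses a minimal emitter/parser restricted to the digraph
node/edge-statement subset; it is not a full Graphviz implementation.

## Reconstruction-tool semantics

The two supported tools report abundance differently, and the distinction
is load-bearing:

* **PhyloWGS** cellular prevalence is *cumulative over the subtree* (the
  fraction of cells carrying a clone's mutations includes all descendants),
  so own abundance = prevalence − Σ children's prevalences.  Negative
  values from inconsistent reconstructions are clipped to zero with a
  warning (tolerance 0.01 before an additional consistency warning names
  the clone and sample) rather than rejected, so real outputs stay
  plottable.  The normal/root population is kept by default; an option
  removes it and renormalizes.  With several candidate trees, the user
  selects the best (maximum reported likelihood, falling back to the first
  with a warning when no likelihood is present), all, or an explicit index.
* **CALDER** proportions are already per-clone; they are transposed into
  clone × sample form with no subtraction.  Rows summing above 1.01 and
  clone labels that disagree between matrix and DOT are consistency errors.

Both semantics are fixed by round-trip tests: the fixture writer encodes a
known history in each dialect and the parsers must reproduce it within
1e-9.  ClonEvol's native outputs are serialized R objects, so its support
is via a documented clone/parent/sample/frequency CSV dialect.

## Threshold filtering

A clone is removed iff it is not a root and its maximum frequency over the
whole time course (computed on the normalized history) is below the
threshold — whole-clone removal, not per-time masking, so filtered clones
vanish entirely.  The default mode **merges** the removed clone's mass into
its parent at every time and re-parents its children, conserving every
column total exactly (removal proceeds children-first so chains of
sub-threshold clones collapse into the nearest survivor); **drop** discards
the mass and is opt-in.  Merge is the default because conservation keeps
Muller totals meaningful after filtering.

## Synthetic generator

`simulate_clonal_dynamics` is a discrete branching-logistic process: per
step each clone updates `n' = n · exp(r · fitness · (1 − N/K))` with fixed
`r = 0.5`, then each clone of size ≥ 1 spawns a child with probability
`mutation_rate`, seeded with exactly 1 individual (so origin times are
unambiguous) and fitness equal to the parent's times `exp(N(0, sd))`.
Defaults — 30 steps, K = 1000, mutation rate 0.05/clone/step, fitness-effect
sd 0.2, initial size 10 — produce histories of a handful to a few dozen
clones with the competing-sweep dynamics Muller plots are designed to show,
at sizes where hundreds of replicates run in seconds.  The size-1 spawning
floor exists because a clone with less than one individual cannot plausibly
emit one.

What the generator does *not* emulate: measurement noise, missing samples,
reconstruction error (children are never observed before parents), clone
extinction to exactly zero (logistic decay is asymptotic), or realistic
mutation spectra.  Passing tests therefore certify the geometry, parsing
and conservation machinery on clean trees, not robustness to inconsistent
real-world reconstructions — that robustness is exercised separately by the
clipping/warning paths in the parsers.

## Numerical choices

* Conservation and round-trip tolerances: 1e-9 absolute; oracle agreement:
  1e-12; frequency column sums: 1e-12 after normalization, 1e-9 on input
  validation.
* Ties in label placement (argmax of visible thickness) resolve to the
  earliest time.
* Rendering is deterministic: a fixed SVG hash salt, no date metadata, and
  palettes assigned by clone order, so identical inputs give byte-identical
  SVG.
* The acceptance script derives per-replicate seeds as
  `(seed · 100003 + i) mod 2^31` so different base seeds give disjoint
  replicate sets; problem sizes are 200 histories for conservation/nesting,
  1441 forests for the oracle, 50 seeds per round-trip dialect, 100
  histories for filtering.

## Known limitations

* The Muller layout is the deterministic half-split only — no curvature
  optimization or force-directed smoothing of band boundaries.
* The DOT parser handles the tree-exchange subset, not arbitrary Graphviz.
* CALDER's on-disk layout varies across versions; the parser targets the
  labeled proportion-matrix + DOT contract and version-specific wrappers
  are left to callers.
* Wide tables with duplicate time headers, and histories whose times are
  not representable as floats, are unsupported.
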