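# Methods

This note documents the models and procedures behind `modnet`, the
parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not establish about real data.

## Network model

The substrate is an undirected simple graph with typed node/edge
attributes, extended with *hyper-edges* (≥ 2 participants with free-form
roles, for reactions that binary edges cannot express) and *groups*
(compound nodes with pairwise-disjoint member sets, the display vehicle for
clusters).  Hyper-edges are data only: degree, shortest paths, clustering
and layout forces all operate on binary edges exclusively, because every
analysis step in the pipeline is defined on the binary interaction graph.
Duplicate edge input (including reciprocal A–B / B–A rows) collapses to one
undirected edge keeping the maximum confidence score — deterministic, and
the right bias for confidence networks where the higher evidence wins.
Node ids are case-sensitive, whitespace-stripped strings; identifier
mapping (symbol/Ensembl/Entrez conversion) is deliberately out of scope and
must happen upstream.  A node carries at most one of the roles
`seed`/`linker`; seed wins on conflict so a gene that is itself altered is
never displayed as a mere connector.

GraphML is the lossless persistence format (group membership as a
`__group` node attribute plus a graph-level JSON header; hyper-edges in a
sidecar JSON, since GraphML has no hyper-edge standard).  Node iteration is
sorted before serialization so identical networks serialize byte-identically
across processes regardless of Python hash randomization.

## Seed selection and subnetwork extraction

Seeds are genes with mutation frequency strictly above `mut_freq_min`
(default 0.02) **or** CNA frequency strictly above `cna_freq_min` (default
0.03); both thresholds are fractions of the patient cohort.  Strict
inequalities are used throughout (a gene exactly at a threshold is not
selected), matching the convention "frequency > t".

Extraction takes the score-filtered background (edges with confidence
strictly > `min_score`, default 900 on a STRING-like 0–1000 scale,
isolated nodes dropped) and keeps, for every unordered seed pair at graph
distance ≤ `max_distance` (default 2), every node and edge lying on *any*
shortest path between them.  Ties are therefore all included; longer-than-
shortest paths are never included; pairs farther apart than the threshold
contribute nothing (no path is forced).  Non-seed nodes in the result are
flagged linkers.  Seeds absent from the background are dropped with a
warning; if fewer than two survive, the seeds-only network is returned
rather than raising.

## Linker significance

A candidate linker with global degree *k* in the filtered background
(*N* nodes, *s* of them seeds) touching *x* seeds is scored with the
upper-tail hypergeometric probability P(X ≥ x), X ~ Hypergeom(N, s, k).
The sampling frame is the *score-filtered* background, not the full source:
that is the graph the paths were extracted from, so it is the universe in
which "how many seed neighbors would a degree-k gene have by chance" is the
right question.  The test is applied once to the initial candidate set (no
iterative re-testing after removals).  Default α = 0.01 with no
multiple-testing adjustment; BH adjustment is available by flag.  Linkers
at p ≥ α are removed with their incident edges; seeds are never removed,
and seeds isolated by the removal are kept — they are the objects of study.
The computation uses `scipy.stats.hypergeom.sf`; tests verify it against an
exact big-integer tail summation to 1e−10.

## Correlation weighting

Each edge's weight becomes the Pearson correlation of its endpoint genes'
expression across samples (all samples; per-subgroup weighting is a
deliberate non-feature — slice the expression matrix upstream if wanted).
The signed r is kept for display; |r| is stored as `similarity` and is what
clustering consumes, since flow simulation requires non-negative
capacities.  Zero-variance genes yield weight 0 with a warning (r is
undefined); genes absent from the expression matrix leave the weight at 1.0
with a `weight_missing` flag rather than silently biasing the clustering
toward dropped edges.  At least 3 shared samples are required.

## Clustering

**MCL.**  The adjacency (similarity) matrix gets self-loops equal to each
node's maximum incident weight (1 for isolated nodes) — the standard guard
against period-2 oscillation — and is column-normalized to a stochastic
flow matrix.  Each iteration applies expansion (matrix power, default 2),
inflation (entrywise power followed by column renormalization), and entry
pruning below 1e−5; iteration stops when the largest column-wise change
drops below 1e−8 or after 100 iterations (non-convergence returns the
current interpretation with a flag, never an exception).  Clusters are read
off attractor rows (positive diagonal mass); attractor systems sharing
support are merged, and a node supported by several systems goes to the one
with the larger limit entry, ties to the lexicographically smaller
attractor id — this makes the partition deterministic and invariant to node
relabeling.

The inflation default is **1.6**.  Inflation sets granularity, and the
value is calibrated to the scale this package targets: gene modules of
roughly 10–30 members in sparse interaction graphs.  At inflation 2.0 MCL
shatters 20-node modules with within-module edge probability 0.3 into
fragments of 3–8 nodes (verified against an independent implementation —
this is inherent MCL behavior, not an implementation artifact), while 1.6
recovers planted modules of that shape with mean adjusted Rand ≈ 0.94.
Users clustering much smaller, denser complexes should raise it.

**MCODE.**  Vertex weight = (highest k-core number of the vertex's closed
neighborhood) × (density of that core subgraph); vertices below
`degree_cutoff` (default 2) get weight 0.  Complexes grow outward from the
highest-weight unvisited seed, admitting neighbors whose weight is at least
(1 − `vertex_weight_percentage`) × seed weight (default 0.2), each vertex
visited at most once, so complexes are disjoint.  The optional haircut
(default on) iteratively strips members with fewer than two in-complex
neighbors; the optional fluff stage (default off) adds unvisited direct
neighbors whose own neighborhood density exceeds `fluff_density` (0.5 —
this threshold is an implementation parameter: the fluff rule needs a
density cutoff to be well-defined).  Seed ties break lexicographically, so
output is independent of node insertion order.

Non-singleton clusters can be promoted to groups `cluster_1..k` in
size order (ties by smallest member id); singletons are never promoted.

## Over-representation analysis

Ontology terms come from an OBO file (obsolete terms excluded, `is_a`
cycles rejected); annotations from GAF 2.x (NOT-qualified rows skipped,
optional evidence-code filter) or a two-column term↔gene TSV.  Annotations
propagate over `is_a` ancestors only — the smallest defensible closure;
`part_of` is intentionally ignored.  The default universe is every gene
with at least one propagated annotation (standard ORA practice), overridable
per call; query genes outside the universe are dropped with a warning and
the query size reduced, avoiding silently deflated p-values.  Per term,
p is the same hypergeometric upper tail as the linker test; terms smaller
than `min_term_size` (default 3) are skipped; adjustment is BH by default
(Bonferroni and none available).  The multiple-testing procedure and
universe are exposed as flags precisely because different communities
default differently.

## Layout

A spring-electrical model with two group terms:

* spring along each edge: F = k_s (d − L) toward rest length L (defaults
  k_s = 0.1, L = 50 abstract units);
* inverse-square repulsion between every node pair: F = C / d² (default
  C = 5000), multiplied by `group_repulsion_gain` (default 2) when the two
  nodes belong to *different* groups;
* centroid attraction for grouped nodes: F = g · k_s · (centroid − x)
  with `group_attraction_gain` g = 3.

Damped velocity integration: v ← damping · (v + h·F), x ← x + h·v, with
damping 0.9 and step size h = 0.2 (chosen for stable, reasonably fast
settling at the default force constants).  The run stops when the mean
per-node displacement falls below `convergence_tol` (1e−3) or at
`max_iter` (500).  Initial positions are drawn from a seeded uniform disc;
coincident points are jittered deterministically from (seed, iteration).
All per-iteration reductions run in sorted node order, so a given
(network, params, seed) yields a bitwise-identical coordinate trace, and
advancing a state n steps at a time with constant parameters reproduces a
single long run exactly (the state carries uncentered positions for exact
continuation; the public coordinates are always re-centered so the global
centroid sits at the origin).  Changing parameters between steps is the
dynamic-reconfiguration contract used for interactive tuning.

Two caveats are intentional.  Energy monotonicity is not guaranteed —
damped dynamics may overshoot — so convergence is defined on displacement,
not energy.  And a network whose groups/components share no edges has no
attractive term bounding them, so mutual repulsion pushes them apart
indefinitely; such runs end at `max_iter` unconverged, with the geometry
still perfectly usable.  No Barnes–Hut approximation is used: exact
pairwise repulsion keeps determinism trivial, and the intended problem
sizes (hundreds of nodes) do not need the speedup.

Group outlines: rectangle = padded axis-aligned bounding box; circle =
smallest centroid-centered circle covering the members, padded; convex
hull = scipy's hull of member coordinates scaled outward by the padding
(collinear member sets degrade to a segment, singletons to a padded point).

## Visual mapping and overlay

A mapping is a monotone linear interpolation from a numeric attribute
domain (explicit or observed min/max) to a size interval or a 2–3-anchor
hex color gradient; 3-anchor gradients place the middle anchor at the
domain midpoint.  Interpolation is linear in sRGB — chosen for bit-exact
testability over perceptual uniformity, and documented as such.  Values
outside the domain clamp (default) or hide; missing values render neutral
with an `absent` flag; a constant attribute maps everything to the range
midpoint with a warning.  Overlay frames share one coordinate set and, by
default, one value domain pooled across all conditions, so identical
styles mean identical values in every frame — the point of serial
comparison.  The export contract is the styled tables/GraphML, not pixels.

## Synthetic fixtures

`planted_network` draws a planted-partition graph: within-module edges
with probability `p_in`, cross-module with `p_out`, uniform confidence
scores.  `simulate_omics` generates expression from a per-module one-factor
model — gene = √ρ · module factor + √(1−ρ) · noise — so the expected
within-module pairwise correlation is exactly ρ, giving a closed-form
target for verification; per-condition mean shifts are added per module,
and a chosen fraction of designated "altered" modules' genes receive
mutation/CNA frequencies drawn above the selection thresholds while all
other genes stay below them (frequencies are drawn, not fixed, so the
strict-threshold boundary logic is exercised).

The end-to-end preset (`gbm_like_configs`): 5 modules × 20 genes, 3
altered modules at altered fraction 0.8, ρ = 0.6, 100 samples, 4 condition
labels named after tumor expression subtypes, scores ~ U(800, 1000) with
raw p_in = 0.6 and p_out = 0.02.  The raw p_in is set so the
*post-confidence-filter* within-module edge probability is 0.3 — the
density regime in which planted modules of this size are recoverable, and
a reasonable emulation of real confidence networks, where high-confidence
subnetworks of true complexes remain dense.  Problem sizes throughout the
test suite (100-node fixtures, 20-seed replications, ≤ 200 layout
iterations) are chosen as the smallest scales at which the statistical
claims are meaningful.

What passing fixtures do **not** show: real interaction networks have
heavy-tailed degrees, module overlap and annotation bias that the planted
model lacks; real expression has batch effects and non-Gaussian tails; real
alteration frequencies correlate with gene length and copy-number context.
The fixtures validate the machinery — selection logic, path semantics, the
hypergeometric kernel, flow clustering, determinism — not biological
discovery performance.

## Pipeline

`modnet pipeline --config run.toml` runs seeds → extract → filter →
weight → cluster → groups → enrich → layout → overlay.  Stage outputs are
files, not in-memory handoffs, so any stage can be rerun or inspected in
isolation; a JSON run log records each stage's parameters and SHA-256
output checksums.  The pipeline is a pure function of (config, inputs):
reruns are byte-identical, which the test suite asserts file by file.
Unknown config keys are rejected before any stage runs; a stage failure
aborts with the stage name, retaining partial outputs.  Exit codes: 0
success, 2 config error, 3 stage failure.

## Known limitations

* Undirected simple graphs only; no directed or multi-edge semantics, no
  SBML/BioPAX import, no identifier conversion.
* The linker universe is the filtered background; genes outside it are
  invisible to the significance test.
* MCL is dense linear algebra: fine to a few thousand nodes, not for
  genome-scale graphs.
* GAF parsing uses the DB-object-symbol column as the gene id and assumes
  it matches the network's node ids.
* sRGB-linear color interpolation is not perceptually uniform.
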