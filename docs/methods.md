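# Methods

## Flow fields and grids

A flow field holds the moisture volume `m_ij` (mm per month, or mm per year
for annual fields) evaporated in grid cell *i* that precipitates in cell
*j*, as a sparse non-negative matrix over a regular lat–lon grid with
row-major cell indexing. Cell centers follow
`lat = −90 + res/2 + row·res`, `lon = −180 + res/2 + col·res`; longitudes
wrap. Annual fields are the per-pair sum of twelve monthly fields (mass is
additive). Fields round-trip through two formats: a netCDF link list
(written with the NetCDF3/scipy backend; the land mask as int8) and plain
text triplets with a YAML grid sidecar.

## Backbone extraction

Interpreting the weighted flows directly as an unweighted graph would
ignore that flow magnitudes span many orders of magnitude. The backbone
therefore includes links strongest-first until the cumulative included
volume first reaches ρ of the total transport; "reaches" is read as ≥, so
the edge that crosses the threshold is included and the edge set is the
minimal prefix of the ranking. Choices the ranking needs:

* **Tie rule.** Stable sort by (flow descending, source index ascending,
  target index ascending), recorded in the network header. Any tie rule
  yields a valid backbone; fixing one makes runs bit-reproducible.
* **Self-loops.** Within-cell recycling `i→i` is never an edge candidate
  (all three motifs require distinct nodes). By default self-loop volume is
  also removed from the thresholding denominator
  (`self_loop_policy="exclude"`); `"retain_denominator"` keeps it in the
  denominator only. Both are recorded in the output metadata.
* **Land-to-land scope.** The default restricts the field to land–land
  pairs first and thresholds against that subtotal
  (`threshold_scope="restricted"`); the alternative thresholds globally and
  then drops non-land-land edges. Both are exposed because either reading
  of "selecting the land-to-land connections" is defensible.

Consequences used as test invariants: edge sets are monotone in ρ, the
captured fraction is ≥ ρ, and dropping the weakest included edge falls
below ρ.

## Motif census

On the backbone adjacency `A` (no self-loops), with `R = A ∘ Aᵀ` the
reciprocal-pair indicator:

* `k_in(i) = Σ_j a_ji`, `k_out(i) = Σ_j a_ij`.
* **FFL** — counted at the target: `ffl(c) = Σ_{a,b} a_ab a_bc a_ac`
  (node distinctness is implied by the edges). In matrix form the column
  sums of `A ∘ A²`.
* **ZL** — `zl(i) = Σ_j R_ij`, the number of reciprocal partners. The node
  sum is twice the reciprocal-pair count.
* **NBr** — counted at the center, the ZL member receiving the external
  edge: occurrences are triples `(s, c, p)` with `c↔p`, `s→c`, and `s`
  distinct from both ZL members; in pattern mode
  `nbr(c) = zl(c)·(k_in(c) − 1)`. A reverse edge `c→s` does not
  disqualify in pattern mode.

Two counting modes: **pattern** (default — an occurrence needs only its
required edges) and **induced** (no other edges may exist among the
participating nodes; for ZL the modes coincide because a pair has no
non-motif edge slots). Pattern counts are monotone under edge addition and
bound induced counts from above; both facts are property-tested, and the
whole census is validated against an exhaustive triple enumeration.

Beyond role counts the census reports, per edge, the number of occurrences
(any type, any role) containing it, and per node the number of occurrences
containing it in any role ("total involvement" — the role-specific counts
remain available separately). One triple may count toward both FFL and NBr
totals; no exclusivity correction is applied and types are always reported
separately. All products are dense float64 matrix algebra (counts are small
integers, exact in float64), O(n²·n) time and O(n²) memory — ample
headroom at the desk-scale grid of ~10³ cells.

## Strengths, regional aggregation, classification

Per-node counts are rescaled by the global per-type maximum
(`strength = count / max`), so the strongest node of each type has strength
1; if a type has no occurrence anywhere its strengths are zero and the
normalizer is flagged. Regional values are means of the per-node difference
fields (FFL−ZL, FFL−NBr) over the region's cells — uniform by default, with
cos-latitude weighting available (the desk-scale grids make the difference
small; on real 0.5° grids area weighting matters more).

Labels use a dead zone ε = 0.01 against numerical noise:
FFL−ZL > ε → directed lens; both differences < −ε → the more negative one
decides (washing machine for FFL−ZL, corridor for FFL−NBr; an exact tie is
"mixed"); only one < −ε → that regime; otherwise mixed. Classification is
invariant under a common positive rescaling of the fields and ε.

Threshold sensitivity reruns the whole pipeline per ρ ∈ {0.20, 0.25, 0.30}
(configurable); the summary reports the aggregate at the reference
ρ = 0.25 and the min/max across the grid as error bars. Monthly profiles
aggregate each monthly field separately and compare the monthly mean with
the annual-field value.

## Null models

Two ensembles, reported side by side (R = 50 replicates by default, seeded):

* **density_matched_random** — directed graphs with the same node and edge
  count, edges uniform without replacement. With the edge count fixed at m
  over `N = n(n−1)` slots, the exact per-node FFL-target expectation is
  `(n−1)(n−2)·m(m−1)(m−2)/(N(N−1)(N−2))`, which converges to the
  independent-edge form `(n−1)(n−2)p³` for large networks; both forms are
  exercised in the tests.
* **degree_preserving_rewire** — 10·m accepted pairwise swaps
  `(a→b, c→d) → (a→d, c→b)` per replicate, rejecting self-loops and
  duplicates, preserving every in/out degree. If the proposal budget
  (100× the swap target) runs out, the replicate is kept and a warning
  reports the achieved swap count.

## Lagrangian tracker

Per time step of length Δt (default 0.1 h), each parcel:

1. advects by the bilinearly interpolated wind at its level (winds in grid
   cells per hour; longitude wraps, latitude clamps at the poles);
2. with probability Δt / mixing period (default 24 h) is redistributed
   along the column with probability proportional to the vertical moisture
   profile;
3. rains out: with `f = min(P/TPW, 1)` at its cell, allocates
   `A = f · W · E_source` to that cell (credited against its origin), and
   updates `W ← W + (E − P)·W/TPW` (the precipitation term capped at full
   rainout).

The source-fraction update is the point where the published scheme is
ambiguous: the printed update multiplies by the allocated amount `A`
itself, which is dimensionally inconsistent for a fraction. The default
`fraction_conserving` mode therefore keeps two buckets — source moisture
decays by `(1 − f)` while moisture gained from local evaporation is
non-source — which keeps `E_source` in [0, 1] (property-tested) and closes
the per-origin mass budget to 1e−9 relative (released = allocated +
remaining, exactly in exact arithmetic). The `literal` mode applies the
printed update verbatim and is flagged experimental; it carries no
conservation guarantee.

Release: `round(parcels_per_mm · E)` parcels per cell and step (default
100 per mm), each with an equal share of the cell's evaporation,
`E_source = 1`, at uniform random positions in the cell, one level above
the surface (the vertical coordinate is an abstract level index with a
supplied moisture-profile weight vector — no pressure physics at desk
scale, so "one level up" stands in for a fixed pressure offset). Parcels
retire after 30 days or once 99% of their initial moisture has
precipitated. Forcing is taken from the state sequence step by step
(nearest state in time; no temporal interpolation at desk scale). Units:
E, P, TPW and W all in mm.

## Synthetic generator

The generator is the study-conditions module: it emulates what matters
statistically about gridded recycling data — sparse non-negative flows
spanning ≥ 3 orders of magnitude, a land/sea partition, and spatially
coherent motif regimes — without attempting real geography or seasonality
physics.

Default grid 24×48 at 7.5° with four 5×5 tropical blocks: one lens, two
washing machines, one corridor (mirroring the classical hub pattern of one
lens-like and several reciprocity-dominated regions). Wiring per regime:

* lens: `i→i+1, i→i+2, i→i+3` along a block ordering — interior cells are
  FFL targets (count 3), no reciprocal edges;
* washing machine: a reciprocal ring — every cell `zl = 2`, no FFLs;
* corridor: reciprocal pairs, each member fed by 3 disjoint feeder cells —
  members have `nbr = 3`, `zl = 1`; feeders stay motif-free.

These counts make the block-level strength differences separate cleanly
(lens ≈ +0.9, washing machine = −1, corridor FFL−NBr < FFL−ZL < 0), with
every contrast far above the declared minimum effect size of 0.05.

Magnitudes: planted edges draw log-normal flows around 100 mm (σ = 0.25);
background edges (30 000 random ordered pairs among non-block cells) draw
log-normal flows with σ = 2, clipped below half the weakest planted flow
and rescaled so the planted wiring carries 14% of total volume. Hence all
planted edges rank above all background edges and fit below ρ = 0.20, so
the complete planted wiring is inside every backbone of the sensitivity
grid, while background edges admitted at higher ρ form a sparse random
graph whose motif counts stay below the planted normalizers (verified over
seeds 0–9). Monthly sequences redraw magnitudes with month-indexed seeds
under a shared land mask; selected months can flip a block's regime.

What passing on synthetic data does *not* show: real flow fields have
spatially autocorrelated, seasonally varying flows and motifs arise from
continuous physics rather than discrete wiring, so recovery here validates
the pipeline's correctness, not the climatological conclusions one would
draw from reanalysis-driven data.

## Numerical choices and problem sizes

Thresholds compare with a 1e−12 relative guard so exact-boundary cases
(e.g. cumulative exactly ρ·total) are included deterministically. All
stochastic components take explicit seeds; month seeds derive from the base
seed via seed sequences. The shipped analyses and the acceptance script use
the desk-scale defaults (24×48 regime grid, 6×12 tracker grid, R = 200
null replicates at n = 50), which keep a full run in the minutes range on
one CPU; all sizes are plain parameters.

## Known limitations

* No ingestion of reanalysis data or the published global flow dataset; no
  regridding between resolutions.
* The census implementation is dense; grids beyond ~10⁴ cells would need a
  sparse triad formulation (the role decompositions carry over).
* Focus-region rectangles for real-world grids are configurable
  approximations; conclusions depending on exact box coordinates are
  reproducible only up to the configured boxes.
* The literal source-fraction update is provided for comparison only.
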