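# Methods

This note documents the models, conventions, and design choices behind
each stage of the pipeline, the parameters that matter, and what the
synthetic landscape does and does not establish about real data.

## Spatial conventions

All data live on one planar metric grid (meters): row 0 is the
northmost row, the origin is the top-left corner of cell (0, 0), and a
cell's area is `cell_size²` (0.09 km² at the 300 m study resolution —
this is what makes the 35 km² source filter a 389-cell threshold).
Geographic coordinate systems are out of scope; users project their data
first. Rasters round-trip through ESRI ASCII grids with full float
precision; joint operations refuse rasters whose grid contracts differ.

## Synthetic landscape generator

`synthland` builds the study system the tests and analysis scripts run
on: a latent suitability field in [0, 1] (sum of Gaussian bumps plus
white noise, clipped), covariates, occurrences, and binary patch
mosaics with declared geometry. One integer seed drives every draw.

The default landscape is a 200 × 200 grid of 300 m cells (3600 km²)
with three plateau-topped habitat blocks built from overlapping
amplitude-1 bumps (σ = 900 m, 1.5 km spacing) whose clipped sum
saturates — giving compact high-suitability cores with steep margins,
like forested massifs — plus two sub-threshold stepping-stone islets
and five faint ridges (amplitude 0.22) that give the resistance surface
corridor structure without becoming habitat. Field noise is small
(σ = 0.005). These choices emulate the situation the workflow is built
for: habitat occupying roughly a tenth of the extent, fragmented at the
500–1000 m dispersal scale, with presence/background discrimination in
the high range reported for real forest-pheasant surveys (test AUC
≈ 0.88–0.92, TSS ≈ 0.73–0.75 under the defaults). Covariates are
monotone transforms of the field plus independent noise (σ = 0.05 in
the pipeline default); one engineered near-collinear combination
exercises the VIF screen.

What the generator does *not* emulate: real climate surface structure,
anisotropic terrain, sampling bias in occurrence records, temporal
change, and label noise from misidentified records. Passing tests
therefore demonstrate the correctness of the algorithms and the
recoverability of a well-posed landscape, not performance on national
survey data.

Presence points are drawn with probability proportional to suitability
(with replacement — field surveys revisit good habitat); background
points are uniform, with count defaulting to the presence count. The
study this emulates never states its pseudo-absence design, so the
simplest mechanism is used and documented here.

## Occurrence thinning

Sequential 1 km thinning: scan presences in input order, keep a point
iff it is ≥ 1000 m from every previously kept point. This is
deterministic and idempotent but order-sensitive; it does not maximize
the retained count (no thinning rule that does is canonical).
Background points are never thinned.

## VIF screening

VIF of layer k is `1/(1 − R²_k)` with R² from ordinary least squares of
layer k's values (sampled at the occurrence and background cells,
nearest cell) on all other remaining layers. The screen removes the
single worst layer while any VIF ≥ 10 and recomputes. Exact collinearity
(R² = 1) is treated as infinite VIF and removed first; constant layers
have undefined R² and are removed with a warning. Note that with several
monotone transforms of one underlying gradient the screen may legitimately
remove informative layers too — as it does for real bioclimatic stacks.

## Learners and the ensemble

The three model families are deliberately thin wrappers over
scikit-learn: a spline-basis logistic regression (smooth additive), a
random forest, and an L2-regularized logistic regression on quadratic
features (maximum-entropy-style). Their internals are not the package's
contribution; the ensemble logic is:

* **Gates.** A learner is excluded if AUC < 0.8 *or* TSS < 0.7. The
  source description of the gate is grammatically ambiguous ("AUC below
  0.8 and TSS below 0.7 were considered poor"); the disjunctive reading
  is used because either failure alone is labeled poor performance, and
  it is the stricter of the two. Each exclusion is reported with its
  reason.
* **Weights.** Raw weight `(AUC − 0.5)²` (zero at random performance),
  normalized to sum to 1 over retained learners so the weighted mean is
  well defined.
* **Scores.** AUC is the Mann–Whitney rank statistic with ties counting
  one half; TSS is maximized over the observed score thresholds with
  prediction rule `score ≥ t` (Allouche et al. convention).
* **Jackknife.** Importance of variable v is
  `max(0, AUC_full − AUC_without_v)`, normalized to percent
  contributions summing to 100; with-only-v AUCs are reported for
  reference. An all-zero score vector (e.g. perfectly redundant
  variables) degenerates to uniform contributions with a warning.
* **Binarization.** The habitat cut is the max-TSS threshold of the
  ensemble scores on the held-out set — the source study never states
  its cut, and max-TSS is the standard presence/background choice.
  Degenerate test sets fall back to 0.5 with a warning.

## Connectivity indices

Patches are 8-connected components; `a_i` is cell count × cell area,
and `A_L` is the full raster extent (so indices are comparable across
maps of the same extent). Inter-patch distance is the minimum Euclidean
distance between boundary-cell centers. For dispersal distance `d*`,
binary links satisfy `d_ij ≤ d*` and dispersal probabilities follow the
negative-exponential kernel `p_ij = exp(−α d_ij)` calibrated so
`p = 0.5` at `d*` (the Conefor convention; the species' 500 m average
and 1000 m maximum weekly movement distances are the two `d*` values
used throughout).

`nl_ij` comes from unweighted shortest paths; pairs in different
components contribute nothing to IIC. `P*_ij` is computed as a
shortest path on edge weights `−ln p` over the complete graph (the
exponential kernel gives every pair a positive direct probability);
probability-1 links are preserved as zero-weight edges. The printed
bound `0 < IIC < 1` is implemented as `0 < IIC ≤ 1`: a single patch
filling the landscape attains exactly 1. For dPC, removing a patch
deletes its rows and links but `A_L` is held fixed — removal destroys
habitat, not landscape — so `dPC` of the sole patch is 100.

All-pairs shortest paths use scipy's C implementations; with a few
hundred patches the full per-patch dPC table computes in seconds.

## MSPA

Classes are assigned with chessboard distances matching the 8-connected
foreground rule, with edge width `s` in cells (default 1 = 300 m, the
movement-scale resolution; the source study never states its edge
width):

* core — foreground farther than `s` from background (cells beyond the
  raster border count as background), identical to erosion by a
  `(2s+1)²` square;
* islet — components containing no core;
* perforation / edge — non-core cells within `s` of core, split by the
  adjoining background: perforation borders a hole (a background
  component, 4-connected, not reaching the raster border), edge borders
  the outer background; cells near both are classed perforation;
* bridge / loop / branch — remaining connector cells, labeled per
  connector component by contact counting: two or more distinct core
  components → bridge; one core component at two or more disjoint
  contact zones → loop; one contact → branch.

The eight-class list in the source text includes a "missing" class that
does not exist in the standard seven-class scheme; it is treated as a
typo and omitted. Sources are core components of ≥ 35 km² (strictly
smaller excluded), with areas over core cells only.

## Resistance and corridors

Resistance is the minimal monotone map `R = r_min + (r_max − r_min)(1 − H)`
with `r_min = 1`, `r_max = 100` (configurable): continuous by
construction, never binary. Step cost between adjacent cells is the
mean of the endpoint resistances × center-to-center distance (√2 × cell
for diagonals), the convention of standard least-cost GIS tools.
Cost-weighted distance is a single multi-source Dijkstra via a virtual
zero-cost super-source; least-cost paths are reconstructed from the
Dijkstra predecessor arrays (exact and deterministic), and the meeting
cell among cost ties is the lowest row-major index.

A corridor's swath is `CWD_a + CWD_b − lcp ≤ cutoff` with the 20,000
cost-unit default. The cutoff is interpreted as the swath-truncation
rule: reported real corridors tens of kilometers long are impossible
under a reading that drops any corridor whose total least-cost cost
exceeds 20,000 (even at the minimum resistance of 1, cost equals path
meters), so the drop rule exists (`drop_above_cutoff`) but is off in
the pipeline default. Candidate pairs are sources whose cost-allocation
regions (each cell assigned to its cheapest source, ties to the lower
id) share an 8-neighbor boundary — the Linkage-Mapper "adjacent core
areas" convention — with an all-pairs option.

## Prioritization

The four importance levels (0–25 / 25–50 / 50–75 / > 75%) are
percentile-rank bins over the observed score distribution, not
fractions of the maximum score; ties share the mean rank and hence the
class, and an item exactly on a boundary goes to the lower class. For
corridors the score is the least-cost cost standardized to [0, 1] by
`(x − min)/(max − min)`, with *lower* standardized cost more important
(a cheaper corridor transmits more); the direction is configurable
since the source text does not state it. A single corridor is class 4
by convention.

Percent declines are `100 (v_start − v_end)/v_start`, reported to two
decimals. Recomputing the published habitat areas 91,571 → 10,002 km²
gives 89.08%, not the printed 89.58%; the package reports recomputed
values and flags the mismatch rather than matching the printed figure.

## Problem sizes and numerical choices

The analysis scripts and acceptance run use the default 200 × 200
landscape with 200 presences — sizes at which every stage (three model
fits, the full per-patch dPC table on ~45 patches, three corridor
Dijkstras on 40,000 cells) completes in seconds while exhibiting all
the structure of the method. Oracle-equivalence tests run exhaustive
enumeration on graphs of ≤ 6 patches (tolerance 1e-12) and
Bellman-Ford relaxation on grids up to 40 × 40 (tolerance 1e-9).
Shortest-path tie-breaks inherit scipy's deterministic ordering; all
randomness flows from one integer seed per run.

## Known limitations

* Learner families approximate, not reproduce, GAM/RF/MaxEnt as fielded
  in R's dismo; weights and gates are exact, learner scores are not
  comparable to the originals' decimal by decimal.
* MSPA connector subclasses (loop/bridge/branch) are assigned per
  connector component, not per pixel; Guidos transition subclasses are
  not implemented.
* `P*` maximization considers paths through patch nodes only (no
  corridor-mediated stepping through non-habitat).
* The generator's uniform background sampling means synthetic AUC/TSS
  carry no survey-bias effects; real-data scores will differ.
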