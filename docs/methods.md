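# Methods

This note documents the models, parameter choices and numerical decisions
behind `psboundary`, and what the synthetic generator does and does not
emulate.

## The synthetic germband

### Geometry

The tissue is a conforming honeycomb mesh: pointy-top hexagonal cells of
edge length `cell_radius` (R, default 10 px) in `n_parasegments ×
parasegment_width_cells` anteroposterior (AP) columns by `n_rows`
dorsoventral (DV) rows (defaults 5 × 4 × 10 = 200 cells, matching the ~4
cells per parasegment of the early germband).  Image convention: x is AP
(anterior → posterior), y is DV.  The left/right (vertical) edges of each
hexagon are the AP interfaces between AP-neighbour cells; parasegment
identity is assigned by AP column blocks, and the anterior-most column of
each parasegment (`en_stripe_width`, default 1) is *engrailed*-positive.
Ground-truth interface classes follow directly: the interface column at each
internal block boundary is the PSB, and the columns one cell anterior /
posterior are the −1 / +1 controls.  Parasegment parity alternates
even/odd, with even parasegments carrying the brighter reporter dots.

### Interface disorder is angular

In a honeycomb, every mesh vertex belongs to exactly one vertical edge, so a
vertical edge can be rotated about its midpoint without moving any other
vertical edge.  We exploit this: per frame, each AP interface is rotated by
a wrapped-normal angle φ (wrapped into (−90°, 90°], since interfaces are
undirected) with standard deviation

    σ(t) = σ0 + σ1 · max(t, 0)   degrees,

with σ0 = 35°/min⁰ and σ1 = 0.7°/min by default.  Rotated edges shorten as
L = R / (1 + |φ|/90°), mimicking the approach to a T1 configuration and
keeping the mesh valid (polygons simple, interiors disjoint) even at large
disorder.  A small positional vertex jitter proportional to the local σ
adds irregularity.  Ground-truth PSB edges use the reduced deviation

    σ_psb(t) = (1 − β)·σ(t) + β·σ0·max(0, 1 − t/t_relax),

where β ∈ [0, 1] is the boundary tension (β = 1, σ0 = 0 gives exactly
DV-aligned boundaries) and t_relax = 15 min lets the PSB column straighten
continuously after extension onset rather than jumping at t = 0.  Before
t = 0, with `initial_alignment` on, *all* columns use σ0 — the emulation of
the invaginating mesoderm transiently aligning every interface, which puts
every column's co-alignment near 0.6 at GBE onset.  σ_psb is non-increasing
in β at every t, and control columns are unaffected by β (with a fixed seed
they are bit-identical across β values, which the tests exploit).

Why angular rather than positional disorder: reaching the observed
co-alignment range (≈0.6 at onset, decaying to ≈0.35 for controls) with iid
vertex jitter requires displacements ~0.7× the edge length, which folds a
conforming mesh and violates the disjoint-interiors invariant.  Rotating
the interfaces themselves gives the interface-angle distribution directly
— co-alignment is P(|φ| ≤ 30°) in closed form — and makes edge angles
independent across interfaces, which the Kolmogorov–Smirnov calibrations
assume.  Defaults were chosen from that closed form: σ0 = 35° gives
P(|N(0, σ0)| ≤ 30°) ≈ 0.61 at onset; σ1 = 0.7°/min brings controls to
σ ≈ 56° and co-alignment ≈ 0.4 by t = 30 min.

### What the generator does not emulate

Topological T1 swaps (intercalation appears only as the growing disorder
schedule), cell division and apoptosis, mechanical force balance, 3D
curvature of the embryo surface, and the spatial patterns of strain.  Tests
passing on this tissue therefore validate the *analysis logic* — angle
statistics, classification against known truth, calibration of the tests —
not segmentation or tracking robustness on real microscopy data.

### Dots, traces, screen tables

Transcription dots are emitted at en-positive cell centroids with per-frame
probability `p_on` (0.9), Gaussian positional jitter (2 px, well under the
~8.7 px cell inradius), intensity `base × parity_ratio` (100 × 2 for even
parasegments) plus additive noise (sd 5), optionally rendered as Gaussian
spots (PSF sd 1.5 px).  The dot-intensity model is an assumption (the
emission process is not specified by the analyses it feeds); only the
bright/dim alternation and rough magnitudes matter downstream.

Line-trace pairs plant `ceil(0.2·n)` pixels at the background level and the
rest at the signal level (× f for the PSB trace) with Gaussian noise and
shuffled pixel order.  With the default zero background level the
enrichment analysis recovers log₁₀(f) exactly in expectation; a nonzero
background level B shifts the planted ratio to (fS − B)/(S − B), which is a
property of the construction, not of the estimator.

Screen fixtures plant exact Venn-region sizes for the three criteria,
inject aliases into the symbol lists, and sample temporal fractions away
from the 5% threshold (low-early genes in [0, 4.5%], others in [6%, 60%])
so float noise cannot flip the strict-inequality rule.

## Analysis decisions

* **AP interface** is operationalised as a shared edge whose adjoining
  cells' centroid displacement satisfies |Δx| > |Δy|.  At high disorder an
  occasional diagonal interface crosses this line; such edges contaminate
  the condition samples slightly and are simply accepted (both samples are
  affected alike under the null).
* **Interface angle** is the chord between the endpoints of the shared-edge
  chain, in [0°, 180°) against AP.
* **Parasegment extent**: each expressing stripe seeds a parasegment that
  runs posteriorly to the next stripe; AP rank is BFS depth along posterior
  AP-neighbour steps.  Cells anterior to the first stripe are out of range;
  cells posterior to the last stripe default to the last parasegment
  (`trailing="exclude"` available), so the last PSB keeps its +1 control.
* **Offset interfaces**: the stripe is rank 0 regardless of width, so the
  +1 column sits between the posterior end of the stripe and the first
  non-expressing cell; the −1 column is anterior of the PSB's
  non-expressing partner.  In two-cell-wide parasegments the +1 column of
  one boundary coincides with the −1 column of the next; the collision is
  resolved to "other" with a warning, in both the generator truth and the
  classifier.
* **Dot→cell assignment**: point-in-polygon; dots on a shared edge or
  within the capture radius (5 px) of the mesh go to the nearest-centroid
  cell, ties to the smaller cell id.  Tracking is greedy closest-first
  linking (dots are sparse and near-stationary relative to cell size);
  a brute-force minimum-displacement oracle bounds its error on small
  instances in the tests.
* **Co-alignment threshold** is inclusive at 60° ("between 60 and 90°" read
  as a closed interval); times are binned to the nearest minute, the test
  timepoint uses a ±1 min window, and interfaces are pooled across the
  tissue before KS (per-embryo testing would be a caller-side split).
* **LOESS** is implemented in `psboundary.loess`: tricube weights on the
  `floor(span·n)` nearest points, locally quadratic, pointwise SE from the
  equivalent-kernel rows with the one-delta residual-variance correction;
  it matches R's `loess(..., surface="direct")` to ~1e−8 on the fit and
  ~0.5% on the SE in the test oracle.  The 95% band is fit ± 1.96·SE.
* **KS test**: `scipy.stats.ks_2samp`, asymptotic two-sided p by default
  (exact available for small samples).  Significance annotation: ns /
  * <0.05 / ** <0.01 / *** <0.001.
* **Enrichment ratio**: each trace's background is the mean of its dimmest
  `ceil(0.2·n)` pixels (the "20% of total pixels" rule read per trace, and
  as the dimmest-20%-mean rather than an intensity-percentile cut); signal
  is the mean of the retained pixels (mean, not sum, so the ratio is
  length-invariant).  The ratio uses each trace's own background:
  (PSB − bg_PSB)/(control − bg_ctl), the only reading symmetric about 0 on
  the log scale.  Non-positive background-subtracted signal raises an
  undefined-ratio error and the pair is excluded and logged, as are
  division-flagged pairs.
* **Screen**: symbols missing from the alias table are identity-mapped and
  *reported* as unresolved rather than dropped (a `strict` switch excludes
  them); one symbol mapping to two canonical ids is an error.  The temporal
  rule excludes strictly below 5%, equality keeps; zero total expression
  excludes with its own reason code.  The three QC rules are recorded
  per gene in an exclusion ledger.

## Problem sizes and determinism

The test suite and acceptance script run everything at the generator's
default scale: 200-cell tissues over 61 one-minute frames for curve
analyses, single-frame tissues for null calibrations (200 seeds), 50 trace
pairs per enrichment estimate (120 seeds for the null), 1000 replicates of
n = 100 samples for KS calibration, and 100 random screen fixtures.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; re-running any stage with the same config
produces byte-identical CSV/JSON outputs, which is itself a tested
property.

## Known limitations

The generator's fixed topology cannot produce tracking-specific failure
modes (merges, splits, missed detections beyond `p_on`); the co-alignment
decay is calibrated through the angular-disorder schedule rather than
derived from tissue mechanics; stripe-parity classification assumes at most
two brightness classes; and the screen operates on pre-exported tables —
live database mining and the upstream image processing of real embryos are
out of scope.
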