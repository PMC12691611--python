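# Methods

`myxoquant` implements the measurement layer of a single-cell
surface-motility study: it quantifies how rod-shaped *Myxococcus xanthus*
cells explore a surface, how two fluorescence channels co-distribute, and
how tightly a pilin domain binds polysaccharide ligands. Every analysis
operation is paired with a synthetic-data generator that carries ground
truth, so the package can be validated end to end by parameter recovery.

## Motility simulation

Cells are point-like agents with a capsule-shaped footprint (length L,
width W) moving in a rectangular arena with reflective boundaries.
Per frame (default interval 10 s over a 1,000 s observation window):

1. **Heading** evolves as a persistent random walk: a Gaussian turn with
   SD `(1 − persistence)·π` radians is added each step, so
   `persistence = 1` yields straight-line motion and `persistence = 0` an
   uncorrelated walk. Independent 180° reversals occur with probability
   `1 − exp(−reversal_rate·Δt)` per frame, the standard description of
   *M. xanthus* reversal behaviour. Default `reversal_rate = 0.005 s⁻¹`
   (≈ one reversal per 200 s, a realistic order for moving cells).
2. **Speed** is drawn per step from a normal distribution truncated at
   zero. The underlying location/scale are solved numerically so that the
   *truncated* distribution has exactly the configured mean and SD
   (defaults 10.36 and 5.03 µm/min, the wild-type population figures).
   Without this correction, truncation at zero would bias the realized
   mean upward by several percent at mutant-like speed parameters.
3. **Trail following** (optional): every cell deposits unit mass per
   frame into a shared occupancy raster (resolution = cell width,
   exponential decay with a 500 s e-folding time, emulating slowly fading
   extracellular polysaccharide trails). When
   `trail_following_strength > 0`, each cell samples the trail field one
   step-length ahead along candidate headings within ±80° and rotates its
   heading toward the strongest trail by the configured mixing weight.
   This reproduces the qualitative constraint that secreted trails impose
   on neighbours: at matched speed parameters, trail-following
   populations explore measurably less unique area.

The simulator reproduces kinematic statistics only; it contains no
mechanistic pilus extension/retraction force model, no cell–cell
mechanics, and no growth or division. The printed per-frame ground-truth
speed is the realized displacement speed (reflection at a boundary can
shorten a step; with default arenas this affects < 0.1% of steps).

Rendering draws each capsule with an anti-aliased ~1 px edge, convolves
with a Gaussian point-spread function (default σ 0.3 µm) and adds
Gaussian background noise. Intensity-weighted centroids of rendered
static cells match ground truth to well under half a pixel, which bounds
the velocity bias of the full tracking chain.

## Detection and tracking

Detection: global threshold (Otsu by default, fixed value optionally),
8-connected component labelling, area filter, then per-component second
moments give the centroid (intensity-weighted), axial orientation
(mod π — rod ends are indistinguishable) and axis lengths. Axis lengths
use the uniform-rod conversion `√12·σ` from the principal moment σ rather
than the equivalent-ellipse convention `4σ`: for capsule-shaped bacteria
the ellipse convention systematically overestimates width by ~15%.

Linking: for each frame transition, a Hungarian (global optimal)
one-to-one assignment with cost
`distance + morphology_weight·|Δarea|/mean(area)`; candidate links beyond
`max_link_distance` (default 5 µm, several times a typical 10 s step) are
forbidden. Unmatched detections seed new tracks; a track may coast
through up to `max_gap_frames` missed frames (default 1), and a link that
bridges a gap is flagged so that velocity steps spanning it can be
excluded. Ties are resolved deterministically; identical inputs always
produce identical tracks. There is no division handling and no curved-rod
shape model.

## Motility metrics

* **Instantaneous velocity**: per-step Euclidean displacement divided by
  the frame interval, in µm/min; steps across gaps are excluded. Speeds
  are pooled at step level across all tracks (the granularity shown by
  violin plots of instantaneous velocity); per-track means are also
  available.
* **Percent reduction**: `100·(reference − test)/reference`, reported to
  two decimals.
* **Student's t**: pooled-variance two-sample t with two-sided p.
  Zero-variance degenerate cases follow the documented convention
  (equal means → t = 0, p = 1; unequal → ±∞, p = 0).
* **Cumulative coverage**: each detection stamps a disc at its centroid
  with radius equal to the minor *semi*-axis (half the short-axis width);
  a grid pixel is covered when its centre lies inside the disc. The
  "short axis as radius" footprint rule is ambiguous between semi-axis
  and full axis; the semi-axis avoids double-width footprints and the
  full-width variant is available behind a flag. Coverage is the union
  over all cells and frames; cumulative per-frame fractions are
  monotone by construction and the final raster is exactly equal to a
  brute-force per-pixel membership test (tested on 256×256 grids).
* **Density heatmap**: 2-D histogram of cell centres smoothed by a
  normalized Gaussian with reflect padding, which conserves total mass
  (array sum = number of points, to 1e-9), making the invariant testable.

## Colocalization

PCC, Manders M1/M2 and ICQ over an optional analysis mask. Manders
thresholds default to per-channel Otsu with explicit overrides. ICQ
excludes pixels whose mean-deviation product is exactly zero from both
numerator and denominator, which makes the ±0.5 limiting cases exact.
Degenerate inputs (constant channel, zero-sum channel, all-zero
products) raise errors rather than returning 0 — a silent 0 would be
indistinguishable from "no colocalization". No Costes thresholding,
registration or deconvolution is provided.

## Binding models

**SPR steady state.** `Req = Rmax·C/(K_D + C)` fitted by
Levenberg–Marquardt in log-parameter space (positivity enforced), with
`Rmax₀ = 1.1·max(Req)` and `K_D₀ = median(C)`. A fitted `K_D` outside
`[min(C)/100, 100·max(C)]` is flagged unreliable. Kinetic (k_on/k_off)
sensorgram fitting is out of scope; only equilibrium plateaus are
modelled.

**ITC one set of sites.** Cumulative heat

    Q = (n·M_t·ΔH·V0/2)·[1 + X_t/(n·M_t) + K_D/(n·M_t)
        − √((1 + X_t/(n·M_t) + K_D/(n·M_t))² − 4·X_t/(n·M_t))]

with the standard overfilled-cell displacement bookkeeping
(`M_t = M0(1−ΔV/2V0)/(1+ΔV/2V0)`, `X_t = X0(ΔV/V0)/(1+ΔV/2V0)`,
`ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V0)(Qᵢ + Qᵢ₋₁)/2`), normalized per mole of
injectant. The exact displacement convention is not universal across
instruments; this form is fixed here and unit-tested against an
independent oracle that solves the binding equilibrium by root bracketing
instead of the closed-form quadratic. The fit frees (n, K_D, ΔH, offset),
uses multi-start over weak-to-tight `K_D₀` values, flags Wiseman
`c = n·M_t/K_D < 0.1` results as low-confidence, and raises on
constant-heat (ΔH ≈ 0) data, which is unidentifiable. First-injection
exclusion is available but off by default. Default simulated geometry:
300 µL cell, 19 × 2 µL injections; the simulated ΔH defaults to
−5 kcal/mol (a typical moderate exothermic binding enthalpy) and is
always explicit in the config.

## What the generators do and do not emulate

Synthetic movies have uniform illumination, additive Gaussian noise, no
drift, no focus changes, and no cell contact mechanics; segmentation
failure modes on real phase-contrast data (halos, touching cells,
debris) are therefore not exercised, and passing recovery tests bounds
algorithmic error only, not real-image robustness. Synthetic
colocalization images are punctate discs, not biofilm textures; no claim
is made of matching any real-image bar values. Synthetic binding data
assume homoscedastic Gaussian noise and an exact 1:1 model — recovery
tests demonstrate estimator correctness and precision at realistic noise,
not model adequacy for real sensorgrams/thermograms.

## Problem sizes and numerics

Recovery protocols use 10 replicates per condition; the full tracking
chain is validated at 100 cells × 100 frames on a 250 µm arena at
0.25 µm/px (≈ 10⁴ velocity steps), which the package processes in well
under a minute per population. Fits use scipy `least_squares` with
`lm`/`trf` methods; log-parameterization makes positivity constraints
implicit. Assignment ties in linking are broken by detection order,
making every pipeline stage bit-deterministic for a fixed seed.
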