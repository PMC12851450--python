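# Methods

## The growth model

The simulator is a stochastic cellular automaton on a 3D cubic lattice.
Each voxel holds at most *K* cells (default 3 — a deliberate compromise:
larger capacities are more realistic but multiply the per-step work).
State advances in discrete steps. The cells alive at the start of a step
are processed once each, in a uniformly random permutation; each cell

1. proliferates with probability *p_p* if its voxel is below capacity
   (counting offspring already placed this step). The offspring is placed
   in the same voxel and is ineligible to act until the next step;
2. then attempts a move with probability *p_m* to a von Neumann neighbor
   drawn from the mixed direction distribution below. Moves into full
   voxels or off the brain mask are aborted and the cell stays put.

Processing cells as a permutation (rather than n independent draws with
replacement) guarantees every cell acts exactly once per step; the two
readings differ only at O(1/n) and the permutation makes the bookkeeping
(newborn exclusion, per-step totals) exact.

### Anatomy-biased migration

For a structure mask (white matter or vasculature), the attraction at a
voxel x is built from every structure voxel y with 0 < ‖y − x‖ ≤ d
(Euclidean, inclusive; d = 5 voxels by default): the unit vector from x to
y is folded onto the six lattice axes — positive component to the positive
slot, the magnitude of a negative component to the negative slot — the
folded vectors are summed and L1-normalized into a probability vector
P_wm (or P_bv). Taking magnitudes in the negative slots is the only
reading of the axis-folding construction that always yields a probability
vector; it reproduces the intended behavior for axis-aligned directions
(a cell due −x of a structure voxel is pulled in −x). Two conventions
close the degenerate cases: the cell's own voxel is excluded (zero
distance has no direction), and a cell sensing no structure at all gets
the uniform 1/6 distribution, so the attraction term degrades gracefully
to isotropic motion instead of 0/0.

The final move distribution mixes isotropic and structure terms:
(1/6)(1 − w_wm − w_bv)·1 + w_wm·P_wm + w_bv·P_bv with w_wm, w_bv ≥ 0 and
w_wm + w_bv ≤ 1. A "white-matter-only" model variant fixes w_bv = 0 and is
otherwise identical.

The attraction fields depend only on position, not on the cell, so both
are precomputed once per atlas as six cross-correlations of the mask with
fixed kernels (evaluated by FFT; exact up to FFT round-off, with true
nonzero sums ≥ 1 the fallback threshold of 1e-6 cleanly separates "no
structure sensed" from round-off). The per-cell loop is a numba kernel
that looks the fields up; a pure-geometry reference implementation
(`structure_attraction`) is kept alongside and the test suite asserts
field/reference agreement. Simulations are bit-reproducible for a fixed
seed; the kernel holds its own RNG stream, seeded once per run.

Tumors are seeded as a sphere (inclusive Euclidean radius) of voxels at
`cells_per_voxel`; radius 8 at 3 cells/voxel gives the canonical 6327-cell
inoculum. Seeding spheres must lie wholly inside the brain mask.

## Anatomy

Real scaffolds are three co-registered binary masks — brain, white matter
(fractional anisotropy thresholded at 0.5, inclusive ≥; the strictness of
the threshold is a convention, FA values exactly at 0.5 are a measure-zero
set in practice), vasculature — read from NIfTI (spacing in the header
zooms, micron units) or an .npz dialect. The synthetic generator builds
stand-ins from geometric primitives: axis-aligned slabs and spherical-shell
arcs (corpus-callosum-like tracts), and capsules or recursive branching
capsule trees (vessel networks down to ~1-voxel-radius tubes). Primitives
extending beyond the grid are clipped with a logged warning. Masks are
stored index-ordered with 0-based indices; the default grid is
configurable (desk-scale work uses 32³–64³ at 43 µm).

The generator emulates the features the migration bias responds to —
bounded brain, planar/arched tracts, sparse branching tubes — and nothing
else. It does not reproduce cortical layering, gray/white contrast,
realistic vessel density (~0.5% of brain volume here vs several percent of
capillary-rich tissue), or inter-animal variability; conclusions from
synthetic-atlas tests are about the method's behavior, not about mouse
anatomy.

## Morphometrics

A virtual histology slice is one lattice plane thresholded at ≥ 1 cell.
Connected components use 8-connectivity (the conventional default of
region-labeling tools). Per region the package reports area, filled area
(holes closed), perimeter (the classical weighted boundary-contour
estimator of region-property tools, fixed so values are bit-stable), and
eccentricity of the same-second-moments ellipse. The 8-vector summary is
(n_components, mean area, std area, mean ecc, std ecc, std perimeter, max
perimeter, max filled area); standard deviations are population (n), so a
single-region image scores 0, and an empty image maps to the zero vector
so extinct simulations remain rankable. The vector is deliberately
location-free: statistics are invariant to translation and axis flips,
which is the point of using it instead of overlap measures like Jaccard
(complementary checkerboards — visually identical — have Jaccard 0).

The distance between summary vectors is the Euclidean norm after
componentwise standardization by the pool's median absolute deviation
(floored at 1e-9); the components span orders of magnitude (counts vs
areas), so an unscaled norm would be dominated by the largest. The scale
is computed once per simulation pool and stored with results. A
consequence: acceptance thresholds (δ) are comparable within a pool but
not across differently-scaled studies.

## ABC fitting

Priors: p_m ∼ U(0,1), p_p ∼ U(0,0.015), w_wm, w_bv ∼ U(0,1) subject to
w_wm + w_bv ≤ 1, sampled by rejection (redraw violating pairs), which makes
the weight marginals triangular with mean 1/3. One simulation per
parameter set (the model's run-to-run variance is small relative to the
prior spread, and the procedure absorbs it). The best `accept_frac` of
simulations by distance are retained (stable sort; ties broken by
simulation index); δ is the largest accepted distance.

Regression adjustment: each parameter is logit-transformed to its prior
range, regressed on the summary discrepancies s_i − s_obs by weighted
least squares with Epanechnikov weights 1 − (d_i/δ)², and shifted by the
fitted slope; the back-transform keeps samples strictly inside the priors.
Discrepancy columns that are constant across the accepted set (common:
all-singleton slices zero out the std components) are collinear with the
intercept and are dropped before the fit — without this the fallback for
singular designs would fire on most runs. A genuinely singular design
falls back to the unadjusted samples with a logged warning. Adjusted
weight pairs leaving the simplex are projected radially back onto it
(scaled by 1/(w_wm + w_bv)); the adjustment treats parameters one at a
time, so nothing else enforces the joint constraint. Parameters pinned at
a prior boundary (w_bv = 0 in the white-matter-only variant) are left
unadjusted.

Point estimates: samples are rescaled to [0,1] by their prior range so the
Epanechnikov KDE bandwidth of 1/10 means the same thing for every
parameter; the density is truncated to [0,1], renormalized on a 2001-point
grid, and the estimate is its mean, reported with 10%/90% density
quantiles (sample percentiles are stored as well; the two conventions are
close unless the sample piles near a boundary). Rescaling to physical
units uses Δt = duration_days·24/steps hours: P_m = p_m·spacing/Δt (µm/h),
P_p = p_p·24/Δt (1/day).

Model comparison pools equal-size simulation sets from the full and
white-matter-only models under one distance scale; the support for each
model is its share of the accepted set.

## The benchmark study

16 ground truths — every combination of p_m ∈ {0.2, 1}, p_p ∈ {0.0005,
0.005}, w_wm ∈ {0.1, 0.45}, w_bv ∈ {0.1, 0.45} — each produce one observed
slice; three methods (Jaccard-direct, geometric-direct,
geometric+regression) are scored by the error E: the absolute relative
error averaged over the four parameters (per accepted sample) and then
over the accepted set. Direct methods score the raw accepted samples;
the regression method scores the adjusted ones.

The study here is a scaled-down replica: a 64³ synthetic phantom, T = 200
steps, seeding radius 6, one shared pool of 1000 prior simulations serving
all 16 cases and all three methods (as one pool serves every fit in a full
study), accepting the top 5% = 50 sets — the same accepted count a
full-size study uses, which matters because the adjustment regresses ~50
points on 8 discrepancy columns. These sizes keep the full study to a few
minutes on one CPU. At this scale the absolute errors are atlas- and
size-dependent and are not comparable to full-size runs; the stable,
meaningful output is the ordering of the three methods, and the package's
tests assert exactly that (regression beats both direct methods on the
mean and on at least 12 of 16 cases).

## Treatment experiments

A drug mix with anti-migration fraction q blocks, for each cell at each
treated step independently, either its migration (probability q) or —
otherwise — its proliferation. The per-step redraw follows the
each-time-step reading of the mechanism assignment; a permanent per-cell
assignment would be a different (bimodal) model and is not the default.
The schedule grows a tumor untreated for 30 days, treats for 60, and
compares against an untreated 90-day control with its own seed stream;
days map to steps at 20 steps/day (1800 steps ↔ 90 days). The treated run
executes as a single seeded stream with the drug switching on at the
treatment step, so a no-drug "sham" run is bit-identical to a control with
the same seed — the baseline ratios are exactly 1 by construction, a
useful end-to-end determinism check. Readouts per mix: total cell count
and convex-hull volume of occupied voxel centers (degenerate hulls report
volume 0), each relative to the control.

## Numerical and degenerate-input conventions

- Distances and radii are inclusive (≤) everywhere: sensing, seeding,
  FA threshold.
- Direction distributions must sum to 1 within 1e-12; the mixed
  distribution inherits this from its convex-combination form.
- The coordinate buffer of the simulation kernel grows geometrically on
  overflow and the run is retried from its seed, so results are
  independent of the initial buffer guess.
- Jaccard of two empty masks is 1 (identical sets); empty images score the
  zero summary vector; an empty tumor has no convex hull (error).
- Relative parameter error is undefined for a zero true parameter
  (rejected); the benchmark grid uses strictly positive truths.

## Known limitations

- No cell death, nutrient/hypoxia dynamics, angiogenesis, adhesion, or
  subclonal heterogeneity; treatment effects are purely mechanistic blocks
  of migration/proliferation with no pharmacokinetics.
- The attraction construction carries no explicit distance weighting
  within the sensing ball; closer structures dominate only through solid
  angle.
- Synthetic-atlas results validate the estimation machinery, not anatomy:
  real scaffolds (DTI-derived white matter, cleared-tissue vasculature)
  bring registration error and slice-selection ambiguity the benchmark
  does not model.
- The geometric distance ignores tumor location entirely; fits agree in
  morphology, not position.
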