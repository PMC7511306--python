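# Methods

This note documents the models and procedures implemented in `tractquant`,
the parameter defaults and why they hold, the numerical choices made where
the conventional description of the method is silent, and what the
synthetic phantoms do and do not establish.

## Deterministic streamline tracking

### Substrate

The tracker operates on an `OrientationField`: a regular 3D grid in which
every voxel stores up to K axial unit vectors (the peaks of a fiber
orientation distribution) and one quantitative-anisotropy (QA) scalar per
peak.  Voxel indices are 0-based; a voxel's center maps through the 4x4
voxel-to-world affine; world coordinates are millimetres (RAS).  An
all-zero vector marks an empty peak slot.  How the peaks were obtained
(e.g. from a diffusion reconstruction) is outside scope: the field is an
input.

### Propagation

From position **p** with incoming unit direction **d**:

1. *Lookup* — the peaks of the voxel nearest to **p** (`rint` of the
   fractional voxel coordinate; no interpolation of directions).  numpy's
   round-half-to-even convention decides exact half-voxel positions; it is
   deterministic and affects only measure-zero seed placements.
2. *Gate* — peaks with QA below `qa_threshold` are never selectable.  This
   single rule subsumes "stop when QA drops below threshold": a voxel whose
   best peak is sub-threshold terminates the track.
3. *Congruence* — each surviving peak is evaluated in both sign polarities
   (fiber orientations are axes, not vectors); the polarity-resolved
   direction with the smallest angle to **d** wins, and is accepted only if
   that angle is strictly below `angle_threshold_deg`.  Exact angle ties go
   to the higher QA, then the lower peak index, so output is deterministic.
4. *Smoothing* — the moving direction is
   `normalize(w * d + (1 - w) * selected)` with `w = smoothing_weight`.
   The angle test is applied to the *raw* selected peak and smoothing
   afterwards; whether the original tool orders these two operations the
   same way is not documented anywhere we know of, so this package fixes
   the order explicitly.  A consequence worth noting: because the smoothed
   direction bisects the turn, consecutive *segments* of an emitted
   streamline always subtend less than half the nominal angle threshold.
5. *Advance* — `step_size_mm` along the smoothed direction.  There is no
   terminal partial step: the last accepted position is the final point,
   and arc length is the polyline length, `(n_points - 1) * step`.

Termination reasons are recorded per end: `qa_below_threshold`,
`no_congruent_orientation`, `left_field`, or `max_length`.  Because the
voxel examined at each iteration is the one containing the *current*
point, a track's terminal point sits inside the first voxel that failed
the gate — typically just past the anatomical (or phantom) bundle
boundary.  End-cap ROI regions must therefore extend slightly beyond a
bundle's end (see Phantoms below).

### Seeding and assembly

`whole_brain_track` draws `n_seeds` seeds by first picking a mask voxel
uniformly at random, then a uniform sub-voxel offset, so the expected
number of seeds in any voxel subset is proportional to its size.  Each
seed is tracked bidirectionally, starting along the +/- of the seed
voxel's highest-QA selectable peak; the two half-tracks are concatenated
with the seed appearing once.  Tracks shorter than `min_length_mm` are
discarded; a track that would exceed `max_length_mm` is truncated (the
forward half is trimmed) and flagged `max_length`.  Propagation is
vectorised over seeds in fixed-size chunks, which changes memory use only;
the output is bit-identical to seed-by-seed tracking and to reruns with
the same `(field, mask, n_seeds, rng_seed)`.

### Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `step_size_mm` | 0.8 | mm | propagation step; below typical voxel size so point rasterization leaves no gaps |
| `min_length_mm` | 20 | mm | discard spurious short tracks |
| `max_length_mm` | 800 | mm | runaway cap |
| `angle_threshold_deg` | 75 | deg | maximum turning angle per step |
| `qa_threshold` | 0.06 | — | QA stopping/selection gate |
| `smoothing_weight` | 0.5 | — | weight of the incoming direction in the moving-direction estimate |
| `max_seeds` | 10,000,000 | — | seed-budget cap for whole-brain runs |

These are the standard deterministic-tracking settings for high-resolution
(1.25 mm) diffusion data and are the package defaults; every one is
overridable per run (YAML via the CLI).

## ROI connectivity and the connection index

`two_roi_select` keeps streamlines with one endpoint in ROI group A and
the other in group B, order-agnostic; the groups must be disjoint.
Endpoint-region assignment is the label of the voxel containing the
terminal point — no dilation and no radius search, the simplest rule
consistent with "ending within a region".  Streamlines with a background
endpoint are excluded but counted, so accounting is auditable.

The count matrix tallies streamlines per region pair; the volume matrix
counts the distinct voxels visited by the union of each pair's streamlines
(point-membership rasterization of the polyline samples; with 0.8 mm steps
on >= 1 mm voxels, sample points cannot skip a voxel on the track's own
path).  The connection index divides each subject's matrix by that
subject's total (upper-triangle sum of the same basis), averages across
subjects, zeroes the diagonal (within-region loops are tallied but not
indexed), and rescales so the maximum inter-region entry is exactly 100.
Global-max scaling is one of several readings of "scaled between 0 and
100 with 100 the strongest relative connectivity"; it is the only one
under which the strongest connection is exactly 100, and it is the
implemented choice (per-row or fixed-denominator scaling would be a
one-line variant).  CI is invariant under uniform rescaling of any
subject's counts, which the suite verifies.

## Density and group maps

A density map counts *distinct* streamlines per voxel (a streamline
increments a voxel at most once), so values read as streamline count per
voxel.  Group integration thresholds each subject's map at >= 1 and sums:
the voxel value is the number of subjects whose tract passes through.  All
maps must share one grid and affine; template registration is explicitly
out of scope, so "common space" is a precondition here, not an operation.
A streamline is rasterized as its centerline: a nominal sub-voxel tract
diameter (fractions of a millimetre on a >= 1 mm grid) adds no voxels
beyond those containing the polyline points, so centerline semantics are
the well-defined grid-level reading of a sub-voxel diameter.

## Laterality

LI = (L - R)/(L + R) over any non-negative paired scalar; +1 is complete
left-lateralization.  L + R = 0 yields an explicit *undefined* — never a
silent 0, which would fabricate symmetry from absent data.  The cohort
summary is the arithmetic mean of defined per-subject LIs (not the LI of
pooled totals): subjects are the unit of analysis, and pooling would let
high-yield subjects dominate.

## Connectogram tables

The connectogram artifact here is the weight table, not the drawing:
tab-delimited text in CIRCOS tableviewer layout, regions ordered
left-hemisphere group, right group, then unlateralized, each in
region-table order.  Cells are CI values at a configurable precision
(default 2 decimals), with an optional floor to declutter ribbons
(default off).  Output is byte-stable and parses back to the CI matrix
within rounding, which the suite checks.

## Synthetic phantoms

### What they emulate

* **Straight bundles** — a cylinder of radius `radius_mm` around a
  straight centerline; inside voxels carry one peak parallel to the axis
  with `qa_inside`, everything else `qa_outside`.  QA is piecewise
  constant by design: a sharp QA edge makes the stopping rule exactly
  testable (smooth falloff would only blur the oracle).  Membership is by
  voxel-center distance to the centerline segment and is verified against
  an exhaustive per-voxel scan.
* **End caps** — label regions at the bundle termini, extending
  `radius + 2` voxels beyond the end and `1.5` voxels laterally past the
  radius.  This envelope provably contains every tracked endpoint, which
  comes to rest at most one step plus one voxel past the cylinder
  (including its rounded end).
* **Crossings** — two bundles whose overlap voxels carry both peaks
  (K = 2), each with its own QA.  The stated crossing angle is validated
  against the centerlines (within 1 degree) rather than trusted.
* **Yield-ratio pairs and cohorts** — bundles whose expected streamline
  yields are *designed*.  These run along the grid z-axis and are built
  from whole columns (one (x, y) cross-section cell over the full axial
  extent, flat ends): under uniform in-mask seeding every column yields
  the same expected number of retained streamlines, so expected yield is
  exactly proportional to column count, and full columns leave no
  sub-threshold gaps a track could stop in.  Column counts are targeted
  exactly using a deterministic, mirror-symmetric tie-break on the heavily
  tied lattice distances; at the default radius (3 mm, ~29 columns) the
  LI discretization from integer column counts is below 0.02 and the
  designed 3:1 ratio is exact.
* **Cohorts** — per subject, the designed LI is `target_li` plus Gaussian
  noise (`yield_noise_sd`, on the LI scale, clipped at +/- 0.95 as a
  guard), and the left/right column counts are set to
  `c0 * (1 +/- li)`.  Mirroring is x-index reflection about the grid's
  mid-sagittal plane; hemisphere tags follow the side of that plane.  With
  target 0 and no noise, left and right are voxel-for-voxel mirror
  images — a property the suite asserts exactly.  Per-subject RNG streams
  are spawned from `base_seed` via `numpy` seed sequences.
* **Orientation jitter** — an optional von-Mises-Fisher-style angular
  perturbation of in-bundle peaks (`jitter_sd_deg`) exists as an extension
  knob; it is *not* calibrated to any empirical dispersion and defaults to
  off, so the reference phantoms are exactly noiseless.

### What they do not emulate

Phantoms have no curvature, no branching, no partial-volume QA gradients,
no orientation dispersion by default, no realistic cortical geometry, and
cohort "subjects" differ only in designed bundle area — not in shape,
position, or registration error.  Passing the suite therefore shows the
*pipeline arithmetic* is right (selection, stopping, counting, scaling,
averaging, file formats) under controlled conditions; it does not certify
tracking accuracy on real diffusion data, where crossing/branching/merging
artifacts dominate error.

## Validation design and problem sizes

The validation suite runs, per invocation: a 1000-seed straight-bundle run
(20x20x60 grid, 1 mm voxels) checked against the analytic axis (lateral
deviation < 1e-6 mm, >= 95% end-cap connection — in practice 100%); a
600-seed 90-degree crossing run (40^3) with < 5% contamination (in
practice 0%); a 2000-seed 3:1 yield-ratio run recovering CI = 100 exactly
and CI ~= 33.3 within the binomial error of that seed count; and 20
generator seeds x 20-subject cohorts (1500 seeds per subject) recovering a
designed mean count-LI of -0.15 within +/- 0.03 in >= 95% of generator
seeds.  These sizes put one full suite run at well under a minute of
tracking on one CPU while keeping the statistical bounds meaningful: at
1500 seeds per subject the per-subject binomial LI noise (~0.029) is
already below the designed inter-subject noise (0.05), so the cohort test
is dominated by the quantity it is meant to recover.

`scripts/acceptance.py` recomputes the same quantities from scratch with
seeds derived from a single `--seed` and writes them as JSON.

## Known limitations

* Nearest-voxel orientation lookup (no trilinear direction interpolation)
  is a deliberate contract, not an approximation to one.
* Max-length truncation trims the forward half; a track hitting the cap
  from both ends is not re-centred on the seed.
* TRK/TCK store float32 coordinates: round trips are exact to ~1e-5 mm at
  phantom scales, not bit-exact.
* The volume matrix rasterizes sample points only; at steps larger than
  the voxel size (non-default) a track could skip voxels it crosses.
* Group maps require a shared grid; no registration, smoothing or
  rendering is provided.
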