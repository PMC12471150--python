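# Methods

## Scope and model

`vesselquant` implements a sequential pipeline for continuous vessel-calibre
assessment of the aorto-iliac access route, plus the uncertainty-guided
active-learning (AL) machinery that makes segmentation annotation
affordable. The pipeline assumes a *single-vessel binary mask* on an
axis-aligned grid: volumes are normalised to RAS orientation and (z, y, x)
indexing at load time, and in the intended workflow resampled to 1 mm
isotropic spacing (trilinear for images and probability maps,
nearest-neighbour for masks, which keeps them binary). The vessel is assumed
tubular and loop-free, with a dominant inferior–superior course; the aorta
and iliac arteries on pre-TAVI angiographic acquisitions satisfy this.

## Centerline extraction

1. **Thinning.** The mask is reduced to a 1-voxel-wide skeleton with
   topology-preserving 3D thinning (scikit-image). One failure mode is
   handled explicitly: a perfectly symmetric tube of even voxel width can be
   annihilated entirely, because symmetric border voxels are removed
   simultaneously. When a mask component retains no skeleton voxel, it is
   re-thinned after a one-voxel one-sided dilation (which breaks the
   symmetry) and the result is mapped back to the nearest in-component
   voxels. Real masks are never exactly symmetric, but the synthetic
   phantoms can be.
2. **Pruning.** Only the largest 26-connected component is kept; ties are
   broken deterministically toward the component containing the
   lexicographically smallest voxel.
3. **Graph and path.** Skeleton voxels become graph nodes; 26-neighbours
   are joined by edges weighted with the Euclidean distance in mm between
   voxel centres, so "longest" remains meaningful on anisotropic grids.
   The principal centerline is the endpoint pair (degree-1 nodes) whose
   shortest connecting path has maximal physical length; endpoint-pair ties
   are broken lexicographically. The path is ordered so the z coordinate of
   the first point does not exceed that of the last.
4. **Refinement.** Y and X coordinate sequences are corrected for jumps
   (a consecutive-point jump larger than 3 voxels is replaced by the
   neighbour mean — applied before the filter, so a window of 1 still
   removes outliers) and smoothed with a moving-average window of 5 points.
   The first and last ⌈5% · N⌉ points are snapped to the foreground centre
   of mass of their z-slice; both ends are corrected, since both path
   endpoints are equally prone to sit near the lumen wall. If a slice holds
   several foreground components, the component nearest the current point
   is used, and a centre of mass falling outside a non-convex component is
   snapped to the nearest foreground pixel. Steep segments can place
   several consecutive points in one slice; after correction such
   coincident duplicates are dropped.

## Diameter estimation

At each refined centerline point two estimators are averaged:
`D_raw = (D_DT + median(D_ray)) / 2`.

- **Distance transform.** `D_DT = 2·EDT(P)` with the EDT computed once per
  mask using the physical spacing, sampled trilinearly at sub-voxel points.
  A point whose nearest voxel is background yields a missing value rather
  than an error. *End-cap rejection:* when the direction from P to its
  nearest background voxel lies within 45° of the local tangent, the EDT is
  measuring the truncated vessel end, not the lumen wall; the value is
  recorded as missing and recovered by interpolation. Without this, the
  profile of any tube dips spuriously near its ends, because thinning
  leaves skeleton endpoints closer to the cap than one radius.
- **Ray casting.** Tangents are central differences of neighbouring points
  (one-sided at the ends, widening past coincident neighbours), expressed
  in physical coordinates. A tangent deviating more than 30° from the mean
  of its six neighbours is replaced by that mean — the analogue, for the
  derived tangent field, of the coordinate jump correction; an isolated
  kink (typically where an endpoint was snapped to a slice centre of mass
  on an oblique vessel) would otherwise tilt the measurement plane and
  inflate every chord. The in-plane basis is the YX slice when the tangent
  is within 10° of the z-axis, otherwise the branchless Frisvad basis
  completion (including its guard for near-antiparallel inputs). Eight ray
  directions span half-plane angles i·π/8; each is marched in ±d with a
  step of 0.25 × the smallest spacing, using nearest-voxel mask lookup,
  and the exit is refined by 24 bisection steps between the last inside
  and first outside samples. Rays that never exit within half the volume
  diagonal are dropped; the per-ray diameter is the spacing-weighted norm
  of the exit-point difference.

Missing raw values are linearly interpolated over the point index (edge
gaps take the nearest valid value), then a Savitzky–Golay filter of order 3
smooths the profile with window `min(51, largest odd ≤ N)`; smoothing is
skipped when the window would not exceed the order, and non-positive
smoothed values are clamped to the smallest positive raw value with a
warning. The final profile has a value at every centerline point.

Expected accuracy on digitised geometry: the voxelised wall lies within
half a voxel of the analytic surface, so individual chords carry ≈1-voxel
uncertainty and the combined, median-filtered, smoothed profile recovers
cylinders of radius 3–15 mm at tilts up to 60° to well within 1.5 voxel
spacings (measured ≤ 0.65 mm at 1 mm spacing), with error decreasing as
spacing shrinks.

## Uncertainty scoring and the AL loop

Per class, over voxels with p > 0.01: `S_c = H̄_c + (1 − F_c/100)`, H̄_c the
mean binary entropy in bits (log base 2 makes both terms range over [0, 1]
and the score over [0, 2]) and F_c the percentage of voxels with p > 0.9.
Both thresholds are strict and configurable. The case score averages the
left- and right-iliac class scores only; aortic segmentation is reliably
easy, and iliac quality is what limits access-route assessment.

The loop splits the cases (seeded shuffle) into holdout (26), initial
manual pool (15) and unlabelled pool. Each iteration trains the backend on
manual + pseudo labels, scores every unlabelled case, sends the 3
highest-scoring cases to the annotation oracle and accepts the model's own
predictions, binarized at 0.5, for the 12 lowest-scoring. Score ties are
broken by case id; the certain picks are drawn from the cases left after
removing the uncertain picks, so the selections are always disjoint.
Pseudo-labels are frozen at the iteration they are accepted and never
refreshed by later models. The loop stops when the holdout mean Dice
improves by less than `min_delta` (default 0.005) for `patience`
(default 1) consecutive iterations, measured against the best value so
far, or when the unlabelled pool can no longer supply a full selection.
Pool disjointness and case conservation are asserted after every iteration.

The segmentation network itself is out of scope: any object with
`train(manual, pseudo)` and `predict(case_id) -> {class: probability map}`
plugs in. The bundled `MockSegmenterBackend` assigns each case a tiny tube
phantom as ground truth and a per-case difficulty drawn once from the seed;
predicted probability maps are confidence-shaped truths whose interior
confidence grows with the training-set size. This yields a nontrivial
uncertainty ranking, imperfect early pseudo-labels and a rising, plateauing
holdout Dice, while keeping a full 171-case, 5-iteration simulation under a
second of compute.

## Synthetic phantoms

Phantoms are voxelised by centre-point membership (a voxel is foreground
iff its centre lies inside the analytic tube), which keeps masks strictly
binary; each generator returns the exact axis and an exact diameter
function. Shapes: straight/tilted cylinders (radius 3–15 mm covers the
iliac-to-aortic calibre range), linearly tapered tubes (default 20 → 10 mm
over 100 mm, the aortic tapering regime; steeper tapers emulate stenoses),
a quarter-torus (tube radius 5 mm, bend radius 30 mm — iliac-like calibre
under strong curvature) and an aorto-iliac bifurcation (vertical trunk,
two branches descending at ±30°) whose principal path exercises the
longest-shortest-path logic. Probability-map phantoms place interior
voxels at `p_in`, a boundary shell at `p_boundary`, background at exactly
0, with optional seeded Gaussian noise on the foreground.

What the phantoms do *not* emulate: CMR intensity statistics and artefacts,
segmentation-induced mask errors (holes, leaks, touching structures),
non-circular lumina, and calcification. Passing phantom tests therefore
demonstrates geometric correctness of the measurement chain on exactly
known tubes, not robustness to imperfect segmentations — on real data the
profile error is bounded below by the segmentation error.

## Numerical choices and defaults

| parameter | default | note |
|---|---|---|
| resampled spacing | 1 mm isotropic | trilinear images, nearest masks |
| smoothing window `win` | 5 points | uniform filter on Y/X |
| jump threshold | 3 voxels | consecutive-point jump correction |
| endpoint fraction | 5% | both ends, slice CoM |
| `theta_thresh` | 10° | YX-slice vs Frisvad plane switch |
| `N_rays` | 8 | half-plane spacing i·π/8, cast in ±d |
| march step | 0.25 × min spacing | nearest-voxel lookup, 24 bisections |
| max ray length | half volume diagonal | longer rays → missing |
| cap-reject angle | 45° | EDT missing near vessel ends |
| tangent-outlier angle | 30° | neighbour-mean replacement |
| SG filter | order 3, window ≤ 51 | shrinks for short centerlines |
| uncertainty thresholds | p > 0.01, p > 0.9 | strict |
| AL protocol | 26 / 15 / 3+12 | holdout / initial / per-iteration |
| plateau | min_delta 0.005, patience 1 | against best-so-far Dice |

Problem sizes in the test and acceptance runs — cylinders of length 60 mm
on ≈50–100³ grids, a 100 mm taper, 171–200-case AL simulations — keep the
full suite in the tens of seconds while exercising every code path at
clinically realistic calibres.

## Known limitations

- Branch-aware multi-path extraction is out of scope; a bifurcation yields
  the single trunk-plus-longer-branch path.
- Pure-loop topologies (no skeleton endpoints) are rejected explicitly.
- The slice-CoM endpoint correction assumes a near-vertical vessel at its
  ends; for strongly oblique ends it can displace endpoints off-axis
  (mitigated, for the diameter, by the tangent-outlier correction).
- MAPE between two profiles resamples both onto 100 equally spaced
  normalized arc-length positions; profiles whose anatomical extents
  differ substantially are compared only up to this normalisation.
- Eligibility uses strict "below threshold" semantics; a vessel exactly at
  5.0 mm everywhere is eligible at 5.0 mm and ineligible at 5.5 mm. Both
  thresholds are always reported.
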