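# vesselquant

Automated aorto-iliac vessel diameter quantification and annotation-efficient
active-learning simulation for TAVI (transcatheter aortic valve implantation)
access-route planning.

Transfemoral TAVI requires threading a large delivery catheter through the
iliac arteries; arteries with lumen diameters below about 5–5.5 mm carry a
markedly higher risk of vascular complications. Given a 3D binary
segmentation mask of the aorta or an iliac artery (NIfTI, e.g. derived from
contrast-enhanced CMR), `vesselquant` extracts the vessel centerline,
computes a *continuous* diameter profile along it, and screens the profile
against the clinical eligibility thresholds. A second group of modules
scores segmentation uncertainty from class probability maps and simulates
the active-learning protocol that keeps the manual-annotation budget small.
It is a library for imaging-pipeline developers and methods researchers,
with a thin CLI for shell use; everything is testable end-to-end on built-in
synthetic phantoms with analytic ground truth.

## Method

**Centerline.** The mask M (reoriented to RAS, indexed z,y,x) is thinned to
a 1-voxel-wide skeleton; the largest 26-connected component is converted to
a weighted graph G = (V, E) with edge weights equal to the physical distance
between neighbouring voxel centres. The principal centerline C is the
*longest shortest path* between any two degree-1 endpoints of G (Dijkstra),
ordered so z₁ ≤ z_N. The Y/X coordinate sequences are smoothed with a 1D
uniform filter (jump correction for sudden coordinate jumps), and the first
and last 5% of points are snapped to the slice-wise centre of mass of the
mask, giving the refined centerline C″.

**Diameter.** At each point P_k of C″ two estimates are combined:

- distance-transform diameter `D_DT,k = 2 · EDT(P_k)` (inscribed-sphere
  diameter, spacing-aware);
- ray-casting diameters: N_rays = 8 rays in the plane orthogonal to the
  local tangent T_k (the YX slice when T_k is within 10° of the z-axis,
  otherwise a Frisvad orthonormal basis), each marched in ±d until the mask
  is exited, with `D_ray,ki = ‖(B⁺_ki − B⁻_ki) ⊙ S‖₂`.

The raw profile is `D_raw,k = (D_DT,k + median{D_ray,ki}) / 2`; missing
values are linearly interpolated and a Savitzky–Golay filter (order 3,
window up to 51 points) yields the final profile `D_final,k`.

**Uncertainty and active learning.** For each vessel class c, over voxels
with predicted probability p > 0.01,
`S_c = H̄_c + (1 − F_c/100)` where H̄_c is the mean binary entropy (bits)
and F_c the percentage of voxels with p > 0.9; the case score is
`S_case = (S_LI + S_RI)/2` over the two iliac classes. Each AL iteration
trains a pluggable segmenter backend on the labelled pools, scores all
unlabelled cases, sends the 3 most uncertain to the expert and
pseudo-labels the 12 most certain, and repeats until holdout Dice plateaus.

## Worked example

```bash
python examples/measure_phantom_diameter.py
```

```
cylinder (true diameter 12.0 mm):
  55 centerline points over 54.0 mm
  mean recovered diameter 12.24 mm, max abs error 0.24 mm

tapered tube (true diameter 20.0 -> 10.0 mm):
  recovered range 18.85 -> 10.21 mm
  profile MAPE vs analytic truth: 0.88%
```

The cylinder's profile is recovered to within a quarter of a voxel; the
tapered tube — a stand-in for a stenosing iliac — tracks the analytic
calibre with sub-percent mean error. `examples/access_route_report.py`
turns two such profiles into the clinical screening report:

```
Access-route report (thresholds 5.0 / 5.5 mm)
  left_iliac: min 7.91 mm at index 25, mean 7.91 mm -> eligible at 5.0 mm, eligible at 5.5 mm
  right_iliac: min 5.22 mm at index 51, mean 6.41 mm -> eligible at 5.0 mm, INELIGIBLE at 5.5 mm
  recommended access side: left_iliac
```

`examples/active_learning_simulation.py` and
`examples/uncertainty_scoring.py` demonstrate the annotation-budget loop
and the entropy-based case ranking. The same functionality is exposed on
the command line as `vesselquant phantom | measure | select | simulate-loop`.

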