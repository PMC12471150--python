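"""Diameter profiling on phantoms with known geometry.

Builds a straight cylinder and a linearly tapered tube, extracts their
centerlines, runs the hybrid distance-transform + ray-casting estimator and
compares the recovered profiles with the analytic truth.
"""

import numpy as np

import vesselquant as vq


def main() -> None:
    # --- straight cylinder: the profile should be flat at 12 mm -------------
    mask, truth = vq.cylinder_phantom(radius=6.0, length=60.0)
    centerline = vq.extract_centerline(mask)
    profile = vq.compute_profile(mask, centerline)
    err = np.abs(profile.d_final - 12.0)
    print("cylinder (true diameter 12.0 mm):")
    print(f"  {len(profile)} centerline points over {centerline.length_mm:.1f} mm")
    print(f"  mean recovered diameter {profile.d_final.mean():.2f} mm, "
          f"max abs error {err.max():.2f} mm")

    # --- tapered tube: diameter shrinks linearly 20 -> 10 mm ----------------
    mask, truth = vq.tapered_phantom(radius_start=10.0, radius_end=5.0, length=100.0)
    centerline = vq.extract_centerline(mask)
    profile = vq.compute_profile(mask, centerline)
    ref = np.array([truth.diameter_at(p) for p in profile.points])
    mape = 100.0 * np.mean(np.abs(profile.d_final - ref) / ref)
    print("\ntapered tube (true diameter 20.0 -> 10.0 mm):")
    print(f"  recovered range {profile.d_final.max():.2f} -> {profile.d_final.min():.2f} mm")
    print(f"  profile MAPE vs analytic truth: {mape:.2f}%")
    print("\nSub-voxel max error and low-percent MAPE mean the estimator tracks"
          "\nthe true lumen calibre to about the voxel discretisation limit.")


if __name__ == "__main__":
    main()
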