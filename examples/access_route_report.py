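"""Iliac access-route screening against the 5.0 / 5.5 mm thresholds.

Simulates a patient whose left iliac artery is uniformly wide but whose
right iliac tapers below the catheter-safety threshold, then prints the
eligibility report a TAVI planning workflow would consume.
"""

import vesselquant as vq
from vesselquant.metrics import access_report


def main() -> None:
    profiles = {}
    # left iliac: healthy 8 mm vessel
    mask, _ = vq.cylinder_phantom(radius=4.0, length=60.0)
    profiles["left_iliac"] = vq.compute_profile(mask, vq.extract_centerline(mask))
    # right iliac: tapers from 8 mm down to ~4.4 mm (stenotic distal segment)
    mask, _ = vq.tapered_phantom(radius_start=4.0, radius_end=2.2, length=60.0)
    profiles["right_iliac"] = vq.compute_profile(mask, vq.extract_centerline(mask))

    report = access_report(profiles, thresholds=(5.0, 5.5))
    print(report.to_text())
    print("\nA vessel is eligible at a threshold only if no point of its"
          "\ndiameter profile falls strictly below it; the recommended side"
          "\nis the eligible iliac with the larger minimal diameter.")


if __name__ == "__main__":
    main()
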