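"""Evaluation metrics and the clinical access-route report.

Segmentations are compared with the Dice similarity coefficient
``2|A n B| / (|A| + |B|)``; diameter profiles with the mean absolute
percentage error after resampling both profiles onto a common normalized
arc-length grid. The access report screens each iliac profile against the
5.0 and 5.5 mm minimal-lumen thresholds that govern transfemoral catheter
eligibility and recommends the more favourable side.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .diameter import DiameterProfile
from .volumes import Volume

__all__ = [
    "VesselAssessment",
    "AccessReport",
    "dice",
    "profile_mape",
    "access_report",
    "plot_profiles",
]


def dice(a: Volume, b: Volume) -> float:
    """Dice similarity coefficient between two binary masks on the same grid.

    Defined as 1.0 when both masks are empty.
    """
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    fa, fb = a.data.astype(bool), b.data.astype(bool)
    denom = int(fa.sum()) + int(fb.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.count_nonzero(fa & fb) / denom)


def _resample_normalized(profile: DiameterProfile, n_samples: int) -> np.ndarray:
    s = profile.arc_lengths()
    total = s[-1]
    if total == 0:
        raise ValueError("profile has zero arc length")
    grid = np.linspace(0.0, 1.0, n_samples)
    return np.interp(grid, s / total, profile.d_final)


def profile_mape(pred: DiameterProfile, ref: DiameterProfile, n_samples: int = 100) -> float:
    """MAPE (percent) between two diameter profiles.

    Both final-diameter sequences are linearly resampled onto ``n_samples``
    equally spaced normalized arc-length positions, then
    ``100 * mean(|pred - ref| / ref)``.
    """
    if len(pred) == 0 or len(ref) == 0:
        raise ValueError("profiles must be nonempty")
    p = _resample_normalized(pred, n_samples)
    r = _resample_normalized(ref, n_samples)
    if (r <= 0).any():
        raise ValueError("reference diameters must be positive")
    return float(100.0 * np.mean(np.abs(p - r) / r))


@dataclass(frozen=True)
class VesselAssessment:
    """Per-vessel screening result against the eligibility thresholds."""

    min_diameter_mm: float
    min_location_index: int
    mean_diameter_mm: float
    fraction_below: Mapping[float, float]  # threshold -> fraction of points below
    eligible: Mapping[float, bool]  # threshold -> no point strictly below


@dataclass(frozen=True)
class AccessReport:
    """Access-route screening of the iliac diameter profiles.

    ``recommended`` names the preferred access side, or None when neither
    iliac passes the lower threshold.
    """

    vessels: Mapping[str, VesselAssessment]
    thresholds: tuple[float, float]
    recommended: str | None
    warnings_: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "thresholds_mm": list(self.thresholds),
            "recommended": self.recommended,
            "warnings": list(self.warnings_),
            "vessels": {
                name: {
                    "min_diameter_mm": va.min_diameter_mm,
                    "min_location_index": va.min_location_index,
                    "mean_diameter_mm": va.mean_diameter_mm,
                    "fraction_below": {str(t): f for t, f in va.fraction_below.items()},
                    "eligible": {str(t): e for t, e in va.eligible.items()},
                }
                for name, va in self.vessels.items()
            },
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_text(self) -> str:
        lines = [f"Access-route report (thresholds {self.thresholds[0]} / {self.thresholds[1]} mm)"]
        for name, va in self.vessels.items():
            flags = ", ".join(
                f"{'eligible' if va.eligible[t] else 'INELIGIBLE'} at {t} mm"
                for t in self.thresholds
            )
            lines.append(
                f"  {name}: min {va.min_diameter_mm:.2f} mm at index "
                f"{va.min_location_index}, mean {va.mean_diameter_mm:.2f} mm -> {flags}"
            )
        lines.append(
            f"  recommended access side: {self.recommended or 'none (no eligible iliac)'}"
        )
        lines.extend(f"  warning: {w}" for w in self.warnings_)
        return "\n".join(lines)


def _assess(profile: DiameterProfile, thresholds: tuple[float, float]) -> VesselAssessment:
    d = profile.d_final
    return VesselAssessment(
        min_diameter_mm=float(d.min()),
        min_location_index=int(np.argmin(d)),
        mean_diameter_mm=float(d.mean()),
        fraction_below={t: float(np.mean(d < t)) for t in thresholds},
        eligible={t: bool(not (d < t).any()) for t in thresholds},
    )


def access_report(
    profiles: Mapping[str, DiameterProfile],
    thresholds: tuple[float, float] = (5.0, 5.5),
) -> AccessReport:
    """Screen iliac diameter profiles for transfemoral access eligibility.

    Eligibility at a threshold requires *no* point strictly below it (a
    constant 5.0 mm profile is eligible at 5.0 mm but not at 5.5 mm). When
    both iliacs pass the lower threshold the side with the larger minimum
    diameter is recommended; equal minima fall back to the larger mean,
    and a full tie goes to the left by convention.
    """
    lo = thresholds[0]
    warns: list[str] = []
    assessed = {name: _assess(p, thresholds) for name, p in profiles.items()}
    iliacs = [n for n in ("left_iliac", "right_iliac") if n in assessed]
    for side in ("left_iliac", "right_iliac"):
        if side not in assessed:
            warns.append(f"missing iliac profile: {side}; partial report")
    eligible = [n for n in iliacs if assessed[n].eligible[lo]]
    if not eligible:
        recommended = None
    elif len(eligible) == 1:
        recommended = eligible[0]
    else:
        # larger minimum wins; tie -> larger mean; tie -> left by convention
        recommended = max(
            eligible,
            key=lambda n: (
                assessed[n].min_diameter_mm,
                assessed[n].mean_diameter_mm,
                n == "left_iliac",
            ),
        )
    if warns:
        for w in warns:
            warnings.warn(w, RuntimeWarning, stacklevel=2)
    return AccessReport(
        vessels=assessed,
        thresholds=thresholds,
        recommended=recommended,
        warnings_=tuple(warns),
    )


def plot_profiles(
    profiles: Mapping[str, DiameterProfile],
    path: str,
    thresholds: tuple[float, float] = (5.0, 5.5),
) -> None:
    """Diameter-vs-point-index plot with the eligibility band shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, p in profiles.items():
        ax.plot(np.arange(len(p)), p.d_final, label=name)
    ax.axhspan(thresholds[0], thresholds[1], color="red", alpha=0.15,
               label=f"{thresholds[0]}-{thresholds[1]} mm threshold")
    ax.set_xlabel("centerline point index (proximal to distal)")
    ax.set_ylabel("diameter (mm)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
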