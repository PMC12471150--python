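"""Per-case segmentation uncertainty from class probability maps.

For each vessel class c, over the voxels whose predicted probability exceeds
a small foreground threshold (default 0.01):

    S_c = H_mean_c + (1 - F_c / 100)

where ``H_mean_c`` is the mean binary entropy (base 2, so it lies in [0, 1])
and ``F_c`` is the percentage of considered voxels that are *very confident*
(p > 0.9). Both terms grow with uncertainty, so S_c ranges from 0 (all
voxels fully confident) to 2 (all voxels at p = 0.5).

The case score is the mean of the left- and right-iliac class scores; the
aorta class, though scored, does not contribute, since iliac segmentation
quality is what limits access-route assessment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .volumes import Volume

__all__ = [
    "ClassUncertainty",
    "CaseScore",
    "binary_entropy",
    "class_uncertainty",
    "case_uncertainty",
    "score_case",
    "ILIAC_CLASSES",
]

ILIAC_CLASSES = ("left_iliac", "right_iliac")


@dataclass(frozen=True)
class ClassUncertainty:
    """Uncertainty components for one class: S_c = h_mean + (1 - f_pct/100)."""

    s_c: float
    h_mean: float  # mean binary entropy, bits, in [0, 1]
    f_pct: float  # percent of very-confident voxels, in [0, 100]


@dataclass(frozen=True)
class CaseScore:
    """Per-class scores plus the aggregate iliac case score."""

    per_class: Mapping[str, ClassUncertainty]
    s_case: float


def binary_entropy(p) -> np.ndarray | float:
    """Elementwise binary entropy -p*log2(p) - (1-p)*log2(1-p), in bits.

    Defined as 0 at p = 0 and p = 1.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log2(p), 0.0) - np.where(
            p < 1, (1 - p) * np.log2(1 - p), 0.0
        )
    h = np.where((p == 0) | (p == 1), 0.0, h)
    return float(h) if h.ndim == 0 else h


def class_uncertainty(
    prob: Volume, fg_thresh: float = 0.01, conf_thresh: float = 0.9
) -> ClassUncertainty:
    """Score one class's probability map.

    Only voxels with p > ``fg_thresh`` are considered (strict inequality);
    ``conf_thresh`` defines the very-confident population.
    """
    p = np.asarray(prob.data, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probability map values must lie in [0, 1]")
    sel = p[p > fg_thresh]
    if sel.size == 0:
        raise ValueError(
            f"no voxel above the foreground threshold {fg_thresh}; cannot score class"
        )
    h_mean = float(np.mean(binary_entropy(sel)))
    f_pct = float(100.0 * np.mean(sel > conf_thresh))
    s_c = h_mean + (1.0 - f_pct / 100.0)
    return ClassUncertainty(s_c=s_c, h_mean=h_mean, f_pct=f_pct)


def case_uncertainty(scores: Mapping[str, float]) -> float:
    """Aggregate case score: mean of the left- and right-iliac class scores.

    Other entries (e.g. the aorta) are ignored.
    """
    missing = [c for c in ILIAC_CLASSES if c not in scores]
    if missing:
        raise ValueError(f"missing iliac class score(s): {missing}")
    return float(np.mean([scores[c] for c in ILIAC_CLASSES]))


def score_case(
    prob_maps: Mapping[str, Volume],
    fg_thresh: float = 0.01,
    conf_thresh: float = 0.9,
) -> CaseScore:
    """Score every provided class map and aggregate the iliac classes."""
    per_class = {
        name: class_uncertainty(vol, fg_thresh=fg_thresh, conf_thresh=conf_thresh)
        for name, vol in prob_maps.items()
    }
    s_case = case_uncertainty({name: cu.s_c for name, cu in per_class.items()})
    return CaseScore(per_class=per_class, s_case=s_case)
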