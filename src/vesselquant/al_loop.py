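"""Uncertainty-guided active-learning loop for segmentation annotation budgeting.

The study protocol this simulates: a pool of post-contrast cases is split
into a training pool and a holdout test set (default 26 cases). Fifteen
randomly chosen training cases are manually annotated to start. Each
iteration then (1) trains the segmenter on all manual + pseudo labels,
(2) predicts probability maps for every unlabelled case, (3) ranks cases by
the iliac case-uncertainty score, (4) routes the 3 most uncertain cases to
the expert for manual annotation and accepts the model's own predictions
(binarized at 0.5) as pseudo-labels for the 12 most certain, and repeats
until holdout performance plateaus. After five iterations this bookkeeping
yields 30 manual, 60 pseudo-labelled and 55 untouched cases.

The segmentation network itself is out of scope here: any object satisfying
the :class:`SegmenterBackend` protocol can plug in, and a deterministic
:class:`MockSegmenterBackend` built on tiny tube phantoms makes the whole
loop runnable and testable on a laptop.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol

import numpy as np

from . import metrics
from .phantoms import cylinder_phantom, make_probability_map
from .uncertainty import ILIAC_CLASSES, score_case
from .volumes import Volume

__all__ = [
    "ALState",
    "SegmenterBackend",
    "MockSegmenterBackend",
    "initialize",
    "select_cases",
    "al_iteration",
    "run_until_plateau",
    "holdout_mean_dice",
]

Labels = Mapping[str, Volume]  # class name -> binary mask
Annotator = Callable[[str], Labels]


class SegmenterBackend(Protocol):
    """Contract a segmentation trainer/predictor must satisfy."""

    def train(self, manual: Mapping[str, Labels], pseudo: Mapping[str, Labels]) -> None:
        """(Re)train on the current manual + pseudo labelled pools."""

    def predict(self, case_id: str) -> Mapping[str, Volume]:
        """Per-class probability maps (values in [0, 1]) for one case."""


@dataclass
class ALState:
    """Disjoint case pools plus iteration bookkeeping.

    The four pools partition the case universe; manual and pseudo pools only
    ever grow. ``pseudo_labels`` freezes the predictions accepted at the
    iteration a case was pseudo-labelled (they are never refreshed by later
    models).
    """

    manual_pool: set[str]
    pseudo_pool: set[str]
    unlabelled_pool: set[str]
    holdout: set[str]
    iteration: int = 0
    history: list[dict] = field(default_factory=list)
    pseudo_labels: dict[str, Labels] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.check_invariants()

    @property
    def universe(self) -> set[str]:
        return self.manual_pool | self.pseudo_pool | self.unlabelled_pool | self.holdout

    def check_invariants(self) -> None:
        pools = [self.manual_pool, self.pseudo_pool, self.unlabelled_pool, self.holdout]
        total = sum(len(p) for p in pools)
        if total != len(self.universe):
            raise AssertionError("case pools are not pairwise disjoint")

    def to_json(self, path: str) -> None:
        payload = {
            "manual_pool": sorted(self.manual_pool),
            "pseudo_pool": sorted(self.pseudo_pool),
            "unlabelled_pool": sorted(self.unlabelled_pool),
            "holdout": sorted(self.holdout),
            "iteration": self.iteration,
            "history": self.history,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ALState":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            manual_pool=set(payload["manual_pool"]),
            pseudo_pool=set(payload["pseudo_pool"]),
            unlabelled_pool=set(payload["unlabelled_pool"]),
            holdout=set(payload["holdout"]),
            iteration=payload["iteration"],
            history=payload["history"],
        )


def initialize(
    cases: list[str], n_holdout: int = 26, n_initial: int = 15, seed: int = 0
) -> ALState:
    """Shuffle the cases and split into holdout / initial-manual / unlabelled.

    Deterministic given ``seed``. Defaults mirror the study protocol: 26
    holdout cases and 15 initially annotated training cases.
    """
    cases = list(cases)
    if len(cases) < n_holdout + n_initial:
        raise ValueError(
            f"need at least {n_holdout + n_initial} cases, got {len(cases)}"
        )
    rng = np.random.default_rng(seed)
    order = list(np.asarray(sorted(cases))[rng.permutation(len(cases))])
    holdout = set(order[:n_holdout])
    manual = set(order[n_holdout : n_holdout + n_initial])
    unlabelled = set(order[n_holdout + n_initial :])
    return ALState(
        manual_pool=manual, pseudo_pool=set(), unlabelled_pool=unlabelled, holdout=holdout
    )


def select_cases(
    scores: Mapping[str, float], n_uncertain: int = 3, n_certain: int = 12
) -> tuple[list[str], list[str]]:
    """Split the scored pool into manual-annotation and pseudo-label picks.

    The ``n_uncertain`` highest case-uncertainty scores go to the expert; the
    ``n_certain`` lowest scores among the *remaining* cases become
    pseudo-label candidates, so the two sets are disjoint by construction.
    Ties are broken by case id ascending.
    """
    if not scores:
        raise ValueError("no scores to select from")
    if n_uncertain + n_certain > len(scores):
        raise ValueError(
            f"cannot select {n_uncertain}+{n_certain} from {len(scores)} cases "
            "without overlap"
        )
    by_uncertain = sorted(scores, key=lambda cid: (-scores[cid], cid))
    manual_ids = by_uncertain[:n_uncertain]
    rest = set(scores) - set(manual_ids)
    by_certain = sorted(rest, key=lambda cid: (scores[cid], cid))
    pseudo_ids = by_certain[:n_certain]
    return manual_ids, pseudo_ids


def _binarize(prob_maps: Mapping[str, Volume], thresh: float = 0.5) -> Labels:
    return {
        name: Volume(data=(v.data > thresh).astype(np.uint8), spacing=v.spacing)
        for name, v in prob_maps.items()
    }


def holdout_mean_dice(state: ALState, backend: SegmenterBackend, annotator: Annotator) -> float:
    """Mean Dice over all holdout cases and classes, predictions binarized at 0.5."""
    vals = []
    for cid in sorted(state.holdout):
        truth = annotator(cid)
        pred = _binarize(backend.predict(cid))
        for cls in truth:
            vals.append(metrics.dice(pred[cls], truth[cls]))
    return float(np.mean(vals))


def al_iteration(
    state: ALState,
    backend: SegmenterBackend,
    annotator: Annotator,
    n_uncertain: int = 3,
    n_certain: int = 12,
    evaluator: Callable[[ALState, SegmenterBackend], dict] | None = None,
) -> ALState:
    """One active-learning cycle: train, score, select, move cases.

    Returns a new state; the input state is not mutated. ``evaluator`` (by
    default holdout mean Dice) supplies the metrics appended to the history.
    """
    if len(state.unlabelled_pool) < n_uncertain + n_certain:
        raise ValueError(
            f"iteration {state.iteration + 1}: unlabelled pool too small "
            f"({len(state.unlabelled_pool)} < {n_uncertain + n_certain})"
        )
    manual_labels = {cid: annotator(cid) for cid in sorted(state.manual_pool)}
    try:
        backend.train(manual_labels, dict(state.pseudo_labels))
        scores = {}
        predictions = {}
        for cid in sorted(state.unlabelled_pool):
            probs = backend.predict(cid)
            predictions[cid] = probs
            scores[cid] = score_case(probs).s_case
    except Exception as exc:
        raise RuntimeError(f"backend failed at iteration {state.iteration + 1}") from exc

    manual_ids, pseudo_ids = select_cases(scores, n_uncertain, n_certain)
    new_pseudo_labels = dict(state.pseudo_labels)
    for cid in pseudo_ids:
        new_pseudo_labels[cid] = _binarize(predictions[cid])

    new_state = ALState(
        manual_pool=state.manual_pool | set(manual_ids),
        pseudo_pool=state.pseudo_pool | set(pseudo_ids),
        unlabelled_pool=state.unlabelled_pool - set(manual_ids) - set(pseudo_ids),
        holdout=set(state.holdout),
        iteration=state.iteration + 1,
        history=list(state.history),
        pseudo_labels=new_pseudo_labels,
    )
    new_state.check_invariants()
    if new_state.universe != state.universe:
        raise AssertionError("case conservation violated by iteration")

    if evaluator is None:
        record = {"dsc": holdout_mean_dice(new_state, backend, annotator)}
    else:
        record = dict(evaluator(new_state, backend))
    record["iteration"] = new_state.iteration
    record["n_manual"] = len(new_state.manual_pool)
    record["n_pseudo"] = len(new_state.pseudo_pool)
    record["n_unlabelled"] = len(new_state.unlabelled_pool)
    new_state.history.append(record)
    return new_state


def run_until_plateau(
    state: ALState,
    backend: SegmenterBackend,
    annotator: Annotator,
    patience: int = 1,
    min_delta: float = 0.005,
    n_uncertain: int = 3,
    n_certain: int = 12,
    max_iterations: int = 100,
    evaluator: Callable[[ALState, SegmenterBackend], dict] | None = None,
) -> ALState:
    """Iterate until the holdout DSC improvement stays below ``min_delta``
    for ``patience`` consecutive iterations, or the unlabelled pool can no
    longer supply a full selection."""
    if not state.holdout:
        raise ValueError("plateau detection needs a nonempty holdout set")
    if patience < 1:
        raise ValueError("patience must be >= 1")
    best = -np.inf
    streak = 0
    while state.iteration < max_iterations:
        if len(state.unlabelled_pool) < n_uncertain + n_certain:
            break  # pools exhausted
        state = al_iteration(
            state, backend, annotator, n_uncertain, n_certain, evaluator=evaluator
        )
        dsc = state.history[-1]["dsc"]
        improvement = dsc - best
        best = max(best, dsc)
        if improvement < min_delta:
            streak += 1
            if streak >= patience:
                break
        else:
            streak = 0
    return state


def _crc_seed(*parts) -> int:
    return zlib.crc32("|".join(str(p) for p in parts).encode()) % (2**31 - 1)


class MockSegmenterBackend:
    """Deterministic stand-in for the segmentation network.

    Each case owns a tiny tube-phantom truth mask per vessel class. Predicted
    probability maps are confidence-shaped versions of the truth: interior
    confidence grows with the size of the training set and shrinks with a
    per-case difficulty drawn once from the seed, so uncertainty ranking is
    nontrivial, pseudo-labels are imperfect early, and holdout Dice improves
    and then plateaus as training data accumulates.
    """

    classes = ("aorta",) + ILIAC_CLASSES

    def __init__(
        self,
        case_ids: list[str],
        seed: int = 0,
        grid_radius: float = 2.0,
        grid_length: float = 8.0,
        saturation: int = 75,
    ):
        self.seed = int(seed)
        self.saturation = saturation
        self._n_train = 0
        self.difficulty: dict[str, float] = {}
        self._truths: dict[str, Labels] = {}
        base_mask, _ = cylinder_phantom(
            radius=grid_radius, length=grid_length, spacing=(1.0, 1.0, 1.0), margin_mm=2.0
        )
        for cid in case_ids:
            rng = np.random.default_rng(_crc_seed(self.seed, cid))
            self.difficulty[cid] = float(rng.uniform(0.05, 0.95))
            self._truths[cid] = {cls: base_mask for cls in self.classes}

    def truth(self, case_id: str) -> Labels:
        return self._truths[case_id]

    def annotator(self) -> Annotator:
        """Expert-annotation oracle: returns the ground-truth masks."""
        return self.truth

    def train(self, manual: Mapping[str, Labels], pseudo: Mapping[str, Labels]) -> None:
        self._n_train = len(manual) + len(pseudo)

    def _confidence(self, case_id: str) -> float:
        progress = min(1.0, self._n_train / self.saturation)
        skill = 0.55 + 0.44 * progress
        conf = skill - 0.25 * self.difficulty[case_id] * (1.0 - progress)
        return float(np.clip(conf, 0.51, 0.99))

    def predict(self, case_id: str) -> Mapping[str, Volume]:
        conf = self._confidence(case_id)
        out = {}
        for cls in self.classes:
            seed = _crc_seed(self.seed, case_id, cls, self._n_train)
            out[cls] = make_probability_map(
                self._truths[case_id][cls],
                p_in=conf,
                p_boundary=0.8 * conf,
                boundary_width=1,
                noise_sd=0.01,
                seed=seed,
            )
        return out
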