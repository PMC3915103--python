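"""Label propagation and (weighted) majority-voting label fusion.

Each selected exemplar's label map is pulled onto the subject grid with
nearest-neighbour interpolation through its exemplar -> subject
displacement field.  Fusion then scores, per voxel, every candidate label
by the sum of the voting weights of the exemplars proposing it, and keeps
the highest-scoring label.  Background (label 0) votes like any other
label, which prevents foreground bleeding where most templates see
background.  Ties go to the smallest label value.  Weights are global (one
scalar per exemplar, ``1 - edge cost`` to the subject); no per-voxel
weighting is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .graph import SelectionResult
from .registration import RegistrationResult
from .volumes import LabelVolume, warp

__all__ = [
    "VoteStack",
    "propagate_labels",
    "weighted_majority_vote",
    "unweighted_majority_vote",
]


@dataclass
class VoteStack:
    """Warped candidate segmentations on the subject grid with their weights."""

    warped_labels: list[LabelVolume]
    weights: list[float]

    def __post_init__(self) -> None:
        if len(self.warped_labels) == 0:
            raise ValidationError("vote stack must contain at least one segmentation")
        if len(self.warped_labels) != len(self.weights):
            raise ValidationError("labels and weights must be aligned lists")
        shape = self.warped_labels[0].shape
        for lv in self.warped_labels[1:]:
            if lv.shape != shape:
                raise ValidationError("all label volumes in a stack must share one grid")
        if any(w < 0 for w in self.weights):
            raise ValidationError("voting weights must be >= 0")


def propagate_labels(
    selection: SelectionResult,
    atlas_labels: dict[str, LabelVolume],
    registrations: dict[tuple[str, str], RegistrationResult],
    subject_id: str = "subject",
) -> VoteStack:
    """Warp each exemplar's labels to the subject grid (nearest-neighbour)."""
    warped: list[LabelVolume] = []
    for ex in selection.exemplars:
        if ex not in atlas_labels:
            raise ValidationError(f"no label volume for exemplar {ex!r}")
        key = (ex, subject_id)
        if key not in registrations:
            raise ValidationError(f"missing registration for pair {key}")
        warped.append(warp(atlas_labels[ex], registrations[key].field, "nearest"))
    return VoteStack(warped, list(selection.weights))


def _vote(stack: VoteStack, weights: np.ndarray) -> tuple[LabelVolume, np.ndarray]:
    grids = np.stack([lv.data for lv in stack.warped_labels])  # (k, nx, ny, nz)
    labels = np.unique(grids)
    shape = grids.shape[1:]
    best_label = np.full(shape, labels[0], dtype=np.int32)
    best_score = np.full(shape, -1.0)
    for lab in labels:  # ascending -> strict improvement keeps smallest label on ties
        score = np.tensordot(weights, (grids == lab).astype(np.float64), axes=1)
        better = score > best_score + 1e-12
        best_label = np.where(better, np.int32(lab), best_label)
        best_score = np.where(better, score, best_score)
    ref = stack.warped_labels[0]
    return LabelVolume(best_label, ref.spacing, ref.origin), best_score


def weighted_majority_vote(
    stack: VoteStack, return_confidence: bool = False
) -> LabelVolume | tuple[LabelVolume, np.ndarray]:
    """Per-voxel argmax of weight-summed label votes; ties -> smallest label."""
    weights = np.asarray(stack.weights, dtype=np.float64)
    if np.all(weights == 0):
        raise ValidationError("all voting weights are zero")
    fused, score = _vote(stack, weights)
    return (fused, score) if return_confidence else fused


def unweighted_majority_vote(
    stack: VoteStack, return_confidence: bool = False
) -> LabelVolume | tuple[LabelVolume, np.ndarray]:
    """Plain majority voting: every candidate segmentation weighs equally."""
    weights = np.ones(len(stack.warped_labels))
    fused, score = _vote(stack, weights)
    return (fused, score) if return_confidence else fused
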