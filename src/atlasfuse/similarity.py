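"""Pairwise similarity terms and directed edge costs.

Each directed edge i -> j of the atlas graph carries a cost

    e_ij = w1 * M_ij + w2 * H_ij

where ``M_ij`` is the mean squared voxel-wise intensity difference between
image j and image i warped onto j's grid, and ``H_ij`` is the harmonic
energy of the i -> j displacement field — the mean Frobenius norm of the
Jacobian of the displacement, a dimensionless summary of how much and how
irregularly i had to deform to match j.  The Jacobian is taken of the
displacement (not the full transform), so the identity transform scores 0.

M carries intensity^2 units and H is dimensionless, so before weighting
both terms are min–max normalized to [0, 1] over all edges of the graph;
this also makes ``1 - e_ij`` a well-defined voting weight.  Default weights
are ``w1 = 0.2`` and ``w2 = 0.8``, favouring shape agreement over raw
intensity agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .volumes import DisplacementField, LabelVolume, VolumeImage

__all__ = [
    "EdgeTerms",
    "CostWeights",
    "intensity_msd",
    "jacobian_frobenius",
    "harmonic_energy",
    "normalize_terms",
    "edge_cost",
]

_TOL = 1e-9


@dataclass(frozen=True)
class EdgeTerms:
    """Raw similarity terms for one directed edge."""

    M: float
    H: float
    source_id: str
    target_id: str

    def __post_init__(self) -> None:
        for name, v in (("M", self.M), ("H", self.H)):
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"edge term {name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class CostWeights:
    """Weights of the intensity (w1) and shape (w2) terms; must sum to 1."""

    w1: float = 0.2
    w2: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.w1 <= 1.0 and 0.0 <= self.w2 <= 1.0):
            raise ValidationError(f"weights must lie in [0, 1], got w1={self.w1}, w2={self.w2}")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValidationError(f"w1 + w2 must equal 1, got {self.w1 + self.w2}")


def _mask_array(mask: LabelVolume | np.ndarray | None, shape) -> np.ndarray | None:
    if mask is None:
        return None
    arr = mask.data if isinstance(mask, LabelVolume) else np.asarray(mask)
    if arr.shape != tuple(shape):
        raise ValidationError(f"mask shape {arr.shape} does not match grid {tuple(shape)}")
    arr = arr > 0
    if not arr.any():
        raise ValidationError("mask is empty")
    return arr


def intensity_msd(
    target: VolumeImage,
    warped_source: VolumeImage,
    mask: LabelVolume | np.ndarray | None = None,
) -> float:
    """Mean squared voxel-wise intensity difference over the included voxels."""
    if target.shape != warped_source.shape:
        raise ValidationError(
            f"shape mismatch: target {target.shape} vs source {warped_source.shape}"
        )
    diff2 = (target.data - warped_source.data) ** 2
    m = _mask_array(mask, target.shape)
    return float(diff2[m].mean()) if m is not None else float(diff2.mean())


def jacobian_frobenius(fld: DisplacementField) -> VolumeImage:
    """Per-voxel Frobenius norm of the 3x3 Jacobian of the displacement.

    Central differences in the interior, one-sided at the boundary; all in
    voxel units, so a pure translation scores exactly 0 everywhere.
    """
    if min(fld.grid_shape) < 2:
        raise ValidationError(
            f"field grid must span >= 2 voxels in every dimension, got {fld.grid_shape}"
        )
    acc = np.zeros(fld.grid_shape)
    for comp in range(3):
        for axis in range(3):
            d = np.gradient(fld.data[..., comp], axis=axis)
            acc += d * d
    return VolumeImage(np.sqrt(acc), fld.spacing, fld.origin)


def harmonic_energy(
    fld: DisplacementField, mask: LabelVolume | np.ndarray | None = None
) -> float:
    """Mean Frobenius norm of the displacement Jacobian over the included voxels."""
    frob = jacobian_frobenius(fld).data
    m = _mask_array(mask, frob.shape)
    return float(frob[m].mean()) if m is not None else float(frob.mean())


def normalize_terms(
    all_M: np.ndarray, all_H: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Min–max rescale each term matrix to [0, 1] over its finite entries.

    Non-finite entries (absent edges, the diagonal when flagged with NaN)
    pass through unchanged.  A degenerate term (max == min) maps to all
    zeros, so a graph of identical images yields zero costs.
    """
    out = []
    for name, mat in (("M", all_M), ("H", all_H)):
        mat = np.asarray(mat, dtype=np.float64)
        finite = np.isfinite(mat)
        if finite.any() and np.any(mat[finite] < 0):
            raise ValidationError(f"{name} contains negative entries")
        scaled = mat.copy()
        if finite.any():
            lo = mat[finite].min()
            hi = mat[finite].max()
            if hi - lo > _TOL:
                scaled[finite] = (mat[finite] - lo) / (hi - lo)
            else:
                scaled[finite] = 0.0
        out.append(scaled)
    return out[0], out[1]


def edge_cost(Mhat, Hhat, w: CostWeights) -> float | np.ndarray:
    """Weighted edge cost ``w1*Mhat + w2*Hhat``; inputs must lie in [0, 1]."""
    Mhat = np.asarray(Mhat, dtype=np.float64)
    Hhat = np.asarray(Hhat, dtype=np.float64)
    for name, v in (("Mhat", Mhat), ("Hhat", Hhat)):
        finite = np.isfinite(v)
        if np.any((v[finite] < -_TOL) | (v[finite] > 1 + _TOL)):
            raise ValidationError(f"{name} must lie in [0, 1] after normalization")
    cost = w.w1 * Mhat + w.w2 * Hhat
    if cost.ndim == 0:
        return float(cost)
    return cost
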