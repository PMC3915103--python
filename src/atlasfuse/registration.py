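"""Pairwise deformable registration behind a pluggable backend contract.

The selection and fusion stages only require, for each ordered image pair
(moving, fixed), a displacement field on the fixed grid such that
``warp(moving, field)`` approximates ``fixed``.  Any tool able to produce
such a field can drive the pipeline; three backends are provided:

``builtin``
    A deterministic multi-resolution demons-style registrator: Gaussian
    pyramid, Thirion force updates on the mean-squared intensity
    difference, Gaussian field regularization each iteration.  It is a
    lightweight general-purpose deformable registrator adequate for
    smooth, moderate deformations; it makes no topology-preservation
    guarantee.
``oracle``
    Pass-through of a caller-supplied field — used with synthetic
    populations whose ground-truth deformations are known, and for
    injecting fields computed by any external registration tool.
``external``
    Like ``oracle`` but reads the field from a NIfTI file
    (``field_path``), matching the on-disk layout the CLI uses
    (``<moving>__to__<fixed>.nii.gz``).

Both directions of a pair are registered independently; the atlas graph is
directed, so forward/backward asymmetry is tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

from .errors import ValidationError
from .volumes import DisplacementField, VolumeImage, read_field, warp

__all__ = ["RegistrationParams", "RegistrationResult", "register", "invertible_pair"]


@dataclass(frozen=True)
class RegistrationParams:
    """Builtin-backend knobs; all deterministic (no random state).

    iterations are ordered coarse -> fine and must match ``levels``.
    ``smooth_sigma`` (voxels) regularizes the field after every update;
    ``max_step`` caps the per-iteration update magnitude in voxels.
    """

    levels: int = 3
    iterations: tuple[int, ...] = (60, 30, 10)
    smooth_sigma: float = 1.0
    max_step: float = 2.0

    def __post_init__(self) -> None:
        if self.levels < 1 or len(self.iterations) != self.levels:
            raise ValidationError(
                f"need one iteration count per level: levels={self.levels}, "
                f"iterations={self.iterations}"
            )
        if self.smooth_sigma < 0 or self.max_step <= 0:
            raise ValidationError("smooth_sigma must be >= 0 and max_step > 0")


@dataclass
class RegistrationResult:
    field: DisplacementField
    moving_id: str = "moving"
    fixed_id: str = "fixed"
    initial_msd: float | None = None
    final_msd: float | None = None


def _msd(a: np.ndarray, b: np.ndarray) -> float:
    return float(((a - b) ** 2).mean())


def _warp_array(moving: np.ndarray, u: np.ndarray) -> np.ndarray:
    shape = u.shape[:3]
    coords = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(np.float64)
    coords += np.moveaxis(u, -1, 0)
    return map_coordinates(moving, coords, order=1, mode="constant", cval=0.0)


def _demons_level(
    moving: np.ndarray, fixed: np.ndarray, u: np.ndarray, n_iter: int, p: RegistrationParams
) -> np.ndarray:
    eps = 1e-12
    for _ in range(n_iter):
        warped = _warp_array(moving, u)
        diff = warped - fixed
        grads = np.gradient(warped)
        gnorm2 = sum(g * g for g in grads)
        denom = gnorm2 + diff * diff
        scale = np.where(denom > eps, diff / np.maximum(denom, eps), 0.0)
        update = np.stack([-scale * g for g in grads], axis=-1)
        mag = np.sqrt((update**2).sum(axis=-1, keepdims=True))
        over = mag > p.max_step
        if over.any():
            update = np.where(over, update * (p.max_step / np.maximum(mag, eps)), update)
        u = u + update
        if p.smooth_sigma > 0:
            for c in range(3):
                u[..., c] = gaussian_filter(u[..., c], p.smooth_sigma, mode="nearest")
    return u


def _resize_field(u: np.ndarray, new_shape: tuple[int, ...]) -> np.ndarray:
    factors = [ns / s for ns, s in zip(new_shape, u.shape[:3])]
    out = np.empty(tuple(new_shape) + (3,))
    for c in range(3):
        comp = zoom(u[..., c], factors, order=1, mode="nearest", grid_mode=True)
        out[..., c] = comp * factors[c]  # displacement rescales with the grid
    return out


def _demons(moving: VolumeImage, fixed: VolumeImage, p: RegistrationParams) -> DisplacementField:
    pyramids: list[tuple[np.ndarray, np.ndarray]] = []
    mov, fix = moving.data, fixed.data
    shapes = []
    for level in range(p.levels):
        factor = 2 ** (p.levels - 1 - level)
        shape = tuple(max(4, s // factor) for s in fixed.shape)
        shapes.append(shape)
    for shape in shapes:
        if shape == fixed.shape:
            pyramids.append((mov, fix))
        else:
            f = [ns / s for ns, s in zip(shape, fixed.shape)]
            sig = [0.5 / fi if fi < 1 else 0.0 for fi in f]
            ms = gaussian_filter(mov, sig, mode="nearest")
            fs = gaussian_filter(fix, sig, mode="nearest")
            pyramids.append(
                (
                    zoom(ms, f, order=1, mode="nearest", grid_mode=True),
                    zoom(fs, f, order=1, mode="nearest", grid_mode=True),
                )
            )
    u = np.zeros(shapes[0] + (3,))
    for level, (m_l, f_l) in enumerate(pyramids):
        if u.shape[:3] != m_l.shape:
            u = _resize_field(u, m_l.shape)
        u = _demons_level(m_l, f_l, u, p.iterations[level], p)
    if u.shape[:3] != fixed.shape:
        u = _resize_field(u, fixed.shape)
    return DisplacementField(u, fixed.spacing, fixed.origin)


def register(
    moving: VolumeImage,
    fixed: VolumeImage,
    backend: str = "builtin",
    params: RegistrationParams | None = None,
    known_field: DisplacementField | None = None,
    field_path: str | None = None,
    moving_id: str = "moving",
    fixed_id: str = "fixed",
) -> RegistrationResult:
    """Estimate (or pass through) the fixed->moving pull-back displacement field.

    Non-convergence of the builtin backend is not an error: the best
    iterate is returned and the residual MSD recorded on the result.
    """
    if moving.shape != fixed.shape:
        raise ValidationError(
            f"registration requires a common grid: moving {moving.shape} vs fixed {fixed.shape}"
        )
    if backend == "builtin":
        fld = _demons(moving, fixed, params or RegistrationParams())
    elif backend == "oracle":
        if known_field is None:
            raise ValidationError("oracle backend requires known_field")
        fld = known_field
    elif backend == "external":
        if known_field is not None:
            fld = known_field
        elif field_path is not None:
            fld = read_field(field_path)
        else:
            raise ValidationError("external backend requires known_field or field_path")
    else:
        raise ValidationError(f"unknown registration backend {backend!r}")
    if fld.grid_shape != fixed.shape:
        raise ValidationError(
            f"field grid {fld.grid_shape} does not match fixed image {fixed.shape}"
        )
    res = RegistrationResult(fld, moving_id=moving_id, fixed_id=fixed_id)
    res.initial_msd = _msd(moving.data, fixed.data)
    res.final_msd = _msd(warp(moving, fld, "linear").data, fixed.data)
    return res


def invertible_pair(
    moving: VolumeImage,
    fixed: VolumeImage,
    backend: str = "builtin",
    params: RegistrationParams | None = None,
    known_forward: DisplacementField | None = None,
    known_reverse: DisplacementField | None = None,
    moving_id: str = "moving",
    fixed_id: str = "fixed",
) -> tuple[RegistrationResult, RegistrationResult]:
    """Register both directions independently, populating edges i->j and j->i."""
    fwd = register(
        moving, fixed, backend, params, known_forward, moving_id=moving_id, fixed_id=fixed_id
    )
    rev = register(
        fixed, moving, backend, params, known_reverse, moving_id=fixed_id, fixed_id=moving_id
    )
    return fwd, rev
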