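"""Synthetic labelled phantoms and atlas populations with controlled
cluster structure.

The generator stands in for a real multi-atlas population: a base anatomy
of a few compact structures (one large thalamus-like ellipsoid, one thin
ventricle-like sheet to stress surface metrics, two small spheres), imaged
with partial-volume edge smoothing, a smooth multiplicative bias field and
additive Gaussian noise.  A population is built in two deformation tiers:
``k_modes`` smooth random "mode" fields (anatomical sub-types, maximum
displacement ``between_mode_disp``) each composed with smaller per-member
fields (``within_mode_disp``), so that members of one mode resemble each
other far more than members of different modes — exactly the structure the
graph-based atlas selection is meant to detect.  The composed ground-truth
fields are returned so an oracle registration backend can bypass real
registration in tests.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

from .errors import ValidationError
from .volumes import DisplacementField, LabelVolume, VolumeImage, warp

__all__ = [
    "Structure",
    "PhantomSpec",
    "PopulationSpec",
    "Population",
    "make_phantom",
    "random_smooth_field",
    "exponential_field",
    "compose_fields",
    "invert_field",
    "true_pairwise_field",
    "make_population",
    "oracle_registrations",
]


@dataclass(frozen=True)
class Structure:
    """Axis-aligned ellipsoid: centre and radii in voxels, label and intensity."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    label: int
    intensity: float


def _default_structures() -> list[Structure]:
    # centres/radii for a 32^3 grid; rescaled to other grids in make_phantom
    return [
        Structure((13.0, 16.0, 16.0), (7.0, 6.0, 5.5), 1, 160.0),  # large, thalamus-like
        Structure((23.0, 16.0, 16.0), (1.6, 7.0, 5.0), 2, 200.0),  # thin, ventricle-like
        Structure((13.0, 7.0, 9.0), (3.2, 3.2, 3.2), 3, 80.0),  # small sphere
        Structure((13.0, 25.0, 22.0), (3.0, 3.0, 3.0), 4, 120.0),  # small sphere
    ]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and corruption parameters of one phantom scan."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    structures: list[Structure] = dc_field(default_factory=_default_structures)
    background_intensity: float = 40.0
    # surrounding-tissue envelope (skull-stripped look): intensity is 0
    # outside an ellipsoid of this fractional radius, so warps sampling
    # beyond the grid (which return 0) match the true background
    envelope_radius_frac: float = 0.42
    smooth_sigma: float = 0.8  # partial-volume edge blur, voxels
    bias_amplitude: float = 0.15  # relative amplitude of the multiplicative field
    noise_sd: float = 2.0  # additive Gaussian noise, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.structures) < 1:
            raise ValidationError("at least one structure is required")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValidationError("noise_sd and bias_amplitude must be >= 0")
        labels = [s.label for s in self.structures]
        if len(set(labels)) != len(labels) or min(labels) < 1:
            raise ValidationError("structure labels must be distinct positive integers")
        shape = np.asarray(self.grid_shape)
        if shape.shape != (3,) or np.any(shape < 8):
            raise ValidationError("grid_shape must be 3 dimensions of at least 8 voxels")
        ref = np.array([32.0, 32.0, 32.0])
        for s in self.structures:
            c = np.asarray(s.center) * shape / ref
            r = np.asarray(s.radii) * shape / ref
            if np.any(c - r < 0) or np.any(c + r > shape - 1):
                raise ValidationError(f"structure with label {s.label} does not fit the grid")


@dataclass(frozen=True)
class PopulationSpec:
    """Two-tier deformation model of an atlas population."""

    base: PhantomSpec = dc_field(default_factory=PhantomSpec)
    k_modes: int = 3
    per_mode: int = 3
    between_mode_disp: float = 6.0  # voxels
    within_mode_disp: float = 1.5  # voxels
    field_sigma: float = 4.0  # smoothness of the random fields, voxels
    # residual per-scan multiplicative bias after upstream inhomogeneity
    # correction (the pipeline documents its inputs as bias-corrected)
    residual_bias: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_modes < 1 or self.per_mode < 1:
            raise ValidationError("k_modes and per_mode must be >= 1")
        if not (self.between_mode_disp > self.within_mode_disp > 0):
            raise ValidationError(
                "need between_mode_disp > within_mode_disp > 0, got "
                f"{self.between_mode_disp} and {self.within_mode_disp}"
            )


@dataclass
class Population:
    """A generated atlas population plus its ground truth.

    The subject is itself a phantom scan: the base anatomy under a small
    idiosyncratic deformation (``within_mode_disp`` scale) with its own
    noise, imaged through the same warp/interpolation path as every
    member, so no image is systematically sharper than the others.
    """

    subject_image: VolumeImage
    subject_labels: LabelVolume
    subject_field: DisplacementField  # subject(x) = base(x + field(x))
    members: list[tuple[VolumeImage, LabelVolume]]
    mode_assignment: list[int]
    true_fields: list[DisplacementField]  # member(x) = base(x + field(x))
    inverse_fields: list[DisplacementField]  # exact inverses via negated velocities
    spec: PopulationSpec


def make_phantom(spec: PhantomSpec) -> tuple[VolumeImage, LabelVolume]:
    """Render one labelled phantom scan; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    scale = np.asarray(shape) / np.array([32.0, 32.0, 32.0])
    labels = np.zeros(shape, dtype=np.int32)
    grid = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(np.float64)
    for s in spec.structures:
        c = np.asarray(s.center) * scale
        r = np.asarray(s.radii) * scale
        ellip = sum(((grid[a] - c[a]) / r[a]) ** 2 for a in range(3)) <= 1.0
        overlap = ellip & (labels > 0)
        if overlap.any():
            other = int(labels[overlap][0])
            raise ValidationError(
                f"structure with label {s.label} overlaps structure with label {other}"
            )
        labels[ellip] = s.label
    if spec.envelope_radius_frac > 0:
        c = (np.asarray(shape) - 1) / 2.0
        r = spec.envelope_radius_frac * np.asarray(shape)
        envelope = sum(((grid[a] - c[a]) / r[a]) ** 2 for a in range(3)) <= 1.0
        image = np.where(envelope, spec.background_intensity, 0.0)
    else:
        image = np.full(shape, spec.background_intensity, dtype=np.float64)
    for s in spec.structures:
        image[labels == s.label] = s.intensity
    if spec.smooth_sigma > 0:
        image = gaussian_filter(image, spec.smooth_sigma, mode="nearest")
    if spec.bias_amplitude > 0:
        image = image * _bias_field(shape, spec.bias_amplitude, rng)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)
    return VolumeImage(image), LabelVolume(labels)


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * (random quadratic polynomial)."""
    grid = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(np.float64)
    coords = [(grid[a] / (shape[a] - 1)) * 2.0 - 1.0 for a in range(3)]
    coeffs = rng.uniform(-1.0, 1.0, size=9)
    poly = (
        coeffs[0] * coords[0]
        + coeffs[1] * coords[1]
        + coeffs[2] * coords[2]
        + coeffs[3] * coords[0] * coords[1]
        + coeffs[4] * coords[0] * coords[2]
        + coeffs[5] * coords[1] * coords[2]
        + coeffs[6] * coords[0] ** 2
        + coeffs[7] * coords[1] ** 2
        + coeffs[8] * coords[2] ** 2
    )
    peak = np.abs(poly).max()
    if peak > 0:
        poly = poly / peak
    return 1.0 + amplitude * poly


def random_smooth_field(
    shape: tuple[int, int, int],
    max_disp: float,
    smoothness_sigma: float,
    seed: int,
) -> DisplacementField:
    """Random coarse-grid vectors, Gaussian-smoothed and rescaled to a
    given maximum displacement magnitude.

    Drawing the randomness on a coarse control grid (node spacing ~
    ``smoothness_sigma``) keeps the number of degrees of freedom small, so
    the typical displacement is commensurate with the maximum instead of
    the maximum being a rare noise spike.
    """
    if max_disp < 0:
        raise ValidationError("max_disp must be >= 0")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    if max_disp == 0:
        return DisplacementField(np.zeros(shape + (3,)))
    spacing = max(smoothness_sigma, 1.0)
    coarse = tuple(max(3, int(np.ceil(s / spacing)) + 1) for s in shape)
    u = np.empty(shape + (3,))
    for c in range(3):
        nodes = rng.normal(0.0, 1.0, size=coarse)
        comp = zoom(nodes, [s / cs for s, cs in zip(shape, coarse)], order=3, mode="nearest", grid_mode=True)
        u[..., c] = gaussian_filter(comp, smoothness_sigma / 2.0, mode="nearest")
    mag = np.sqrt((u**2).sum(axis=-1)).max()
    if mag > 0:
        u *= max_disp / mag
    return DisplacementField(u)


def _sample_field_at(u: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Sample vector field u at x + offsets(x), nearest-edge extension."""
    shape = u.shape[:3]
    coords = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(np.float64)
    coords += np.moveaxis(offsets, -1, 0)
    out = np.empty_like(u)
    for c in range(3):
        out[..., c] = map_coordinates(u[..., c], coords, order=1, mode="nearest")
    return out


def exponential_field(velocity: DisplacementField, n_squarings: int = 6) -> DisplacementField:
    """Group exponential of a stationary velocity field via scaling and squaring.

    The returned displacement is the flow of ``velocity`` for unit time:
    invertible by construction (no folding), with ``exponential_field(-v)``
    its inverse up to discretization error.  Used for the large
    between-mode deformations, whose raw Gaussian-noise counterparts can
    have Jacobian norms above 1 and hence no reliable inverse.
    """
    w = velocity.data / float(2**n_squarings)
    for _ in range(n_squarings):
        w = w + _sample_field_at(w, w)
    return DisplacementField(w, velocity.spacing, velocity.origin)


def compose_fields(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Pull-back composition: warping by the result equals warping by
    ``inner`` first, then ``outer`` applied in the moving space —
    ``c(x) = inner(x) + outer(x + inner(x))``."""
    if outer.grid_shape != inner.grid_shape:
        raise ValidationError("fields must share a grid to compose")
    c = inner.data + _sample_field_at(outer.data, inner.data)
    return DisplacementField(c, inner.spacing, inner.origin)


def invert_field(fld: DisplacementField, n_iter: int = 20) -> DisplacementField:
    """Fixed-point inverse: v with v(x) = -u(x + v(x)).

    Converges when the displacement's Jacobian norm stays below 1
    (e.g. the small within-mode fields); large deformations should be
    built through ``exponential_field`` and inverted by negating the
    velocity instead.
    """
    v = -fld.data.copy()
    for _ in range(n_iter):
        v = -_sample_field_at(fld.data, v)
    return DisplacementField(v, fld.spacing, fld.origin)


def true_pairwise_field(
    c_i: DisplacementField, c_j: DisplacementField, n_iter: int = 20
) -> DisplacementField:
    """Ground-truth i -> j field for members generated as warps of one base.

    With member_k(x) = base(x + c_k(x)), the field f with
    ``warp(member_i, f) ≈ member_j`` is ``f(x) = c_j(x) + inv(c_i)(x + c_j(x))``.
    """
    v = invert_field(c_i, n_iter)
    f = c_j.data + _sample_field_at(v.data, c_j.data)
    return DisplacementField(f, c_j.spacing, c_j.origin)


def make_population(pspec: PopulationSpec) -> Population:
    """Generate a two-tier atlas population from one base anatomy.

    Deformations are flows of smooth random stationary velocity fields
    (``exponential_field``), so every ground-truth field has an exact
    inverse through the negated velocity; the displacement parameters set
    the velocity amplitude, which for these smooth flows approximates the
    resulting maximum displacement.

    Imaging follows acquisition physics per scan: the crisp base anatomy
    is deformed first, and only then does each scan — subject included —
    receive its own residual bias field, partial-volume (PSF) smoothing
    and noise realization.  This keeps every scan equally blurred; were
    the smoothing baked into the shared base instead, the mildly deformed
    subject would stay systematically sharper than the mode-deformed
    members, an asymmetry no real population has.
    """
    crisp_spec = PhantomSpec(
        grid_shape=pspec.base.grid_shape,
        structures=pspec.base.structures,
        background_intensity=pspec.base.background_intensity,
        envelope_radius_frac=pspec.base.envelope_radius_frac,
        smooth_sigma=0.0,
        bias_amplitude=0.0,
        noise_sd=0.0,
        seed=pspec.base.seed,
    )
    crisp_img, base_lab = make_phantom(crisp_spec)
    rng = np.random.default_rng(pspec.seed)
    shape = crisp_img.shape

    def flow_pair(max_disp: float) -> tuple[DisplacementField, DisplacementField]:
        v = random_smooth_field(shape, max_disp, pspec.field_sigma, int(rng.integers(2**31)))
        neg = DisplacementField(-v.data, v.spacing, v.origin)
        return exponential_field(v), exponential_field(neg)

    def acquire(anatomy: VolumeImage) -> VolumeImage:
        img = anatomy.data
        if pspec.residual_bias > 0:
            img = img * _bias_field(shape, pspec.residual_bias, rng)
        if pspec.base.smooth_sigma > 0:
            img = gaussian_filter(img, pspec.base.smooth_sigma, mode="nearest")
        img = img + rng.normal(0.0, pspec.base.noise_sd, size=shape)
        return VolumeImage(img, anatomy.spacing, anatomy.origin)

    # Draw the mode velocities up front and equalize their harmonic energy
    # (mean scale preserved): rescaling by maximum displacement alone leaves
    # the shape-distance of the modes to the base spread by tens of percent,
    # i.e. the cluster structure would not be controlled.
    from .similarity import harmonic_energy

    mode_velocities = [
        random_smooth_field(shape, pspec.between_mode_disp, pspec.field_sigma, int(rng.integers(2**31)))
        for _ in range(pspec.k_modes)
    ]
    energies = np.array([harmonic_energy(v) for v in mode_velocities])
    target = energies.mean()
    mode_flows = []
    for v, e in zip(mode_velocities, energies):
        scaled = DisplacementField(v.data * (target / e), v.spacing, v.origin)
        neg = DisplacementField(-scaled.data, v.spacing, v.origin)
        mode_flows.append((exponential_field(scaled), exponential_field(neg)))

    members: list[tuple[VolumeImage, LabelVolume]] = []
    mode_assignment: list[int] = []
    true_fields: list[DisplacementField] = []
    inverse_fields: list[DisplacementField] = []
    for mode in range(pspec.k_modes):
        mode_field, mode_inv = mode_flows[mode]
        for _ in range(pspec.per_mode):
            member_field, member_inv = flow_pair(pspec.within_mode_disp)
            composed = compose_fields(mode_field, member_field)
            inverse = compose_fields(member_inv, mode_inv)
            members.append(
                (acquire(warp(crisp_img, composed, "linear")), warp(base_lab, composed, "nearest"))
            )
            mode_assignment.append(mode)
            true_fields.append(composed)
            inverse_fields.append(inverse)
    subject_field, _ = flow_pair(pspec.within_mode_disp)
    subject_image = acquire(warp(crisp_img, subject_field, "linear"))
    subj_lab = warp(base_lab, subject_field, "nearest")
    return Population(
        subject_image,
        subj_lab,
        subject_field,
        members,
        mode_assignment,
        true_fields,
        inverse_fields,
        pspec,
    )


def oracle_registrations(
    pop: Population,
    atlas_ids: list[str] | None = None,
    subject_id: str = "subject",
):
    """Ground-truth pairwise fields for every atlas->atlas and atlas->subject
    pair, keyed like the pipeline's registration table."""
    from .registration import RegistrationResult

    n = len(pop.members)
    ids = atlas_ids or [f"atlas{i:02d}" for i in range(n)]
    if len(ids) != n:
        raise ValidationError("atlas_ids length must match population size")
    inverses = pop.inverse_fields
    c_s = pop.subject_field
    regs: dict[tuple[str, str], RegistrationResult] = {}
    for i in range(n):
        f_s = c_s.data + _sample_field_at(inverses[i].data, c_s.data)
        regs[(ids[i], subject_id)] = RegistrationResult(
            DisplacementField(f_s, c_s.spacing, c_s.origin),
            moving_id=ids[i],
            fixed_id=subject_id,
        )
        for j in range(n):
            if i == j:
                continue
            c_j = pop.true_fields[j]
            f = c_j.data + _sample_field_at(inverses[i].data, c_j.data)
            regs[(ids[i], ids[j])] = RegistrationResult(
                DisplacementField(f, c_j.spacing, c_j.origin),
                moving_id=ids[i],
                fixed_id=ids[j],
            )
    return regs
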