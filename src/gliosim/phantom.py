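"""Synthetic brain phantoms: geometry, DTI-like tensors, seeds, calendars.

Clinical post-surgery MR data (registered label maps, DTI, serial tumor
delineations) cannot be redistributed, so every other module is exercised
against parametric-analytic phantoms built here: an ellipsoidal brain with
a gray-matter cortical ribbon, white-matter interior, CSF ventricles, an
optional resection cavity, fiber bundles that orient the white-matter
tensors, and the standard post-surgery therapy calendars (60 Gy in 30
daily 2 Gy fractions; six 5-day temozolomide cycles every 28 days).

Geometry is spheres, tubes and shells only — exactly reproducible, no
atlas download, no MRI intensity simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fields import CAVITY, CSF, GM, OUTSIDE, WM, DensityField, LabeledVolume, TensorField
from .therapy import ChemotherapyPlan, RadiotherapyPlan

# Standard-of-care calendars (per-protocol constants, day units).
RT_N_FRACTIONS = 30
RT_DOSE_PER_FRACTION_GY = 2.0
CHEMO_N_CYCLES = 6
CHEMO_ACTIVE_DAYS_PER_CYCLE = 5
CHEMO_CYCLE_PERIOD_DAYS = 28


@dataclass
class FiberBundle:
    """Straight fiber bundle: a tube around the segment ``start -> end``.

    ``start``/``end`` are voxel-index coordinates; ``radius`` is the
    Gaussian falloff scale of the anisotropy (voxels, in world-mm metric);
    ``anisotropy`` is the principal-to-transverse eigenvalue ratio at the
    bundle core.
    """

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float = 4.0
    anisotropy: float = 5.0


@dataclass
class PhantomSpec:
    """Parametric description of a brain phantom.

    All centers/radii are in voxel-index units unless noted; radii must fit
    inside the grid.  A fixed seed makes the phantom bit-identical across
    runs (the default geometry is fully deterministic; the seed is kept on
    the spec so randomized phantom families are reproducible too).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_margin: int = 2  # voxels between brain surface and grid edge
    cortex_thickness: int = 2  # GM ribbon thickness, voxels
    ventricle_centers: tuple = ()  # CSF spheres: ((center, radius), ...)
    fibers: tuple[FiberBundle, ...] = ()
    cavity_center: tuple[float, float, float] | None = None
    cavity_radius: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        shape = np.asarray(self.shape)
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError(f"shape must be 3 axes of length >= 4, got {self.shape}")
        if self.brain_margin < 0 or self.cortex_thickness < 1:
            raise ValueError("brain_margin >= 0 and cortex_thickness >= 1 required")
        for center, radius in self.ventricle_centers:
            if np.any(np.asarray(center) - radius < 0) or np.any(
                np.asarray(center) + radius > shape - 1
            ):
                raise ValueError(f"ventricle at {center} r={radius} exceeds the grid")
        if self.cavity_radius < 0:
            raise ValueError("cavity radius must be non-negative")
        if self.cavity_center is not None and self.cavity_radius > 0:
            c = np.asarray(self.cavity_center)
            if np.any(c - self.cavity_radius < 0) or np.any(
                c + self.cavity_radius > shape - 1
            ):
                raise ValueError("cavity exceeds the grid")


def default_spec(shape=(64, 64, 64), with_cavity: bool = True, seed: int = 0) -> PhantomSpec:
    """A mid-size phantom with ventricles, one fiber bundle and a cavity."""
    n = np.asarray(shape, dtype=float)
    c = (n - 1) / 2
    spec = PhantomSpec(
        shape=tuple(shape),
        ventricle_centers=(
            ((c[0] - n[0] * 0.08, c[1], c[2]), n.min() * 0.08),
            ((c[0] + n[0] * 0.08, c[1], c[2]), n.min() * 0.08),
        ),
        fibers=(
            FiberBundle(
                start=(n[0] * 0.2, c[1], c[2] + n[2] * 0.18),
                end=(n[0] * 0.8, c[1], c[2] + n[2] * 0.18),
                radius=max(2.0, n.min() * 0.06),
                anisotropy=5.0,
            ),
        ),
        cavity_center=tuple(c + n * 0.16) if with_cavity else None,
        cavity_radius=n.min() * 0.09 if with_cavity else 0.0,
        seed=seed,
    )
    return spec


def random_spec(rng: np.random.Generator, shape=(16, 16, 16)) -> PhantomSpec:
    """Random small phantom for stress/stability sweeps (seeded)."""
    n = np.asarray(shape, dtype=float)
    c = (n - 1) / 2
    theta = rng.uniform(0, np.pi)
    phi = rng.uniform(0, 2 * np.pi)
    axis = np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    half = axis * n.min() * 0.3
    return PhantomSpec(
        shape=tuple(shape),
        ventricle_centers=(((tuple(c + rng.uniform(-2, 2, 3))), n.min() * 0.1),),
        fibers=(
            FiberBundle(
                start=tuple(c - half),
                end=tuple(c + half),
                radius=rng.uniform(1.5, n.min() * 0.2),
                anisotropy=rng.uniform(2.0, 5.0),
            ),
        ),
        cavity_center=None,
        cavity_radius=0.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _index_grid(shape) -> np.ndarray:
    """Voxel-index coordinates, shape (nx, ny, nz, 3)."""
    axes = [np.arange(s, dtype=float) for s in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def make_brain_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Build the tissue label map described by ``spec``.

    The brain is the ellipsoid inscribed in the grid minus ``brain_margin``;
    its outermost ``cortex_thickness`` voxels are GM, the interior is WM,
    ventricle spheres are CSF and the cavity sphere is CAVITY.  The result
    is deterministic for a fixed spec.
    """
    spec.validate()
    shape = spec.shape
    coords = _index_grid(shape)
    center = (np.asarray(shape, dtype=float) - 1) / 2
    semi = center - spec.brain_margin
    if np.any(semi <= spec.cortex_thickness):
        raise ValueError("brain ellipsoid too small for the cortical ribbon")

    # Ellipsoidal brain: normalized radius <= 1.
    r2 = (((coords - center) / semi) ** 2).sum(axis=-1)
    brain = r2 <= 1.0

    labels = np.full(shape, OUTSIDE, dtype=np.int16)
    labels[brain] = WM

    # GM ribbon: brain voxels within cortex_thickness of the surface
    # (Euclidean distance in voxels from the outside).
    dist_in = ndimage.distance_transform_edt(brain)
    labels[brain & (dist_in <= spec.cortex_thickness)] = GM

    for vcenter, vradius in spec.ventricle_centers:
        d2 = ((coords - np.asarray(vcenter, dtype=float)) ** 2).sum(axis=-1)
        labels[(d2 <= vradius**2) & brain] = CSF

    if spec.cavity_center is not None and spec.cavity_radius > 0:
        d2 = ((coords - np.asarray(spec.cavity_center, dtype=float)) ** 2).sum(axis=-1)
        labels[(d2 <= spec.cavity_radius**2) & brain] = CAVITY

    return LabeledVolume(labels, spec.spacing)


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Distance from each point to segment ab and the (unit) tangent."""
    ab = b - a
    L2 = float(ab @ ab)
    if L2 == 0:
        t = np.zeros(points.shape[:-1])
        tangent = np.array([1.0, 0.0, 0.0])
    else:
        t = np.clip(((points - a) @ ab) / L2, 0.0, 1.0)
        tangent = ab / np.sqrt(L2)
    nearest = a + t[..., None] * ab
    return np.linalg.norm(points - nearest, axis=-1), tangent


def _orthonormal_frame(tangent: np.ndarray) -> np.ndarray:
    """Rotation matrix whose first column is ``tangent``."""
    t = tangent / np.linalg.norm(tangent)
    helper = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    n1 = np.cross(t, helper)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(t, n1)
    return np.stack([t, n1, n2], axis=1)


def make_tensor_field(vol: LabeledVolume, spec: PhantomSpec) -> TensorField:
    """DTI-like raw tensor field matching the phantom geometry.

    All tensors are trace-normalized to 1 (unitless, like a normalized
    water-diffusion tensor).  GM and off-bundle WM are isotropic (I/3);
    WM voxels near a fiber bundle get a cigar-shaped tensor whose principal
    eigenvector follows the bundle tangent, with the principal-to-transverse
    ratio relaxing from ``bundle.anisotropy`` at the core to 1 with a
    Gaussian falloff of scale ``bundle.radius``.  CSF, CAVITY and OUTSIDE
    voxels carry the zero tensor: water diffusion is not a migration
    substrate there, and glioma invasion stops at CSF.
    """
    if vol.shape != tuple(spec.shape):
        raise ValueError("volume and spec shapes differ")
    shape = vol.shape
    coords = _index_grid(shape) * np.asarray(vol.spacing)

    matrices = np.zeros(shape + (3, 3), dtype=float)
    iso = np.eye(3) / 3.0
    tissue = vol.mask(GM, WM)
    matrices[tissue] = iso

    wm = vol.labels == WM
    for bundle in spec.fibers:
        a = np.asarray(bundle.start, dtype=float) * np.asarray(vol.spacing)
        b = np.asarray(bundle.end, dtype=float) * np.asarray(vol.spacing)
        dist, tangent = _segment_distance(coords, a, b)
        # anisotropy ratio per voxel, >= 1
        radius_mm = bundle.radius * float(min(vol.spacing))
        ratio = 1.0 + (bundle.anisotropy - 1.0) * np.exp(-(dist**2) / (2 * radius_mm**2))
        frame = _orthonormal_frame(b - a if np.any(a != b) else np.array([1.0, 0, 0]))
        # trace-1 eigenvalues (lam1, lam2, lam2) with lam1/lam2 = ratio
        lam2 = 1.0 / (ratio + 2.0)
        lam1 = ratio * lam2
        affected = wm & (ratio > 1.0 + 1e-12)
        if not affected.any():
            continue
        eigs = np.zeros(shape + (3,), dtype=float)
        eigs[..., 0] = lam1
        eigs[..., 1] = lam2
        eigs[..., 2] = lam2
        local = np.einsum("ia,...a,ja->...ij", frame, eigs, frame)
        matrices[affected] = local[affected]

    return TensorField.from_matrices(matrices, vol.spacing)


def seed_tumor(
    vol: LabeledVolume, center, radius: float = 0.0, smooth_sigma: float = 0.0
) -> DensityField:
    """Initial tumor density: u = 1 on a ball intersected with GM+WM.

    ``center`` is in voxel indices, ``radius`` in mm (world metric).  A
    radius of 0 seeds the single center voxel.  ``smooth_sigma > 0``
    Gaussian-smooths the ball (voxel units) for solver studies where the
    discontinuous profile would be an artifact of the seed, not the model;
    growth tissue masking is re-applied after smoothing.  Seeding entirely
    inside CSF/cavity yields an all-zero field with a warning; a center
    outside the brain is an error.
    """
    center = np.asarray(center, dtype=float)
    idx = tuple(int(round(c)) for c in center)
    if any(i < 0 or i >= s for i, s in zip(idx, vol.shape)):
        raise ValueError(f"seed center {idx} outside the grid")
    if vol.labels[idx] == OUTSIDE:
        raise ValueError(f"seed center {idx} lies outside the brain")

    u = np.zeros(vol.shape, dtype=float)
    growth_tissue = vol.mask(GM, WM)
    if radius <= 0:
        ball = np.zeros(vol.shape, dtype=bool)
        ball[idx] = True
    else:
        coords = _index_grid(vol.shape) * np.asarray(vol.spacing)
        d = np.linalg.norm(coords - center * np.asarray(vol.spacing), axis=-1)
        ball = d <= radius
    u[ball & growth_tissue] = 1.0
    if smooth_sigma > 0:
        u = ndimage.gaussian_filter(u, sigma=smooth_sigma)
        u[~growth_tissue] = 0.0
    if not u.any():
        warnings.warn(
            "tumor seed does not intersect GM/WM; initial density is all zero",
            stacklevel=2,
        )
    return DensityField(u, vol.spacing, time=0.0)


def make_therapy_calendar(kind: str, start_day: int = 0, **overrides):
    """Standard post-surgery therapy calendar.

    ``kind='radiotherapy'`` gives 30 consecutive daily fractions of 2 Gy
    (60 Gy total) starting at ``start_day``; ``kind='chemotherapy'`` gives
    6 cycles of 5 active days with a 28-day cycle period (30 active days
    spanning 145 calendar days).  Keyword overrides pass through to the
    plan constructors (alpha, beta, k, ...).
    """
    if kind == "radiotherapy":
        days = list(range(start_day, start_day + RT_N_FRACTIONS))
        doses = [RT_DOSE_PER_FRACTION_GY] * RT_N_FRACTIONS
        return RadiotherapyPlan(fraction_days=days, doses=doses, **overrides)
    if kind == "chemotherapy":
        days = [
            start_day + cycle * CHEMO_CYCLE_PERIOD_DAYS + d
            for cycle in range(CHEMO_N_CYCLES)
            for d in range(CHEMO_ACTIVE_DAYS_PER_CYCLE)
        ]
        return ChemotherapyPlan(active_days=days, **overrides)
    raise ValueError(f"unknown therapy kind {kind!r}")
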