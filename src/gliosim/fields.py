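"""Voxel-grid containers shared by all stages of the growth model.

Three containers cover everything the simulator touches: a tissue label
map, a symmetric 3x3 tensor field (DTI input or the constructed growth
tensor), and the tumor cell density ``u`` expressed as a fraction of the
carrying capacity.  All grids are regular, voxel-centered and carry their
spacing in millimetres; world coordinates are ``index * spacing``.

Tensors are stored in the 6-component symmetric upper-triangle convention
``(xx, xy, xz, yy, yz, zz)`` — the same layout used for NIfTI round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Tissue label codes — a fixed file-level contract.
OUTSIDE = 0
CSF = 1
GM = 2
WM = 3
CAVITY = 4

LABEL_NAMES = {OUTSIDE: "outside", CSF: "csf", GM: "gm", WM: "wm", CAVITY: "cavity"}

#: index pairs of the symmetric upper triangle in storage order
SYM6_INDICES = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


def _check_spacing(spacing) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise ValueError(f"spacing must be 3 positive lengths (mm), got {spacing!r}")
    return sp


@dataclass
class LabeledVolume:
    """Per-voxel tissue class on a regular grid.

    Parameters
    ----------
    labels
        Integer array with codes ``OUTSIDE=0, CSF=1, GM=2, WM=3, CAVITY=4``.
    spacing
        Voxel size per axis, mm.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        bad = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if bad:
            raise ValueError(f"unknown label codes: {sorted(bad)}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, *codes: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given label codes."""
        return np.isin(self.labels, codes)

    @property
    def brain_mask(self) -> np.ndarray:
        """All intracranial voxels (everything except OUTSIDE)."""
        return self.labels != OUTSIDE

    def label_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 tensor stored as 6 upper-triangle components.

    ``components`` has shape ``grid_shape + (6,)`` in the order
    ``xx, xy, xz, yy, yz, zz``.  Units are mm^2/day for growth tensors and
    arbitrary for raw DTI.
    """

    components: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 4 or self.components.shape[-1] != 6:
            raise ValueError("components must have shape (nx, ny, nz, 6)")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]

    def component(self, i: int, j: int) -> np.ndarray:
        """The (i, j) tensor entry as a scalar volume (symmetry implied)."""
        if i > j:
            i, j = j, i
        return self.components[..., SYM6_INDICES.index((i, j))]

    def as_matrices(self) -> np.ndarray:
        """Dense representation, shape ``grid_shape + (3, 3)``."""
        m = np.empty(self.shape + (3, 3), dtype=float)
        for idx, (i, j) in enumerate(SYM6_INDICES):
            m[..., i, j] = self.components[..., idx]
            m[..., j, i] = self.components[..., idx]
        return m

    @classmethod
    def from_matrices(cls, matrices: np.ndarray, spacing) -> "TensorField":
        matrices = np.asarray(matrices, dtype=float)
        if matrices.shape[-2:] != (3, 3):
            raise ValueError("expected trailing (3, 3) matrix axes")
        comps = np.stack([matrices[..., i, j] for i, j in SYM6_INDICES], axis=-1)
        return cls(comps, spacing)

    @classmethod
    def isotropic(cls, value: np.ndarray, spacing) -> "TensorField":
        """Scalar field ``value`` promoted to ``value * I`` per voxel."""
        value = np.asarray(value, dtype=float)
        comps = np.zeros(value.shape + (6,), dtype=float)
        for idx, (i, j) in enumerate(SYM6_INDICES):
            if i == j:
                comps[..., idx] = value
        return cls(comps, spacing)

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues per voxel, ascending, shape ``grid_shape + (3,)``."""
        return np.linalg.eigvalsh(self.as_matrices())

    def max_eigenvalue(self) -> np.ndarray:
        return self.eigenvalues()[..., -1]

    def trace(self) -> np.ndarray:
        return self.component(0, 0) + self.component(1, 1) + self.component(2, 2)

    def is_admissible(self, tol: float = 1e-10) -> bool:
        """Symmetric by construction; check positive semi-definiteness."""
        return bool(np.all(self.eigenvalues() >= -tol))


@dataclass
class DensityField:
    """Tumor cell density ``u`` in [0, 1] (fraction of carrying capacity)."""

    u: np.ndarray
    spacing: tuple[float, float, float]
    time: float = 0.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3:
            raise ValueError("density must be a 3-D array")
        self.spacing = _check_spacing(self.spacing)
        if self.u.size and (self.u.min() < -1e-12 or self.u.max() > 1 + 1e-12):
            raise ValueError(
                f"density out of [0, 1]: min={self.u.min()}, max={self.u.max()}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def total_mass(self) -> float:
        """Integrated density (sum of u times voxel volume), mm^3."""
        return float(self.u.sum() * self.voxel_volume)
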