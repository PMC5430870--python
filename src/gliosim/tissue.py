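"""Growth diffusion tensors and tissue-derived fields.

Glioma cells migrate preferentially along white-matter fiber tracts, fast
in WM, slower in GM, and not at all through CSF.  The growth diffusion
tensor is built from a DTI-like tensor field by keeping the DTI
eigenvector frame and replacing the eigenvalues with tissue diffusivities:
in WM the principal direction gets ``e1 * D_WM`` (``e1`` the normalized
largest DTI eigenvalue) and the transverse directions get ``D_GM``; GM is
isotropic ``D_GM * I``; CSF, cavity and outside are zero.

A DTI-free scalar variant (``D_WM`` in WM, ``D_GM`` in GM) supports the
isotropic-model reduction, and the local WM-proportion field ``omega``
feeds the heterogeneity-weighted chemotherapy rate.

All diffusivities are handled internally in mm^2/day (inputs in the
conventional cm^2/day are converted; voxel spacing is in mm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import CSF, GM, WM, LabeledVolume, TensorField

logger = logging.getLogger(__name__)

CM2_TO_MM2 = 100.0

DEFAULT_D_GM_CM2_PER_DAY = 0.0013
DEFAULT_WM_TO_GM_RATIO = 5.0
DEFAULT_RHO_PER_DAY = 0.012


@dataclass
class TissueParams:
    """Tissue diffusivities and proliferation rate.

    ``d_gm`` and ``d_wm`` are in cm^2/day (the conventional literature
    unit); ``rho`` in day^-1.  Defaults are the consensus low-grade-glioma
    values: D_GM = 0.0013 cm^2/day, D_WM = 5 D_GM, rho = 0.012 day^-1.
    """

    d_gm: float = DEFAULT_D_GM_CM2_PER_DAY
    d_wm: float = DEFAULT_D_GM_CM2_PER_DAY * DEFAULT_WM_TO_GM_RATIO
    rho: float = DEFAULT_RHO_PER_DAY

    def __post_init__(self):
        if not (self.d_wm >= self.d_gm > 0):
            raise ValueError("require D_WM >= D_GM > 0")
        # rho = 0 is allowed for diagnostic pure-diffusion runs
        if self.rho < 0:
            raise ValueError("proliferation rate must be non-negative")

    @property
    def d_gm_mm2(self) -> float:
        """GM diffusivity in mm^2/day."""
        return self.d_gm * CM2_TO_MM2

    @property
    def d_wm_mm2(self) -> float:
        """WM diffusivity in mm^2/day."""
        return self.d_wm * CM2_TO_MM2


def _sorted_eigensystem(matrices: np.ndarray):
    """Eigendecomposition with eigenvalues sorted descending.

    ``np.linalg.eigh`` returns an ascending, deterministic decomposition; a
    stable descending argsort keeps ties in eigh's deterministic order (so a
    degenerate tensor such as the identity resolves to the coordinate basis
    with the x-axis first).
    """
    vals, vecs = np.linalg.eigh(matrices)
    order = np.argsort(-vals, axis=-1, kind="stable")
    vals = np.take_along_axis(vals, order, axis=-1)
    vecs = np.take_along_axis(vecs, order[..., None, :], axis=-1)
    return vals, vecs


def build_growth_tensor(
    dti: TensorField, vol: LabeledVolume, params: TissueParams
) -> TensorField:
    """Construct the growth tensor field from a raw DTI-like field.

    WM voxels: ``E diag(e1*D_WM, D_GM, D_GM) E^T`` with ``E`` the DTI
    eigenvector matrix (descending eigenvalues) and ``e1`` the largest DTI
    eigenvalue normalized by the maximum largest eigenvalue over WM.  GM:
    ``D_GM * I``.  CSF/CAVITY/OUTSIDE: zero.  WM voxels whose DTI has a
    negative eigenvalue (beyond round-off) are replaced by an isotropic
    fallback and counted in the log.
    """
    if dti.shape != vol.shape:
        raise ValueError("DTI and label volume shapes differ")
    d_gm = params.d_gm_mm2
    d_wm = params.d_wm_mm2

    out = np.zeros(vol.shape + (3, 3), dtype=float)
    gm = vol.labels == GM
    out[gm] = d_gm * np.eye(3)

    wm = vol.labels == WM
    if wm.any():
        mats = dti.as_matrices()[wm]
        vals, vecs = _sorted_eigensystem(mats)
        bad = vals[..., -1] < -1e-10  # most-negative eigenvalue per voxel
        n_bad = int(bad.sum())
        if n_bad:
            logger.warning(
                "replaced %d non-PSD DTI voxel(s) in WM by isotropic fallback", n_bad
            )
            iso = np.eye(3) / 3.0
            mats = mats.copy()
            mats[bad] = iso
            vals, vecs = _sorted_eigensystem(mats)
        lam1 = np.clip(vals[..., 0], 0.0, None)
        lam_max = float(lam1.max())
        if lam_max <= 0:
            raise ValueError("DTI has no positive eigenvalue in WM; cannot normalize")
        e1 = lam1 / lam_max
        diag = np.zeros(vals.shape[:-1] + (3,), dtype=float)
        diag[..., 0] = e1 * d_wm
        diag[..., 1] = d_gm
        diag[..., 2] = d_gm
        out[wm] = np.einsum("...ia,...a,...ja->...ij", vecs, diag, vecs)

    return TensorField.from_matrices(out, vol.spacing)


def scalar_diffusion_map(vol: LabeledVolume, params: TissueParams) -> np.ndarray:
    """DTI-free diffusivity map: D_WM in WM, D_GM in GM, 0 elsewhere (mm^2/day)."""
    d = np.zeros(vol.shape, dtype=float)
    d[vol.labels == GM] = params.d_gm_mm2
    d[vol.labels == WM] = params.d_wm_mm2
    return d


def wm_proportion(vol: LabeledVolume, window_radius: int = 1) -> np.ndarray:
    """Local WM proportion ``omega`` in a cubic window of side ``2r + 1``.

    The proportion is taken among brain voxels (GM/WM/CSF/cavity) inside
    the window, so the field is not diluted at the brain surface; voxels
    with no brain neighborhood get 0.
    """
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    size = 2 * int(window_radius) + 1
    wm = (vol.labels == WM).astype(float)
    brain = vol.brain_mask.astype(float)
    wm_count = ndimage.uniform_filter(wm, size=size, mode="constant")
    brain_count = ndimage.uniform_filter(brain, size=size, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = np.where(brain_count > 0, wm_count / brain_count, 0.0)
    return np.clip(omega, 0.0, 1.0)
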