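"""NIfTI readers/writers, plan serialization and the run manifest.

Volumes travel as NIfTI-1 with the voxel spacing in the header zooms and a
diagonal affine.  Label volumes are validated against the fixed label-code
contract, density volumes against the [0, 1] range, and tensor volumes are
stored as 6-component symmetric upper-triangle images in the order
``xx, xy, xz, yy, yz, zz`` (symmetry is implied by the storage, so a read
tensor is symmetric by construction; non-PSD voxels are repaired to an
isotropic fallback and counted).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import nibabel as nib
import numpy as np

from .fields import LABEL_NAMES, DensityField, LabeledVolume, TensorField

logger = logging.getLogger(__name__)


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_labels(vol: LabeledVolume, path) -> Path:
    img = nib.Nifti1Image(vol.labels.astype(np.int16), _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return Path(path)


def write_density(dens: DensityField, path) -> Path:
    img = nib.Nifti1Image(dens.u.astype(np.float64), _affine(dens.spacing))
    img.header.set_zooms(dens.spacing)
    nib.save(img, str(path))
    return Path(path)


def write_tensor(tf: TensorField, path) -> Path:
    img = nib.Nifti1Image(tf.components.astype(np.float64), _affine(tf.spacing))
    img.header.set_zooms(tf.spacing + (1.0,))
    nib.save(img, str(path))
    return Path(path)


def read_volume(path) -> LabeledVolume | DensityField:
    """Read a 3-D NIfTI as labels (integer dtype) or density (float dtype).

    Label volumes must use only the declared codes; density volumes must
    lie in [0, 1].  Violations raise with the offending voxel count.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if np.issubdtype(data.dtype, np.integer):
        bad = ~np.isin(data, list(LABEL_NAMES))
        if bad.any():
            raise ValueError(
                f"{path}: {int(bad.sum())} voxel(s) carry unknown label codes "
                f"{sorted(set(np.unique(data[bad])))}"
            )
        return LabeledVolume(data.astype(np.int16), spacing)
    out_of_range = (data < 0) | (data > 1)
    if out_of_range.any():
        raise ValueError(
            f"{path}: {int(out_of_range.sum())} density voxel(s) outside [0, 1] "
            f"(min={data.min():.4g}, max={data.max():.4g})"
        )
    return DensityField(data.astype(float), spacing)


def read_tensor(path, repair: bool = True) -> TensorField:
    """Read a 6-component symmetric tensor NIfTI.

    Voxels with negative eigenvalues (beyond round-off) are replaced by an
    isotropic tensor with the same trace (or zero for non-positive traces)
    when ``repair`` is set; the repaired count is logged.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError(
            f"{path}: expected a 4-D volume with 6 components, got {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    tf = TensorField(data, spacing)
    eigs = tf.eigenvalues()
    bad = eigs[..., 0] < -1e-10
    n_bad = int(bad.sum())
    if n_bad:
        if not repair:
            raise ValueError(f"{path}: {n_bad} non-PSD tensor voxel(s)")
        logger.warning("%s: repaired %d non-PSD tensor voxel(s)", path, n_bad)
        trace = np.clip(tf.trace()[bad], 0.0, None)
        comps = tf.components.copy()
        comps[bad] = 0.0
        for idx in (0, 3, 5):
            comps[..., idx][bad] = trace / 3.0
        tf = TensorField(comps, spacing)
        tf.n_repaired = n_bad
    else:
        tf.n_repaired = 0
    return tf


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Inventory of a CLI run: inputs, outputs, timing; written even on failure."""

    def __init__(self, command: str):
        from . import __version__

        self.data = {
            "command": command,
            "tool_version": __version__,
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "inputs": {},
            "outputs": [],
            "status": "running",
        }
        self._t0 = time.monotonic()

    def add_input(self, path) -> None:
        self.data["inputs"][str(path)] = sha256_of(path)

    def add_output(self, path) -> None:
        self.data["outputs"].append(str(path))

    def write(self, path, status: str = "ok") -> None:
        self.data["status"] = status
        self.data["elapsed_s"] = round(time.monotonic() - self._t0, 3)
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2)
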