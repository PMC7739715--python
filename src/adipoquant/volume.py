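"""Voxel-grid container and NIfTI-1 I/O.

All volumes in this package are 3-D (or 4-D for dynamic PET) arrays with
axial slices along the last spatial axis.  World coordinates follow
``world = index * spacing + origin`` on each axis; the affine written to
NIfTI is the corresponding diagonal matrix, so spacing and origin survive
a write/read roundtrip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np

Modality = Literal["MRI", "CT", "PET", "LABEL"]


@dataclass
class ImageVolume:
    """A scalar voxel grid with physical spacing and a modality tag.

    Parameters
    ----------
    voxels : ndarray
        3-D array ``(nx, ny, n_slices)``, or 4-D ``(nx, ny, n_slices, n_frames)``
        for dynamic PET.  MRI voxels are arbitrary intensity units, CT voxels
        Hounsfield units, PET voxels kBq/ml.
    spacing_mm : tuple of float
        (in-plane, in-plane, slice pitch) in millimetres.  The slice value is
        the centre-to-centre pitch, not the slice thickness, so that
        volume integration represents contiguous anatomy.
    origin_mm : tuple of float
        World coordinate of voxel (0, 0, 0).
    modality : {"MRI", "CT", "PET", "LABEL"}
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.1719, 1.1719, 7.2)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = "MRI"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim not in (3, 4):
            raise ValueError(
                f"voxels must be 3-D or 4-D, got {self.voxels.ndim}-D"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        """In-plane pixel area times slice pitch."""
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def slice2d(self, k: int) -> np.ndarray:
        """Axial slice ``k`` as a 2-D array."""
        return self.voxels[:, :, k]

    def with_voxels(self, voxels: np.ndarray, modality: Modality | None = None) -> "ImageVolume":
        """Copy of this volume carrying new voxel data (same geometry)."""
        out = replace(self, voxels=voxels)
        if modality is not None:
            out.modality = modality
        return out


def _affine(volume: ImageVolume) -> np.ndarray:
    aff = np.diag(list(volume.spacing_mm) + [1.0])
    aff[:3, 3] = volume.origin_mm
    return aff


_MODALITY_KEY = {"MRI": 0, "CT": 1, "PET": 2, "LABEL": 3}
_KEY_MODALITY = {v: k for k, v in _MODALITY_KEY.items()}


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz).

    Integer arrays (label masks) are stored as int16 and survive bit-exactly;
    everything else is stored as float32 for MRI/CT/PET or float64 when the
    data is float64.  The modality tag is stashed in the NIfTI
    ``intent_code``-adjacent free field (``descrip``).
    """
    vox = volume.voxels
    if np.issubdtype(vox.dtype, np.integer) or vox.dtype == bool:
        vox = vox.astype(np.int16)
    img = nib.Nifti1Image(vox, _affine(volume))
    img.header["descrip"] = f"adipoquant:{volume.modality}".encode()
    zooms = list(volume.spacing_mm) + ([1.0] if vox.ndim == 4 else [])
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_volume(path: str | Path, modality: Modality | None = None) -> ImageVolume:
    """Read a NIfTI-1 volume written by :func:`write_volume` (or any NIfTI).

    Raises a ``ValueError`` naming the file for anything nibabel cannot parse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
        vox = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several header error types
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if vox.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3-D or 4-D NIfTI, got {vox.ndim}-D")
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    if modality is None:
        descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="ignore")
        if descrip.startswith("adipoquant:"):
            modality = descrip.split(":", 1)[1]  # type: ignore[assignment]
        else:
            modality = "MRI"
    return ImageVolume(vox, spacing, origin, modality)
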