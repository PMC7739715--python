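"""CT-based adipose VOIs: connected HU thresholding and spillover erosion."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from ..volume import ImageVolume

#: Hounsfield-unit window of adipose tissue (inclusive at both ends).
ADIPOSE_HU_RANGE = (-150.0, -50.0)


def segment_adipose_voi_ct(
    ct: ImageVolume,
    seed_point: tuple[int, int, int],
    hu_range: tuple[float, float] = ADIPOSE_HU_RANGE,
) -> np.ndarray:
    """Connected-threshold adipose segmentation on CT.

    Returns the 26-connected component of voxels with
    ``hu_range[0] <= HU <= hu_range[1]`` containing ``seed_point``.
    """
    hu = ct.voxels
    i, j, k = (int(c) for c in seed_point)
    seed_hu = float(hu[i, j, k])
    lo, hi = hu_range
    if not (lo <= seed_hu <= hi):
        raise ValueError(
            f"seed voxel HU = {seed_hu:.1f} outside adipose range [{lo}, {hi}]"
        )
    band = (hu >= lo) & (hu <= hi)
    labels, _ = ndimage.label(band, structure=np.ones((3, 3, 3), dtype=int))
    return labels == labels[i, j, k]


def erode_voi(mask: np.ndarray, pixels: int = 2) -> np.ndarray:
    """Per-slice 2-D erosion by a disc of the given pixel radius.

    Applied to every VOI before transfer to PET to avoid spillover from
    adjacent structures.  The result is always a subset of the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if pixels <= 0:
        return mask.copy()
    selem = disk(pixels)
    out = np.zeros_like(mask)
    for k in range(mask.shape[2]):
        out[:, :, k] = ndimage.binary_erosion(mask[:, :, k], structure=selem)
    return out


def mean_voi_activity(pet: ImageVolume, voi: np.ndarray) -> float:
    """Mean activity of a (3-D, single-frame) PET volume over a VOI."""
    voi = np.asarray(voi, dtype=bool)
    if not voi.any():
        raise ValueError("VOI is empty")
    return float(pet.voxels[voi].mean())
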