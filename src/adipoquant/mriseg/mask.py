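"""Foreground (body) masking."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from ..volume import ImageVolume


def body_mask(volume: ImageVolume) -> np.ndarray:
    """Largest connected foreground component per slice, holes filled.

    The foreground threshold is a single Otsu cut on the whole volume
    (background air vs tissue).  A slice with no foreground yields an empty
    mask slice with a warning rather than an error.
    """
    if volume.modality != "MRI":
        raise ValueError(f"body masking expects an MRI volume, got {volume.modality}")
    vox = volume.voxels.astype(float)
    if np.ptp(vox) == 0:
        raise ValueError("constant volume: no foreground to mask")
    thresh = threshold_otsu(vox)
    out = np.zeros(vox.shape, dtype=bool)
    for k in range(vox.shape[2]):
        fg = vox[:, :, k] > thresh
        if not fg.any():
            warnings.warn(f"slice {k} has no foreground; empty body mask", RuntimeWarning)
            continue
        labels, n = ndimage.label(fg)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            fg = labels == keep
        out[:, :, k] = ndimage.binary_fill_holes(fg)
    return out
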