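"""Intensity bias-field correction.

Scanner shading is modelled as a smooth multiplicative field per axial
slice.  Because subcutaneous and visceral fat share one true T1 intensity,
the field is estimated from the bright (fat-like) voxels only: a degree-4
polynomial is fitted to their log-intensities and divided out of the whole
slice, then rescaled so the mean foreground intensity is preserved.
Estimating on a single tissue class keeps anatomy (the fat/muscle contrast)
out of the fitted field.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from ..volume import ImageVolume


def _poly_design(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(x)]
    for total in range(1, degree + 1):
        for px in range(total + 1):
            cols.append(x**px * y ** (total - px))
    return np.stack(cols, axis=-1)


def correct_bias(volume: ImageVolume, degree: int = 4) -> ImageVolume:
    """Divide out a per-slice log-domain polynomial bias field.

    Raises if a slice has no foreground.  A constant slice is returned
    unchanged (nothing to correct).
    """
    if volume.modality != "MRI":
        raise ValueError(f"bias correction expects an MRI volume, got {volume.modality}")
    vox = volume.voxels.astype(float)
    out = np.empty_like(vox)
    n = vox.shape[0]
    c = (n - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(vox.shape[0]), np.arange(vox.shape[1]), indexing="ij")
    xn = (ii - c) / max(c, 1.0)
    yn = (jj - c) / max(c, 1.0)

    for k in range(vox.shape[2]):
        sl = vox[:, :, k]
        if np.ptp(sl) == 0:
            out[:, :, k] = sl
            continue
        fg_thresh = threshold_otsu(sl)
        foreground = sl > fg_thresh
        if not foreground.any():
            raise ValueError(f"slice {k}: no foreground voxels above Otsu threshold")
        fg_vals = sl[foreground]
        if np.ptp(fg_vals) == 0:
            out[:, :, k] = sl
            continue
        # bright (fat-like) voxels within the foreground
        bright = sl > threshold_otsu(fg_vals)
        if bright.sum() < 30:  # too few samples to support a degree-4 fit
            bright = foreground
        logv = np.log(np.maximum(sl[bright], 1e-6))
        design = _poly_design(xn[bright], yn[bright], degree)
        coef, *_ = np.linalg.lstsq(design, logv, rcond=None)
        full = _poly_design(xn.ravel(), yn.ravel(), degree) @ coef
        field = np.exp(full.reshape(sl.shape))
        field /= field[bright].mean()  # unit-mean field over the estimation voxels
        # guard against wild polynomial extrapolation outside the body
        field = np.clip(field, 1.0 / 3.0, 3.0)
        corrected = sl / field
        mean_before = sl[foreground].mean()
        mean_after = corrected[foreground].mean()
        if mean_after != 0:
            corrected *= mean_before / mean_after
        out[:, :, k] = corrected
    return volume.with_voxels(out)
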