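"""End-to-end MRI depot segmentation.

Chains the stages: bias correction -> body mask -> per-slice polar
unrolling and circular boundary detection of the subcutaneous annulus ->
k-means thresholding of the internal compartment -> exclusion of manually
supplied liver / bone-marrow masks -> anatomical slice selection ->
volume-to-mass conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..volume import ImageVolume
from .bias import correct_bias
from .boundary import BoundaryCurve, detect_sat_boundaries
from .depots import DepotMask, DepotMass, mask_to_mass, restrict_to_slices, select_slices
from .mask import body_mask
from .polar import mask_inside_curve, sat_mask_from_boundaries, unroll_slice
from .threshold import kmeans_threshold, segment_internal_fat


@dataclass
class SegmentationResult:
    masses: dict[str, DepotMass]
    depot_masks: dict[str, DepotMask]
    threshold: float
    sat_mask: np.ndarray
    internal_mask: np.ndarray
    boundaries: list[tuple[BoundaryCurve, BoundaryCurve] | None]


def segment_depots(
    mri: ImageVolume,
    landmarks: dict[str, int],
    region: str = "abdomen",
    liver_mask: np.ndarray | None = None,
    marrow_mask: np.ndarray | None = None,
    seed: int = 0,
    delta: int = 2,
    n_angles: int = 360,
    bias_degree: int = 4,
) -> SegmentationResult:
    """Segment all depots of one scan and convert them to masses.

    ``liver_mask`` (abdomen) and ``marrow_mask`` (thigh) are externally
    supplied exclusion masks, mirroring manual liver segmentation and the
    separate bone-marrow delineation.
    """
    corrected = correct_bias(mri, degree=bias_degree)
    body = body_mask(corrected)
    nx, ny, n_slices = corrected.voxels.shape

    sat3d = np.zeros_like(body)
    internal3d = np.zeros_like(body)
    boundaries: list[tuple[BoundaryCurve, BoundaryCurve] | None] = []
    for k in range(n_slices):
        bslice = body[:, :, k]
        if not bslice.any():
            boundaries.append(None)
            continue
        ci, cj = ndimage.center_of_mass(bslice)
        polar = unroll_slice(
            corrected.slice2d(k),
            (ci, cj),
            n_angles=n_angles,
            pixel_size_mm=corrected.spacing_mm[0],
        )
        outer, inner = detect_sat_boundaries(polar, delta=delta)
        sat3d[:, :, k] = sat_mask_from_boundaries(outer, inner, polar) & bslice
        internal3d[:, :, k] = mask_inside_curve(inner, polar) & bslice & ~sat3d[:, :, k]
        boundaries.append((outer, inner))

    internal_vals = corrected.voxels[internal3d]
    threshold = kmeans_threshold(internal_vals, k=5, seed=seed)
    exclusions = [m for m in (liver_mask, marrow_mask) if m is not None]
    internal_fat = segment_internal_fat(
        corrected.voxels, internal3d, threshold, exclusions, sat_mask=sat3d
    )

    if region == "abdomen":
        plan = {"abdominal_sat": sat3d, "visceral": internal_fat}
    elif region == "thigh":
        plan = {"femoral_sat": sat3d, "inter_muscular": internal_fat}
        if marrow_mask is not None:
            plan["bone_marrow"] = np.asarray(marrow_mask, dtype=bool)
    else:
        raise ValueError(f"region must be 'abdomen' or 'thigh', got {region!r}")

    depot_masks: dict[str, DepotMask] = {}
    masses: dict[str, DepotMass] = {}
    for depot, mask in plan.items():
        rng_sl = select_slices(n_slices, landmarks, depot)
        dm = restrict_to_slices(mask, rng_sl, depot)
        depot_masks[depot] = dm
        masses[depot] = mask_to_mass(dm, corrected.spacing_mm)
    return SegmentationResult(
        masses=masses,
        depot_masks=depot_masks,
        threshold=threshold,
        sat_mask=sat3d,
        internal_mask=internal3d,
        boundaries=boundaries,
    )
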