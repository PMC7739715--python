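"""Intensity thresholding of the internal compartment.

Visceral and inter-muscular fat are delineated by a single intensity cut
derived from a 5-component 1-D k-means clustering of the internal
(muscular/abdominal) compartment.  With the bright-fat T1 contrast the
sorted cluster centres split into lower (muscle/organ) and upper (fat)
groups; the default rule places the threshold at the midpoint between the
3rd and 4th sorted centres, i.e. fat is everything above the median
cluster.  Taking the median centre itself is available as an alternative
interpretation but sits inside the muscle intensity mode whenever fat is a
minority of the compartment.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from sklearn.cluster import KMeans


def kmeans_threshold(
    intensities: np.ndarray,
    k: int = 5,
    seed: int | None = 0,
    n_restarts: int = 10,
    interpretation: Literal["above_median_cluster", "median_center"] = "above_median_cluster",
) -> float:
    """Threshold from a k-component 1-D k-means of the compartment voxels.

    Deterministic given ``seed``; requires at least ``k`` distinct values.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if len(np.unique(x)) < k:
        raise ValueError(f"need at least {k} distinct intensities, got {len(np.unique(x))}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(x.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())
    mid = k // 2
    if interpretation == "median_center":
        return float(centers[mid])
    return float((centers[mid] + centers[mid + 1]) / 2.0)


def segment_internal_fat(
    volume_voxels: np.ndarray,
    internal_mask: np.ndarray,
    threshold: float,
    exclusion_masks: list[np.ndarray] | None = None,
    sat_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Voxels of the internal compartment above threshold, minus exclusions.

    ``exclusion_masks`` (manually segmented liver, separately delineated
    bone marrow) are removed after thresholding.  If ``sat_mask`` is given
    it must be disjoint from the internal compartment.
    """
    internal = np.asarray(internal_mask, dtype=bool)
    if sat_mask is not None and (internal & np.asarray(sat_mask, dtype=bool)).any():
        raise ValueError("internal compartment overlaps the subcutaneous mask")
    fat = internal & (np.asarray(volume_voxels) > threshold)
    for excl in exclusion_masks or []:
        fat &= ~np.asarray(excl, dtype=bool)
    return fat
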