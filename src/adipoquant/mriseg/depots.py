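"""Depot definitions: anatomical slice selection and volume-to-mass conversion."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ADIPOSE_DENSITY_KG_PER_L = 0.9

DEPOTS = ("abdominal_sat", "visceral", "femoral_sat", "inter_muscular", "bone_marrow")

# depot -> (upper landmark: first analyzed slice, lower landmark: first slice
# of the excluded structure; analyzed range is upper .. lower-1 inclusive)
_SLICE_RULES: dict[str, tuple[str, str]] = {
    "visceral": ("th11_th12_disc", "iliac_crest"),
    "abdominal_sat": ("th12_l1_disc", "caput_femoris"),
    "femoral_sat": ("gluteal_lower", "patella"),
    "inter_muscular": ("gluteal_lower", "patella"),
    "bone_marrow": ("gluteal_lower", "patella"),
}


@dataclass
class DepotMask:
    """Binary mask of one depot restricted to its analyzed slice range."""

    mask: np.ndarray
    depot: str
    slice_range: tuple[int, int]  # inclusive
    n_slices_analyzed: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        lo, hi = self.slice_range
        outside = self.mask.copy()
        outside[:, :, lo : hi + 1] = False
        if outside.any():
            raise ValueError(f"{self.depot}: mask has voxels outside slices {lo}..{hi}")


@dataclass(frozen=True)
class DepotMass:
    depot: str
    volume_L: float
    mass_kg: float  # = volume_L * 0.9 exactly
    n_slices_analyzed: int


def select_slices(
    n_slices: int,
    landmarks: dict[str, int],
    depot: str,
) -> tuple[int, int]:
    """Inclusive analyzed slice range for a depot from labeled landmarks.

    The upper delimiter (e.g. the Th11/Th12 disc for the visceral depot) is
    the first analyzed slice; the lower landmark marks the first slice
    containing the excluded structure (iliac crest, femoral head, patella),
    so analysis stops on the slice before it.
    """
    if depot not in _SLICE_RULES:
        raise ValueError(f"unknown depot {depot!r}; expected one of {DEPOTS}")
    upper_name, lower_name = _SLICE_RULES[depot]
    for name in (upper_name, lower_name):
        if name not in landmarks:
            raise ValueError(f"missing landmark {name!r} required for depot {depot!r}")
    first = int(landmarks[upper_name])
    last = int(landmarks[lower_name]) - 1
    if first > last:
        raise ValueError(
            f"{depot}: upper landmark (slice {first}) lies below the lower "
            f"landmark (first excluded slice {last + 1})"
        )
    if first < 0 or last >= n_slices:
        raise ValueError(
            f"{depot}: analyzed range {first}..{last} exceeds the volume "
            f"({n_slices} slices)"
        )
    return first, last


def restrict_to_slices(mask: np.ndarray, slice_range: tuple[int, int], depot: str) -> DepotMask:
    """Zero a mask outside the analyzed range and wrap it as a DepotMask."""
    lo, hi = slice_range
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    out[:, :, lo : hi + 1] = mask[:, :, lo : hi + 1]
    return DepotMask(out, depot, (lo, hi), hi - lo + 1)


def mask_to_mass(mask: DepotMask | np.ndarray, spacing_mm: tuple[float, float, float],
                 depot: str | None = None) -> DepotMass:
    """Convert a binary depot mask to litres and kilograms.

    Voxel volume is in-plane pixel area times the slice pitch (centre-to-
    centre), and mass = volume x 0.9 kg/L.
    """
    if isinstance(mask, DepotMask):
        arr, depot_name, n_sl = mask.mask, mask.depot, mask.n_slices_analyzed
    else:
        arr = np.asarray(mask, dtype=bool)
        depot_name = depot or "depot"
        n_sl = arr.shape[2]
    voxel_L = spacing_mm[0] * spacing_mm[1] * spacing_mm[2] * 1e-6
    volume_L = float(arr.sum()) * voxel_L
    return DepotMass(depot_name, volume_L, volume_L * ADIPOSE_DENSITY_KG_PER_L, n_sl)
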