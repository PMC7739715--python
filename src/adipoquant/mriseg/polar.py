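"""Polar unrolling of axial slices.

Resampling a slice onto an (angle x radius) grid turns the ring-shaped
subcutaneous fat into a horizontal band, so its two boundaries become
near-horizontal curves that a circular shortest-path search can find.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class PolarImage:
    """An (angle x radius) resampling of one axial slice.

    ``samples[j, i]`` is the bilinear sample at angle ``j * angular_step``
    and radius ``i * radial_step_mm`` from ``center_px``.  The angle axis is
    circular: row ``n_angles - 1`` is adjacent to row 0.  ``inverse_map``
    holds the source pixel coordinates of every sample so masks drawn in
    polar space can be mapped back.
    """

    samples: np.ndarray           # (n_angles, n_radii)
    center_px: tuple[float, float]
    angular_step: float           # radians
    radial_step_mm: float
    pixel_size_mm: float
    inverse_map: np.ndarray       # (n_angles, n_radii, 2) source (row, col)
    source_shape: tuple[int, int]

    @property
    def n_angles(self) -> int:
        return self.samples.shape[0]

    @property
    def n_radii(self) -> int:
        return self.samples.shape[1]

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * self.angular_step

    def radii_mm(self, idx: np.ndarray | float) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.radial_step_mm


def unroll_slice(
    slice2d: np.ndarray,
    center_px: tuple[float, float],
    n_angles: int = 360,
    radial_step_mm: float | None = None,
    pixel_size_mm: float = 1.1719,
    n_radii: int | None = None,
) -> PolarImage:
    """Resample a slice on rays from ``center_px`` (bilinear interpolation).

    ``radial_step_mm`` defaults to half the in-plane pixel for sub-pixel
    boundary localization; ``n_radii`` defaults to just enough to reach the
    nearest image edge.
    """
    slice2d = np.asarray(slice2d, dtype=float)
    nr, nc = slice2d.shape
    ci, cj = center_px
    if not (0 <= ci <= nr - 1 and 0 <= cj <= nc - 1):
        raise ValueError(f"center {center_px} lies outside the {nr}x{nc} slice")
    if radial_step_mm is None:
        radial_step_mm = pixel_size_mm / 2.0
    if radial_step_mm <= 0:
        raise ValueError("radial step must be positive")
    if n_radii is None:
        max_r_px = min(ci, nr - 1 - ci, cj, nc - 1 - cj)
        n_radii = int(np.floor(max_r_px * pixel_size_mm / radial_step_mm)) + 1
    theta = np.arange(n_angles) * (2 * np.pi / n_angles)
    r_px = np.arange(n_radii) * radial_step_mm / pixel_size_mm
    rows = ci + np.cos(theta)[:, None] * r_px[None, :]
    cols = cj + np.sin(theta)[:, None] * r_px[None, :]
    samples = map_coordinates(slice2d, [rows, cols], order=1, mode="nearest")
    inverse = np.stack([rows, cols], axis=-1)
    return PolarImage(
        samples=samples,
        center_px=(float(ci), float(cj)),
        angular_step=2 * np.pi / n_angles,
        radial_step_mm=float(radial_step_mm),
        pixel_size_mm=float(pixel_size_mm),
        inverse_map=inverse,
        source_shape=(nr, nc),
    )


def reroll_mask(polar: PolarImage, polar_mask: np.ndarray) -> np.ndarray:
    """Map a binary (angle x radius) mask back to cartesian pixels.

    Each cartesian pixel is converted to polar coordinates and looked up in
    the polar mask (nearest angle, linear radius threshold handled by the
    caller).  Used for round-trip checks.
    """
    nr, nc = polar.source_shape
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    di = (ii - polar.center_px[0]) * polar.pixel_size_mm
    dj = (jj - polar.center_px[1]) * polar.pixel_size_mm
    r_idx = np.hypot(di, dj) / polar.radial_step_mm
    a_idx = np.round(np.arctan2(dj, di) / polar.angular_step).astype(int) % polar.n_angles
    r_near = np.clip(np.round(r_idx).astype(int), 0, polar.n_radii - 1)
    inside = r_idx <= polar.n_radii - 1
    return inside & polar_mask[a_idx, r_near]


def mask_inside_curve(curve: "BoundaryCurve", polar: PolarImage) -> np.ndarray:
    """Cartesian mask of the region strictly inside a circular boundary curve."""
    r_curve = np.asarray(curve.radius_per_angle, dtype=float)
    nr, nc = polar.source_shape
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    di = (ii - polar.center_px[0]) * polar.pixel_size_mm
    dj = (jj - polar.center_px[1]) * polar.pixel_size_mm
    r_idx = np.hypot(di, dj) / polar.radial_step_mm
    theta = np.mod(np.arctan2(dj, di), 2 * np.pi)
    grid = np.append(polar.angles, 2 * np.pi)
    r_at = np.interp(theta, grid, np.append(r_curve, r_curve[0]))
    return r_idx <= r_at


def sat_mask_from_boundaries(
    outer: "BoundaryCurve",
    inner: "BoundaryCurve",
    polar: PolarImage,
) -> np.ndarray:
    """Cartesian mask of the annulus between two circular boundary curves.

    A pixel belongs to the band when its radius lies in
    ``(inner(theta), outer(theta)]`` at its own polar angle (radii linearly
    interpolated between angle columns).
    """
    inner_r = np.asarray(inner.radius_per_angle, dtype=float)
    outer_r = np.asarray(outer.radius_per_angle, dtype=float)
    if np.any(inner_r >= outer_r):
        bad = int(np.argmax(inner_r >= outer_r))
        raise ValueError(
            f"inner boundary must lie strictly inside the outer at every angle "
            f"(violated at angle index {bad})"
        )
    nr, nc = polar.source_shape
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    di = (ii - polar.center_px[0]) * polar.pixel_size_mm
    dj = (jj - polar.center_px[1]) * polar.pixel_size_mm
    r_idx = np.hypot(di, dj) / polar.radial_step_mm
    theta = np.mod(np.arctan2(dj, di), 2 * np.pi)
    # circular linear interpolation of the two radius profiles
    grid = np.append(polar.angles, 2 * np.pi)
    inner_at = np.interp(theta, grid, np.append(inner_r, inner_r[0]))
    outer_at = np.interp(theta, grid, np.append(outer_r, outer_r[0]))
    return (r_idx > inner_at) & (r_idx <= outer_at)
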