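"""Optimal circular boundary detection on unrolled slices.

The subcutaneous-fat boundaries are found as minimal-cost circular paths on
the polar image: one radius per angle column, the jump between adjacent
columns bounded by a smoothness delta, and the path closed (the last column
is adjacent to the first).  The search is exact — dynamic programming over
the columns, run jointly for every admissible start radius, which for a
single surface is equivalent to the minimal closed s-t cut formulations
used for optimal surface detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, minimum_filter1d

from .polar import PolarImage

_BIG = 1e18


@dataclass
class BoundaryCurve:
    """One radial sample index per angle column of a polar image."""

    radius_per_angle: np.ndarray
    smoothness_delta: int

    def __post_init__(self) -> None:
        self.radius_per_angle = np.asarray(self.radius_per_angle, dtype=int)
        closure = abs(int(self.radius_per_angle[0]) - int(self.radius_per_angle[-1]))
        if closure > self.smoothness_delta:
            raise ValueError(
                f"curve violates circular closure: |r(0) - r(n-1)| = {closure} "
                f"> delta = {self.smoothness_delta}"
            )


def min_circular_path(cost: np.ndarray, delta: int) -> tuple[np.ndarray, float]:
    """Exact minimal-cost circular path through a (n_angles x n_radii) cost grid.

    The path picks one radius per angle column with ``|r[j+1] - r[j]| <= delta``
    for all columns including the wrap-around.  Exactness comes from solving
    the constrained DP once per admissible start radius; the start dimension
    is vectorized, so the cost is O(n_angles * n_radii^2) array work.

    Returns ``(radii, total_cost)``.  Raises if no feasible path exists
    (all-blocked columns).
    """
    cost = np.asarray(cost, dtype=float)
    n_ang, n_rad = cost.shape
    if delta < 0:
        raise ValueError("smoothness delta must be non-negative")
    window = 2 * delta + 1

    # D[s, r]: best cost of a path starting at radius s in column 0 and
    # currently at radius r.  Column 0 initializes the diagonal.
    D = np.full((n_rad, n_rad), _BIG)
    idx = np.arange(n_rad)
    D[idx, idx] = cost[0]
    for j in range(1, n_ang):
        if delta > 0:
            D = minimum_filter1d(D, size=window, axis=1, mode="constant", cval=_BIG)
        D = D + cost[j][None, :]
        np.minimum(D, _BIG, out=D)
    # closure: end radius within delta of the start radius
    closing = np.full((n_rad, n_rad), _BIG)
    for off in range(-delta, delta + 1):
        d = np.diagonal(D, offset=off)
        k = len(d)
        rows = idx[:k] if off >= 0 else idx[-off : -off + k]
        cols = rows + off
        closing[rows, cols] = d
    best_flat = int(np.argmin(closing))
    s_best, r_end = divmod(best_flat, n_rad)
    total = float(closing[s_best, r_end])
    if total >= _BIG / 2:
        raise ValueError(
            f"no feasible circular path with smoothness delta = {delta}; "
            "every candidate violates the jump or blocking constraints"
        )

    # reconstruct: ordinary DP with the start pinned at s_best
    d_prev = np.full(n_rad, _BIG)
    d_prev[s_best] = cost[0, s_best]
    back: list[np.ndarray] = []
    for j in range(1, n_ang):
        stepped = np.full(n_rad, _BIG)
        argmin = np.zeros(n_rad, dtype=int)
        for off in range(-delta, delta + 1):
            shifted = np.full(n_rad, _BIG)
            if off >= 0:
                shifted[: n_rad - off] = d_prev[off:]
            else:
                shifted[-off:] = d_prev[:off]
            better = shifted < stepped
            stepped[better] = shifted[better]
            argmin[better] = idx[better] + off
        d_prev = stepped + cost[j]
        back.append(argmin)
    feas = np.abs(idx - s_best) <= delta
    final = np.where(feas, d_prev, _BIG)
    r = int(np.argmin(final))
    path = [r]
    for argmin in reversed(back):
        r = int(argmin[r])
        path.append(r)
    path.reverse()
    return np.asarray(path, dtype=int), total


def brute_force_circular_path(cost: np.ndarray, delta: int) -> tuple[np.ndarray, float]:
    """Exhaustive enumeration of all feasible circular paths (tiny grids only).

    Independent oracle for :func:`min_circular_path`; complexity grows as
    ``n_radii * (2*delta+1)^(n_angles-1)``.
    """
    cost = np.asarray(cost, dtype=float)
    n_ang, n_rad = cost.shape
    best_path, best_cost = None, np.inf

    def recurse(j: int, r: int, acc: float, path: list[int]) -> None:
        nonlocal best_path, best_cost
        if j == n_ang:
            if abs(r - path[0]) <= delta and acc < best_cost:
                best_cost, best_path = acc, list(path)
            return
        lo, hi = max(0, r - delta), min(n_rad - 1, r + delta)
        for nr in range(lo, hi + 1):
            recurse(j + 1, nr, acc + cost[j, nr], path + [nr])

    for start in range(n_rad):
        recurse(1, start, cost[0, start], [start])
    if best_path is None:
        raise ValueError("no feasible circular path")
    return np.asarray(best_path, dtype=int), float(best_cost)


def detect_sat_boundaries(
    polar: PolarImage,
    delta: int = 2,
    smooth_sigma: tuple[float, float] = (2.0, 1.0),
    margin: int = 3,
) -> tuple[BoundaryCurve, BoundaryCurve]:
    """Locate the outer (skin) and inner (fat/muscle) boundaries of the
    subcutaneous annulus.

    The outer curve is the last foreground sample per angle column of the
    unrolled slice (tissue-to-background transition, Otsu cut).  The inner
    curve is the minimal-cost circular path of a gradient-based cost — the
    negated outward-rising radial gradient, so the strongest circularly
    continuous muscle-to-fat edge wins — constrained to lie at least
    ``margin`` samples inside the outer curve and to jump at most ``delta``
    samples between adjacent angles.
    """
    img = polar.samples
    smoothed = gaussian_filter(img, sigma=smooth_sigma, mode=("wrap", "nearest"))
    lo, hi = float(smoothed.min()), float(smoothed.max())
    if hi == lo:
        raise ValueError("flat polar image: no annulus to delineate")
    fg = smoothed > (lo + hi) / 2.0
    if not fg.any() or not fg[:, 1:].any():
        raise ValueError("no foreground in the polar image")
    # outer boundary: last foreground sample per column, refined to the
    # sub-sample 50% crossing before rounding (halves quantization error)
    rev = fg[:, ::-1]
    outer_idx = polar.n_radii - 1 - np.argmax(rev, axis=1)
    outer_idx[~fg.any(axis=1)] = 0
    cut = (lo + hi) / 2.0
    cols = np.arange(polar.n_angles)
    nxt = np.minimum(outer_idx + 1, polar.n_radii - 1)
    s_in, s_out = smoothed[cols, outer_idx], smoothed[cols, nxt]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(s_in > s_out, (s_in - cut) / (s_in - s_out), 0.0)
    outer_idx = np.round(outer_idx + np.clip(frac, 0.0, 1.0)).astype(int)
    outer_idx = np.minimum(outer_idx, polar.n_radii - 1)

    grad = np.gradient(smoothed, axis=1)
    cost = -np.maximum(grad, 0.0)
    # block everything at/inside margin of the outer curve and radius 0
    radii = np.arange(polar.n_radii)[None, :]
    blocked = radii >= (outer_idx[:, None] - margin)
    cost = np.where(blocked, _BIG, cost)
    cost[:, 0] = _BIG
    inner_path, _ = min_circular_path(cost, delta)

    outer_jumps = np.abs(np.diff(np.append(outer_idx, outer_idx[0])))
    outer = BoundaryCurve(outer_idx, smoothness_delta=max(delta, int(outer_jumps.max(initial=0))))
    inner = BoundaryCurve(inner_path, smoothness_delta=delta)
    return outer, inner
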