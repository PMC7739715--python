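"""Blood input functions: the image-derived input function (IDIF) and its AUC.

The blood FDG concentration driving all kinetic quantification is measured
from a cylindrical aortic VOI rather than arterial sampling.  For the static
femoral acquisition the blood curve must be integrated beyond the sampled
60 min, which is done with a mono-exponential tail fitted to the final
portion of the curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .frames import FrameSchedule
from ..volume import ImageVolume


@dataclass
class InputFunction:
    """Sampled blood tracer concentration Cp(t).

    Attributes
    ----------
    times_min, cp_kBq_per_ml : ndarray
        Strictly increasing sample times (minutes) and non-negative
        concentrations.
    source : {"IDIF", "simulated"}
    """

    times_min: np.ndarray
    cp_kBq_per_ml: np.ndarray
    source: Literal["IDIF", "simulated"] = "IDIF"

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.cp_kBq_per_ml = np.asarray(self.cp_kBq_per_ml, dtype=float)
        if self.times_min.ndim != 1 or self.times_min.shape != self.cp_kBq_per_ml.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if len(self.times_min) < 2:
            raise ValueError("input function needs at least two samples")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("input-function times must be strictly increasing")
        if np.any(self.cp_kBq_per_ml < 0):
            raise ValueError("blood concentrations must be non-negative")

    def __call__(self, t_min: np.ndarray | float) -> np.ndarray:
        """Linear interpolation; zero before the first sample (pre-injection)."""
        t = np.asarray(t_min, dtype=float)
        left = 0.0 if self.times_min[0] > 0 else self.cp_kBq_per_ml[0]
        return np.interp(t, self.times_min, self.cp_kBq_per_ml, left=left)

    def cumulative_integral(self, t_min: np.ndarray | float) -> np.ndarray:
        """Trapezoid integral of Cp from 0 (or the first sample) to ``t``."""
        cum = cumulative_trapezoid(self.cp_kBq_per_ml, self.times_min, initial=0.0)
        # contribution of the [0, t0] gap assuming Cp rises from 0
        lead = 0.5 * self.times_min[0] * self.cp_kBq_per_ml[0] if self.times_min[0] > 0 else 0.0
        return np.interp(np.asarray(t_min, dtype=float), self.times_min, cum + lead)

    def auc(self, t0_min: float = 0.0, t1_min: float | None = None) -> float:
        """Trapezoid AUC over ``[t0, t1]`` within the sampled range."""
        if t1_min is None:
            t1_min = float(self.times_min[-1])
        return float(self.cumulative_integral(t1_min) - self.cumulative_integral(t0_min))


def extract_idif(
    dynamic: ImageVolume | Sequence[ImageVolume],
    aorta_voi: np.ndarray,
) -> InputFunction:
    """Mean activity over an aortic VOI per frame, placed at frame mid-times.

    Parameters
    ----------
    dynamic : 4-D ImageVolume (x, y, z, frame) carrying a FrameSchedule in
        ``dynamic.frame_schedule``, or a sequence of 3-D frames (in which case
        a schedule must be attached to the first element).
    aorta_voi : boolean mask matching the spatial shape.
    """
    if isinstance(dynamic, ImageVolume):
        frames = [dynamic.voxels[..., k] for k in range(dynamic.voxels.shape[-1])]
        schedule: FrameSchedule = getattr(dynamic, "frame_schedule", None)
    else:
        frames = [v.voxels if isinstance(v, ImageVolume) else np.asarray(v) for v in dynamic]
        schedule = getattr(dynamic[0], "frame_schedule", None)
    if schedule is None:
        raise ValueError("dynamic volume must carry a 'frame_schedule' attribute")
    voi = np.asarray(aorta_voi, dtype=bool)
    if voi.shape != frames[0].shape:
        raise ValueError(f"VOI shape {voi.shape} does not match frame shape {frames[0].shape}")
    if not voi.any():
        raise ValueError("aorta VOI is empty")
    means = np.array([float(f[voi].mean()) for f in frames])
    return InputFunction(schedule.mid_min, np.maximum(means, 0.0), source="IDIF")


def extrapolate_idif_auc(
    input_function: InputFunction,
    to_time_min: float = 70.0,
    tail_window_min: float = 20.0,
) -> float:
    """AUC of the blood curve from 0 to ``to_time``, past the sampled range.

    The sampled portion is integrated by trapezoid; the unsampled tail is a
    mono-exponential fitted (log-linear least squares) to the last
    ``tail_window_min`` minutes of the curve and integrated analytically.  A
    non-decaying fitted tail falls back to constant extrapolation at the last
    sampled value, with a warning.

    Returns kBq·min/ml.
    """
    t = input_function.times_min
    if t[-1] < 30.0:
        raise ValueError("input function must cover at least 30 min for extrapolation")
    if to_time_min < t[-1]:
        raise ValueError(
            f"to_time ({to_time_min} min) precedes the last sample ({t[-1]} min)"
        )
    auc_sampled = input_function.auc(0.0, float(t[-1]))
    if to_time_min == t[-1]:
        return auc_sampled

    sel = t >= t[-1] - tail_window_min
    tt, cc = t[sel], input_function.cp_kBq_per_ml[sel]
    pos = cc > 0
    lam = None
    if pos.sum() >= 2 and np.ptp(cc[pos]) > 0:
        slope, intercept = np.polyfit(tt[pos], np.log(cc[pos]), 1)
        if slope < 0:
            lam = -slope
    c_end = float(input_function.cp_kBq_per_ml[-1])
    dt = to_time_min - float(t[-1])
    if lam is None:
        warnings.warn(
            "IDIF tail is not decaying; extrapolating at a constant level",
            RuntimeWarning,
            stacklevel=2,
        )
        tail = c_end * dt
    else:
        # integral of c_end * exp(-lam * (t - t_end)) over [t_end, to_time]
        tail = c_end / lam * (1.0 - np.exp(-lam * dt))
    return float(auc_sampled + tail)
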