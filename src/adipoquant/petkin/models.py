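"""Irreversible two-tissue-compartment (2TCM, k4 = 0) FDG model.

The tissue concentration for an irreversible tracer is

    Ct(t) = Vb * Cp(t) + h(t) (*) Cp(t),
    h(t)  = K1/(k2+k3) * (k3 + k2 * exp(-(k2+k3) t)),

so the net influx rate constant is Ki = K1*k3/(k2+k3): the late-time slope
of tissue activity against the integrated blood curve.  This module provides
the forward simulation used both by the phantom generators and by the
nonlinear fitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import fftconvolve

from .frames import FrameSchedule, TimeActivityCurve
from .idif import InputFunction


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the irreversible 2TCM.

    K1 in ml blood · ml tissue^-1 · min^-1; k2, k3 in min^-1; Vb is the
    fractional blood volume.  ``ki`` = K1*k3/(k2+k3) is derived and always
    <= K1.
    """

    K1: float
    k2: float
    k3: float
    Vb: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "Vb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.Vb > 1:
            raise ValueError(f"Vb is a fraction, got {self.Vb}")

    @property
    def ki(self) -> float:
        denom = self.k2 + self.k3
        return 0.0 if denom == 0 else self.K1 * self.k3 / denom


def tissue_curve(
    params: KineticParams,
    input_function: InputFunction,
    t_min: np.ndarray,
    dt_min: float = 0.0025,
) -> np.ndarray:
    """Noiseless instantaneous tissue concentration at the requested times.

    The convolution is evaluated on a uniform fine grid (``dt_min``
    resolution) and interpolated to ``t_min``.
    """
    t_min = np.asarray(t_min, dtype=float)
    t_end = max(float(t_min.max()), dt_min)
    grid = np.arange(0.0, t_end + dt_min, dt_min)
    cp = input_function(grid)
    beta = params.k2 + params.k3
    if params.K1 == 0:
        conv = np.zeros_like(grid)
    else:
        irf = params.K1 / beta * (params.k3 + params.k2 * np.exp(-beta * grid)) if beta > 0 else np.full_like(grid, params.K1)
        conv = fftconvolve(irf, cp)[: len(grid)] * dt_min
    ct = params.Vb * cp + conv
    return np.interp(t_min, grid, ct)


def frame_average_tac(
    params: KineticParams,
    input_function: InputFunction,
    schedule: FrameSchedule,
    dt_min: float = 0.0025,
) -> TimeActivityCurve:
    """Noiseless TAC with exact frame averaging of the fine-grid curve."""
    t_end = float(schedule.end_s[-1]) / 60.0
    grid = np.arange(0.0, t_end + dt_min, dt_min)
    ct = tissue_curve(params, input_function, grid, dt_min=dt_min)
    cum = cumulative_trapezoid(ct, grid, initial=0.0)

    def integral(t: np.ndarray) -> np.ndarray:
        return np.interp(t, grid, cum)

    start = schedule.start_s / 60.0
    end = schedule.end_s / 60.0
    means = (integral(end) - integral(start)) / (end - start)
    return TimeActivityCurve(schedule, means, decay_corrected_to=0.0)
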