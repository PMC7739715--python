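"""Patlak graphical analysis for irreversible tracers.

Plotting y = Ct(t)/Cp(t) against x = int_0^t Cp dτ / Cp(t) ("normalized
time") linearizes an irreversible uptake curve once the reversible
compartments have equilibrated; the late-time slope is the influx rate
constant Ki and the intercept the initial distribution volume V0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import TimeActivityCurve
from .idif import InputFunction


@dataclass(frozen=True)
class PatlakFit:
    """Result of an ordinary-least-squares Patlak fit."""

    ki: float                # ml blood · ml tissue^-1 · min^-1
    intercept_V0: float      # ml/ml
    r_squared: float
    t_star_min: float
    n_points: int


def patlak_ki(
    tac: TimeActivityCurve,
    input_function: InputFunction,
    t_star_min: float = 20.0,
) -> PatlakFit:
    """Fit the Patlak slope on frames with mid-time >= ``t_star_min``.

    The cumulative blood integral is taken by trapezoid on the sampled input
    function.  All post-t* points are weighted equally.
    """
    t = tac.mid_min
    sel = t >= t_star_min
    if sel.sum() < 3:
        raise ValueError(
            f"need >= 3 frames with mid-time >= t* = {t_star_min} min, have {int(sel.sum())}"
        )
    cp = input_function(t[sel])
    if np.any(cp <= 0):
        raise ValueError("blood concentration must be positive on the fitted frames")
    x = input_function.cumulative_integral(t[sel]) / cp
    y = tac.activity_kBq_per_ml[sel] / cp
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return PatlakFit(
        ki=float(slope),
        intercept_V0=float(intercept),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        t_star_min=float(t_star_min),
        n_points=int(sel.sum()),
    )
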