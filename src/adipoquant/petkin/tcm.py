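"""Nonlinear compartmental fit of the irreversible 2TCM.

Provided as the cross-check to Patlak: weighted least squares on the frame
averages with k4 fixed at zero, seeded multi-start to step over local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .frames import TimeActivityCurve
from .idif import InputFunction
from .models import KineticParams, frame_average_tac


@dataclass(frozen=True)
class TcmFit:
    params: KineticParams
    residual_norm: float
    converged: bool
    n_starts: int

    @property
    def ki(self) -> float:
        return self.params.ki


def fit_2tcm_irreversible(
    tac: TimeActivityCurve,
    input_function: InputFunction,
    init: KineticParams | None = None,
    seed: int | None = None,
    n_starts: int = 4,
    fit_vb: bool = True,
    dt_min: float = 0.01,
) -> TcmFit:
    """Fit K1, k2, k3 (and optionally Vb) to a frame-averaged TAC.

    Residuals are weighted by the square root of frame duration (longer
    frames average more counts).  ``n_starts - 1`` extra starts are drawn
    log-uniformly around the initial guess using ``seed``.  Non-convergence
    of every start is flagged on the result rather than raised.
    """
    if init is None:
        init = KineticParams(0.05, 0.2, 0.05, 0.05 if fit_vb else 0.0)
    if min(init.K1, init.k2, init.k3) <= 0:
        raise ValueError("initial K1, k2, k3 must be positive")
    y = tac.activity_kBq_per_ml
    w = np.sqrt(tac.schedule.duration_s / tac.schedule.duration_s.max())

    def unpack(theta: np.ndarray) -> KineticParams:
        if fit_vb:
            k1, k2, k3, vb = np.exp(theta[:3]).tolist() + [theta[3]]
        else:
            k1, k2, k3 = np.exp(theta).tolist()
            vb = 0.0
        return KineticParams(k1, k2, k3, min(max(vb, 0.0), 1.0))

    def residuals(theta: np.ndarray) -> np.ndarray:
        model = frame_average_tac(unpack(theta), input_function, tac.schedule, dt_min=dt_min)
        return w * (model.activity_kBq_per_ml - y)

    base = np.log([init.K1, init.k2, init.k3])
    starts = [np.concatenate([base, [init.Vb]]) if fit_vb else base]
    rng = np.random.default_rng(seed)
    for _ in range(max(n_starts - 1, 0)):
        jitter = base + rng.uniform(-1.0, 1.0, size=3)
        starts.append(
            np.concatenate([jitter, [rng.uniform(0.0, 0.15)]]) if fit_vb else jitter
        )

    best = None
    any_converged = False
    for theta0 in starts:
        if fit_vb:
            bounds = ([-np.inf] * 3 + [0.0], [np.inf] * 3 + [1.0])
        else:
            bounds = (-np.inf, np.inf)
        sol = least_squares(residuals, theta0, bounds=bounds, xtol=1e-10, ftol=1e-10)
        any_converged = any_converged or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    params = unpack(best.x)
    return TcmFit(
        params=params,
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(any_converged),
        n_starts=len(starts),
    )
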