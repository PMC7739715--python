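"""Simulated blood input functions.

A Feng-type tri-exponential curve — a sharp injection peak followed by two
slower washout terms — is the conventional analytic stand-in for a measured
arterial or image-derived FDG input:

    Cp(t) = (A1·u − A2 − A3)·e^{l1·u} + A2·e^{l2·u} + A3·e^{l3·u},  u = t − t0

for t >= t0 and zero before the appearance time t0.  All three decay rates
l1 < l2 < l3 < 0.  The curve integrates in closed form, which the AUC
examples and the static-scan extrapolation checks rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..petkin.idif import InputFunction


@dataclass(frozen=True)
class FengParams:
    """Coefficients of the tri-exponential input model.

    Amplitudes in kBq/ml (A1 in kBq/ml/min), rates in 1/min (negative),
    ``t0_min`` the tracer appearance time.  Defaults give a realistic bolus:
    ~75 kBq/ml peak at ~45 s decaying to ~11 kBq/ml at 60 min.
    """

    A1: float = 851.1
    A2: float = 21.88
    A3: float = 20.81
    l1: float = -4.1339
    l2: float = -0.1191
    l3: float = -0.0104
    t0_min: float = 0.5

    def __post_init__(self) -> None:
        if any(l > 0 for l in (self.l1, self.l2, self.l3)):
            raise ValueError("decay rates must be non-positive")
        if self.t0_min < 0:
            raise ValueError("appearance time must be non-negative")

    def __call__(self, t_min: np.ndarray | float) -> np.ndarray:
        u = np.asarray(t_min, dtype=float) - self.t0_min
        up = np.maximum(u, 0.0)
        val = (
            (self.A1 * up - self.A2 - self.A3) * np.exp(self.l1 * up)
            + self.A2 * np.exp(self.l2 * up)
            + self.A3 * np.exp(self.l3 * up)
        )
        return np.where(u >= 0, np.maximum(val, 0.0), 0.0)

    def auc(self, t_min: float) -> float:
        """Closed-form integral of Cp from 0 to ``t_min``."""
        u = max(t_min - self.t0_min, 0.0)

        def i0(lam: float) -> float:  # int_0^u e^{lam s} ds
            return u if lam == 0 else (np.exp(lam * u) - 1.0) / lam

        def i1(lam: float) -> float:  # int_0^u s e^{lam s} ds
            if lam == 0:
                return u * u / 2.0
            return np.exp(lam * u) * (u / lam - 1.0 / lam**2) + 1.0 / lam**2

        return float(
            self.A1 * i1(self.l1)
            - (self.A2 + self.A3) * i0(self.l1)
            + self.A2 * i0(self.l2)
            + self.A3 * i0(self.l3)
        )


def simulate_input_function(
    params: FengParams | float,
    times_min: np.ndarray,
) -> InputFunction:
    """Sample a simulated blood curve at the given times.

    ``params`` is either a :class:`FengParams` or a scalar for a
    constant-plasma curve (useful as a degenerate test input).  The returned
    :class:`InputFunction` carries the analytic model as ``.model`` and its
    closed-form AUC as ``.analytic_auc``.
    """
    times_min = np.asarray(times_min, dtype=float)
    if np.any(times_min < 0):
        raise ValueError("sample times must be non-negative")
    if np.any(np.diff(times_min) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if np.isscalar(params) or isinstance(params, (int, float)):
        c = float(params)
        if c < 0:
            raise ValueError("constant plasma level must be non-negative")
        out = InputFunction(times_min, np.full_like(times_min, c), source="simulated")
        out.model = lambda t: np.full_like(np.asarray(t, dtype=float), c)
        out.analytic_auc = lambda t: c * float(t)
        return out
    out = InputFunction(times_min, params(times_min), source="simulated")
    out.model = params
    out.analytic_auc = params.auc
    return out
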