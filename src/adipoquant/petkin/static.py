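"""Estimated Ki from a static late scan (fractional uptake rate).

For regions only covered by a late static acquisition, Ki is estimated as
the mean VOI activity divided by the blood AUC extrapolated to the middle
of the static scan.  This fractional uptake rate (FUR) upper-bounds the
Patlak Ki: FUR = Ki + V0·Cp(T)/∫Cp, and the excess shrinks as the blood
curve decays.
"""

from __future__ import annotations

from dataclasses import dataclass

from .idif import InputFunction, extrapolate_idif_auc


@dataclass(frozen=True)
class StaticUptake:
    mean_voi_activity_kBq_per_ml: float
    mid_time_min: float
    auc_kBq_min_per_ml: float
    estimated_ki: float  # = mean activity / AUC, ml·ml^-1·min^-1


def estimated_ki_static(
    mean_voi_activity_kBq_per_ml: float,
    auc_kBq_min_per_ml: float,
    mid_time_min: float = 70.0,
) -> StaticUptake:
    """Ki estimate = late tissue concentration / time-integrated blood curve."""
    if auc_kBq_min_per_ml <= 0:
        raise ValueError(f"blood AUC must be positive, got {auc_kBq_min_per_ml}")
    if mean_voi_activity_kBq_per_ml < 0:
        raise ValueError("VOI activity must be non-negative")
    return StaticUptake(
        mean_voi_activity_kBq_per_ml=float(mean_voi_activity_kBq_per_ml),
        mid_time_min=float(mid_time_min),
        auc_kBq_min_per_ml=float(auc_kBq_min_per_ml),
        estimated_ki=float(mean_voi_activity_kBq_per_ml) / float(auc_kBq_min_per_ml),
    )


def estimated_ki_from_idif(
    mean_voi_activity_kBq_per_ml: float,
    input_function: InputFunction,
    mid_time_min: float = 70.0,
) -> StaticUptake:
    """Convenience wrapper extrapolating the IDIF AUC to the static mid-time."""
    auc = extrapolate_idif_auc(input_function, to_time_min=mid_time_min)
    return estimated_ki_static(mean_voi_activity_kBq_per_ml, auc, mid_time_min)
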