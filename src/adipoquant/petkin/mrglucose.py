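"""Metabolic rate of glucose from the FDG influx rate constant.

    MRglucose = 1000 · Ki · [glucose]_plasma / (LC · density)

with the lumped constant LC translating FDG kinetics into glucose kinetics
(1.14 for adipose tissue) and tissue density 0.9 g/ml converting per-ml
tissue rates to per-kg.  Units: Ki in ml·ml^-1·min^-1, glucose in mmol/L,
result in µmol·kg^-1·min^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Lumped constant of adipose tissue.
ADIPOSE_LUMPED_CONSTANT = 1.14
#: Density of adipose tissue, g/ml (equivalently kg/L).
ADIPOSE_DENSITY_G_PER_ML = 0.9


@dataclass(frozen=True)
class MRglucoseResult:
    ki_used: float
    plasma_glucose_mmol_per_L: float
    lumped_constant: float
    density_g_per_ml: float
    mr_glucose: float  # µmol · kg^-1 · min^-1


def mr_glucose(
    ki: float,
    plasma_glucose_mmol_per_L: float,
    lumped_constant: float = ADIPOSE_LUMPED_CONSTANT,
    density_g_per_ml: float = ADIPOSE_DENSITY_G_PER_ML,
) -> MRglucoseResult:
    """Insulin-stimulated glucose uptake in µmol per kg tissue per minute."""
    if ki < 0 or plasma_glucose_mmol_per_L < 0:
        raise ValueError("ki and plasma glucose must be non-negative")
    if lumped_constant <= 0 or density_g_per_ml <= 0:
        raise ValueError("lumped constant and density must be positive")
    value = 1000.0 * ki * plasma_glucose_mmol_per_L / (lumped_constant * density_g_per_ml)
    return MRglucoseResult(
        ki_used=float(ki),
        plasma_glucose_mmol_per_L=float(plasma_glucose_mmol_per_L),
        lumped_constant=float(lumped_constant),
        density_g_per_ml=float(density_g_per_ml),
        mr_glucose=float(value),
    )
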