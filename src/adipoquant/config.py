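"""Run configuration: one document that fixes every stage parameter.

All defaults are the study constants used throughout the package: lumped
constant 1.14, adipose density 0.9 kg/L, HU window [-150, -50], two-pixel
VOI erosion, 26-frame (12x10 s, 4x120 s, 10x300 s) dynamic schedule, static
mid-time 70 min.  Unknown keys anywhere in the document are rejected, and
the full config travels into every result file, so a run is reproducible
from its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

VALID_STAGES = ("simulate", "segment", "quantify", "analyze")


@dataclass
class PhantomConfig:
    region: str = "abdomen"
    n_slices: int = 10
    pixel_size_mm: float = 1.1719
    slice_pitch_mm: float = 7.2
    body_radius_mm: float = 130.0
    sat_thickness_mean_mm: float = 18.0
    sat_thickness_amp_mm: float = 6.0
    internal_fat_fraction: float = 0.15
    bias_amplitude: float = 0.2
    noise_sd: float = 50.0


@dataclass
class KineticConfig:
    K1: float
    k2: float
    k3: float
    Vb: float = 0.0


@dataclass
class PetConfig:
    frame_pattern: list = field(
        default_factory=lambda: [[12, 10.0], [4, 120.0], [10, 300.0]]
    )
    t_star_min: float = 20.0
    static_mid_time_min: float = 70.0
    plasma_glucose_mmol_per_L: float = 5.0
    lumped_constant: float = 1.14
    density_g_per_ml: float = 0.9
    hu_range: list = field(default_factory=lambda: [-150.0, -50.0])
    erosion_px: int = 2
    tac_noise_sd: float = 0.0
    tissues: dict = field(
        default_factory=lambda: {
            # subcutaneous vs visceral adipose kinetics; visceral trapping higher
            "abdominal_sat": {"K1": 0.02, "k2": 0.30, "k3": 0.0200, "Vb": 0.04},
            "visceral": {"K1": 0.03, "k2": 0.30, "k3": 0.0332, "Vb": 0.06},
        }
    )


@dataclass
class CohortConfig:
    n_per_group: int = 20
    between_subject_cv: float = 0.30
    within_subject_cv: float = 0.05
    sat_time_effect: float = 0.96
    visceral_time_effect: float = 0.94
    group_effect: float = 1.0
    ki_ratio_visceral_over_sc: float = 2.39


@dataclass
class SegmentationConfig:
    smoothness_delta: int = 2
    n_angles: int = 360
    bias_degree: int = 4
    kmeans_k: int = 5


@dataclass
class AnalysisConfig:
    outcomes: list = field(
        default_factory=lambda: ["abdominal_sat_mass", "visceral_mass"]
    )
    model: str = "mixed"  # "mixed" | "ancova"
    covariate: str = "n_slices_analyzed"
    log_scale: bool = False


@dataclass
class RunConfig:
    stages: list = field(default_factory=lambda: list(VALID_STAGES))
    seed: int = 0
    output_dir: str = "adipoquant_run"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    pet: PetConfig = field(default_factory=PetConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        for st in self.stages:
            if st not in VALID_STAGES:
                raise ValueError(f"unknown stage {st!r}; valid: {VALID_STAGES}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Hash of the scientific configuration (the output path is excluded,
        so the same analysis written elsewhere hashes identically)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed fan-out from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def _build(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


_SECTIONS = {
    "phantom": PhantomConfig,
    "pet": PetConfig,
    "cohort": CohortConfig,
    "segmentation": SegmentationConfig,
    "analysis": AnalysisConfig,
}


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    data = dict(data)
    kwargs: dict[str, Any] = {}
    for key, cls in _SECTIONS.items():
        if key in data:
            kwargs[key] = _build(cls, data.pop(key))
    top = {f.name for f in dataclasses.fields(RunConfig)} - set(_SECTIONS)
    unknown = set(data) - top
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs.update(data)
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a JSON or YAML file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(data)
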