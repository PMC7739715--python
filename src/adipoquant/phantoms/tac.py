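"""Simulated tissue time-activity curves and dynamic PET phantom volumes."""

from __future__ import annotations

import numpy as np

from ..petkin.frames import FrameSchedule, TimeActivityCurve
from ..petkin.idif import InputFunction
from ..petkin.models import KineticParams, frame_average_tac
from ..volume import ImageVolume


def simulate_tissue_tac(
    input_function: InputFunction,
    params: KineticParams,
    schedule: FrameSchedule,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TimeActivityCurve:
    """Frame-averaged irreversible-2TCM tissue curve, optionally noisy.

    ``noise_sd`` is a fraction: each frame value is perturbed by Gaussian
    noise with standard deviation ``noise_sd * value`` (multiplicative,
    clipped at zero).  ``noise_sd = 0`` is exactly deterministic.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    tac = frame_average_tac(params, input_function, schedule)
    if noise_sd == 0:
        return tac
    rng = np.random.default_rng(seed)
    noisy = tac.activity_kBq_per_ml * (1.0 + noise_sd * rng.standard_normal(tac.schedule.n_frames))
    return TimeActivityCurve(schedule, np.maximum(noisy, 0.0), tac.decay_corrected_to)


def generate_dynamic_pet_phantom(
    input_function: InputFunction,
    tissue_params: KineticParams,
    schedule: FrameSchedule,
    shape: tuple[int, int, int] = (32, 32, 8),
    aorta_center: tuple[int, int] = (16, 16),
    aorta_radius_px: int = 3,
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> tuple[ImageVolume, np.ndarray, np.ndarray]:
    """A toy 4-D PET volume: an aortic cylinder carrying the blood curve
    inside a tissue background carrying the 2TCM curve.

    Returns ``(dynamic, aorta_mask, tissue_mask)``.  The dynamic volume
    carries the schedule as ``.frame_schedule`` so the IDIF extractor can
    place frame mid-times.
    """
    nx, ny, nz = shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
    aorta2d = (xx - aorta_center[0]) ** 2 + (yy - aorta_center[1]) ** 2 <= aorta_radius_px**2
    aorta = np.repeat(aorta2d[:, :, None], nz, axis=2)
    tissue = ~aorta

    # frame-averaged blood curve for the aorta voxels
    cp_frames = np.empty(schedule.n_frames)
    for i, (s, e) in enumerate(zip(schedule.start_s / 60.0, schedule.end_s / 60.0)):
        tt = np.linspace(s, e, 25)
        cp_frames[i] = np.trapezoid(input_function(tt), tt) / (e - s)
    ct_frames = frame_average_tac(tissue_params, input_function, schedule).activity_kBq_per_ml

    vox = np.zeros(shape + (schedule.n_frames,), dtype=float)
    vox[aorta] = cp_frames
    vox[tissue] = ct_frames
    vol = ImageVolume(vox, spacing_mm, modality="PET")
    vol.frame_schedule = schedule
    return vol, aorta, tissue
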