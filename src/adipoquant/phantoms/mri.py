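"""Digital MRI/CT phantoms of abdominal and thigh cross-sections.

The phantom emulates the appearance the segmentation stage expects from an
axial T1-weighted abdominal scan: a bright subcutaneous-fat annulus under
the skin, a darker internal compartment (muscle and organs) with scattered
bright visceral or inter-muscular fat, a multiplicative low-order bias
field, and additive Gaussian noise.  A matched CT volume carries adipose
voxels inside the [-150, -50] HU window.  Every phantom comes with exact
per-voxel ground-truth labels and depot masses (voxel count x voxel volume
x 0.9 kg/L), which is what makes the downstream pipeline testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

from ..volume import ImageVolume

# tissue labels
BACKGROUND, SAT, MUSCLE, INTERNAL_FAT, LIVER, BONE_MARROW = 0, 1, 2, 3, 4, 5

LABEL_NAMES = {
    BACKGROUND: "background",
    SAT: "sat",
    MUSCLE: "muscle",
    INTERNAL_FAT: "internal_fat",
    LIVER: "liver",
    BONE_MARROW: "bone_marrow",
}

# nominal T1 intensities (arbitrary units): fat bright, muscle mid, air dark
MRI_INTENSITY = {
    BACKGROUND: 20.0,
    SAT: 1000.0,
    MUSCLE: 400.0,
    INTERNAL_FAT: 1000.0,
    LIVER: 450.0,
    BONE_MARROW: 1000.0,  # fatty marrow is bright on T1, hence excluded separately
}

ADIPOSE_DENSITY_KG_PER_L = 0.9


@dataclass(frozen=True)
class Organ:
    """A labeled ellipse placed on a range of slices."""

    label: int
    center_mm: tuple[float, float]
    radii_mm: tuple[float, float]
    slices: tuple[int, int] | None = None  # inclusive range; None = all


@dataclass
class PhantomSpec:
    """Geometry and noise model of a synthetic cross-section stack.

    ``sat_thickness_mm`` is either a constant or ``(mean, amplitude)`` of a
    cosine profile around the circumference, so the subcutaneous annulus need
    not be rotationally symmetric.  ``bias_amplitude`` scales a per-slice
    multiplicative degree-2 polynomial field; noise is additive Gaussian
    applied after the bias.  Identical spec + seed gives a bit-identical
    phantom.
    """

    n_slices: int = 10
    pixel_size_mm: float = 1.1719
    slice_pitch_mm: float = 7.2
    body_radius_mm: float = 130.0
    sat_thickness_mm: float | tuple[float, float] = (18.0, 6.0)
    internal_fat_fraction: float = 0.15
    organ_layout: tuple[Organ, ...] | None = None
    bias_amplitude: float = 0.2
    noise_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices <= 0 or self.pixel_size_mm <= 0 or self.slice_pitch_mm <= 0:
            raise ValueError("slice count, pixel size and slice pitch must be positive")
        if self.body_radius_mm <= 0:
            raise ValueError(f"body radius must be positive, got {self.body_radius_mm}")
        mean_t = self.sat_mean_thickness
        if mean_t <= 0 or mean_t >= self.body_radius_mm:
            raise ValueError("SAT thickness must be positive and smaller than the body radius")
        if not 0.0 <= self.internal_fat_fraction <= 1.0:
            raise ValueError("internal_fat_fraction must be in [0, 1]")
        if not 0.0 <= self.bias_amplitude < 1.0:
            raise ValueError("bias_amplitude must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def sat_mean_thickness(self) -> float:
        if np.isscalar(self.sat_thickness_mm):
            return float(self.sat_thickness_mm)
        return float(self.sat_thickness_mm[0])

    def sat_thickness(self, theta: np.ndarray) -> np.ndarray:
        """Annulus thickness (mm) at polar angle theta."""
        if np.isscalar(self.sat_thickness_mm):
            return np.full_like(np.asarray(theta, dtype=float), float(self.sat_thickness_mm))
        mean, amp = self.sat_thickness_mm
        return mean + amp * np.cos(np.asarray(theta, dtype=float))


@dataclass
class GroundTruth:
    """Per-voxel labels plus exact depot masses and anatomical landmarks."""

    label_volume: ImageVolume
    depot_masses_kg: dict[str, float]
    landmarks: dict[str, int]
    region: str

    def mask(self, label: int) -> np.ndarray:
        return self.label_volume.voxels == label


def _default_organs(region: str, spec: PhantomSpec) -> tuple[Organ, ...]:
    r = spec.body_radius_mm
    if region == "abdomen":
        # liver-like ellipse in the upper-right quadrant of the upper half of the stack
        top = max(spec.n_slices // 2 - 1, 0)
        return (
            Organ(LIVER, (0.35 * r, 0.25 * r), (0.35 * r, 0.25 * r), (0, top)),
        )
    if region == "thigh":
        return (Organ(BONE_MARROW, (0.0, 0.0), (12.0, 12.0), None),)
    raise ValueError(f"region must be 'abdomen' or 'thigh', got {region!r}")


def _depot_names(region: str) -> dict[int, str]:
    if region == "abdomen":
        return {SAT: "abdominal_sat", INTERNAL_FAT: "visceral"}
    return {SAT: "femoral_sat", INTERNAL_FAT: "inter_muscular", BONE_MARROW: "bone_marrow"}


def _default_landmarks(region: str, n_slices: int) -> dict[str, int]:
    # phantom anatomy spans the full analyzed range: upper delimiters on the
    # first slice, the excluded structure first "appearing" just past the stack
    if region == "abdomen":
        return {
            "th11_th12_disc": 0,
            "th12_l1_disc": 0,
            "iliac_crest": n_slices,
            "caput_femoris": n_slices,
        }
    return {"gluteal_lower": 0, "patella": n_slices}


def generate_phantom(
    spec: PhantomSpec,
    region: Literal["abdomen", "thigh"] = "abdomen",
) -> tuple[ImageVolume, ImageVolume, GroundTruth]:
    """Generate matched MRI and CT volumes with ground truth.

    Returns ``(mri, ct, truth)``.  MRI intensity = label intensity x bias
    field + additive noise; CT Hounsfield units place every adipose label
    inside [-150, -50] and everything else well outside.
    """
    rng = np.random.default_rng(spec.seed)
    organs = spec.organ_layout if spec.organ_layout is not None else _default_organs(region, spec)

    margin = 6.0  # mm of air around the body
    half_mm = spec.body_radius_mm + spec.sat_mean_thickness * 0.0 + margin
    n_px = int(np.ceil(2 * half_mm / spec.pixel_size_mm)) | 1  # odd: voxel-centred
    c = (n_px - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(n_px), np.arange(n_px), indexing="ij")
    x_mm = (ii - c) * spec.pixel_size_mm
    y_mm = (jj - c) * spec.pixel_size_mm
    r_mm = np.hypot(x_mm, y_mm)
    theta = np.arctan2(y_mm, x_mm)

    inner_r = spec.body_radius_mm - spec.sat_thickness(theta)
    body = r_mm <= spec.body_radius_mm
    sat = body & (r_mm > inner_r)
    internal = body & ~sat

    labels = np.zeros((n_px, n_px, spec.n_slices), dtype=np.int16)
    for k in range(spec.n_slices):
        sl = np.full((n_px, n_px), BACKGROUND, dtype=np.int16)
        sl[internal] = MUSCLE
        # organs first, so scattered fat is drawn from the remaining muscle
        organ_mask_all = np.zeros_like(internal)
        for organ in organs:
            if organ.slices is not None and not (organ.slices[0] <= k <= organ.slices[1]):
                continue
            ox, oy = organ.center_mm
            oa, ob = organ.radii_mm
            om = internal & (((x_mm - ox) / oa) ** 2 + ((y_mm - oy) / ob) ** 2 <= 1.0)
            sl[om] = organ.label
            organ_mask_all |= om
        eligible = internal & ~organ_mask_all
        if spec.internal_fat_fraction > 0 and eligible.any():
            # blobby scattered fat: thresholded smooth Gaussian random field
            noise_field = gaussian_filter(rng.standard_normal((n_px, n_px)), sigma=3.0)
            vals = noise_field[eligible]
            cut = np.quantile(vals, 1.0 - spec.internal_fat_fraction)
            fat = eligible & (noise_field > cut)
            sl[fat] = INTERNAL_FAT
        sl[sat] = SAT
        labels[:, :, k] = sl

    # ---- MRI intensities: base x bias + noise --------------------------------
    base = np.zeros_like(labels, dtype=float)
    for lab, inten in MRI_INTENSITY.items():
        base[labels == lab] = inten

    mri_vox = np.empty_like(base)
    xn = (ii - c) / c
    yn = (jj - c) / c
    for k in range(spec.n_slices):
        if spec.bias_amplitude > 0:
            coef = rng.uniform(-1.0, 1.0, size=5)
            poly = (
                coef[0] * xn + coef[1] * yn + coef[2] * xn**2 + coef[3] * xn * yn + coef[4] * yn**2
            )
            fld = 1.0 + spec.bias_amplitude * poly / max(np.abs(poly).max(), 1e-12)
        else:
            fld = 1.0
        mri_vox[:, :, k] = base[:, :, k] * fld
    if spec.noise_sd > 0:
        mri_vox = mri_vox + rng.normal(0.0, spec.noise_sd, size=mri_vox.shape)

    # ---- CT Hounsfield units -------------------------------------------------
    ct_vox = np.full(labels.shape, -1000.0)
    fat_labels = labels == INTERNAL_FAT
    fat_labels |= labels == SAT
    fat_labels |= labels == BONE_MARROW
    ct_vox[fat_labels] = np.clip(rng.normal(-100.0, 12.0, int(fat_labels.sum())), -148.0, -52.0)
    for lab, hu in ((MUSCLE, 40.0), (LIVER, 55.0)):
        m = labels == lab
        ct_vox[m] = hu + rng.normal(0.0, 8.0, int(m.sum()))
    bg = labels == BACKGROUND
    ct_vox[bg] = -1000.0 + rng.normal(0.0, 5.0, int(bg.sum()))

    spacing = (spec.pixel_size_mm, spec.pixel_size_mm, spec.slice_pitch_mm)
    mri = ImageVolume(mri_vox, spacing, modality="MRI")
    ct = ImageVolume(ct_vox, spacing, modality="CT")
    label_vol = ImageVolume(labels, spacing, modality="LABEL")

    voxel_L = spec.pixel_size_mm**2 * spec.slice_pitch_mm * 1e-6
    masses = {
        name: float((labels == lab).sum()) * voxel_L * ADIPOSE_DENSITY_KG_PER_L
        for lab, name in _depot_names(region).items()
    }
    truth = GroundTruth(
        label_volume=label_vol,
        depot_masses_kg=masses,
        landmarks=_default_landmarks(region, spec.n_slices),
        region=region,
    )
    return mri, ct, truth
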