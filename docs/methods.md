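# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical choices a maintainer would want to know.

## Image model and geometry

Volumes are 3-D voxel grids with axial slices on the last axis and world
coordinate `index × spacing + origin`. The in-plane pixel is 1.1719 mm and
the slice spacing 7.2 mm centre-to-centre (acquired slices are 6 mm thick
with a 1.2 mm gap). Volume integration uses the 7.2 mm pitch, not the
6 mm thickness, so each slice's count stands for a contiguous 7.2 mm slab
of anatomy; this is the convention under which `mass = count × 1.1719² ×
7.2 mm³ × 0.9 kg/L` is exact for the phantom ground truth by construction.

## MRI phantom

The abdominal phantom is a circular body of radius 130 mm with a
subcutaneous fat annulus whose thickness varies around the circumference
as `18 + 6·cos θ` mm, an internal compartment of muscle (intensity 400)
with blobby scattered visceral fat (intensity 1000, 15 % of the
compartment by default, generated by thresholding a smoothed Gaussian
random field at the matching quantile so the fraction is honoured
per slice), a liver-like ellipse (intensity 450) on the upper slices, and
air background (intensity 20). The thigh variant has a central fatty
bone-marrow disc instead of a liver. The contrast model (fat bright,
muscle mid, background dark) stands in for a water-suppressed T1
appearance; no MR physics (relaxation, chemical shift, partial volume
from thick-slice averaging) is simulated. Intensities are multiplied by a
per-slice degree-2 polynomial bias field (amplitude 0.2 by default,
normalized so the field stays within ±amplitude of 1) and Gaussian noise
(sd 50 ≈ 5 % of the fat intensity) is added *after* the bias. The matched
CT assigns fat-labelled voxels HU ~ N(−100, 12) clipped inside
[−148, −52], muscle ≈ 40 HU, background −1000 HU.

Consequently, a passing segmentation suite shows that the chain recovers
masses when tissue classes are homogeneous up to smooth bias and additive
noise; it does not certify behaviour under partial-volume mixing, motion,
or chemical-shift artefacts, which real scans have.

## Bias correction

Scanner shading is modelled as multiplicative and smooth per slice. The
field is estimated only from the bright (fat-like) voxels — selected by a
two-stage Otsu cut — because subcutaneous and internal fat share one true
intensity, so their log-intensities sample the bias field directly without
anatomy leaking into the fit. A degree-4 polynomial is fitted to those
log-intensities by least squares, exponentiated, normalized to unit mean
over the estimation voxels, clipped to [1/3, 3] against extrapolation
outside the body, and divided out; the corrected slice is rescaled to
preserve the mean foreground intensity. A degree-4 fit contains the
degree-2 generating family of the phantom, so on noiseless data the
generated field is removed exactly.

## Unrolling and boundary detection

Each slice is resampled on 360 rays from the body-mask centroid with a
radial step of half a pixel (0.586 mm) — fine enough that the integer
boundary radii localize the annulus to sub-pixel accuracy. The outer
(skin) boundary is the last foreground sample per angle, refined to the
sub-sample 50 % crossing before rounding, which halves the quantization
error. The inner boundary is the exact minimal-cost circular path: one
radius per angle, jumps between adjacent angles bounded by delta = 2
samples (wrap-around included), cost = the negated outward-rising radial
gradient of the smoothed polar image (Gaussian sigma 2 samples along
angle, 1 along radius), restricted to at least 3 samples inside the outer
curve. Using the rising-gradient sign rather than the gradient magnitude
keeps the path off the skin edge (a falling gradient) and lets circular
continuity reject the incidental rising edges of visceral fat blobs. The
search runs the column-wise dynamic program jointly for all start radii
(a 2-D state updated with a sliding-window minimum), so circular closure
is handled exactly; for a single surface this is equivalent to the minimal
closed-cut formulations of optimal surface detection. A brute-force path
enumerator over tiny polar grids serves as the oracle in the tests.

## Internal-fat threshold

The threshold derives from a 5-component 1-D k-means (10 restarts, seeded)
of the internal-compartment intensities. The sorted centres split into a
lower (muscle/organ) and an upper (fat) group; the threshold is the
midpoint between the 3rd and 4th sorted centres — i.e. fat is everything
above the median cluster. The alternative of using the median centre
itself is selectable but not the default: whenever fat is a minority of
the compartment, three of the five centres land inside the muscle mode and
the median centre sits *within* the muscle intensity distribution, which
floods the depot with false positives. The midpoint rule places the cut in
the muscle–fat gap in essentially every draw of a bimodal mixture with
fat fractions of 10–40 %. Segmentation is invariant to global intensity
scaling since both the boundary costs and the threshold are derived from
the data.

## Slice selection

Depot rules are pairs (upper landmark = first analyzed slice, lower
landmark = first slice containing the excluded structure): visceral from
the Th11/Th12 disc to the slice before the iliac crest; abdominal SAT from
the Th12/L1 disc to the slice before the femoral head; femoral depots from
the lower gluteal delimitation to the slice before the patella. Ranges are
half-open internally and inclusive in reports; the slice count is carried
into the ANCOVA as its covariate. Landmarks are inputs (phantom metadata
or user JSON); there is no vertebra auto-detection.

## Blood input function

The simulated input is a Feng-type curve, `(A1·u − A2 − A3)e^{l1 u} +
A2 e^{l2 u} + A3 e^{l3 u}` with u = t − t0: a sharp peak (~103 kBq/ml at
~0.8 min with the defaults) and two washout terms, zero before the 0.5-min
appearance time. It integrates in closed form, which anchors the AUC and
extrapolation tests. The defaults are conventional bolus kinetics, not
matched to any cohort's measured curves. For the static-scan AUC the
sampled curve is integrated by trapezoid and a mono-exponential fitted
log-linearly to the last 20 min is integrated analytically to the static
mid-time (70 min, the middle of a 2×10-min acquisition after the 60-min
dynamic scan); a non-decaying tail falls back to constant extrapolation
with a warning.

## Tissue kinetics

Tissue curves follow the irreversible two-tissue-compartment model,
`Ct = Vb·Cp + K1/(k2+k3)·(k3 + k2·e^{−(k2+k3)t}) ⊛ Cp`, evaluated by FFT
convolution on a 0.0025-min grid and averaged over frames through the
cumulative integral (exact frame averaging, not midpoint sampling). Frame
noise is multiplicative Gaussian. The dynamic Ki estimator is the Patlak
slope on frames with mid-time ≥ t* = 20 min, ordinary least squares with
uniform weights, with the blood integral trapezoided on the sampled input.
The compartmental alternative is seeded multi-start weighted least squares
(weights ∝ √frame duration, log-parameterized rates, k4 = 0) and recovers
simulated rate constants to well under 1 %.

Two intrinsic limits of the graphical method are worth recording. With a
decaying input, a purely reversible tissue (k3 = 0) leaves a small
residual Patlak slope (≈ −2×10⁻⁴ with the default input), and for very
slow trapping (k3 ≈ 0.01 min⁻¹) the unequilibrated reversible transient
biases the slope by several percent of the tiny Ki even on noiseless data.
These are properties of the approximation — the compartmental fit on the
same curves is unbiased — and the tests bound them rather than hide them.

Decay correction is `exp(ln 2 · t_mid / 109.77 min)` per frame referenced
to scan start; a flag on the curve makes double application an error. The
static ("estimated") Ki is the fractional uptake rate, late tissue
concentration over blood AUC; it upper-bounds the Patlak Ki by
V₀·Cp(T)/∫Cp, and the bound tightens as the blood curve decays — both
verified as properties in the tests. CT adipose VOIs are 26-connected
components within [−150, −50] HU (inclusive ends) from a seed voxel;
erosion is per-slice 2-D by a disc of radius 2 pixels, since the scans'
in-plane and through-plane resolutions differ by a factor of several.

## Cohort simulation and statistics

Cohorts are two groups of 20 with two visits. Depot masses are
`baseline mean × group multiplier × participant intercept × time
multiplier × slice-count ratio × noise`, with log-normal unit-mean
intercept (CV 0.30) and residual (CV 0.05) — masses are positive and the
encoded effects are relative changes, hence multiplicative throughout. The
analyzed-slice count (13–19, constant within participant) scales mass, so
the ANCOVA covariate is informative. Defaults encode the study conditions:
training multiplies SAT by 0.96 and VAT by 0.94 in both groups, and
visceral glucose uptake is 2.39× subcutaneous. Baseline depot means
(SAT 4.0 kg, VAT 1.2 kg, femoral 5.0 kg) are configurable conventions for
a normal-weight cohort, not measured values. Note that with multiplicative
noise the expected arithmetic follow-up/baseline ratio exceeds the true
multiplier by a factor 1 + CV², about 0.25 % at the default CV.

The mixed model is `value ~ group * time` with a random participant
intercept (compound symmetry — no richer covariance is identifiable with
two visits), fitted by REML through statsmodels; main effects are
contrasts averaged over the other factor, and tests use containment
degrees of freedom `n_obs − rank(X) − (n_participants − 1)`, which are
deterministic and exact for balanced two-period data (the single-group
time contrast reproduces the paired t-test to optimizer tolerance,
~10⁻⁵ on the t statistic). A fit with zero within-subject variance falls
back to per-group paired summaries with a warning. ls-means within-group
change contrasts are reported when the interaction is significant (or on
request) and are deliberately unadjusted for multiplicity, stated in the
report metadata. The ANCOVA is an ordinary linear model with sum-coded
factors and type-III F tests; it ignores the repeated-measures pairing,
so for within-subject effects it is conservative relative to the mixed
model. Outcomes are analyzed on the raw scale by default with a log-scale
flag, matching the multiplicative generator.

Power and type-I error are estimated by seeded Monte-Carlo rejection rates
with normal-approximation binomial intervals. At the defaults the
interaction's type-I error over 1000 null cohorts sits near 5 %, and a
−6 % time effect at n = 20/group is detected essentially always; the
power-calibration test instead tunes the within-subject CV analytically
(t-quantiles at the containment df) so that a 20 % change yields ~80 %
power, and verifies the simulation reproduces it.

## Reproducibility and problem sizes

A single run seed fans out to per-stage seeds by SHA-256 hashing, so any
stage rerun alone reproduces its part of a full run; result files carry
the config hash and seed and contain no timestamps, making fixed-seed runs
byte-identical. Default problem sizes keep the whole suite desk-scale: a
233×233×10 phantom (~0.5 M voxels) for segmentation, 100 noisy curve
replicates for Patlak, 1000 + 500 cohort replicates for the error-rate and
power estimates, and 8-angle × 6-radius grids for the exhaustive path
oracle. These sizes give Monte-Carlo standard errors comfortably inside
the tested bounds.

## Known limitations

No PET reconstruction, attenuation/scatter, partial-volume or metabolite
modelling; no reversible (k4 > 0) kinetics; no vertebra or marrow
auto-detection (landmarks and exclusion masks are inputs); MR physics is
not simulated; the aorta VOI geometry for a real IDIF (dimensions,
partial-volume handling) is out of scope. Conclusions from the synthetic
suite transfer to real data only to the extent that the phantom's
homogeneous-tissue assumption holds.
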