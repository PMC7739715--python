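# adipoquant

Quantification of adipose-tissue mass and insulin-stimulated glucose uptake
from MRI and dynamic [18F]FDG-PET, exercised end to end on synthetic
phantoms and simulated cohorts with known ground truth.

The package is aimed at imaging scientists who need a tested, reproducible
re-implementation of the analysis chain used in exercise-intervention
studies of body composition in mid-life women: how much subcutaneous (SAT)
and visceral (VAT) fat a participant carries, how avidly each depot takes
up glucose under insulin stimulation, and whether a training intervention
changed either — without access to participant data.

## What it computes

**MRI depot masses.** Axial T1 slices (pixel 1.1719 × 1.1719 mm, slice
pitch 7.2 mm) are bias-corrected, each slice is unrolled into polar
(angle × radius) coordinates, and the subcutaneous fat annulus is
delineated by two exact minimal-cost circular paths (dynamic programming
with a smoothness bound, the single-surface form of optimal graph-search
segmentation). Internal (visceral / inter-muscular) fat is thresholded at
a cut derived from a 5-component k-means clustering of the internal
compartment, with manually supplied liver and bone-marrow masks excluded.
Depots are restricted to anatomical slice ranges given by landmarks
(Th11/Th12 disc, iliac crest, femoral head, patella) and converted to mass
as

&nbsp;&nbsp;&nbsp;&nbsp;mass = voxel count × (1.1719² × 7.2 mm³) × 0.9 kg/L.

**PET glucose uptake.** Dynamic 60-min abdominal acquisitions are framed
as 12×10 s + 4×120 s + 10×300 s (26 frames). With an image-derived input
function Cp(t) from an aortic VOI, the FDG influx rate constant is the
Patlak slope

&nbsp;&nbsp;&nbsp;&nbsp;Ct(t)/Cp(t) = Ki · ∫₀ᵗCp dτ / Cp(t) + V₀,&nbsp;&nbsp;t ≥ t* = 20 min,

with an irreversible two-tissue-compartment fit (k₄ = 0) as cross-check.
Regions covered only by a late static scan use the fractional uptake rate,
mean VOI activity divided by the blood AUC extrapolated to the static
mid-time (70 min). Glucose uptake follows

&nbsp;&nbsp;&nbsp;&nbsp;MR_glucose = 1000 · Ki · [glucose] / (LC · ρ),&nbsp;&nbsp;LC = 1.14, ρ = 0.9 g/ml,

in µmol · kg⁻¹ · min⁻¹. Adipose VOIs come from CT connected thresholding
in the −150…−50 HU window with a two-pixel erosion against spillover.

**Statistics.** Outcomes are analyzed with a linear mixed model (group ×
time fixed effects, random participant intercept, REML, containment-df
tests, ls-means within-group contrasts) and, for masses, a two-way ANCOVA
with the number of analyzed slices as covariate. Simulation harnesses
estimate type-I error and power.

**Phantoms.** Every input above is generated synthetically: MRI/CT
abdominal and thigh cross-sections with exact per-voxel labels and depot
masses, tri-exponential blood curves with closed-form AUC, 2TCM tissue
curves with known Ki, and two-group pre/post cohorts with multiplicative
training effects (defaults: SAT ×0.96, VAT ×0.94, visceral/subcutaneous
uptake ratio 2.39).

## Worked example

```bash
adipoquant simulate-tac --out demo
adipoquant quantify-pet --tac demo/tissue_tac.csv \
    --input-function demo/input_function.csv --glucose 5.0 --out demo/pet.json
```

prints

```
Ki = 0.00959 ml/ml/min, MRglucose = 46.71 µmol/kg/min -> demo/pet.json
```

The simulated tissue uses K1 = 0.05, k2 = 0.25, k3 = 0.06 min⁻¹, so the
true influx constant is K1·k3/(k2+k3) = 0.009677 ml·ml⁻¹·min⁻¹; the Patlak
estimate 0.00959 recovers it within 1%, and MR_glucose converts it to a
glucose uptake of 46.7 µmol per kg tissue per minute at 5 mmol/L plasma
glucose.

The same from Python, for a full phantom run:

```python
from adipoquant import RunConfig, run_pipeline
bundle = run_pipeline(RunConfig(seed=7, output_dir="run"))
print(bundle["masses"]["visceral"])         # recovered vs true depot mass
print(bundle["kinetics"]["visceral"])       # Patlak Ki, static Ki, MRglucose
print(bundle["analysis"]["visceral_mass"])  # mixed-model group/time report
```

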