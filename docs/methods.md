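# Methods

`mcbp` implements a simulation-first route to cuffless blood pressure: a
voxel Monte Carlo model of light transport through a finger predicts how the
detected photon intensity depends on arterial pressure, and measured PPG
signals are mapped onto that simulated scale and inverted back to pressure.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic tests do and do not demonstrate.

## Finger model

The finger is a layered slab: stratum corneum (0.02 mm), epidermis (0.25),
papillary dermis (0.10), upper blood net dermis (0.08), reticular dermis
(0.20), deep blood net dermis (0.30), fat (0.55), muscle (1.5) and bone
(2.0 mm), mirrored about the bone so a transmission detector sees skin on
both faces. Each layer carries (μa, μs, g, n) at 905 and 940 nm from the
packaged constants table; these constants are authoritative. The
chromophore-mixture formulas (baseline power law 7.84·10⁷·λ⁻³·²⁵⁵, melanin
6.6·10¹⁰·λ⁻³·³, water/melanin volume-fraction mixing for the epidermis and
stratum corneum, and the general k-constituent mixture) are exposed as
utilities for custom tissues; they do not exactly regenerate the packaged
dermal constants, which derive from digitized literature spectra, and we do
not force agreement.

The digital artery is a cylinder along the axis perpendicular to the
reflection source–detector offset, centred at the interface between the
upper blood net dermis and the reticular dermis. Its lumen diameter follows
d = 0.8531·p^0.1023 (d in mm, p in mmHg; ≈1.37 mm at 100 mmHg), with a
0.2 mm wall annulus. Lumen and wall volume fractions of the coaxial
cylinder weight the whole-blood and vessel-wall absorption coefficients
into a single homogenized artery medium (a lumen+wall two-media mode is a
config switch). Artery scattering is fixed (μs 4.85 mm⁻¹, g 0.8, n 1.39).

**Artery embedding.** At any pressure in the working range the artery's
outer diameter (1.65–1.87 mm) exceeds the 0.95 mm dermis, so a cylinder
literally carved into the default stack would breach the skin surface. The
default geometry therefore *inserts* a band of thickness equal to the outer
diameter at the artery depth and shifts the deeper layers down; the band is
filled with reticular dermis around the cylinder. Total slab thickness then
grows with pressure (≈9.8 mm at 100 mmHg). The alternative `"overwrite"`
embedding carves the cylinder into a fixed stack, raising a geometry error
when it does not fit — usable with custom, thicker dermal stacks.

## Photon transport

A voxel Monte Carlo random walk with photon packets (hop–drop–spin):

- step lengths from l = −ln ξ/(μa+μs), with the dimensionless optical
  pathlength carried across voxel boundaries so heterogeneous voxels are
  traversed exactly; μt = 0 voxels are ballistic;
- implicit capture: at each interaction, the fraction μa/μt of the weight
  is deposited in the local voxel, the rest is scattered through a
  Henyey–Greenstein polar angle (inverse-CDF sampling; isotropic branch at
  g = 0) and uniform azimuth;
- unpolarized Fresnel reflection / Snell refraction at voxel faces where n
  changes and at the air–tissue surface (n_out = 1), including total
  internal reflection; specular reflection at launch; lateral faces are
  matched-index escapes binned separately (finite finger width);
- Russian roulette below weight 10⁻⁴ with survival probability 0.1. To
  keep the per-run weight ledger exact, killed weight is charged to the
  absorbed tally and the survivor boost is credited against it; the tally
  stays unbiased in expectation while reflected + transmitted + absorbed +
  lateral always equals the launched weight to ~10⁻¹⁴ relative;
- an interaction cap of 10⁶ events per packet guarantees termination
  (cap terminations are counted and are zero in practice).

The kernel is numba-compiled and single-threaded; a (configuration, seed)
pair reproduces bit-identical tallies. Detected intensity is the weight sum
exiting into the detector aperture, normalized per launched packet
(recorded in the output metadata). Default apertures: a 1 mm square on the
exit face opposite the source (transmission) or offset 0.4 mm on the entry
face (reflection); a negative half-width accepts the whole face. The
engine is validated against closed forms (Beer–Lambert ballistic limit,
HG first moment, exponential step mean, Fresnel normal incidence) and
against an independently written, vectorized non-voxel layered Monte Carlo
(`tests/mc_oracle.py`) on a two-layer slab.

## Pressure → intensity table

Sweeping pressure over 42–200 mmHg (grid count ⌊(max−min)/step⌋+1; the
full 1 mmHg grid has 159 points) rebuilds the voxel model per point and
records detected intensity with its Monte Carlo standard error. By default
all points share one RNG stream (common random numbers): photon histories
are identical until they reach the artery region, which cancels most of the
point-to-point noise in pressure *differences*; independent per-pressure
substreams are available (`seed_strategy="split"`).

Monte Carlo noise can still break monotonicity, and inversion needs a
single-valued map, so the table is passed through isotonic regression
(pool-adjacent-violators) oriented by the sign of the Spearman correlation
of the raw table; the operation is idempotent and a trend-free table is
rejected with advice to raise the photon budget. Inversion is
piecewise-linear inverse interpolation; flat runs map to their mean
pressure; intensities outside the range clamp to the endpoint pressures and
set a flag.

**Benchmark geometry.** The full mirrored finger transmits only ~10⁻⁶ of
the launched light, and the pressure dependence of that transmittance is a
few percent — resolving it would need ≥10⁷ packets per grid point. The
packaged `compact_benchmark_geometry()` keeps the skin layers and the
artery model untouched but thickens the reticular dermis to 2.0 mm (so the
artery fits wholly inside the dermis, overwrite embedding), trims fat,
muscle and bone to 0.1 mm each and drops the mirrored side. Transmission is
then ~2·10⁻² with a strong monotone pressure dependence (+50 % over the
range, dominated by the low-scattering artery displacing high-scattering
dermis), which 2·10⁵ packets per point resolve cleanly. Tests and the
acceptance script tabulate on this geometry at a 20 mmHg step; the default
finger remains the package default for production sweeps.

## PPG processing

Segments are band-pass filtered with a zero-phase 6th-order Butterworth
(0.5–25 Hz for the 1 kHz public-style profile, 0.5–8 Hz for the 83 Hz
selfmade-style profile); forward–backward filtering keeps beat landmarks
unshifted. Systolic peaks are local maxima above a moving 60th-percentile
threshold (two-beat window) separated by at least 0.4 expected beat
periods; pulse onsets are the same detector on the negated trace, paired
one-to-one with the following peak. Signal quality is the sample skewness
and excess (Fisher) kurtosis; cohort screening ranks subjects by summed
per-segment skewness with deterministic id tie-breaks.

Per-subject intensities are medians across all beats and segments. Three
readout conventions exist: `"filtered"` (zero-mean band-passed values, the
default), `"raw"` (raw device units at the detected indices) and
`"filtered_plus_dc"` (band-passed value plus the raw segment mean). The
pipeline uses `filtered_plus_dc`: a zero-mean trace retains only the pulse
amplitude, from which systolic and diastolic *levels* cannot be separately
identified, while restoring the segment mean keeps the denoised values on
the device's absolute intensity scale that the calibration needs.

## Calibration and estimation

Per branch (systolic/diastolic), an XGBoost regression ensemble (300 trees,
depth 4, learning rate 0.05, subsample 0.9; all overridable) maps the
six-feature vector (systolic intensity, diastolic intensity, skewness,
kurtosis, BMI, pulse rate) to the simulated intensity interpolated from the
table at the subject's reference SBP or DBP. No per-subject
personalization. Accuracy is the mean R² over 10-fold cross-validation
repeated 3 times with derived seeds; rows are sorted by subject id first so
the score is row-order invariant; the final model refits on all rows.

Two numerical notes: (1) targets are standardized before fitting — with raw
targets of magnitude ~10⁻², XGBoost's tree building stalls with a large
un-fit residual independent of rounds or learning rate; predictions are
mapped back through the stored affine transform and clamped at zero.
(2) models persist as raw Booster JSON plus a metadata sidecar, because the
sklearn-wrapper save path is broken against current scikit-learn releases.

Estimation inverts each branch's calibrated intensity through its monotone
table; MAP = DBP + (SBP − DBP)/3 (a convex combination, so MAP always lies
between DBP and SBP). DBP > SBP pairs are flagged and reported unmodified.

## Evaluation battery

MAE, RMSE, SD of the signed error (n−1 denominator), Pearson r, and R²
taken as r² (documented convention; RMSE² = bias² + SD²(n−1)/n holds).
Bland–Altman bias with 1.96·SD limits of agreement. BHS grading from
cumulative error percentages at 5/10/15 mmHg (A: 60/85/95, B: 50/75/90,
C: 40/65/85, all three conditions required, else D). The AAMI-style check
passes iff MAE ≤ 5 and SD ≤ 8 mmHg (inclusive); the ≥85-subject cohort
guideline is an informational flag. Error-grid analysis for MAP classifies
(reference, estimate) pairs over a configurable polygon partition; the
packaged default uses symmetric bands of half-width 5+5 %, 12+10 %,
20+15 %, 35+25 % of the reference for A–D and E elsewhere, validated as a
total non-overlapping partition, with boundary points assigned to the
better region (a 10⁻⁴ mmHg tolerance absorbs vertex rounding in region
files).

## Synthetic data

Covariates (SBP, DBP, BMI, pulse rate, age) are truncated normals matching
the published summary statistics of the two cohort profiles
(public-style: SBP 124.4±19.7 in [80, 182], 1 kHz, 3×2.1 s segments;
selfmade-style: SBP 104.6±11.7 in [81, 133], 83 Hz, 1×240 s), with joint
redraws until SBP > DBP + 10. PPG waveforms are beat trains from a
two-Gaussian pulse template (systolic wave at 30 % of the beat, smaller
diastolic wave at 62 %), rescaled per beat so the onset sample equals the
DBP-coupled level and the systolic peak the SBP-coupled level:
level = polarity·gain·table(pressure) + offset. The polarity flips
automatically for decreasing (transmission) tables, as a transimpedance
front end does, so systolic landmarks are maxima. Beat-period jitter is
uniform ≤3 %; additive white noise, 0.25 Hz baseline wander, per-beat
amplitude jitter and per-subject gain jitter all scale with a single noise
level in the end-to-end fixture, so "zero noise" is fully deterministic
given the seed.

**What the synthetic tests show.** With the generator coupled through the
same table used for calibration targets and inversion, zero-noise recovery
is exact up to waveform-sampling error (MAE ≪ 1 mmHg) — an identifiability
check of the whole chain, not a clinical accuracy claim. At 5 % noise the
cohort-level errors stay small mainly because calibration is fit and
evaluated on the same 30 subjects (the workflow the reported protocol
implies); the held-out-noise property test shows errors growing with noise
as expected. Real PPG adds morphology variability, motion artifacts and
device nonlinearity the generator does not model, and the cross-validated
R² on 30 subjects is far below what a real, larger cohort with a wider
pressure range could give. None of the published cohort error statistics
can be reproduced without the original recordings.

## Problem sizes

Defaults: 10⁶ packets per table point on the full finger. Tests and the
acceptance script use: 10⁴ packets × 20 randomized configurations for the
conservation audit; 10⁶ draws for sampling-law moments; 10⁵ packets for the
Beer–Lambert and oracle comparisons; 3·10⁴ for fluence localization on the
default finger; 2·10⁵ packets × 8 points (20 mmHg step) for the benchmark
table; and a 30-subject selfmade-style cohort for end-to-end recovery.
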