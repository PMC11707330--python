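# Methods

## Measurement model

A lane of a capillary gel electropherogram (or a 1-D agarose lane profile) is
modelled as a sum of isoform bands on top of a slowly varying background:

    s(t) = b(t) + Σ_i m_i · r_i · g_i(t) + ε(t)

where `m_i` is the DNA amount of isoform `i ∈ {Lin, SC, OC}`, `r_i` its
detector response per unit amount, `g_i` a unit-area band shape centered at
the isoform's migration time, `b(t)` the background and `ε` detector noise.
The quantity of interest is the fraction vector

    f_i = (A_i / e_i) / Σ_j (A_j / e_j)

where `A_i` is the band area assigned to isoform `i` and `e_i` a dye
attachment efficiency. Fractions are invariant under rescaling the whole
signal, which is why they are comparable across concentrations and runs
without per-run calibration — the property the mixture-linearity and
concentration analyses verify.

Assumptions: bands are well approximated by Gaussians at this resolution;
the background is linear in time over the separation window (or equals the
pure-buffer lane's signal); band positions may shift rigidly between
capillaries but band shapes do not change; detector noise is additive,
homoscedastic and zero-mean.

## Processing steps and numerical choices

**Background.** Linear mode fits an ordinary least-squares line to all
samples outside the three isoform windows (≥ 10 samples required — fewer is
an error, not a silent fallback). Buffer mode subtracts a pure-buffer lane,
resampled onto the sample grid by linear interpolation when grids differ;
disjoint grids are an alignment error. In the batch pipeline, buffer mode is
followed by a linear refit to remove residual drift.

**Windows.** Defaults are Lin [350, 450] s, SC [450, 600] s, OC [650, 850] s
around the pUC19 band centers at 400/500/750 s. Centers are physical; widths
are a package convention (no published widths exist) chosen to cover the
visible bands without overlap, and are config-exposed. With an
alignment-marker lane, all windows shift rigidly by (marker apex − reference
time); the apex must stand ≥ 5× the lane's robust noise above its median.

**Integration.** Trapezoidal rule on the native grid, with the signal
linearly interpolated at window endpoints so that integration is exactly
additive under window splits. Negative raw integrals (noise in an empty
window after background subtraction) are clipped to 0 and flagged; only
clipping larger than numerical roundoff emits a warning. At the default 1 s
sampling the trapezoid error for a σ ≥ 5 s Gaussian is far below every
tolerance used; the dominant integration error is tail truncation by the
window. The default OC window truncates ≈ 0.1 % of a σ = 30 s band; the
exact-recovery guarantees below therefore use *matched* windows
(`synth.matched_windows`, center ± 6σ, truncation < 2e-9).

**Noise and QC.** Noise σ is 1.4826 × the median absolute deviation of the
signal outside all windows (robust to residual peaks); per-window
SNR = max signal inside / σ, with an infinity sentinel at zero noise. A
sample lane is included iff min-over-windows SNR ≥ `min_snr` (default 10),
total integrated intensity ≥ `min_total`, and no saturation plateau (≥
`min_run` = 5 consecutive samples at or above the configured full-scale
level). The saturation level is never inferred from the data — silent
quantile heuristics would mask clipping — so the check is skipped unless a
level is configured. Note that the min-over-windows rule is strict: a lane
genuinely lacking one isoform has only noise in that window (SNR ≈ 3), so
mixture-type lanes are screened with a lower threshold or with QC applied to
the bands expected to be present.

**Dye correction.** Gel quantification divides the SC band intensity by the
SYBR-Gold SC/OC attachment-efficiency ratio 1.05 before normalization;
capillary quantification applies unit efficiencies (no correction is defined
for the capillary dye, and the fractions are normalized within each lane).

**Deconvolution.** Overlapping gel bands are fitted as a sum of Gaussians by
bounded nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective) over (center, σ, area) per peak, with σ > 0, area ≥ 0 and centers
inside the axis range; non-convergence returns the last iterate with
`converged=False`, which downstream code must not use. Initialization is the
caller's (typically apexes of the visible bands); the fit tolerates coarse
inits in practice. For two bands of σ = 8 placed 1.9σ apart with both apexes
at SNR 50, the *expected* per-band area error is below 2 %; individual noise
realizations scatter around that (s.d. of similar magnitude), so accuracy
tests assert the mean over a fixed seed ensemble rather than a single draw.

**Size calibration.** Ladder peaks (local maxima ≥ 5× robust noise above the
median) are paired in order with the ladder's band sizes — a count mismatch
is an error, never a partial match. Apparent size interpolates log(size)
linearly in migration time between knots; outside the knots the edge
segments' slopes extrapolate, with a warning. Monotonicity of the map follows
from strictly increasing knots.

**Study analyses.** Replicates aggregate as arithmetic mean and sample SD
(n−1); n = 1 yields NaN SD with an explicit flag rather than a silent zero.
Mixture linearity normalizes each level's mean SC fraction to the mean of the
100 %-SC reference level (replicate means first, then the ratio — the
aggregation order is a package choice) and fits unweighted OLS; R² is the
squared correlation, identical to 1 − SS_res/SS_tot for a line with
intercept. The concentration analysis reports the spread of mean SC fraction
across levels and the Pearson correlation of concentration with mean total
intensity. The kinetics analysis only tabulates fractions per (incubation
time, run) and their run-2 − run-1 deltas; no rate model is fitted — the
first-order model `f_lin(t) = 1 − exp(−kt)` exists in the simulator as
ground truth only.

## The synthetic generator

`synth` emulates pUC19 capillary densiograms: a 0–1320 s grid at 1 s steps;
unit-area Gaussian bands at 400/500/750 s with σ = 5/8/30 s (sharp Lin and
SC, broad low OC — at equal amounts the SC peak is higher and narrower than
OC); a linear baseline (default intercept 2, slope 0.01 signal units/s, so
drift is of the same order as the bands); additive Gaussian noise (default
0.05, i.e. 1 % of the pure-SC apex at total mass 100); migration jitter
drawn once per capillary (default σ = 2 s); optional hard clipping at a
detector ceiling. Study designs: SC:OC mixture series (per level x,
sc = x·M, oc = (1−x)·M, plus one buffer lane), digestion series (first-order
SC→Lin; a second run converts an extra fraction of each lane's remaining SC,
modelling continued room-temperature digestion between back-to-back runs —
a single extra-conversion fraction, not a second rate constant, since only
the direction and rough size of the effect are constrained), and agarose
profiles (gel-position axis, SC intensity ×1.05, OC/Lin centers 1.5σ apart
in overlap mode).

What the generator does *not* emulate: asymmetric/tailed band shapes,
baseline curvature, heteroscedastic or correlated noise, injection-amount
variability, lane-to-lane response drift, and gel smile. Passing tests
therefore demonstrate correctness of the analysis chain under the stated
model, not robustness to every instrument artefact; the QC layer is the
guard against the grossest real-data violations (low SNR, clipping).

With noise, jitter and clipping disabled and matched windows, the pipeline
recovers the generating fractions to 1e-6 (observed ≈ 3e-10); this
round-trip is the package's core correctness guarantee and is asserted as a
property test over random compositions.

## Problem sizes

Default analyses run in seconds: the dilution series is 34 lanes × 1321
samples, the digestion series ≤ 24 lanes, deconvolution fixtures ≤ 2400
points, and the full test suite completes in a few seconds on one CPU. These
sizes match the scale of the emulated experiments (8–12 lanes per
cartridge/gel, a handful of replicates).

## Known limitations

* Window quantification is biased when bands overlap or drift beyond the
  window edges; the marker shift handles rigid drift only (an optional
  two-point affine warp is the natural extension and is not implemented).
* The min-over-windows QC rule penalizes lanes that legitimately lack an
  isoform (see above).
* Gaussian deconvolution assumes the band count is known; model selection
  (how many bands) is out of scope, though a superfluous peak shrinks to
  near-zero area in practice.
* Fractions are relative; absolute amounts require an external response
  calibration, which the package does not attempt.
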