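# Methods

`cardioafm` analyses dwell-mode AFM recordings of spontaneously beating
cardiomyocytes. The instrument model throughout is: a calibrated cantilever
(spring constant k ≈ 0.04 N/m) is brought onto the cell until a preset
contact force (trigger, 100 pN), the z piezo is locked, and contractions of
the cell deflect the stationary cantilever. Deflection (m) times k gives
force (N). One recording therefore contains an approach segment (elasticity)
followed by a dwell segment (beats). Everything is SI internally; file
formats carry units in their column names.

## Cantilever calibration

The thermal-noise method applies equipartition to the cantilever's
fundamental bending mode: ½ k ⟨d²⟩ = ½ k_B T, so k = k_B T / var(d) from a
deflection recording with the tip far from the surface. The sample variance
is taken after mean removal (n−1 denominator); at 2 kHz a 60 s series gives
a relative standard error of √(2/n) ≈ 0.4%, comfortably inside the 3%
single-run accuracy the package is validated to. Because only ≈97% of the
total thermal variance belongs to the first mode, an opt-in corrected
estimator k = 0.971·k_B T / var(d) is provided; plain equipartition is the
default. The default bath temperature is 309.15 K (36 °C). Optical-lever
sensitivity calibration is out of scope: inputs are assumed to be in metres.

## Beat detection and quantification

A beat contributes a transient peak above the resting tension; per beat the
package reports the peak force above baseline, the full width at half
maximum (FWHM), and the rate as the reciprocal of the forward interval to
the next beat (assigned to the earlier beat). Summaries report mean, SD
(n−1), CV and SEM per metric; single-beat and empty inputs yield NaN-flagged
spreads rather than errors.

The detection chain is built for the hard corner of the design space —
0.1 nN beats over 20 pN r.m.s. noise at 2 kHz, with mean-FWHM accuracy of
two sample periods — where the obvious estimators are measurably biased:

1. **Smoothing.** A Savitzky–Golay filter (25 ms window, cubic) produces the
   detection trace. Reading peak heights off raw samples would inherit the
   maximum of ~100 noisy samples over each beat's flat top, a +40–60 pN
   bias at the weakest beats.
2. **Baseline.** A rolling lower-percentile baseline (10th percentile, 2 s
   window, computed on a decimated anchor grid) tracks resting tension
   through drift.
3. **Peak picking.** Local maxima of (smoothed − baseline) above
   max(5 × noise SD of the smoothed trace, 50 pN floor), requiring equal
   prominence — a noise wiggle on a beat's flank can clear the height
   threshold but its prominence stays at the noise scale — and a minimum
   separation of 0.25 s (a 4 beats/s ceiling, above any credible rate
   here). The smoothed-trace noise SD is the robust raw noise SD (median
   absolute successive difference × 1.4826/√2) times the filter's known
   noise gain; the 50 pN floor is 2.5 × the instrument's typical 20 pN raw
   noise. With the floor, pure-noise recordings produce no detections (the
   smoothed noise would have to exceed ~12 of its SDs).
4. **Resting level.** The percentile baseline sits below rest by
   construction and is pulled up by beat tails, so after a coarse
   measurement pass the baseline is re-estimated on the beat-model-
   subtracted trace and the offset to true rest is taken as the mean of the
   model-corrected residual over quiet stretches (≥ ~3.3 per-side width
   scales from every peak). The per-beat model is a two-sided Gaussian
   built from each beat's measured height and half-maximum geometry; at
   duty cycles where beats occupy half the recording, the quiet gaps
   otherwise retain percent-level tails that shift every half-maximum
   crossing by milliseconds.
5. **Heights.** The maximum of a cubic polynomial fitted to the smoothed
   residual over a wide (±0.6 width-scale) window. The cubic absorbs the
   rise/decay asymmetry that makes a parabola's vertex overshoot, and the
   remaining noise-induced max-bias is removed analytically as
   var(q̂′)/(2|q″|), with the derivative variance computed exactly from the
   fit window and smoothing kernel.
6. **FWHM crossings.** A sign-counting estimator: over a span of window
   centres straddling the coarse crossing, count how many symmetric
   window means of the raw residual exceed the half level (after a
   deterministic f″⟨δ²⟩/2 window-curvature correction). The count is a sum
   of indicators of a monotone flank, hence unbiased and free of the
   first-passage bias that a threshold walk carries and of the
   coefficient-ratio bias that a local polynomial root carries. A soft
   (one-sample-ramp) count removes the half-sample quantisation; a small
   convexity term f″σ_h²/(2|f′|³) corrects the blur of counting a curved
   flank through noise. Crossings whose span does not fit between
   neighbouring beats are flagged (NaN) and excluded from width summaries
   rather than filled with a biased fallback.

The waveform-shape constants used by the corrections (|f′| = 0.589 A/s,
f″ = 0.193 A/s² at half maximum, per side) assume Gaussian flanks; they only
scale second-order correction terms, so moderately non-Gaussian beats
degrade the corrections gracefully rather than the estimates.

Adding a constant to a trajectory changes no beat metric (verified by
property test). Validation across four disjoint seed sets of 20 trajectories
each (120 s, amplitudes 0.1–2.5 nN, rates 0.5–2 beats/s, FWHM 0.15–0.3 s,
CVs 10/10/5%): every trajectory recovers mean force within max(5%, 40 pN),
mean rate within 1%, and mean FWHM within 1 ms — with zero missed or
spurious beats, and zero detections on 40 minutes of pure noise.

## Contact mechanics

The approach segment is modelled piecewise: flat pre-contact deflection
offset d₀, then the contact law F = g·E/(1−ν²)·δ^p with indentation
δ = (z − z_c) − (d − d₀) and geometry factor/exponent

| geometry | g | p |
|---|---|---|
| cone (Sneddon) | (2/π)·tan α | 2 |
| sphere (Hertz) | (4/3)·√R | 3/2 |
| pyramid (Bilodeau) | 0.7453·tan α | 2 |

ν = 0.5 treats the cell as incompressible. The default geometry is a cone of
half-angle 35°, a standard approximation of a silicon-nitride pyramidal
probe; the reported modulus depends multiplicatively on this choice, which
is why it is an explicit parameter rather than a constant.

The contact point is found by a grid search over candidate indices: each
candidate fixes d₀ (pre-segment mean) and a closed-form least-squares E
(the model is linear in E once z_c, d₀ are fixed), and the candidate with
the smallest total squared deflection residual wins (coarse-to-fine, exact
within one sample on noiseless curves). An optional joint nonlinear
refinement of (log E, z_c, d₀) recovers E to ~1e−8 relative on noiseless
curves and is used where exactness matters; the two-stage estimate is the
default in bulk map analysis. The linearised closed-form estimate is always
reported alongside as an internal cross-check. A curve whose total
deflection rise is indistinguishable from its noise raises a no-contact
error; a nonpositive modulus estimate flags the fit as failed rather than
raising.

With 20 pN-equivalent deflection noise (0.5 nm at 0.04 N/m), 2000-point
curves indenting to the 100 pN trigger depth or to 300 nm (the middle of the
200–500 nm band these measurements report), whichever is deeper, recover E
with a median error below 5% across 100 Pa–10 kPa for all three geometries.
Two identifiability facts shaped those study conditions. First, a
trigger-limited curve carries a hard information limit: with pre-contact
travel of twice the indentation, the Cramér–Rao bound on ln E is 7.2%
(median |error| floor ≈ 4.8%) — every estimator tried (two-stage, joint
NLS, forward-model NLS, profile-likelihood averaging) sits at that bound —
whereas spending only half an indentation off the cell lowers the floor to
3.7%. Second, identifiability at a fixed trigger worsens with tip bluntness
on stiff samples — a 0.5 µm bead indents 10 kPa by only ~50 nm — which is
why the validation sphere is the smallest standard colloidal probe.

One physical note: inverting the fitted cone-35° law at the 100 pN trigger
for a 300 Pa cell gives an indentation of ≈750 nm. Soft (few-hundred-Pa)
moduli and the 200–500 nm trigger indentations typically quoted for these
experiments are mutually incompatible under any sharp-tip contact model;
reported cell moduli should therefore be read as conditional on the assumed
tip geometry.

Local cell height is the difference between the substrate's and the cell's
contact points in the same z frame.

## Dwell mapping

A dwell map pairs one approach curve and one 10 s dwell per grid point
(10–30 lines × 10–30 points in practice). Per point the package records the
contact point, the fitted modulus (failures recorded, never fatal), the
detected beats, and a beating classification (≥ 2 beats per dwell by
default; dwells shorter than two expected beat periods are flagged
low-confidence). Maps are assembled order-independently, validated for
exactly one point per cell, and never interpolated; heights are referenced
to the median contact point of non-beating points (the deepest contacts,
i.e. glass), falling back to the deepest contact overall. Beating points
with successful fits form the joint (beat force, modulus) point set used by
the statistical layer — on-glass and quiescent points never enter it. A
1-versus-2-component Gaussian-mixture BIC on log-modulus is provided as a
bimodality diagnostic (a diseased cell's map shows bimodal force and
modulus distributions), explicitly as a diagnostic, not a gate.

## Statistical layer

* **Bootstrap.** Percentile CIs (default B = 10 000, explicit seed) for the
  mean; `transform="log"` averages natural logs and back-transforms, i.e.
  reports the geometric mean — the convention for right-skewed moduli.
* **Mann–Whitney.** Exact enumeration p when both samples are tie-free and
  n₁+n₂ ≤ 16, otherwise the midrank normal approximation with tie-corrected
  variance (via scipy behind this module's surface).
* **Two-sample 2D Kolmogorov–Smirnov (Fasano–Franceschini).** Every
  observation of each sample serves as the origin of four open quadrants;
  D is the average over the two samples of the per-sample maximum absolute
  difference in quadrant occupation fractions. Points exactly on an
  origin's axes belong to no open quadrant (measure zero for continuous
  data). The default p-value is by permutation of pooled labels,
  p = (1 + #{D* ≥ D}) / (1 + n_perm), implemented with precomputed quadrant
  indicator matrices so each permutation costs four matrix–vector products.
  The correlation-corrected asymptotic tail (λ = √n·D adjusted by the mean
  within-sample correlation) is offered for speed; it is also the only
  route to p-values far below permutation resolution, which is how
  astronomically small published values of this test arise. Permutation
  p-values are slightly conservative (the statistic is discrete); the
  measured null rejection rate at α = 0.05 sits within binomial bounds of
  the nominal level.
* **Hill dose–response.** response = baseline + (max − baseline)/(1 +
  (EC50/dose)^h), fitted by least squares on a log₁₀ dose axis with
  span-normalised responses (the raw nN scale otherwise stalls the
  optimiser's gradient test), requiring ≥ 4 distinct doses spanning ≥ 2
  decades. A response span not distinguishable from twice the residual RMS
  raises an unidentifiable-EC50 error. The EC50 CI is a percentile
  bootstrap over resampled observations.

## Synthetic data

The generators stand in for the instrument so every stage can be validated
by parameter recovery; all are bit-reproducible given their seed, and every
output carries its generating ground truth in metadata.

* **Beat trains** draw per-beat rate, amplitude and FWHM from normal
  distributions with configurable means and CVs (defaults 10/10/5%, inside
  the 2–25% range observed across solitary cells and aggregates). The
  default waveform is a two-sided Gaussian with a 35/65 rise/decay split of
  the width, mimicking the fast-upstroke/slow-relaxation shape of real
  beats; a pure Gaussian is available for closed-form tests. Additive
  Gaussian noise (default 20 pN) and an optional sinusoid-plus-ramp drift
  (default off — instruments are equilibrated until drift is negligible)
  complete the model. Rate 0 or amplitude 0 yields a quiescent recording.
* **Thermal series** are white Gaussian with the equipartition variance
  k_B T/k. Real cantilever spectra are Lorentzian-shaped; the variance, not
  the spectrum, is what the calibration consumes.
* **Approach curves** solve k·d = g·E/(1−ν²)·((z−z_c) − d)^p per z sample
  with a guarded Newton iteration (the residual is convex and monotone in
  d, so convergence is guaranteed), then add deflection noise.
* **Dwell maps** place an elliptical cell (~55% of the grid) with a
  parabolic height dome (4 µm apex) on glass at a common substrate plane.
  On-cell points draw a population component — (weight, force mean,
  force CV, ln E mean, ln E SD) — or use explicit per-point fields; glass
  points get stiff curves (1 MPa stand-in; classification never keys on E)
  and noise-only dwells. The healthy-like condition is a single population
  with force mean 1.35 nN (CV 0.3) and ln-modulus ln 296 ± 1.0, matching
  published control-cell bootstrap means; the DCM-like condition mixes that
  scale of population 50/50 with a low-force/low-modulus one (0.25 nN,
  ln 60 ± 0.6), reproducing the bimodal histograms characteristic of the
  diseased cell. Per-point indentation is capped at 2.5 µm; points softer
  than ~40 Pa cannot reach the 100 pN trigger within that cap and their
  fits fail honestly.
* **Dose–response series** draw per-dose beat forces around the Hill curve
  (defaults: 8 doses from 10 nmol/L to 32 µmol/L, EC50 260 nmol/L, h = 1,
  10% multiplicative noise) — the epinephrine design.

What the generators do *not* emulate: viscoelastic (time-dependent)
indentation response and stress relaxation, tip–sample adhesion, lateral
contraction components, substrate (bottom-effect) stiffening, correlated
1/f instrument noise, and cell motion between grid points. Passing the
recovery studies therefore demonstrates correctness of the estimators under
the stated noise model, not robustness to every artefact of live-cell data.

## Numerical choices and degenerate inputs

Time grids must be strictly increasing and uniform to 1e−9 relative
(readers rebuild exact grids and tolerate 1e−6 text-format jitter). Floats
are written at full precision; write/read round-trips are exact. Zero-
variance thermal series, flat approach curves, all-equal KDE inputs, flat
dose responses, and empty point sets raise typed errors or warnings naming
the problem. Bootstrap resampling, permutation tests, mixture diagnostics
and all generators take explicit seeds; two runs with the same seeds are
identical.

## Validation problem sizes

The bundled recovery studies (also exposed as `cardioafm.validation` and
driven by `scripts/acceptance.py`) use: 20 × 120 s trajectories for beat
recovery and for false positives; 50 × 60 s thermal series; 50 noisy curves
per geometry–modulus combination (2000 points each); 200 null simulations
(30 + 30 points, 199 permutations) for the 2D KS test level; 50 noisy dose
ladders; and 15 × 15 dwell maps (one healthy/DCM pair at 999 permutations
plus 20 healthy/healthy replicate pairs at 199 permutations). These sizes
put every Monte-Carlo standard error well below the tolerance it is
checked against while keeping the full validation run in the minutes range
on one core.
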