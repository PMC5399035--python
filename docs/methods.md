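# Methods

This note documents the models, numerical choices and limitations of the
alphasync pipeline in enough detail to reproduce or audit any stage.

## Synthetic data model

### Phase coupling

Oscillator phases are generated from a correlated circular complex
Gaussian field. Innovations ε(t) ~ CN(0, Ρ) are AR(1)-smoothed with
coherence time τ (default 0.05 s — a phase-noise bandwidth of roughly
1/(πτ) ≈ 6 Hz around the carrier, commensurate with the 4.5 Hz analysis
band), and the phase of source k is φ_k(t) = 2π·f_c·t + arg z_k(t) with
f_c = 9.4 Hz by default. For a circular Gaussian pair with correlation ρ
the expected phase-difference resultant is

    PLV(ρ) = (π/4)·ρ·₂F₁(1/2, 1/2; 2; ρ²),

strictly increasing from 0 to 1, so any target PLV matrix is mapped
elementwise to a correlation matrix Ρ and is feasible exactly when Ρ is
positive semidefinite (checked by eigendecomposition; infeasible targets
raise an error naming the strongest requested pair). The map is inverted
on a 4001-point tabulation (max error < 5·10⁻⁴). This construction was
chosen over a mixing-calibration table because the PLV↔ρ relation is
closed-form, exact for every pair simultaneously, and gives a principled
feasibility criterion.

Realized PLV estimated from T samples converges to the target with the
usual resultant bias and variance; at τ = 0.05 s and rate 1 kHz the
effective sample count is roughly T/100, so a 40,000-sample run estimates
a target of 0.3 to about ±0.02 (1 sd).

### Signals, forward model, cohort

Source signals are env(t)·cos(φ(t)) + white noise, with a Rician envelope
|a + c(t)| (c: AR-smoothed complex Gaussian, so constant amplitude is the
zero-variance special case and the mean signal power is (a² + 2σ²)/2).
Defaults: a = 1, σ = 0.3, noise sd 0.5. Source amplitudes and SNR of
real recordings are not known quantities here; these values are package
choices, and sensor noise is added at 10% of the projected signal RMS.

The forward model is the analytic current-dipole field in a spherical
conductor (magnetometers only): volume currents cancel radially, radial
dipoles and dipoles at the centre are silent, and the implementation is
validated against a finite-difference gradient of the magnetic scalar
potential and against the free-space radial-component identity.

The toy head places 10 atlas areas (4 anterior, 6 posterior by
y-coordinate) quasi-uniformly on an 8 cm source shell inside an 80-
magnetometer cap at 12 cm, 2–3 tangential sources per area. Baseline
coupling is block-structured — 0.25 within the anterior and within the
posterior sets, 0.10 long-range — with within-area source pairs at 0.45.
The group phenotype raises 3 anterior edges (+0.12 SCD, +0.15 MCI) and
lowers 14 of the 15 posterior edges (−0.10 SCD, −0.12 MCI). Covariates:
ages N(70.4, 3.7²)/N(71.6, 4.5²)/N(73.0, 3.7²) by group; MMSE- and
BNT-like scores are linear in two realized edge PLVs (negative anterior
weight, positive posterior weight) plus Gaussian noise; normalized
hippocampal volume is 5.0·10⁻³ in HC/SCD and 4.4·10⁻³ in MCI (sd
0.5–0.7·10⁻³) with a weak positive posterior-edge loading. Epoch counts
are drawn per group (47.6 ± 7.3 / 46.2 ± 9.4 / 42.2 ± 7.0, floored at the
15-epoch inclusion minimum).

What the generator does *not* emulate: 1/f background spectra, ocular and
cardiac artifacts, head movement, realistic anatomy (BEM, cortical
folding), gradiometers, and non-stationarity beyond the AR envelope.
Passing tests therefore demonstrate correctness of the estimators and
statistics under a controlled phase-coupling model, not robustness to
every property of clinical recordings.

## Pipeline

### Spectral stage

Welch-style epoch-averaged periodograms (one Hann window per 4 s epoch,
zero-padded to ≤ 0.2 Hz resolution). The alpha peak is automated as the
highest local maximum of the posterior-channel-averaged spectrum in
6–13 Hz; a peakless spectrum raises an explicit error rather than
returning a range edge. "Posterior" channels are those with sensor
y ≤ −0.02 m (config). The band is (IAF − 2.5, IAF + 2) Hz; by default one
band from the sample-average IAF is applied to all subjects, with
per-subject banding as a config switch.

### Filtering

Windowed-sinc (Hanning) band-pass FIR, order 1800 at 1 kHz, scaled
proportionally (rounded to even) at other rates so the impulse response
keeps its duration in seconds. Epochs are reflection-padded (2000 samples
at 1 kHz, scaled likewise) and convolved twice (forward + backward
equivalent), giving an identically zero phase response and doubling
stop-band attenuation in dB. Because epochs are cut before filtering,
padding is by reflection rather than by neighbouring recording samples;
the resulting edge transients are confined to one kernel support per pass
(≤ 900 samples at 1 kHz) inside each epoch edge. Artifact rejection is a
z-score stand-in for interactive screening: per-epoch maxima of amplitude
and first-difference z-scores against thresholds (default 6).

### Beamformer

Scalar LCMV with diagonal loading C → C + λ·tr(C)/n·I, λ = 0.05 by
default. With free orientations the per-source scalar orientation is the
max-power direction: the minimiser of lᵀC⁻¹l restricted to the non-silent
subspace of the local leadfield (the radial direction of a spherical
conductor is silent and must be excluded before the eigenproblem).
Unit gain w_s·l_s = 1 holds to 10⁻⁶ by construction and is asserted in
tests; output variance grows monotonically with λ. The covariance is
estimated on band-filtered epochs (filtering precedes beamforming).

### Connectivity and significance

Hilbert phases per epoch (reflection padding as above). PLV per source
pair is the segment resultant, averaged arithmetically over segments;
area PLV is the literal double average over cross-area source pairs
(property-tested against the brute-force double sum at 10⁻¹²).
Per-link analytic significance uses the Rayleigh resultant test with
Zar's small-sample exponent; by default T is the nominal samples per
segment, with a config option to deflate T by the band's bandwidth ratio
(2W/rate) for narrowband autocorrelation. The nominal default is
anti-conservative for narrowband signals — it is a screening statistic
here, mirrored FDR-corrected per group in the run outputs.

### Group statistics

Type-II sum-of-squares F for the group factor (group after age), computed
by QR projection of the full (intercept + group dummies + age) and
reduced (intercept + age) designs; degenerate zero-residual edges return
F = 0. Permutations reshuffle group labels only, keeping (age, value)
pairs with their subjects and preserving group sizes; p-values carry the
+1 floor. BH-FDR is implemented directly (step-up, largest rank k with
p_(k) ≤ kQ/m) and cross-checked against statsmodels. Post-hoc contrasts
use age-adjusted group means at the grand-mean age and a Tukey-style
q statistic; family-wise correction within an edge refers each observed
|q| to the permutation distribution of the maximum |q| over the three
group pairs. Score correlations are Pearson with one joint BH family over
all (edge, score) pairs — the conservative reading of a joint correction.
The hippocampal-volume comparison reuses the scalar ANCOVA + permutation
machinery without FDR.

All randomness in a run derives from the single config seed via
`numpy.random.SeedSequence` spawning; reruns are byte-identical.

## Problem sizes used in the shipped checks

Desk-scale runs use 250 Hz sampling (filter order 450, padding 500
samples scaled), 32–80 sensors, 2 sources per area, and 8–20 epochs per
subject; the statistical recovery analysis uses 40 subjects per group
with 2,000 permutations and the null-calibration suites use 500
permutations over 20 seeds. These sizes are the package's choices for
routine verification; the generator's defaults (1 kHz, 4 s epochs,
39/41/51 subjects, study-like epoch counts, 10,000 permutations) remain
available for full-scale runs.

## Known limitations

- **Beamformer-path effect attenuation.** With phase-coupled sources the
  LCMV filter partially cancels the correlated (common-driver) component
  — it is the dominant covariance eigenvector — and leakage between
  reconstructed areas compresses downward coupling differences. On the
  toy head the anterior hyper-synchronisation survives reconstruction
  robustly, while posterior hypo-coupling deltas are attenuated several-
  fold and can invert for the most leakage-exposed area pairs; this
  persists across regularization (0.05–10), sensor counts (48–96) and
  source densities (1–3 per area). It is a genuine property of adaptive
  spatial filters under correlated sources, and exactly why the pipeline
  ships the beamformer-weight correlation diagnostic. The statistical
  recovery guarantees in the test suite are therefore stated at the
  connectivity level (generator phases → PLV → statistics), with the
  sensor→beamformer path validated by its own contracts (unit gain,
  point spread, single- and few-source recovery, leakage null).
- The analytic sphere cannot represent realistic head geometry; sources
  near radial orientation are weakly observable.
- The Rayleigh significance default ignores narrowband autocorrelation
  (see above); use `t_effective_mode: bandwidth` for a conservative
  variant.
- The permutation scheme assumes exchangeability of subjects under the
  null given age is kept with the subject; a Freedman–Lane variant is not
  currently implemented.
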