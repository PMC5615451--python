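# Methods

## Problem and model

Intracranial cerebrospinal fluid (CSF) oscillates with two physiological
drivers: a fast pulsation synchronized with the heartbeat and a slower
oscillation synchronized with breathing. `csfpulse` quantifies the two
contributions from an asynchronous (ungated) 2D phase-contrast MRI
acquisition: a single slice with through-plane velocity encoding sampled
continuously at a frame interval Δt ≈ 0.217 s for ≈ 55 s, VENC 10 cm/s,
under audio-guided respiration at a fixed period (6, 10 or 16 s). Velocity
is signed: positive = cranial (toward the head), per the foot–head flow
encode.

Per voxel, the velocity waveform v(t) is decomposed by discrete Fourier
transform into

- a **cardiac component** v_c(t): DFT bins with 1.0 ≤ f ≤ 1.6 Hz (resting
  heart-rate band; per-subject override supported),
- a **respiratory component** v_r(t): bins with 0.018 ≤ f ≤ 0.3 Hz,
- a **residual**: everything else, including the zero-frequency bin (mean
  flow and sub-respiratory drift).

Selection is brick-wall with inclusive edges and no taper. For the 55-s
record the bin spacing is 1/(253·0.217 s) ≈ 0.0182 Hz, which is exactly the
conventional respiratory-band floor: the band floor *is* the first nonzero
bin, so rectangular bin selection reproduces the band definition with no
edge ambiguity. Components are reconstructed by inverse DFT of their own
bins (conjugate-symmetric partners kept together, outputs real); the
residual is computed as input minus the two components so that the
additivity identity `cardiac + respiratory + residual = input` is exact
rather than within FFT round-off.

## Summary statistics

For each region of interest (ROI), direction and component:

- **Peak velocity.** Each voxel's directional extreme of the component
  waveform — largest positive sample (cranial) or most negative sample
  (caudal, reported with its negative sign) — averaged over the N ROI
  voxels. The alternative (peak of the ROI-mean waveform) is available via
  `aggregation="roi_mean_waveform"`; for spatially uniform ROIs the two
  agree, and per-voxel-then-mean was chosen as primary for consistency with
  the voxel-mean structure of the displacement measure.
- **Velocity fraction.** F_r = v_r/(v_r + v_c) on peak magnitudes,
  F_c = 1 − F_r.
- **Displacement.** D = (1/N) Σ_voxels [ Δt Σ_m v(m·Δt) ], where the inner
  sum runs over the M time points of a *directional excursion* — a maximal
  run of consecutive same-sign samples — and the per-voxel value is the
  mean over the record's excursions in that direction. This is the distance
  the fluid travels before flow reversal: for a sinusoid of peak V and
  period T every excursion displaces V·T/π, so a slow respiratory
  oscillation covers more ground per excursion than a faster cardiac pulse
  of larger velocity — the mechanism behind the respiratory dominance of
  displacement. Summing over the whole record instead (available as
  `mode="total"`) would scale both components by the record duration and
  erase the period dependence. Exactly-zero samples belong to neither
  direction (a measure-zero event for continuous-valued velocities).
- **Displacement fraction.** Same fraction form applied to |D_r|, |D_c|,
  separately per direction.

## Segmentation

CSF voxels are detected by their temporal velocity fluctuation (feature =
per-voxel temporal SD, cm/s; a sinusoid of peak A gives A/√2, static tissue
gives ≈ the noise SD). Because ≈2 mm voxels mix CSF and tissue (partial
volume), a soft clustering is used: fuzzy c-means (k = 2, fuzzifier m = 2)
run *inside a user-supplied rough rectangle* around each region, with a
spatial regularization step that multiplies each membership map by its
3×3-window local mean raised to `spatial_weight` (default 1) and
renormalizes. Per-rectangle clustering matters: CSF is a tiny minority of
the slice and the two regions differ ~4-fold in amplitude, so one global
clustering would absorb the fainter aqueduct into background.
Initialization is a deterministic quantile split; with `spatial_weight=0`
the iteration is plain FCM, whose objective is non-increasing (asserted in
tests); with the spatial step interleaved that monotonicity is not
guaranteed and is not claimed. Hard masks keep voxels with CSF-cluster
membership > 0.5 inside the rectangle, largest 8-connected component only.
Masks can also be supplied as files, bypassing segmentation entirely.

## Cohort statistics

Cardiac vs respiratory fractions are compared per region × direction ×
metric × period with the two-sided Mann–Whitney U test — exact by complete
enumeration of all C(n+m, n) rank arrangements when the pooled sample is
tie-free and ≤ 16 (at n = m = 7 the attainable minimum two-sided p is
2/3432 ≈ 5.8×10⁻⁴), otherwise a midrank normal approximation with tie and
continuity corrections — plus the two-sample Kolmogorov–Smirnov test
(statistic by direct ECDF sweep; p via `scipy.stats.ks_2samp`).
Between-period comparisons are unpaired, mirroring the test choice above,
although the design is actually repeated-measures; since F_c = 1 − F_r and
rank tests are invariant to strictly monotone transforms, one
between-period row per period pair carries the evidence for both
components. P-values are uncorrected by default (Holm optional).

## Synthetic data

The generator emulates one guided-respiration acquisition: a 256×256 slice
(tests and the acceptance script use 64×64 — identical physics, region
sizes and time axis; only the empty background shrinks) with an
"aqueduct" disc ~2–3 voxels across and a "foramen magnum" disc ~12 voxels
across. Region waveforms are

- cardiac: harmonic series Σ_k h_k sin(2πkft + φ_k), defaults
  h = (1, 0.5, 0.25), f = 1.2 Hz, normalized so the *peak* equals the
  stated amplitude (the peak is what the analysis reports). Harmonics at or
  above the sampling Nyquist (2.30 Hz at Δt = 0.217 s — i.e. all but the
  fundamental for normal heart rates) are dropped at generation, mimicking
  the undersampling of cardiac motion at ~4 frames per cycle rather than
  correcting it.
- respiratory: amp·sin(2πt/period), period ∈ {6, 10, 16} s.
- optional drift: a quarter-cycle sinusoid over the record
  (f = 1/(4·duration) ≈ 0.005 Hz, below the respiratory band floor);
  default off.

Aqueduct amplitudes default to 0.2 cm/s cardiac and 0.12 cm/s respiratory;
the foramen magnum scales these by 4.75 and 3.1 — the ratios of published
ROI-mean velocities in the two regions for healthy adults. Partial volume
is emulated by Gaussian spatial blur (σ = 1 voxel) of the velocity maps,
then i.i.d. Gaussian noise (SD 0.02 cm/s) is added and the result is
encoded to phase φ = π·v/VENC wrapped to (−π, π]. Cohorts draw per-subject
log-normal amplitude factors (σ = 0.15; positivity) and a normal
heart-rate jitter clipped to [1.0, 1.6] Hz; each subject keeps its
amplitudes and heart rate across its three period runs.

What the generator does **not** emulate: k-space/SSFP signal formation,
through-plane motion, vessel pulsation artifacts, breathing irregularity,
bulk subject motion, spatially varying noise, or non-sinusoidal respiratory
waveforms. Passing recovery tests therefore demonstrates the correctness of
the *analysis chain* under the stated signal model, not robustness to every
artifact of real scans.

## Numerical behavior and limitations

- **Leakage.** Off-bin tones under brick-wall selection ring at the record
  edges (Gibbs): a half-bin-offset cardiac tone can overshoot its amplitude
  by ~16% within the first/last ~5 s, while away from the edges the peak
  error stays below 5% for band-interior tones (below 10% within a few bins
  of a band edge). No windowing is applied; the behavior is characterized
  by tests instead of suppressed.
- **Noise bias of peaks.** The per-voxel directional peak of a noisy
  band-limited component is biased upward (extreme-value selection over
  ~253 samples); at the default noise level this contributes a systematic
  ≈ +9% to recovered peak velocities. Fractions are nearly unaffected
  because both components share the bias direction, and displacements are
  robust (integrals, not extremes).
- **Partial volume.** Spatial blur attenuates small-region amplitudes (the
  9-voxel aqueduct loses ~40% of its peak at σ = 1). Component *fractions*
  are invariant to this attenuation because both components share the same
  spatial profile.
- **Aliasing.** No phase unwrapping is performed: decoded speeds within 2%
  of VENC are counted and warned about, never corrected — study velocities
  sit an order of magnitude below VENC, so aliasing indicates a
  configuration error.
- **Non-integer cycle counts.** A 55-s record holds 9.15 six-second
  respiratory cycles; the incomplete last cycle makes cranial and caudal
  respiratory displacement magnitudes differ by up to ~10–15%, and their
  sum vanishes only approximately.
- **Problem sizes.** Tests use 64×64 phantoms, 20-seed recovery sweeps,
  10-seed segmentation sweeps and one 7-subject × 3-period cohort; the full
  suite runs in well under a minute.
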