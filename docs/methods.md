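# Methods

This note documents the models, parameter choices and numerical
conventions behind `csds_lfp`, and what the synthetic-data tests do and do
not establish about real recordings.

## Arena geometry and behavior metrics

The arena is a 50 × 50 cm square with the mesh enclosure against the top
wall.  The interaction zone is the 24 cm-wide, 14 cm-deep rectangle centred
on that wall (x ∈ [13, 37], y ∈ [36, 50]); the two corner zones are 9 cm
squares against the opposite wall.  Zone membership uses the tracking
centroid with **closed boundaries** (a point on an edge belongs to the
zone) and interaction-zone priority; the zones are disjoint by
construction, so the priority rule only matters for malformed geometries.
Zone time attributes each tracking sample the interval to the next sample
(the last sample runs to the phase end), which makes zone times additive
over any partition of a phase and bounded by the phase duration.

The corner-zone SI ratio applies the same with/without formula to the
summed time over both corner squares.  Susceptibility is strict:
SI < 1.  Immobility for synthetic traces is time below a motion-energy
threshold; the threshold is caller-supplied because the original
measurements were scored from video.

## Spectral estimation

* STFT with a 0.5 s Hamming window, 0.25 s step (50% overlap).  A 0.5 s
  window has 2 Hz native resolution; the conventional 0.5 Hz grid is
  obtained by zero-padding each window to 2 s.  The window step is a free
  choice balancing time resolution against redundancy.
* Power is a one-sided PSD (µV²/Hz); band power sums bins with
  low ≤ f < high times the 0.5 Hz bin width, so band powers over a
  partition of the spectrum are additive and the full-spectrum sum
  recovers the signal variance (Parseval; verified to 5% on white noise).
* The five bands are 2–7, 7–12, 14–30, 30–50 and 50–80 Hz.  The first
  three reflect the bimodal low-frequency spectrum and the beta range that
  carries the group contrast; the upper two complete a five-band set and
  are configurable.  The 12–14 Hz gap is excluded from every band.
* Band power is z-scored **per channel per band over the full session**
  (both phases pooled), then averaged over channels.  An alternative mode
  z-scores against the No-CD1 phase only (`mode="baseline"`); the two give
  identical change-in-power up to an affine factor when the baseline is
  stationary.  Z-scoring makes all downstream statistics invariant to
  per-channel gain and offset; channel aggregation is the arithmetic mean,
  chosen for linearity in z units.
* Spectrogram bins are assigned to a zone/phase by their **bin centre**,
  taking the zone of the most recent tracking sample.  A condition with no
  qualifying bins yields NaN, which propagates (never silently zero).  In
  the occupancy-weighted total change a zone with zero occupancy
  contributes nothing even if its per-zone change is NaN.

## Synthetic cohort

The generator's defaults are the study conditions: n = 8 control +
8 defeated, two 600 s phases, 16 channels at 2000 Hz (0.5–250 Hz band
limit).  One master seed spawns per-animal, per-component substreams
(`numpy.random.SeedSequence`), so identical (config, seed) pairs are
bit-identical.

**Behavior.** Zone visits are drawn i.i.d. per (group, phase) from zone
probabilities with exponential dwell times; expected occupancy of a zone
is prob × mean dwell (normalised).  The defaults reproduce the canonical
occupancy pattern (defeated with CD1 present: ≈55 s interaction / ≈457 s
corner out of 600 s; control roughly the reverse; no-CD1 occupancies
similar between groups).  The probability/dwell split is additionally
calibrated for epoch tiling: the preferred zone is visited often but
briefly (sub-second to ~1 s dwells that merge into ~2 s bouts) while the
avoided zone is entered rarely but for long bouts (8–15 s), so that
tiling With-CD1 visits into 5 s epochs lands near 396 epochs per cohort
and every one of the four states contributes epochs.  Real mouse bout
statistics are not this bimodal; the visit process should be read as an
occupancy-and-epoch-calibrated stand-in, not an ethological model.  A
shared per-animal log-normal jitter (σ = 0.25) on the visit probabilities
spreads the SI ratio across animals.

**Assays.** Sucrose preference (%) and tail-suspension immobility (s) are
truncated normals (to [0, 100] and [0, 300]).  Group means are the
canonical values (77.55 / 60.33 % preference; 76.0 / 121.1 s immobility);
since only SEMs at n = 8 are reported, within-group SDs are taken as
SEM·√8.  Preference is converted to sucrose/water masses against a ~4 g
total intake.

**LFP.** Each channel is an independent 1/f background (spectral shaping,
amplitude ∝ f^(−exponent/2), exponent 1.0, 12 µV RMS) plus five
band-limited oscillation components: Gaussian white noise band-pass
filtered (4th-order Butterworth, zero-phase) around 4, 9.5, 22, 40 and
65 Hz with RMS amplitudes 14, 10, 5, 3.5 and 2.5 µV.  The 4 and 9.5 Hz
components produce the bimodal 2–12 Hz spectrum; broadband noise rather
than sinusoids gives realistic spectral bumps.  Component amplitude is
modulated by the effect matrix (below) according to the animal's current
zone and phase, with the envelope smoothed by a 300 ms moving average to
avoid edge artifacts; channels share the envelope but have independent
noise and ±10% gain jitter (absorbed by z-scoring).

**Effect matrix.** Multipliers on oscillation amplitude,
(group, zone, phase, band); unlisted cells are 1 (No-CD1 is always 1):

| group | zone | band | multiplier |
|---|---|---|---|
| control | interaction | 2–7 Hz | 1.25 |
| control | interaction | 14–30 Hz | 0.85 |
| control | corner | 2–7 Hz | 1.35 |
| control | corner | 7–12 Hz | 0.75 |
| defeated | interaction | 2–7 Hz | 0.75 |
| defeated | interaction | 14–30 Hz | 1.30 |
| defeated | corner | 2–7 Hz | 1.12 |
| defeated | corner | 7–12 Hz | 1.10 |

The directions encode the avoidance phenotype's oscillatory signature:
defeated animals lose low-frequency power and gain beta power when facing
the aggressor, their corner-zone changes are positive but minor, and each
band's change-in-power correlates with the SI ratio in the expected
direction (positive for 2–7 Hz, negative for interaction 14–30 Hz and
corner 7–12 Hz).  Because defeated animals spend most of the With-CD1
phase in the corner, the occupancy-weighted total 2–7 Hz change is
positive even though the interaction-zone change is negative.

## Group statistics

* Student's pooled-variance t is the default (Welch behind a flag); the
  pooled form is the common default when only t values are reported.
* The mixed ANOVA (group between × band within) is computed by
  `pingouin.mixed_anova`; the reported group main effect has df
  (1, n_animals − 2).  The repeated-measures df convention of the original
  analyses cannot be reconstructed with certainty, so this package's
  convention is documented rather than claimed to match.  With a single
  band the design degenerates to a one-way between-groups ANOVA, making
  F = t² exactly — a cross-check the tests enforce to 1e-8.
* Post hoc group contrasts are per-band unpaired t-tests with Bonferroni
  correction (p × n_bands, capped at 1).
* Pearson p-values come from the exact t-transform, not permutation; the
  implementation is cross-checked against `scipy.stats.pearsonr` and its
  type-I error is verified to be nominal.  Perfectly collinear input is
  reported as r = ±1, p = 0.

## Decoder

* Epochs are non-overlapping 5 s tiles of contiguous interaction/corner
  visits during the With-CD1 phase; a d-second visit yields ⌊d/5⌋ epochs.
  Only susceptible defeated animals (and all controls) are included.
* The "10 measures" are the per-band epoch mean and within-epoch SD of the
  channel-averaged z band power (5 bands × 2).  This is an interpretation:
  the original feature list was never enumerated beyond "10 measures in 5
  frequency ranges".
* Classifier: SVC with polynomial kernel of degree 2, C = 1, coef0 = 1,
  gamma = "scale"; features standardized using training-split statistics
  only; random 80/20 splits (re-drawn if a class is missing from training,
  error after 100 attempts).  Hyperparameters are recorded in every result
  JSON.
* The circular-shift null rotates the time-ordered label sequence by a
  random offset and retrains the decoder per shift.  Two scopes exist:
  **per-animal** rotation preserves within-animal label autocorrelation
  but also preserves group identity (an animal-level property), so when
  features identify the group the per-animal null stays far above chance;
  **global** rotation of the concatenated sequence decouples labels from
  animal identity as well, dropping the null toward the majority-class
  base rate.  The headline readout (`decode_with_null`) uses the global
  scope, which matches the behavior of a null that falls to near-chance
  while real decoding stays high; the stricter per-animal scope is the
  default of the lower-level `circular_shift_null` and available
  everywhere via `scope=`.
* Empirical significance is p = (1 + #{null ≥ real mean}) / (n_shifts+1);
  the label multiset is preserved exactly by shifting, so the null's base
  rate equals the real one.  Per-class recall is reported because the
  four states are imbalanced.

## Problem sizes used by the tests and analyses

The full-scale defaults (16 channels, 2000 Hz) are expensive; the package
analyses its cohorts at reduced rates that leave the statistics unchanged
in expectation:

* `analysis/` drivers and `scripts/acceptance.py`: 400 Hz, 2 channels,
  full 600 s phases, n = 8 + 8; decoder validated with 20 split repeats
  and 200 shifts.
* Repeated-cohort calibrations in the test suite (sign recovery over 100
  cohorts, decoder calibration over 20 cohorts, behavioral battery over
  200 cohorts): 200 Hz, 1 channel, full 600 s phases.  200 Hz keeps all
  five bands below Nyquist.

## What passing tests do and do not show

The synthetic cohort has stationary noise, exchangeable channels, exact
phase boundaries and an effect matrix that is constant within a condition.
Real LFP has non-stationary artifacts, volume conduction, movement
confounds and electrode heterogeneity, none of which are modelled.
Passing sign-recovery and decoder-calibration tests therefore shows the
*pipeline* is correct and well-calibrated (it recovers what was injected
and its null behaves), not that the biological effect sizes are as easy to
detect in vivo.  Known limitations: no spiking activity, no
cross-frequency coupling, no multi-region simulation; visit durations are
calibrated to the epoch count rather than to ethological bout statistics;
published t statistics are not exactly reproducible from printed
means ± SEM and are not used as targets.
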