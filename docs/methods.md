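# Methods

`alpharhythm` implements the sensor-level analysis of hemispheric alpha-power
lateralization under combined spatial and temporal auditory attention,
together with a synthetic-data generator that emulates the trial design,
behavior, and MEG-like signals the analysis assumes. This note documents the
model, the estimators, the defaults, and the numerical choices; it also
states what the generator does *not* emulate, and hence what passing tests do
and do not show about real recordings.

## Paradigm and design constants

A trial presents a visual temporal cue (instructive: one of five number
positions is likely probed; neutral: no position information), then an
auditory spatial cue at t = 0 indicating the to-be-attended ear, then five
pairs of dichotically competing spoken numbers with onsets at
1.5 + 1.25·k s (k = 0..4), i.e. a 0.8-Hz presentation rate. At trial end one
position is probed. The design is constructed exactly, never sampled:

- 160 trials per participant: 80 instructive + 80 neutral temporal cues,
  40 attend-left + 40 attend-right within each cue type;
- instructive cued-position counts 8/18/28/18/8 for positions 1–5, split
  evenly across attended sides (4/9/14/9/4 per side);
- the probed position equals the cued one with probability 0.7 ("valid"),
  otherwise it is drawn uniformly from the four remaining positions (the
  uniform split is an assumption — only the 30% total is designed); neutral
  trials probe a uniformly drawn position.

Schedules other than 160 trials must scale all cell counts integrally
(multiples of 160); anything else is rejected as unpartitionable.

## Synthetic recordings

Sensors are combined planar-gradiometer positions labelled left / right /
midline (canonically 48/48/6 = 102 positions, 204 raw channels); the
generator emits the raw pairs. Per trial, every channel over one hemisphere
carries a 10-Hz alpha carrier with an independent uniform random phase per
channel and trial (power, not phase, carries the effect) whose instantaneous
power is

    P_ipsi(t)  = P0 · (1 + L(t)),    P_contra(t) = P0 · (1 − L(t)),

relative to the attended ear, with midline channels at P0. The planted
lateralization profile is

    L(t) = L0 + d(t) · cos(2π · 0.8 · (t − 1.5 − τ)),

where L0 is a constant baseline (`lat_offset`, default 0.2), d(t) is the
modulation depth during number presentation — `mod_depth_neutral` (0.1) or
`mod_depth_instructive` (0.2), plus `cued_boost` (0.2) within the cued
number's 1.25-s sub-window on instructive trials — and τ = `mod_lag_s`
(0.46 s) is the lag of the lateralization rhythm behind the number onsets.
The instructive depth is twice the neutral depth and the cued boost is
nonzero by default, so the pipeline's two headline contrasts have planted
ground truth to recover.

Each number onset adds a phase-locked evoked transient — a Hann-windowed
3-Hz cycle of 0.4 s duration, amplitude 2e-13, identical across trials and
channels — which produces high 1–5 Hz inter-trial phase coherence around
onsets. Additive Gaussian 1/f noise (`noise_std` 1e-13, spectral exponent 1)
is superimposed. Amplitudes are in T/cm-like field units so that the
conventional 3 pT/cm (3e-12) epoch-rejection threshold is meaningful;
every index downstream is a dimensionless power ratio, so the absolute scale
cancels.

Behavior is Bernoulli accuracy per validity class (defaults 0.93 valid /
0.79 invalid / 0.80 neutral) and lognormal response times with class-specific
medians (0.90 / 1.10 / 1.00 s, log-sd 0.3). These defaults are parameters
chosen to re-exercise the behavioral statistics at realistic effect sizes,
not empirical claims.

One pseudo-random stream per participant is derived from
(master seed, participant id), so cohorts are reproducible and any
participant can be regenerated in isolation.

### What the generator does not emulate

No acoustic waveforms or perceptual-center extraction, no ocular/cardiac
artifacts (the amplitude threshold replaces ICA), no head geometry or
forward model (sensor labels are abstract, so no source analysis is
possible), no trial-order or fatigue effects, and no between-participant
heterogeneity in effect size beyond sampling noise. Passing recovery tests
therefore demonstrates correctness of the estimators and inference under the
assumed signal model — not robustness to the artifacts and variability of
real MEG.

## Preprocessing

Zero-phase FIR band-pass filtering (0.3–180 Hz defaults; the upper edge is
clipped to 0.4 × sampling rate when the data are sampled below 2 × 180 Hz),
polyphase resampling (500 Hz default; identity when the target equals the
current rate), and rejection of epochs whose absolute maximum on any raw
channel exceeds 3e-12. Zero-phase filtering matters because phase
distortions would bias ITPC. The exact filters of the original acquisition
chain are not reproduced; only their cutoffs are.

## Spectral estimators

Single-trial coefficients use a Hann-tapered 0.5-s moving window stepped by
0.05 s on a 1–20 Hz grid. A 0.5-s window natively resolves 2-Hz spacing, so
each window is zero-padded to 1 s before the DFT to honor the 1-Hz grid.
Coefficients are normalized by the taper's sum (window-length-independent
magnitudes). A coefficient at time t uses data [t − 0.25, t + 0.25) s;
windows extending past the epoch edges yield no estimate. Requested
frequencies that do not fall on the padded grid raise an error rather than
being rounded.

Power is the across-trial mean of squared magnitudes; ITPC is the magnitude
of the across-trial mean of unit-normalized coefficients (zero-magnitude
coefficients contribute zero vectors but stay counted in n, with a warning).
Gradiometer pairs are combined by summing power and averaging ITPC per
position.

## Lateralization indices

Topographic: (Pow_attend-left − Pow_attend-right)/(sum), per sensor, on
band- (8–12 Hz) and window- (0–1.5 s pre-stimulus) averaged power.
Time-resolved: (Pow_ipsi − Pow_contra)/(sum) per time step, with
hemisphere-mean alpha power relative to the attended side and midline
sensors excluded. Power is averaged over band and sensor set *before* the
ratio (ratio of averages). Nonpositive denominators are flagged NaN, never
silently zeroed. Both indices are antisymmetric and scale-invariant, and lie
in [−1, 1] wherever both powers are positive.

## Rhythm spectra

Index time courses over 1.5–7.5 s are Hann-windowed, mean-removed, and
zero-padded to 0.02-Hz resolution; amplitude and phase are the magnitude and
angle of the complex coefficients, and the stimulus-rate readout averages
the five bins 0.76–0.84 Hz (closed interval on bin centers). Mean removal is
a deliberate choice the original acquisition convention leaves open: it
keeps 0-Hz leakage out of the stimulus-rate band through the Hann mainlobe.
Amplitudes are scaled by 2/Σ(taper) so a unit in-bin cosine reads 1
regardless of padding. Phase-to-lag conversion wraps (phase/360)/rate into
one cycle; 133° at 0.8 Hz ↔ 0.46 s.

In the generator, the ITPC rhythm peaks near onset + 0.2 s (the evoked
kernel's center), so the planted ITPC-to-lateralization lag equals
`mod_lag_s` − 0.2 s = 0.26 s; the end-to-end tests recover exactly this.

## Sub-epoch analysis

Sub-epochs span −2 to +3.25 s around the onsets of positions 2–4 (positions
1 and 5 are rarely cued and contaminated by the spatial cue and response
preparation). Labels: cued (instructive ∧ position = cued), uncued
(instructive ∧ other positions), neutral (all positions of neutral trials);
a default schedule yields 64 cued sub-epochs per participant
(18 + 28 + 18). Because the moving-window decomposition is
translation-covariant, the pipeline slices whole-trial alpha power at
onset-relative steps — numerically identical to re-decomposing time-domain
sub-epochs, and without losing the windows at sub-epoch edges; the
time-domain extraction is also provided and tested for equivalence of
alignment.

For the cued condition, alpha power is averaged across sub-epochs and
positions per attended side, the time-resolved index is formed per side, and
the two sides are averaged. Uncued/neutral conditions repeat this on random
sub-samples drawn *without replacement* within each (side, position) cell to
exactly the cued counts — 10,000 draws by default. The cued series is
standardized per time point against the draw distribution,
z = (cued − mean)/sd (this standardization is the natural choice; zero
spread is flagged NaN). The same draw set feeds the 2.5th/97.5th percentile
envelopes used for display. Group inference applies per-time-point sign-flip
permutation tests to the participants' z series (uncorrected, as is
conventional for these displays) plus a 95% percentile-bootstrap confidence
interval of the mean (percentile rather than BCa, for simplicity and
determinism).

## Inferential toolbox

- Adjusted logit of proportion correct: ln((0.5 + 0.95(pc − 0.5)) /
  (1 − (0.5 + 0.95(pc − 0.5)))); finite at 0 and 1, odd about 0.5.
- Response speed: RTs above 3 s are discarded, the rest mapped to 1/RT.
- Paired contrasts: sign-flip permutation of per-participant differences
  with the classical paired t statistic; two-sided p as the fraction of
  permuted |t| ≥ observed |t|. When 2^n ≤ the requested permutation count
  the null is enumerated exhaustively (p = k/2^n, counting the identity);
  otherwise p = (k + 1)/(n_perm + 1), so p is never 0. Zero-variance
  differences map t to ±∞ (or 0 when the mean is also 0; all-zero
  differences give p = 1 by convention).
- Correlation: Spearman's rho with permutation of one variable, same p
  convention.
- Circular: Rayleigh test (z = n·R̄², small-sample exponential p
  approximation) and the paired Hotelling second-order test on the Cartesian
  components of per-participant angle differences, F-distributed with
  (2, n − 2) df under the null (Zar's formulation; the test is named, not
  specified, in the conventions this package follows, so the implemented
  formula is stated here and in the docstring). Identical samples return
  the boundary (F = 0, p = 1); otherwise degenerate zero-variance components
  raise.
- Linear trend: per-participant least-squares slope across probed positions,
  slopes tested against zero by sign-flip permutation.

Every test takes an explicit seed; the pipeline derives per-test seeds
deterministically from the master seed, and the report records each
statistic's seed and resampling count.

## Problem sizes

The full-scale defaults (102 sensor positions, 500 Hz, 10,000 draws /
bootstraps / permutations) describe the canonical analysis. The package's
own end-to-end verification runs a scaled-down cohort chosen to keep the
complete check in the minutes range on a single core: 20 participants,
14 combined positions (6/6/2), 100-Hz sampling, and 1,000 draws /
bootstraps / permutations. The design constants (trial counts, cue
probabilities, onset times, analysis windows, frequency bands) are never
scaled. At these sizes the planted effects are recovered with wide margins
(group |z| ≫ 1.96 near cued onsets; instructive vs neutral amplitude
p < 0.001), so the reduction does not trade away sensitivity.

## Known limitations

- The hemisphere assignment of sensors is nominal; no spatial leakage or
  sensor covariance structure is simulated, so topographies are cleaner than
  real ones.
- The sub-sample z assumes the draw distribution is well summarized by its
  first two moments; with very few cued sub-epochs per cell the normal
  reading of z would be optimistic (the permutation test at group level does
  not rely on it).
- The Rayleigh p uses the standard exponential approximation, adequate for
  n ≥ ~10; exact tables are not implemented.
- Source-space analysis (beamforming, homologue-grid contrasts) is out of
  scope by design.
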