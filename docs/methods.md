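# Methods

This note documents the models, numerical conventions, and design choices
behind `p300bench`, and states what the synthetic data can and cannot show.

## Acquisition-system profiles

A `SystemProfile` couples a sampling rate, the on-line Butterworth band-pass
applied during spelling, and a short-circuit noise target — the RMS, in the
0.1–40 Hz band, of the signal the system records with all electrodes tied to
a common conductor. The three built-ins:

| profile   | fs (Hz) | on-line band (Hz) | order | noise floor (μV RMS) |
|-----------|---------|-------------------|-------|----------------------|
| hydrogel  | 256     | 0.1–60            | 4     | 0.68                 |
| tap_water | 250     | 0.1–60            | 4     | 0.37                 |
| dry       | 256     | 0.5–30            | 4     | 0.82                 |

The dry system's amplifier-integrated 0.5–30 Hz filter is modeled as a
4th-order Butterworth; its true analog topology is not public, so this is an
approximation. Hardware notch filters are not modeled: the simulated noise
carries no mains component unless one is added explicitly.

`scalp_noise_scale` (default 10, dimensionless) maps the instrument floor to
scalp-level background EEG for session simulation. It is a free simulation
parameter — spontaneous EEG is dominated by cortical background activity,
not by the instrument — and nothing downstream is sensitive to its exact
value because classifier difficulty is set by the ERP-amplitude-to-noise
ratio.

## Synthetic EEG

**Background noise** is an equal-power (50/50 in-band) mixture of white and
1/f-amplitude ("pink") Gaussian noise, generated per channel in the
frequency domain, with the 1/f shaping flattened below 0.1 Hz to keep power
finite. Each channel is rescaled so its band-limited RMS (zero-phase
8th-order Butterworth, 0.1–40 Hz) equals the profile target times the
requested scale. Because a zero-phase IIR filter's edge transients linger
for seconds at a 0.1 Hz high-pass edge, the calibration measurement trims a
guard of `min(duration/4, 10 s)` from each end; without this the scale
factor inherits the volatile transient power and sub-segment RMS estimates
are biased by 1–3 %. Optional alpha or mains components are deliberately
absent by default: the calibration target constrains only band RMS.

**Flash schedules.** Each sequence is an independent random permutation of
the rows + columns flashes with one constraint: the same flash never occurs
twice in a row across sequence or item boundaries (standard speller
practice). Stimulus-onset asynchrony defaults to 0.25 s with 62.5 ms
highlights — conventional matrix-speller timing, configurable; the protocol
this simulates does not pin these values down.

**ERP model.** The P300 is a Gaussian bump: peak amplitude in μV, latency
0.35 s (inside the canonical 250–500 ms window), σ = 60 ms, scaled per
channel by a fixed centro-parietal topography (Pz maximal). It is added at
every flash that highlights the attended cell and omitted with probability
`lapse_rate` (attention lapses). An optional smaller non-target response can
be added to every flash. Noise and lapse randomness come from independent
streams spawned from the seed, so a rendered session is exactly the
sample-wise sum of its noise-only and noise-free renderings — a property the
tests exploit.

What this generator does *not* emulate: eye/muscle artifacts, electrode
drift and movement, mains interference, latency jitter and habituation of
the P300, inter-channel noise correlation. Passing tests therefore
demonstrate the correctness and statistical behavior of the processing
chain under an idealized signal model, not hardware performance or
real-subject accuracy levels.

## Preprocessing

The on-line path filters causally (a real-time speller cannot look ahead);
offline analyses (noise bench) filter zero-phase. Epochs span 0–800 ms
post-flash, with sample count `floor(end·fs) − floor(start·fs) + 1` (205
samples at 256 Hz, 201 at 250 Hz); events whose window leaves the recording
are dropped and counted. No baseline correction is applied (optional epochs
overlap is inherent to 0.25 s SOA and is permitted). Features are per-channel
moving averages over `floor(n_samples·f_dec/fs)` near-equal bins (16 bins at
20 Hz), concatenated over the six channels → 96 features. Window, decimation
rate, and channel subset are configurable; these values follow common
SWLDA-for-P300 practice rather than a published prescription.

## SWLDA

The discriminant is the classical least-squares formulation: regress ±1
labels on the selected columns plus an intercept. Selection alternates
forward entry (smallest partial-F p-value, admitted if `< p_enter`) and
backward elimination (largest p-value, removed if `> p_remove`) until
stable, with `p_enter = 0.10`, `p_remove = 0.15`, `max_features = 60` as
defaults and a cycle guard at 2 × `max_features` iterations. Partial-F
p-values use the residual-sum-of-squares ratio with `n − k − 1` (removal)
or `n − k − 2` (entry, k features currently in the model) denominator
degrees of freedom. Entry ties break toward the lowest feature index, so
fits are bit-reproducible. Numerically the fit runs on centred Gram
matrices (X'X, X'y), screening all candidates at a step in one vectorized
pass; candidates whose residual variance under the current model is below
1e−10 of their own variance are refused entry (collinearity guard), and an
all-zero-variance design yields an empty model with a warning rather than
an exception.

## Calibration and session simulation

The LOLO-CV curve holds out each training letter, fits SWLDA on the rest,
and classifies the held-out letter at every sequence count 1..15; with five
letters the curve is quantized to 20 % steps. The sequence-count rule is
`clamp(first-100 % + 2, 8, 15)`, else 15 if the maximum exceeds 75 %, else
failure. The +2 result is clamped *up* to 8 as well as down to 15; observed
calibrations in this protocol all lie within 8–15, consistent with either
convention, and the clamp keeps the on-line run inside the stated bounds.

Menu tasks are simulated abstractly: each step draws a uniformly random
target cell in the task's matrix, and the investigator-guided recovery
after an error is modeled as *one wrong selection costs one extra required
correct selection* (a pending-correction counter). This bookkeeping
reproduces the protocol's arithmetic — 10 selections at best, abort at
15/18, session totals in [40, 53] — while making no claim about the true
per-error cost, which the protocol does not specify. Copy-spelling is
uncorrected by instruction. On-line selections reuse the training-time
feature pipeline verbatim; there is no re-fitting during tasks.

## Noise bench

`analyze_noise` band-limits with a zero-phase 8th-order Butterworth
(0.1–40 Hz), then drops head/tail exclusion windows (60 s each by default),
which also absorb the filter's edge transients; the report comprises the
overall RMS, a smoothed RMS trace, a histogram, and a single-sided
rectangular-window amplitude spectrum (Parseval-consistent with the RMS).
The RMS trace smooths the instantaneous mean square with a unit-sum Gaussian
FIR kernel `h(t) ∝ exp(−t²/(2δ²))`, `δ = √(ln 2)/(2π·BT)` in symbol-time
units with BT = 0.1, truncated to 4 symbol periods at one symbol per second
(kernel σ ≈ 1.3 s). This is a documented, bit-reproducible equivalent of a
tool-specific Gaussian smoother; the original's exact parameterization is
not public. The histogram uses 100 equal-width bins spanning ±4 × RMS with
out-of-range samples clipped into the edge bins, so counts always sum to
the analyzed sample count.

## Table aggregation

Accuracy is 100 × correct/total, kept unrounded internally; display
rounding is half-away-from-zero at the printed precision (integers for
accuracies, one decimal for sequence counts). Column statistics are means
and sample SDs (n − 1) over non-missing participants. Each system's overall
mean and SD are computed over its four *display-rounded* task means — the
convention under which the shipped reference tables' per-system summary
figures recompute exactly. Two cells of the reference tables do not
recompute from their own columns and are excluded from reproduction tests
with annotations: the hydrogel web-browser column SD (printed 1, recomputes
≈13; treated as a typo) and the tap-water overall SD (printed 4.5; no
aggregation of the printed per-participant data yields it).

## Synthetic replication

`replicate_study` runs virtual participants through all three profiles.
Per-system effective scalp P300 amplitudes (6.2, 3.2, 3.8 μV for hydrogel,
tap-water, dry) were chosen once from an amplitude sweep so that per-flash
SNR is ordered hydrogel > tap-water > dry — matching the observed
effectiveness ranking — with the dry system in the regime where
classification errors and 15-sequence calibrations occur. Each participant
draws one log-normal amplitude multiplier (σ = 0.25) shared across systems
(stable individual P300 amplitude differences), and a 5 % lapse rate
applies throughout. A failed calibration is retried up to twice with a
fresh seed; exhausted retries leave missing entries, mirroring the
missing-data pattern of real tables. These settings are simulation
conditions, not fitted parameters; the replication supports ordering-level
statements only.

## Problem sizes and determinism

Default test and acceptance runs use 2-minute noise recordings with 10-s
exclusions (10 seeds per profile), 10⁵ random curves for the
sequence-rule oracle, 10⁴ Monte-Carlo selections for the chance level, and
10 seeds × 5 letters for the ceiling-accuracy check; these sizes give
standard errors comfortably inside the asserted tolerances. Every stochastic
path takes a seed (integer or `numpy.random.SeedSequence`) and spawns
independent child streams, so all results are bit-reproducible.

## Known limitations

- The synthetic accuracy levels are not comparable to human data; only
  orderings and protocol arithmetic are meaningful across profiles.
- EDF files can be read (via `mne`) but not written; the package's native
  interchange format is a TSV signal table plus a JSON event sidecar.
- The SWLDA hyperparameters and the feature space are field conventions,
  not reconstructions of any particular deployed classifier; results are
  functions of these settings.
- Reference/ground montage differences between systems have no signal-level
  consequence in the simulation.
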