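# Methods

This note records the analysis conventions, the synthetic-data model, and
the design choices made where the underlying procedures leave room for
interpretation. Tunable values live in `prospectcode.config.PipelineConfig`
(analysis) and `prospectcode.synthetic.SyntheticConfig` (generator); the
defaults stated here are those shipped.

## Track geometry and coordinates

The environment is a 360° annular track of twenty 18° zones with two
reward zones 180° apart (defaults: zones 4 and 14). Because behavior is
symmetric across the two half-laps, analyses fold position onto a
180° distance-to-reward axis whose origin is the exit of a reward zone;
the anticipatory zone occupies folded [144, 162) and the reward zone
[162, 180). Full-track maps use 2° bins (180 bins); folded maps use 3°
bins (60 bins). All angular arithmetic is circular (wrap-aware
differences, wrapped smoothing kernels, circular decoding errors).

## LFP processing and brain states

Raw traces are downsampled to 2 kHz, bandpassed 1–300 Hz, and samples
beyond 15 SD of the raw mean are replaced by linear interpolation. Band
filters are linear-phase FIR equiripple designs applied with zero net
phase. Narrow low-frequency bands are designed and applied at a decimated
rate and resampled back: at 2 kHz a 1–4 Hz equiripple problem is too stiff
for the Parks–McClellan exchange, while at 20 Hz it is routine. Both
transition bands share one width (0.38 × the low edge) because unequal
transitions let the exchange dump unconstrained gain into the wider one;
each design is verified on a dense grid (max gain ≤ 1.05) with a
Hamming-window fallback that has never been needed for the shipped bands.
All bands attenuate ≥ 40 dB one octave outside their edges.

Theta vs non-theta segmentation thresholds the theta/(delta+beta)
envelope ratio: theta when above mean + 2 SD for ≥ 2 s, non-theta when
below 1.1 for ≥ 2 s, with the baseline statistics over the whole session
(a non-theta-only baseline is available as `ratio_baseline="nontheta"`).
The ratio series is smoothed with a 1 s moving average
(`ratio_smooth_s`): envelopes of band-limited noise fluctuate on
sub-second timescales, so a sample-level "continuously above threshold
for 2 s" rule would otherwise reject essentially everything; the Hilbert
envelopes themselves are not smoothed (`envelope_smooth_s = 0`).

SWRs are detected where the 150–250 Hz Hilbert envelope exceeds mean +
3 SD for ≥ 20 ms (crossings < 10 ms apart merged), subject to a
100–250 / 250–400 Hz power-ratio ≥ 4 (periodogram over the padded event
segment) and an amplitude artifact limit of ±1500 µV (the source
convention prints mV, which we read as a units typo; the limit is
configurable). The pyramidal-layer reference channel is the ripple-band
power argmax, ties to the lowest channel id.

## Units and place fields

Units are kept with < 0.8% refractory (1 ms) violations and SNR ≥ 1.
Pyramidal cells: spike width > 0.5 ms and autocorrelogram first moment
< 4.5 ms; interneurons the strict converse; boundary equality is left
unclassified. The first moment is computed from exact positive lags up to
50 ms (zero lag excluded) rather than 1 ms histogram centers, avoiding a
half-bin bias.

Rate maps bin spikes and occupancy with a movement filter
(speed > 1 deg/s), smooth both with a wrapped Gaussian (SD 2 bins,
truncated ±4 SD, kernel normalized) and divide; bins with < 100 ms raw
occupancy are zeroed and excluded from spatial information. Place-cell
significance uses a circular spike-time shuffle with shifts drawn from
[20 s, T]: the default permutes each spike independently
(`shuffle_mode="per_spike"`); a whole-train mode is provided but
degenerates on pause-dominated sessions, where a single shift leaves only
one or two coherent field-crossing bursts inside movement periods and the
null acquires sharp fake fields. Classification requires SI above the
shuffle 95th percentile, mean rate in [0.2, 10] Hz and peak ≥ 1 Hz, on
full-track maps; properties (sparsity, peak statistics) come from the
folded maps. The mean rate is the plain average of the map (not
occupancy-weighted), matching the stated definition of place-cell mean
rate; SI's internal mean rate is occupancy-weighted as its formula
requires.

## Decoding

The decoder is the memoryless Poisson decoder with a flat prior, computed
in log space, with rate maps floored at 0.01 Hz so one stray spike cannot
zero the posterior. Current-position decoding is 5-fold cross-validated
over correct trials (folds seeded), τ = 200 ms, blocks with ≥ 2 spikes;
decoded blocks are restricted to movement — during long reward pauses
place cells express replay rather than current position, which the ripple
pipeline analyzes separately. Argmax ties break toward the previous
block's estimate, then the lowest angle. Session QC keeps sessions whose
mean posterior at the true bin, scaled by the number of position bins so
chance = 1, is at least 1.2; this is our reading of the "averaged
normalized probability" criterion, and the threshold is configurable.

## Theta sequences, prospective coding, SWR content

Theta troughs are the π → −π wraps of the 4–12 Hz Hilbert phase during
running on correct trials. Each 400 ms trough-centered window is decoded
in 20 ms bins (≥ 2 spikes) with folded maps (full-track maps for the
unoccupied-zone analysis) and re-centered on the animal's position.
Averages exclude undecoded bins rather than zero-filling them, which
would bias quadrant sums toward zero. Quadrant sums cover the ±80 ms ×
±45° box only (window edges beyond 80 ms are outside the quadrant
definition). The significance shuffle permutes the time-bin order
independently within every cycle, 500 times, seeded. Prospective ratios
by position use 18° zone bins of the trough position; the post-reward
aggregate is the first two zones after reward exit, the reward-related
aggregate the anticipatory + reward zones; the unoccupied-zone control
area is one zone, half a lap before the reward zone.

SWR windows (250 ms, 25 ms bins, > 1 spike per bin) are decoded with the
same decoder; the prospective window is +9..+63°, retrospective
−9..−63°, with the ±9° local band and ±63..90° edges excluded after
per-bin normalization. Sequence-less decoding uses a single bin with τ
equal to the actual event duration. The far-zone (unoccupied reward zone)
rule flags events whose mean posterior 162–198° away is ≥ mean + 2 SD of
all decoded elements; a zero-SD (uniform) average is degenerate and never
flagged.

## The synthetic session generator

The generator is a testing instrument, not a biophysical model: its
parameters are ground truth that the pipeline must recover.

*Behavior* (50 Hz): laps at ~30 deg/s with long reward pauses (mean 55 s —
the task design rewards pausing, which is also where ripples live), licks
and reward at the pause, anticipatory licks in the zone before reward,
and an 8% fraction of unengaged laps with no licking. *LFP* (2 kHz, 4
channels): 8 Hz theta dominates running, 2.5 Hz delta dominates pauses, a
continuous 32 Hz slow-gamma component carries spike coupling, and 180 Hz
ripple bursts with a per-channel amplitude gradient are injected at
Poisson times during pauses. *Spikes*: 40 place cells with von Mises
tuning (κ = 12, peak 15 Hz) tile the track; within each theta cycle the
represented position sweeps ±25° around the animal; 5 uniform-firing
pyramidal cells and 5 interneurons (15 Hz) are added, plus uniform
background spiking per cell. Spike-gamma coupling of concentration κ is
imposed by nudging each spike (≤ ±16 ms) to the nearest time where the
gamma phase equals a von Mises draw. During each ripple, cells with
fields 9–63° ahead (probability `swr_forward_prob`) or behind fire one
spike each in positional order at 4–8 ms lags.

*Prospective bias.* A static phase/position offset added to the sweep is
unrecoverable by construction: rate maps trained on the same spikes
absorb any per-cell lead, and the decoder re-centers it, leaving the
prospective ratio at zero for every bias (we verified this numerically;
independent-Poisson "lookahead" spiking likewise disappears below the
2-spikes-per-bin decoding minimum). What survives map calibration — and
what prospective theta content looks like in real recordings — is
*coordinated* nonlocal firing. `theta_bias` therefore controls the rate
of one-cycle episodes (probability 0.16·|bias| per cycle) in which cells
with fields 12–45° ahead (behind, for negative bias) fire paired-spike
bursts spanning the cycle while local firing is damped to 25%. Episode
spikes land 12–45° away from the participating cells' fields and add a
diffuse tail to their maps; this leaks a small opposite-signed offset
into all decoded bins, which makes the session-level ratio a saturating
(but monotone) function of |bias| with a slope of roughly 0.025 per unit
bias at the shipped episode rate.

What the generator does *not* emulate: 1/f LFP backgrounds, theta
harmonics and asymmetric cycle shapes, speed-modulated theta frequency,
phase-precession slope heterogeneity, multi-field cells, behavioral
variability beyond lap-speed jitter, and electrode artifacts. Passing the
recovery suite therefore demonstrates correctness of the analysis code
under known ground truth, not robustness to every property of real
recordings.

## Problem sizes and numerical choices

Synthetic sessions default to 900 s, which yields ~15 laps, ~100 s of
running, ~600 decodable theta cycles and ~110 reward-zone ripples — enough
for every statistic to stabilize while keeping a full-session analysis
around half a minute. Recovery experiments in the test suite use 10 seeds
per theta-bias grid point (session-to-session SD of the session ratio is
~0.01, so adjacent grid points separate by > 2.5 SE) and 3 seeds per
`swr_forward_prob` point (effect steps there are ~0.25, far above noise).
Monte-Carlo calibration uses 200 simulations per condition. Shuffle
counts follow the defaults (500) wherever a statistic's null is asserted;
the orchestration smoke test reduces them via config to keep runtime
proportionate.

Numerical conventions worth knowing: posteriors are normalized per time
bin (sum to 1 within 1e−12); undecoded bins are NaN, never zero; the
bandpass subtracts the signal mean so state detection is exactly
invariant to DC offsets; quadrant masks compare bin centers with a 1e−9
slack so the ±45° and ±80 ms edges are included; WPLI reports NaN where
the imaginary cross-spectrum vanishes (zero-lag synchrony is outside its
domain); and every stochastic step (fold assignment, shuffles, the
generator) takes an explicit seed or generator object.

## Known limitations

The theta-bias recovery slope is shallow (|ratio| ≈ 0.025 at full bias),
so single-session sign estimates near zero bias are noisy; recovery
claims are made at the seed-averaged level. The far-zone analyses are
implemented and tested against constructed posteriors, but the default
generator does not plant unoccupied-zone content, so their end-to-end
rates on synthetic sessions are near zero by design. Group-level
statistics (linear mixed-effects across animals) are deliberately out of
scope: the pipeline exports tidy per-unit / per-trial / per-event tables
for external fitting.
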