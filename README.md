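# prospectcode

Analysis of hippocampal CA3–CA1 coordination and prospective spatial
coding in annular-track virtual-reality sessions: LFP brain-state and
sharp-wave-ripple (SWR) detection, spike–field coupling, place-cell
identification, Bayesian position decoding, theta-sequence quadrant
statistics, and prospective-coding ratios for theta cycles and ripples.
A synthetic session generator with full ground truth makes every stage
testable without animal recordings.

The package is written for systems-neuroscience groups analyzing chronic
hippocampal recordings from head-fixed spatial tasks, and for anyone who
needs a reference implementation of the statistics below with explicit,
tested conventions.

## The statistics at the core

**Pairwise phase consistency (PPC).** For spikes grouped into M trials
with phases φ to a band-filtered LFP, PPC averages cos(φ<sub>k,m</sub> −
φ<sub>j,l</sub>) over all pairs of spikes from *different* trials
(l ≠ m), normalized by 1/(M(M−1)) over ordered trial pairs. It is 1 for
perfect locking, ≈ 0 for uniform phases (without the sample-size bias of
resultant-length measures), and negative for anti-phasic modulation.

**Weighted phase-lag index (WPLI).** |E[Im X]| / E[|Im X|] over Welch
windows (1024-sample Hamming, non-overlapping) of the CA3–CA1
cross-spectrum X; volume-conducted zero-lag synchrony does not
contribute, and frequencies where Im X vanishes are reported as
undefined.

**Spatial information.** SI = Σ<sub>i</sub> p<sub>i</sub>
(λ<sub>i</sub>/λ) log₂(λ<sub>i</sub>/λ) bits/spike over
occupancy-normalized rate-map bins; place cells must beat the 95th
percentile of a circular spike-time shuffle and satisfy mean-rate
(0.2–10 Hz) and peak-rate (≥ 1 Hz) criteria.
Sparsity = [1 − (Σλ<sub>i</sub>/L)² / (Σλ<sub>i</sub>²/L)] · L/(L−1).

**Bayesian decoding.** Memoryless Poisson decoder
P(θ|S) ∝ Π<sub>i</sub> (τ f<sub>i</sub>(θ))^{S_i} e^{−τ Σ f<sub>i</sub>(θ)},
5-fold cross-validated on correct trials in 200 ms blocks; sessions are
kept when the mean normalized posterior at the true position is ≥ 1.2
(chance = 1).

**Theta sequences and prospective coding.** 400 ms windows centered on
theta troughs are decoded in 20 ms bins and re-centered on the animal.
Over the ±80 ms × ±45° box, quadrant ratio =
(Q1+Q3−Q2−Q4)/(Q1+Q2+Q3+Q4) with a 500-permutation time-bin shuffle
test, and prospective coding ratio = (Q1−Q3)/(Q1+Q3), +1 for purely
future content, −1 for purely past.

**SWR content.** 250 ms windows around ripple midpoints decoded in 25 ms
bins; prospective ratio (F−B)/(F+B) over the +9..+63° forward and
−9..−63° behind windows (local ±9° and ±63..90° edges excluded); events
with ratio > 0.1 count as prospective. Sequence-less decoding, unoccupied
reward-zone detection (2 SD rule at 162–198° away) and per-cell
activation / per-pair coactivation probabilities are included.

## Worked example

```python
from prospectcode import SyntheticConfig, generate_session, PipelineConfig
from prospectcode.pipeline import run_pipeline

session = generate_session(SyntheticConfig(seed=7, theta_bias=0.5))
result = run_pipeline(session, PipelineConfig(seed=3))
print(result["manifest"]["counts"])
print(result["decoding_qc"])
print(result["theta_significance"])
```

prints (for this seed):

```
{'trials': 16, 'correct_trials': 14, 'theta_periods': 16, 'swr_events': 119,
 'units_included': 50, 'pyramidal': 45, 'place_cells': 40,
 'theta_cycles_decoded': 593, 'swr_decoded': 119}
{'median_error_deg': 7.76, 'normalized_prob': 5.49, 'included': True}
{'significant': True, 'quadrant_ratio': 0.17}
```

meaning: the 900 s synthetic session yielded 16 half-lap trials (14 with
licking in the reward zone), 119 detected ripples, all 40 ground-truth
place cells recovered; cross-validated decoding tracked position to
within 7.8° median error (QC passed, chance-normalized posterior 5.5);
and the session's averaged theta cycles form significant sequences
(quadrant ratio 0.17 against a 500-shuffle null).

The same pipeline runs from the shell:

```
prospectcode simulate --seed 7 --out session_dir
prospectcode run --session session_dir --out results_dir
```

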