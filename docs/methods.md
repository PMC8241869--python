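# Methods

`wakewave` implements an analysis chain for the question of whether
sleep-like EEG slow waves, occurring locally in the awake brain, accompany
attentional lapses in sustained-attention (SART) performance — and whether
the *location* of those waves separates sluggish lapses (misses, mind
blanking) from impulsive ones (false alarms, mind wandering). Because the
package is validated without any recorded data, it pairs every analysis
stage with a synthetic generator that plants known effects, so the chain
can be tested end to end against ground truth.

## Slow-wave detection

Detection follows the approach used for NREM sleep slow waves, applied to
wake EEG:

1. Re-reference to the average of the mastoid leads TP9 and TP10.
2. Down-sample to 128 Hz (`scipy.signal.resample_poly`).
3. Band-pass with a type-2 Chebyshev filter designed for ≥ 25 dB
   attenuation in the [0.1, 15] Hz stopband and < 3 dB loss in the
   [1, 10] Hz passband. The design targets 26 dB / 2.5 dB so both printed
   bounds hold strictly on the discretized filter; the constructor verifies
   the contracts and refuses a violating design. Application is zero-phase
   (forward–backward), preserving wave timing for event-locking.
4. Delimit one candidate wave per negative half-wave: from the
   zero-crossing before the negative peak to the zero-crossing after the
   following positive peak. On sampled data the entering crossing is the
   last non-negative sample and the leaving crossing the last non-negative
   sample of the positive lobe; no sub-sample interpolation is used, so
   every quantity is exactly recomputable by a brute-force sample scan
   (which the tests do). Ties between equally extreme samples keep the
   earliest.
5. Screen candidates: positive peak ≤ 75 µV (blinks are large-positive and
   frontal), no sample exceeding 150 µV absolute within 1 s of the wave's
   [start, end] span, duration ≥ 143 ms (content below ~7 Hz). The
   amplitude criteria are evaluated on the filtered, mastoid-referenced
   signal — the detection substrate — since the choice of signal is
   otherwise open.
6. Keep, per electrode, the top 10% of candidates by peak-to-peak
   amplitude, pooled over the whole recording; the retained count is
   ⌈0.10 · n⌉ so small candidate sets keep at least one wave. The smallest
   retained amplitude is reported as the per-electrode threshold.

Wave properties are the negative/positive peak amplitudes and times,
peak-to-peak amplitude, downward slope |neg| / (t_neg − t_start) and upward
slope (pos − neg) / (t_pos − t_neg), in µV and µV/s. Window summaries
assign a wave to a window iff its *start* lies in the half-open window and
express density in waves/minute; property means are null for empty
windows. A trial is flagged wave-present on an electrode iff a wave starts
during stimulus presentation, [onset, offset) — left-closed, so a wave
starting exactly at onset counts.

## Behaviour

A response belongs to the latest stimulus whose onset precedes it, and the
response window closes at the *next stimulus onset*. Misses are Go trials
without a response in the window; false alarms are NoGo trials with one.
Responses faster than 300 ms mark the trial excluded — it enters neither
numerator nor denominator of any rate. Pre-probe summaries use trials with
onset in [probe − w, probe), w = 20 s by default, with 10 s and 4 × 5 s
splits supported; sub-windows partition the full window exactly.

Pupil traces are cleaned by linear interpolation across blink gaps plus a
100 ms margin on each side (the margin is a parameter: the underlying
blink-correction literature gives no single value), averaged over each
stimulus window, and per-probe means are discretized into 5 rank-based
quantile bins within participant × task; ties share the lower bin.

## Cluster-based permutation statistics

Per electrode, a two-level within-subject contrast (e.g. mind wandering
vs. task-focused pre-probe wave density) is collapsed to per-subject mean
differences and summarized by a paired t across subjects; any richer model
(e.g. a mixed-effects t) can be plugged in as a callback. Electrode
adjacency uses 3-D standard-template positions with a 0.045 m distance
threshold (~1.5× the nearest-neighbour spacing of a 63-channel 10-10
montage; Cz–FCz are neighbours, the graph has no isolated nodes).

Clusters are sign-consistent connected components of electrodes with
one-tailed p < 0.025 (the cluster-forming alpha applied per tail), scored
by the sum of member t values. The null distribution is the maximal
absolute cluster mass over within-subject sign flips of the difference
maps — the permutation scheme that respects subject exchangeability when
subjects are random effects. With 2^n ≤ n_perm the flip space is
enumerated exhaustively; otherwise p = (1 + #{null ≥ observed})/(1 +
n_perm). Significance requires p below 0.05 divided by the number of map
families tested together (Bonferroni). The cluster-level statistic (mass)
and the neighbour definition are deliberate parameters: neither is forced
by the inferential logic, and both are exposed.

Tests cross-check the whole procedure against MNE-Python's independent
implementation of the same scheme and verify family-wise error control by
global-null simulation.

## Drift-diffusion model

Go/NoGo decisions are modelled as a Wiener process with unit noise between
a lower boundary 0 ("withhold") and an upper boundary a ("respond"),
starting at z·a, with drift v_go > 0 on Go trials and v_nogo < 0 on NoGo
trials; RT = first-passage time + non-decision time t_nd. The drift bias
v_bias = |v_go| − |v_nogo| is always derived, never stored. A trial with no
upper crossing before its deadline (the next stimulus onset) is a withhold
with no RT, whether the process was absorbed below, still diffusing, or
crossed too late.

The simulator is Euler–Maruyama at dt = 0.5 ms with a Brownian-bridge
crossing correction inside each step, which removes the O(√dt) bias of
naive grid crossing detection; it matches the analytic choice probability
(1 − e^(−2vaz))/(1 − e^(−2va)) within Monte-Carlo error. The first-passage
density uses the standard small-time/large-time series with per-element
selection of the cheaper expansion at error 1e-10; the two boundary
densities integrate to one to 1e-4 or better.

Fitting is non-hierarchical maximum likelihood per condition: responses
contribute the upper-boundary density at their RT; withheld trials
contribute 1 − ∫₀^deadline f_upper, evaluated by 96-node Gauss–Legendre
quadrature with withheld trials grouped on a 5 ms deadline grid.
Optimization is bounded L-BFGS-B from 5 seeded restarts (bounds: drifts
±8/s, a ∈ [0.3, 4], z ∈ [0.05, 0.95], t_nd ∈ [0.01, 0.8] s). Hierarchical
Bayesian estimation and inter-trial variability parameters are out of
scope; the accepted evidence of correctness is parameter recovery —
each of (v_go, v_nogo, a) within 10% relative error and (z, t_nd) within
0.05 absolute at 5000 trials per trial type.

## Synthetic sessions

The generator emulates the experiment's structure: 2 task types × 3 blocks
× 10 probes by default, probes separated by Uniform(30, 70) s, stimuli
shown for Uniform(0.75, 1.25) s with exactly one NoGo per permuted block
of nine and no identity repeated back to back. A latent vigilance process
(clipped Gaussian random walk per probe epoch, step SD 0.12) drives probe
reports through a softmax whose base rates at reference vigilance are
48/39/13% ON/MW/MB, matching the reported prevalence of the three states.

Ground-truth slow waves arrive as per-channel Poisson processes:
0.5 waves/min/channel baseline, raised to 2/min on frontal channels during
mind-wandering epochs and on posterior channels during mind-blanking
epochs. These rates were chosen so that region-level wave incidence per
1 s stimulus stays in a plausible range and trial outcome rates land near
the observed SART regime (single-digit miss rates, tens-of-percent false
alarm rates). Each wave is a biphasic half-sine template (negative lobe
60% of the duration and twice the positive amplitude; duration
Uniform(0.4, 0.9) s; peak-to-peak ~N(60, 10) µV clipped at 35), added to
1/f^α Gaussian background noise (α = 1, RMS 10 µV) — a realistic EEG
spectrum without modelling physiology. Responses come from the DDM with
planted couplings: a frontal ground-truth wave during the stimulus
multiplies v_nogo by 0.3 (impulsivity), a posterior wave multiplies v_go
by 0.35 (sluggishness), from a base of (v_go 2.8, v_nogo −0.9, a 1.4,
z 0.55, t_nd 0.25 s). Pupil size tracks vigilance linearly (arbitrary
units) with Poisson blinks of 100–300 ms at 15/min.

All randomness flows from one session seed through named
`SeedSequence` child streams spawned in a fixed order (stimuli, probes,
states, waves, responses, eeg, pupil), making sessions bit-reproducible
and the streams independent of one another.

What the generator does *not* emulate — ocular/cardiac artifacts beyond
blinks, volume conduction (waves are injected per channel, not as dipolar
topographies), non-stationary noise, bad channels, probe question screens —
bounds what passing tests show: they establish that the chain recovers
known effects under clean, stationary conditions, not that it is robust to
every failure mode of recorded EEG.

## Pipeline and problem sizes

`run_pipeline` chains simulate → detect → behaviour → stats → ddm. EEG is
written to EDF (a minimal 16-bit writer with 1 s records; reading goes
through MNE) and detection re-reads the saved files, so a stage re-run on
disk intermediates reproduces the full run byte for byte. Every table is
TSV with fixed float formatting; the manifest records the seed, a SHA-256
hash of the canonical config and the package version.

The default run config uses a desk-scale cohort (6 participants, 1 block
per task, 6 probes per block) chosen so a full run completes in minutes;
the generative conditions (rates, couplings, noise, probe spacing) are the
session defaults above. DDM fits are split by wave presence on a small
region-of-interest electrode set (Fz, FCz, Pz, POz by default) rather than
all 63 electrodes, since maximum-likelihood fits per electrode × condition
across the full montage would dominate runtime without changing the
frontal/posterior comparison the fits exist to make. The end-to-end
validation uses a strong-coupling configuration (state-coupled rates
6/min, drift factors 0.25/0.3, 10 subjects × 16 probes) so a single seeded
cohort exposes the planted topography: mind-wandering contrasts should
localize frontally, mind-blanking contrasts posteriorly, and fitted
|v_nogo| (resp. v_go) should drop on trials with frontal (resp. posterior)
waves.

## Numerical notes and limitations

- Intervals are half-open [onset, offset) throughout; t = 0 at recording
  start; seconds everywhere.
- Zero-crossing delimitation is integer-sample by design; wave timing
  granularity is 1/128 s.
- Waves truncated by the recording edges are discarded rather than
  partially delimited.
- The paired-t map treats a zero-variance electrode as t = 0; degenerate
  in practice only for constant synthetic inputs.
- The EDF writer quantizes to 16 bits over each channel's observed range
  (≤ 0.005 µV per step for typical synthetic data); detection operates on
  the quantized signal by construction, so this is part of the pipeline's
  deterministic path, not an error source.
- The exclusion margin around large-amplitude events is measured from the
  wave span to the nearest offending sample, on the filtered signal;
  other readings of "within 1 s" (e.g. peak-to-peak distance, raw signal)
  are possible and would change borderline exclusions.
- `fit_ddm` assumes both trial types are present and ≥ roughly 200 trials
  per condition for stable estimates; smaller conditions are skipped by
  the pipeline rather than fitted badly.
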