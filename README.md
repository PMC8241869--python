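# wakewave

Detection of sleep-like slow waves in waking EEG and analysis of their
behavioural consequences in sustained-attention (Go/NoGo, SART)
experiments.

When an awake person's attention lapses, parts of their cortex can produce
brief, local delta-band slow waves — the electrophysiological signature of
sleep — while the rest of the brain stays awake. `wakewave` provides the
full analysis chain for studying this "local sleep" account of attentional
lapses:

- **`wakewave.swdetect`** — per-electrode slow-wave detection: mastoid
  re-referencing, down-sampling to 128 Hz, a type-2 Chebyshev band-pass
  (≥ 25 dB attenuation over [0.1, 15] Hz, < 3 dB loss over [1, 10] Hz),
  zero-crossing wave delimitation, artifact screening (positive peak
  > 75 µV, ±150 µV events within 1 s, duration < 143 ms), and per-electrode
  top-10% amplitude selection. Wave properties: peak-to-peak amplitude,
  downward slope |neg|/(t_neg − t_start), upward slope
  (pos − neg)/(t_pos − t_neg), density in waves/min.
- **`wakewave.behaviour`** — SART trial scoring (miss / false alarm /
  correct, 300 ms exclusion), pre-probe summaries (20 s / 10 s / 4 × 5 s
  windows), pupil blink interpolation and 5-bin quantile discretization.
- **`wakewave.stats`** — electrode-level within-subject contrasts (paired
  t across subjects, pluggable statistic) with cluster-based permutation
  inference: clusters of neighbouring electrodes at one-tailed p < 0.025,
  cluster mass vs. the max-mass sign-flip null, Monte Carlo p < 0.05 with
  Bonferroni correction across map families.
- **`wakewave.ddm`** — two-boundary drift-diffusion model of Go/NoGo
  decisions: parameters v_Go, v_NoGo, a (threshold), z (start bias),
  t (non-decision time) and the derived drift bias
  v_Bias = |v_Go| − |v_NoGo|; unbiased simulator (Brownian-bridge-corrected
  Euler–Maruyama), analytic first-passage density, maximum-likelihood
  fitting with deadline censoring.
- **`wakewave.synthgen`** — fully synthetic sessions: stimulus streams
  (one NoGo per permuted block of nine, 0.75–1.25 s stimuli), probes every
  30–70 s with ON / mind-wandering / mind-blanking reports driven by latent
  vigilance, ground-truth slow waves whose topography depends on state
  (frontal during MW, posterior during MB), DDM-generated responses
  modulated by wave presence, 63-channel EEG (1/f noise + biphasic wave
  templates) and pupil traces with blinks.
- **`wakewave.pipeline`** — one reproducible run: simulate → detect →
  behaviour → stats → ddm, EDF + TSV intermediates, manifest with config
  hash and seed, plus a thin CLI (`wakewave all --config run.yaml --out d/`).

Because every synthetic effect is planted with a known direction and
topography, the chain is testable end to end: frontal waves are coupled to
weakened NoGo evidence accumulation (false alarms, mind wandering) and
posterior waves to weakened Go accumulation (slow responses, misses, mind
blanking), and the pipeline is expected to recover exactly that
dissociation from the raw synthetic EEG.

## Worked example

```python
import numpy as np
from wakewave import SessionConfig, generate_session, detect_slow_waves

config = SessionConfig(n_tasks=1, n_blocks_per_task=1,
                       n_probes_per_block=5, seed=7)
session = generate_session(config, include_pupil=False)
waves, thresholds = detect_slow_waves(session.eeg)

print(len(waves), waves["channel"].nunique())
print(round(np.mean(list(thresholds.values())), 1))
print(round(waves["p2p_amp"].mean(), 1))
```

prints

```
3595 61
21.9
26.1
```

— 3595 slow waves detected across 61 scalp electrodes (mastoids are
reference leads), with a mean per-electrode top-10% selection threshold of
21.9 µV and a mean peak-to-peak amplitude of 26.1 µV. Checking the
detector against the generator's ground truth on the busiest channel of
this session recovers 7/7 injected waves within 0.25 s
(`examples/02_detect_slow_waves.py`).

The `examples/` directory holds one short narrative script per capability:
session simulation, slow-wave detection, behavioural scoring, cluster
statistics, DDM fitting, and the full pipeline. Each builds a small input,
runs the method and prints what the numbers mean.

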