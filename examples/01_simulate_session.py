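"""Generate one synthetic SART session and look at its structure.

A session is a continuous Go/NoGo stream (one NoGo per permuted block of
nine stimuli, each shown 0.75-1.25 s) interrupted every 30-70 s by an
experience-sampling probe. A latent vigilance process sets each probe's
mental-state report (ON = task-focused, MW = mind wandering, MB = mind
blanking) and modulates where sleep-like slow waves appear: frontal
channels during MW, posterior channels during MB.
"""

from wakewave import SessionConfig, generate_session

config = SessionConfig(n_tasks=2, n_blocks_per_task=1, n_probes_per_block=5,
                       seed=42)
session = generate_session(config)

print(f"session duration: {session.eeg.duration:.0f} s "
      f"({session.eeg.n_channels} channels at {session.eeg.sfreq:.0f} Hz)")
print(f"stimuli: {len(session.stimuli)} "
      f"({session.stimuli['is_nogo'].sum()} NoGo, exactly 1 per 9)")
print(f"probes: {len(session.probes)}")
print(session.probes[["probe", "onset_s", "task", "state", "vigilance"]]
      .to_string(index=False))
print(f"ground-truth slow waves: {len(session.ground_truth_waves)} "
      f"on {session.ground_truth_waves['channel'].nunique()} channels")
print(f"button presses: {len(session.responses)}")

# The wave table is the validation substrate: every downstream stage can be
# checked against these known onsets, channels and amplitudes.
print(session.ground_truth_waves.head().to_string(index=False))
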