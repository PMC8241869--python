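"""Synthetic SART sessions with ground-truth slow waves.

This module emulates the structure of a sustained-attention-to-response
(SART) experiment: a continuous Go/NoGo stimulus stream (one NoGo per
permuted block of nine stimuli, 0.75–1.25 s per stimulus), experience-
sampling probes every 30–70 s (10 per block, 3 blocks per task, 2 tasks),
a latent vigilance process that drives both the probe reports (task-focused
ON, mind wandering MW, mind blanking MB) and the rate and topography of
sleep-like slow waves, drift-diffusion responses whose parameters are
modulated by wave presence, multi-channel EEG (1/f background noise plus
biphasic wave templates on known channels at known times), and a pupil
trace with blinks.

The coupling between latent state, waves and behaviour is a validation
device: it plants effects with a known direction and topography (frontal
waves weaken NoGo evidence accumulation; posterior waves weaken Go
accumulation) so the downstream detection, statistics and modelling stages
can be checked end to end against ground truth.

All randomness derives from a single session seed through named
``numpy.random.SeedSequence`` child streams, spawned in a fixed order
(stimuli, probes, states, waves, responses, eeg, pupil), so a session is
bit-reproducible and adding, say, pupil simulation never perturbs the EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddm import DDMParams, simulate_ddm_trials
from .io import EEGRecording
from .montage import DEFAULT_MONTAGE, FRONTAL_CHANNELS, POSTERIOR_CHANNELS

__all__ = [
    "SessionConfig",
    "CouplingConfig",
    "NoiseSpec",
    "LatentStateTrace",
    "PupilTrace",
    "SessionData",
    "generate_stimulus_stream",
    "generate_session",
    "inject_slow_waves",
    "wave_template",
    "simulate_pupil",
]

_STREAMS = ("stimuli", "probes", "states", "waves", "responses", "eeg", "pupil")


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class SessionConfig:
    """Design parameters of one synthetic SART session (one participant)."""

    n_tasks: int = 2
    n_blocks_per_task: int = 3
    n_probes_per_block: int = 10
    stim_duration_range: tuple[float, float] = (0.75, 1.25)
    nogo_period: int = 9
    probe_interval_range: tuple[float, float] = (30.0, 70.0)
    sampling_rate: float = 500.0
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stim_duration_range", "probe_interval_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered, got ({lo}, {hi})")
        if self.nogo_period < 2:
            raise ValueError("nogo_period must be >= 2")
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage labels must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class CouplingConfig:
    """How the latent state couples to slow waves and decision parameters.

    Rates are ground-truth wave rates in waves/minute/channel. The two
    multiplicative drift factors implement the planted topographic
    dissociation: a frontal wave during a stimulus shrinks |v_nogo|
    (impulsivity, false alarms), a posterior wave shrinks v_go
    (sluggishness, slower RTs and misses).
    """

    baseline_rate: float = 0.5
    mw_frontal_rate: float = 2.0
    mb_posterior_rate: float = 2.0
    state_base_rates: tuple[float, float, float] = (0.48, 0.39, 0.13)  # ON, MW, MB
    vigilance_gain: float = 4.0
    frontal_vnogo_factor: float = 0.3
    posterior_vgo_factor: float = 0.35
    ddm_base: DDMParams = field(
        default_factory=lambda: DDMParams(v_go=2.8, v_nogo=-0.9, a=1.4, z=0.55, t_nd=0.25)
    )

    def __post_init__(self) -> None:
        for r in (self.baseline_rate, self.mw_frontal_rate, self.mb_posterior_rate):
            if r < 0:
                raise ValueError("wave rates must be >= 0")


@dataclass
class NoiseSpec:
    """1/f^alpha Gaussian background noise for synthetic EEG."""

    alpha: float = 1.0
    rms_uv: float = 10.0


@dataclass
class LatentStateTrace:
    """Latent vigilance and per-probe mental states for one session."""

    probe_times_s: np.ndarray          # session-time probe onsets
    states: list[str]                  # 'ON' | 'MW' | 'MB' per probe
    vigilance: np.ndarray              # continuous 0-1, per probe epoch
    duration_s: float
    coupling: CouplingConfig = field(default_factory=CouplingConfig)

    def __post_init__(self) -> None:
        bad = set(self.states) - {"ON", "MW", "MB"}
        if bad:
            raise ValueError(f"invalid mental-state labels: {bad}")


@dataclass
class PupilTrace:
    rate_hz: float
    values: np.ndarray                 # arbitrary units, NaN inside blinks
    blink_intervals: list[tuple[float, float]]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate_hz


@dataclass
class SessionData:
    config: SessionConfig
    stimuli: pd.DataFrame              # onset_s offset_s identity is_nogo task block
    probes: pd.DataFrame               # probe id, onset_s, task, block, state, vigilance
    latent: LatentStateTrace
    responses: pd.DataFrame            # response_time_s per emitted button press
    ground_truth_waves: pd.DataFrame   # channel onset_s duration_s p2p_amp_uv
    eeg: EEGRecording | None = None
    pupil: PupilTrace | None = None


# ---------------------------------------------------------------------------
# stimulus stream
# ---------------------------------------------------------------------------

def generate_stimulus_stream(
    config: SessionConfig,
    seed: int | np.random.Generator,
    n_stimuli: int | None = None,
    total_duration_s: float | None = None,
) -> pd.DataFrame:
    """Continuous Go/NoGo stream: identities permuted per block of
    ``nogo_period``, exactly one NoGo identity per block, never the same
    identity twice in a row, i.i.d. uniform stimulus durations.

    Provide either ``n_stimuli`` or ``total_duration_s``.
    """
    if (n_stimuli is None) == (total_duration_s is None):
        raise ValueError("provide exactly one of n_stimuli / total_duration_s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = config.nogo_period
    lo, hi = config.stim_duration_range

    identities: list[int] = []
    if n_stimuli is None:
        # upper bound on the number of stimuli needed
        n_needed = int(np.ceil(total_duration_s / lo)) + k
    else:
        n_needed = n_stimuli
    while len(identities) < n_needed:
        perm = rng.permutation(k)
        while identities and perm[0] == identities[-1]:
            perm = rng.permutation(k)
        identities.extend(int(i) for i in perm)
    identities = identities[: len(identities) - len(identities) % k]

    durations = rng.uniform(lo, hi, size=len(identities))
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    df = pd.DataFrame({
        "onset_s": onsets,
        "offset_s": onsets + durations,
        "identity": identities,
        "is_nogo": np.asarray(identities) == 0,
    })
    if n_stimuli is not None:
        df = df.iloc[:n_stimuli].reset_index(drop=True)
    else:
        df = df[df["onset_s"] < total_duration_s].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# latent state and waves
# ---------------------------------------------------------------------------

def _sample_states(vig: np.ndarray, coupling: CouplingConfig,
                   rng: np.random.Generator) -> list[str]:
    """Probe label from a softmax over latent vigilance.

    At the reference vigilance 0.65 the probabilities equal the configured
    base rates (~48/39/13% ON/MW/MB); higher vigilance tilts toward ON,
    lower toward MW and (more strongly) MB.
    """
    base = np.log(np.asarray(coupling.state_base_rates))
    direction = np.array([1.0, -0.4, -1.2])
    states = []
    for v in vig:
        logits = base + coupling.vigilance_gain * direction * (v - 0.65)
        p = np.exp(logits - logits.max())
        p /= p.sum()
        states.append(("ON", "MW", "MB")[rng.choice(3, p=p)])
    return states


def _epoch_wave_rates(state: str, montage: tuple[str, ...],
                      coupling: CouplingConfig) -> np.ndarray:
    rates = np.full(len(montage), coupling.baseline_rate)
    if state == "MW":
        for i, ch in enumerate(montage):
            if ch in FRONTAL_CHANNELS:
                rates[i] = coupling.mw_frontal_rate
    elif state == "MB":
        for i, ch in enumerate(montage):
            if ch in POSTERIOR_CHANNELS:
                rates[i] = coupling.mb_posterior_rate
    return rates


def _sample_waves(epochs: list[tuple[float, float, str]], montage: tuple[str, ...],
                  coupling: CouplingConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for t0, t1, state in epochs:
        rates = _epoch_wave_rates(state, montage, coupling)
        span = t1 - t0
        for ch, rate in zip(montage, rates):
            n = rng.poisson(rate / 60.0 * span)
            if n == 0:
                continue
            durs = rng.uniform(0.4, 0.9, size=n)
            # waves start within the epoch and end before it does (onsets
            # stay paired with their durations; the table is sorted later)
            onsets = rng.uniform(t0, np.maximum(t0, t1 - durs), size=n)
            amps = np.clip(rng.normal(60.0, 10.0, size=n), 35.0, None)
            for o, d, a in zip(onsets, durs, amps):
                rows.append((ch, float(o), float(d), float(a)))
    df = pd.DataFrame(rows, columns=["channel", "onset_s", "duration_s", "p2p_amp_uv"])
    return df.sort_values(["onset_s", "channel"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def generate_session(
    config: SessionConfig,
    coupling: CouplingConfig | None = None,
    noise: NoiseSpec | None = None,
    include_eeg: bool = True,
    include_pupil: bool = True,
    blink_rate: float = 15.0,
) -> SessionData:
    """Generate one complete synthetic session.

    Blocks are laid out back to back on one session clock (t=0 at recording
    start, half-open [onset, offset) intervals throughout). Each block ends
    at its last probe.
    """
    coupling = coupling or CouplingConfig()
    noise = noise if noise is not None else NoiseSpec()
    rngs = _spawn_rngs(config.seed)

    stim_parts, probe_rows, epochs = [], [], []
    vig_all: list[float] = []
    t_block = 0.0
    probe_id = 0
    vig = float(rngs["states"].uniform(0.45, 0.85))
    for task in range(config.n_tasks):
        for block in range(config.n_blocks_per_task):
            gaps = rngs["probes"].uniform(*config.probe_interval_range,
                                          size=config.n_probes_per_block)
            probe_local = np.cumsum(gaps)
            block_dur = float(probe_local[-1])
            stim = generate_stimulus_stream(config, rngs["stimuli"],
                                            total_duration_s=block_dur)
            # the block's final probe interrupts the stimulus on screen
            stim = stim.assign(offset_s=stim["offset_s"].clip(upper=block_dur))
            stim = stim.assign(onset_s=stim["onset_s"] + t_block,
                               offset_s=stim["offset_s"] + t_block,
                               task=task, block=block)
            stim_parts.append(stim)

            t_prev = t_block
            for p_local in probe_local:
                vig = float(np.clip(vig + rngs["states"].normal(0.0, 0.12), 0.0, 1.0))
                vig_all.append(vig)
                t_probe = t_block + float(p_local)
                probe_rows.append({"probe": probe_id, "onset_s": t_probe,
                                   "task": task, "block": block,
                                   "vigilance": vig})
                epochs.append((t_prev, t_probe, None))
                t_prev = t_probe
                probe_id += 1
            t_block += block_dur

    duration = t_block
    vig_arr = np.asarray(vig_all)
    states = _sample_states(vig_arr, coupling, rngs["states"])
    epochs = [(t0, t1, states[i]) for i, (t0, t1, _) in enumerate(epochs)]
    probes = pd.DataFrame(probe_rows)
    probes["state"] = states

    waves = _sample_waves(epochs, config.montage, coupling, rngs["waves"])
    stimuli = pd.concat(stim_parts, ignore_index=True)

    latent = LatentStateTrace(probe_times_s=probes["onset_s"].to_numpy(),
                              states=states, vigilance=vig_arr,
                              duration_s=duration, coupling=coupling)

    responses = _simulate_responses(stimuli, waves, coupling, rngs["responses"])

    eeg = None
    if include_eeg:
        n_samp = int(np.ceil(duration * config.sampling_rate))
        eeg = EEGRecording(data=np.zeros((len(config.montage), n_samp)),
                           sfreq=config.sampling_rate,
                           ch_names=list(config.montage), reference="online")
        eeg = inject_slow_waves(eeg, waves, noise, rngs["eeg"])

    pupil = None
    if include_pupil:
        pupil = simulate_pupil(latent, blink_rate=blink_rate, seed=rngs["pupil"])

    return SessionData(config=config, stimuli=stimuli, probes=probes,
                       latent=latent, responses=responses,
                       ground_truth_waves=waves, eeg=eeg, pupil=pupil)


def _trial_wave_presence(stimuli: pd.DataFrame, waves: pd.DataFrame,
                         channels: tuple[str, ...]) -> np.ndarray:
    """True where >=1 ground-truth wave on any of ``channels`` starts
    during stimulus presentation, [onset, offset)."""
    flags = np.zeros(len(stimuli), dtype=bool)
    if not len(waves):
        return flags
    w = waves[waves["channel"].isin(channels)]
    onsets = np.sort(w["onset_s"].to_numpy())
    s0 = stimuli["onset_s"].to_numpy()
    s1 = stimuli["offset_s"].to_numpy()
    lo = np.searchsorted(onsets, s0, side="left")
    hi = np.searchsorted(onsets, s1, side="left")
    return hi > lo


def _simulate_responses(stimuli: pd.DataFrame, waves: pd.DataFrame,
                        coupling: CouplingConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """One DDM decision per stimulus; deadline at the next stimulus onset."""
    onset = stimuli["onset_s"].to_numpy()
    offset = stimuli["offset_s"].to_numpy()
    next_onset = np.append(onset[1:], offset[-1])
    # stimuli truncated by a probe leave (almost) no time to respond; keep
    # the simulator well-posed by flooring the decision window
    deadline = np.maximum(next_onset - onset, coupling.ddm_base.t_nd + 0.05)

    frontal = _trial_wave_presence(stimuli, waves, FRONTAL_CHANNELS)
    posterior = _trial_wave_presence(stimuli, waves, POSTERIOR_CHANNELS)
    is_nogo = stimuli["is_nogo"].to_numpy()

    base = coupling.ddm_base
    rows = []
    # batch trials that share parameter modulation + type for vectorized sim
    for f in (False, True):
        for p in (False, True):
            params = DDMParams(
                v_go=base.v_go * (coupling.posterior_vgo_factor if p else 1.0),
                v_nogo=base.v_nogo * (coupling.frontal_vnogo_factor if f else 1.0),
                a=base.a, z=base.z, t_nd=base.t_nd)
            for tt, mask in (("go", ~is_nogo), ("nogo", is_nogo)):
                sel = mask & (frontal == f) & (posterior == p)
                idx = np.nonzero(sel)[0]
                if idx.size == 0:
                    continue
                resp, rt = simulate_ddm_trials(params, tt, idx.size,
                                               deadline[idx], rng=rng)
                for i, r, t in zip(idx, resp, rt):
                    if r:
                        rows.append(onset[i] + t)
    return pd.DataFrame({"response_time_s": np.sort(np.asarray(rows))})


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def wave_template(duration_s: float, p2p_uv: float, fs: float,
                  neg_fraction: float = 0.6) -> np.ndarray:
    """Biphasic slow-wave template: half-sine negative lobe followed by a
    half-sine positive rebound, negative lobe twice the positive amplitude
    (p2p = |neg| + pos with |neg| = 2·pos)."""
    if duration_s <= 0 or p2p_uv <= 0:
        raise ValueError("duration and amplitude must be positive")
    n = max(int(round(duration_s * fs)), 4)
    n_neg = max(int(round(n * neg_fraction)), 2)
    n_pos = max(n - n_neg, 2)
    a_neg = 2.0 * p2p_uv / 3.0
    a_pos = p2p_uv / 3.0
    t_neg = np.arange(n_neg) / n_neg
    t_pos = np.arange(n_pos) / n_pos
    return np.concatenate([-a_neg * np.sin(np.pi * t_neg),
                           a_pos * np.sin(np.pi * t_pos)])


def _one_over_f_noise(n: int, alpha: float, rms: float,
                      rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    if rms == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x * (rms / np.sqrt(np.mean(x**2)))


def inject_slow_waves(
    eeg: EEGRecording,
    waves: pd.DataFrame,
    noise_spec: NoiseSpec | None,
    seed: int | np.random.Generator,
) -> EEGRecording:
    """Return ``eeg`` plus 1/f background noise plus additive wave templates.

    ``waves`` needs columns channel, onset_s, duration_s, p2p_amp_uv.
    Channels not named in ``waves`` differ from the input by noise only.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = eeg.sfreq
    n = eeg.n_samples
    data = eeg.data.copy()
    if noise_spec is not None and noise_spec.rms_uv > 0:
        for i in range(eeg.n_channels):
            data[i] += _one_over_f_noise(n, noise_spec.alpha, noise_spec.rms_uv, rng)
    duration = n / fs
    for row in waves.itertuples(index=False):
        if row.onset_s < 0 or row.onset_s + row.duration_s > duration + 0.5 / fs:
            raise ValueError(
                f"wave at {row.onset_s:.2f}s (+{row.duration_s:.2f}s) "
                "falls outside the recording")
        i0 = int(round(row.onset_s * fs))
        tpl = wave_template(row.duration_s, row.p2p_amp_uv, fs)
        tpl = tpl[: n - i0]               # sample-rounding at the very end
        ci = eeg.channel_index(row.channel)
        data[ci, i0 : i0 + tpl.size] += tpl
    return eeg.copy_with(data=data, reference=eeg.reference)


# ---------------------------------------------------------------------------
# pupil
# ---------------------------------------------------------------------------

def simulate_pupil(
    latent: LatentStateTrace,
    blink_rate: float = 15.0,
    seed: int | np.random.Generator = 0,
    rate_hz: float = 1000.0,
) -> PupilTrace:
    """Pupil-size trace (arbitrary units) tracking latent vigilance.

    Mean size increases linearly with vigilance; blinks arrive as a Poisson
    process at ``blink_rate`` per minute and appear as 100–300 ms missing
    (NaN) segments, the footprint left after eyelink blink detection.
    """
    if blink_rate < 0:
        raise ValueError("blink_rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(np.ceil(latent.duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    if latent.probe_times_s.size >= 2:
        vig_t = np.interp(t, latent.probe_times_s, latent.vigilance)
    else:
        vig_t = np.full(n, latent.vigilance[0] if latent.vigilance.size else 0.65)
    values = 1000.0 + 400.0 * vig_t + rng.normal(0.0, 5.0, size=n)

    blink_intervals: list[tuple[float, float]] = []
    n_blinks = rng.poisson(blink_rate * latent.duration_s / 60.0)
    for onset in np.sort(rng.uniform(0.0, latent.duration_s, size=n_blinks)):
        dur = rng.uniform(0.1, 0.3)
        i0, i1 = int(onset * rate_hz), min(int((onset + dur) * rate_hz), n)
        values[i0:i1] = np.nan
        blink_intervals.append((float(onset), float(min(onset + dur, latent.duration_s))))
    return PupilTrace(rate_hz=rate_hz, values=values, blink_intervals=blink_intervals)
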