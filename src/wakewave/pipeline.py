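"""End-to-end pipeline: simulate -> detect -> behaviour -> stats -> DDM.

One :func:`run_pipeline` call generates a cohort of synthetic participants,
writes their EEG to EDF and event tables to TSV, detects slow waves from
the saved EDFs (so every later stage operates on the same on-disk
intermediates it would see when re-run standalone), summarizes pre-probe
wave features, contrasts mental states over the electrode map with the
cluster-permutation test, and fits drift-diffusion parameters split by
slow-wave presence on a small set of region-of-interest electrodes.

All outputs are plain TSV plus a manifest.json recording the seed, the
configuration hash and package version, so a run is reproducible and each
stage independently re-runnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behaviour import discretize_pupil, preprobe_summary, preprocess_pupil, score_trials, trial_pupil_means
from .ddm import fit_ddm
from .io import read_edf, read_table, write_edf, write_table
from .montage import MASTOIDS
from .stats import DEFAULT_ADJACENCY_THRESHOLD, build_adjacency, cluster_permutation
from .swdetect import DetectionParams, detect_slow_waves, flag_trial_wave_presence, summarize_waves
from .synthgen import CouplingConfig, NoiseSpec, SessionConfig, generate_session

__all__ = ["RunConfig", "StageError", "run_pipeline",
           "stage_simulate", "stage_detect", "stage_behaviour",
           "stage_stats", "stage_ddm"]


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything that influences a pipeline run.

    The session block keeps the experiment's generative conditions; the
    cohort block sets the problem size of the run (number of simulated
    participants, blocks and probes), which defaults to a desk-scale cohort.
    """

    n_subjects: int = 6
    session: SessionConfig = field(default_factory=lambda: SessionConfig(
        n_blocks_per_task=1, n_probes_per_block=6))
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    windows_s: tuple[float, ...] = (20.0,)
    contrasts: tuple[tuple[str, str], ...] = (("MW", "ON"), ("MB", "ON"), ("MB", "MW"))
    properties: tuple[str, ...] = ("density",)
    cluster_alpha: float = 0.025
    n_perm: int = 1000
    mc_threshold: float = 0.05
    n_comparisons: int = 1
    adjacency_threshold: float = DEFAULT_ADJACENCY_THRESHOLD
    ddm_roi: tuple[str, ...] = ("Fz", "FCz", "Pz", "POz")
    ddm_enabled: bool = True
    include_pupil: bool = True
    seed: int = 0

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["session"].pop("seed", None)   # per-subject seeds derive from the run seed
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "session" in d:
            s = dict(d["session"])
            for key in ("stim_duration_range", "probe_interval_range"):
                if key in s:
                    s[key] = tuple(s[key])
            if "montage" in s:
                s["montage"] = tuple(s["montage"])
            d["session"] = SessionConfig(**s)
        if "coupling" in d:
            c = dict(d["coupling"])
            if "state_base_rates" in c:
                c["state_base_rates"] = tuple(c["state_base_rates"])
            if "ddm_base" in c:
                from .ddm import DDMParams
                c["ddm_base"] = DDMParams(**c["ddm_base"])
            d["coupling"] = CouplingConfig(**c)
        if "noise" in d:
            d["noise"] = NoiseSpec(**d["noise"])
        if "detection" in d:
            det = dict(d["detection"])
            for key in ("passband", "stopband"):
                if key in det:
                    det[key] = tuple(det[key])
            d["detection"] = DetectionParams(**det)
        for key in ("windows_s", "properties", "ddm_roi"):
            if key in d:
                d[key] = tuple(d[key])
        if "contrasts" in d:
            d["contrasts"] = tuple(tuple(c) for c in d["contrasts"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def subject_seeds(self) -> list[int]:
        children = np.random.SeedSequence(self.seed).spawn(self.n_subjects)
        return [int(c.generate_state(1)[0] % (2**31)) for c in children]


# ---------------------------------------------------------------------------
# stages (each reads its inputs from disk and writes its outputs to disk)
# ---------------------------------------------------------------------------

def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def stage_simulate(config: RunConfig, out: Path) -> None:
    (out / "eeg").mkdir(parents=True, exist_ok=True)
    stimuli, responses, probes, gtw, pupil_rows = [], [], [], [], []
    for subj, seed in enumerate(config.subject_seeds()):
        sess_cfg = dataclasses.replace(config.session, seed=seed)
        sess = generate_session(sess_cfg, coupling=config.coupling,
                                noise=config.noise, include_eeg=True,
                                include_pupil=config.include_pupil)
        write_edf(out / "eeg" / f"subj-{subj:02d}.edf", sess.eeg)
        stimuli.append(sess.stimuli.assign(participant=subj))
        responses.append(sess.responses.assign(participant=subj))
        probes.append(sess.probes.assign(participant=subj))
        gtw.append(sess.ground_truth_waves.assign(participant=subj))
        if config.include_pupil and sess.pupil is not None:
            clean = preprocess_pupil(sess.pupil)
            trials_min = sess.stimuli[["onset_s", "offset_s"]]
            _, per_probe = trial_pupil_means(clean, trials_min, sess.probes)
            per_probe["participant"] = subj
            per_probe = per_probe.merge(
                sess.probes[["probe", "task"]], on="probe")
            pupil_rows.append(per_probe)
    write_table(out / "stimuli.tsv", _concat(stimuli))
    write_table(out / "responses.tsv", _concat(responses))
    write_table(out / "ground_truth_waves.tsv", _concat(gtw))
    probes_df = _concat(probes)
    if pupil_rows:
        pupil = _concat(pupil_rows)
        pupil["pupil_bin"] = discretize_pupil(pupil)
        probes_df = probes_df.merge(
            pupil[["participant", "probe", "pupil_mean", "pupil_bin"]],
            on=["participant", "probe"], how="left")
    write_table(out / "probes.tsv", probes_df)


def stage_detect(config: RunConfig, out: Path) -> None:
    probes = read_table(out / "probes.tsv")
    waves_all, thr_rows, summ_all = [], [], []
    channels = [ch for ch in config.session.montage if ch not in MASTOIDS]
    for subj in range(config.n_subjects):
        eeg = read_edf(out / "eeg" / f"subj-{subj:02d}.edf")
        waves, thresholds = detect_slow_waves(eeg, config.detection)
        waves_all.append(waves.assign(participant=subj))
        thr_rows.extend({"participant": subj, "channel": ch, "threshold_uv": v}
                        for ch, v in sorted(thresholds.items()))
        p = probes[probes["participant"] == subj]
        for w in config.windows_s:
            windows = [(int(r.probe), r.onset_s - w, r.onset_s)
                       for r in p.itertuples(index=False)]
            summ = summarize_waves(waves, windows, channels)
            summ["participant"] = subj
            summ["window_len_s"] = w
            summ_all.append(summ)
    write_table(out / "waves.tsv", _concat(waves_all))
    write_table(out / "thresholds.tsv", pd.DataFrame(thr_rows))
    write_table(out / "summaries.tsv", _concat(summ_all))


def stage_behaviour(config: RunConfig, out: Path) -> None:
    stimuli = read_table(out / "stimuli.tsv")
    responses = read_table(out / "responses.tsv")
    probes = read_table(out / "probes.tsv")
    trials_all, behav_all = [], []
    for subj in range(config.n_subjects):
        st = stimuli[stimuli["participant"] == subj].reset_index(drop=True)
        rs = responses[responses["participant"] == subj]
        trials = score_trials(st.drop(columns=["participant"]), rs)
        trials["participant"] = subj
        trials_all.append(trials)
        pr = probes[probes["participant"] == subj]
        for w in config.windows_s:
            b = preprobe_summary(trials, pr, window_s=w)
            b["participant"] = subj
            behav_all.append(b)
    write_table(out / "trials.tsv", _concat(trials_all))
    write_table(out / "behaviour.tsv", _concat(behav_all))


def stage_stats(config: RunConfig, out: Path) -> None:
    summaries = read_table(out / "summaries.tsv")
    probes = read_table(out / "probes.tsv")
    channels = [ch for ch in config.session.montage if ch not in MASTOIDS]
    w = config.windows_s[0]
    summ = summaries[summaries["window_len_s"] == w]
    wide = summ.pivot_table(index=["participant", "window"], columns="channel",
                            values=list(config.properties), dropna=False)
    meta = probes.set_index(["participant", "probe"])
    adjacency = build_adjacency(channels, config.adjacency_threshold)

    stat_rows, cluster_rows = [], []
    n_comp = config.n_comparisons or len(config.contrasts) * len(config.properties)
    for prop in config.properties:
        feat = wide[prop][channels]
        idx = feat.index
        subjects = idx.get_level_values("participant").to_numpy()
        states = meta.loc[idx, "state"].to_numpy()
        X = np.nan_to_num(feat.to_numpy(), nan=0.0)
        for contrast in config.contrasts:
            try:
                clusters, smap = cluster_permutation(
                    X, subjects, states, contrast, adjacency, channels,
                    cluster_alpha=config.cluster_alpha, n_perm=config.n_perm,
                    mc_threshold=config.mc_threshold, n_comparisons=n_comp,
                    seed=np.random.default_rng(config.seed + 7))
            except ValueError as exc:
                warnings.warn(f"contrast {contrast} skipped: {exc}", stacklevel=2)
                continue
            df = smap.frame()
            df["property"] = prop
            df["contrast"] = smap.contrast
            stat_rows.append(df)
            for k, c in enumerate(clusters):
                cluster_rows.append({
                    "property": prop, "contrast": smap.contrast, "cluster": k,
                    "channels": ",".join(c.channels), "mass": c.mass,
                    "sign": c.sign, "p_cluster": c.p_cluster,
                    "significant": c.significant})
    write_table(out / "statmap.tsv", _concat(stat_rows))
    write_table(out / "clusters.tsv", pd.DataFrame(
        cluster_rows, columns=["property", "contrast", "cluster", "channels",
                               "mass", "sign", "p_cluster", "significant"]))


def stage_ddm(config: RunConfig, out: Path) -> None:
    if not config.ddm_enabled:
        write_table(out / "ddm_fits.tsv", pd.DataFrame())
        return
    trials = read_table(out / "trials.tsv")
    waves = read_table(out / "waves.tsv")
    probes = read_table(out / "probes.tsv")

    rows = []
    fit_rows = []
    w = config.windows_s[0]
    for subj in range(config.n_subjects):
        tr = trials[trials["participant"] == subj].reset_index(drop=True)
        pr = probes[probes["participant"] == subj]
        onset = tr["onset_s"].to_numpy()
        # response window closes at the next stimulus onset
        next_onset = np.append(onset[1:], tr["offset_s"].to_numpy()[-1:])
        tr = tr.assign(deadline_s=next_onset - onset,
                       trial_type=np.where(tr["is_nogo"], "nogo", "go"),
                       responded=tr["outcome"].isin(["correct_go", "false_alarm"]),
                       rt_rel_s=tr["rt_ms"] / 1000.0)
        # restrict to trials near probes, as in the pre-probe analyses
        near = np.zeros(len(tr), dtype=bool)
        for t_probe in pr["onset_s"]:
            near |= (onset >= t_probe - w) & (onset < t_probe)
        tr = tr[near & (tr["outcome"] != "excluded")].reset_index(drop=True)
        flags = flag_trial_wave_presence(
            tr, waves[waves["participant"] == subj], list(config.ddm_roi))
        for ch in config.ddm_roi:
            rows.append(tr.assign(electrode=ch,
                                  wave_flag=flags.loc[tr.index, ch].to_numpy()))
    pooled = _concat(rows)
    for (ch, flag), sub in pooled.groupby(["electrode", "wave_flag"], sort=True):
        fit_input = pd.DataFrame({
            "trial_type": sub["trial_type"],
            "responded": sub["responded"],
            "rt_s": sub["rt_rel_s"],
            "deadline_s": sub["deadline_s"].clip(lower=0.35)})
        if (fit_input["trial_type"] == "nogo").sum() < 10 or len(fit_input) < 100:
            continue
        fit = fit_ddm(fit_input, seed=config.seed)
        p = fit.params
        fit_rows.append({"electrode": ch, "wave_flag": int(flag),
                         "v_go": p.v_go, "v_nogo": p.v_nogo, "a": p.a,
                         "z": p.z, "t_nd": p.t_nd, "v_bias": p.v_bias,
                         "loglik": fit.loglik, "converged": fit.converged,
                         "n_trials": fit.n_trials})
    write_table(out / "ddm_fits.tsv", pd.DataFrame(
        fit_rows, columns=["electrode", "wave_flag", "v_go", "v_nogo", "a", "z",
                           "t_nd", "v_bias", "loglik", "converged", "n_trials"]))


_STAGES = [("simulate", stage_simulate), ("detect", stage_detect),
           ("behaviour", stage_behaviour), ("stats", stage_stats),
           ("ddm", stage_ddm)]


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 stages: list[str] | None = None) -> dict:
    """Run the pipeline (or a subset of stages) into ``out_dir``.

    Returns the manifest dict. Any stage failure raises :class:`StageError`
    with the stage name; outputs of completed stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    for name, fn in _STAGES:
        if stages is not None and name not in stages:
            continue
        try:
            fn(config, out)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError(name, exc) from exc
    manifest = {
        "package": "wakewave",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": config.n_subjects,
        "stages": [n for n, _ in _STAGES if stages is None or n in stages],
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
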