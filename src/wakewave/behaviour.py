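"""Trial scoring, pre-probe behavioural summaries, pupil preprocessing.

SART scoring rules: a response belongs to the latest stimulus whose onset
precedes it; the response window for a stimulus closes at the *next
stimulus onset*. A Go trial without a response in its window is a miss; a
NoGo trial with a response is a false alarm. Responses faster than 300 ms
mark the trial as excluded — such trials count in neither the correct nor
the error tallies.

Pre-probe summaries aggregate trials whose onset falls in the half-open
window [probe_onset - w, probe_onset), with w = 20 s by default (10 s and
a 4 x 5 s split are supported for sensitivity analyses).

Pupil preprocessing linearly interpolates across blink gaps (plus a margin),
averages over each stimulus-presentation window, and discretizes per-probe
means into five quantile bins within participant and task so pupil size is
comparable across participants.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synthgen import PupilTrace

__all__ = [
    "score_trials",
    "preprobe_summary",
    "preprocess_pupil",
    "trial_pupil_means",
    "discretize_pupil",
]

RT_EXCLUSION_MS = 300.0


def score_trials(stimuli: pd.DataFrame, responses: pd.DataFrame | np.ndarray
                 ) -> pd.DataFrame:
    """Score every stimulus as correct_go / miss / correct_nogo /
    false_alarm / excluded.

    Parameters
    ----------
    stimuli : DataFrame
        Columns onset_s, offset_s, is_nogo (plus any carried along, e.g.
        task/block), ordered by onset, non-overlapping.
    responses : DataFrame with column response_time_s, or 1-D array
        Button-press timestamps (seconds, session clock).
    """
    onsets = stimuli["onset_s"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("stimuli must be strictly ordered by onset")
    if np.any(stimuli["offset_s"].to_numpy()[:-1] > onsets[1:] + 1e-9):
        raise ValueError("stimuli overlap: offset exceeds the next onset")

    if isinstance(responses, pd.DataFrame):
        rtimes = responses["response_time_s"].to_numpy(dtype=float)
    else:
        rtimes = np.asarray(responses, dtype=float)
    rtimes = np.sort(rtimes)

    # window of stimulus i is [onset_i, onset_{i+1}); the last window is
    # closed by the last stimulus offset
    next_onset = np.append(onsets[1:], stimuli["offset_s"].to_numpy()[-1])
    idx = np.searchsorted(onsets, rtimes, side="right") - 1

    first_rt = np.full(len(stimuli), np.nan)
    for i, t in zip(idx, rtimes):
        if i < 0 or t >= next_onset[i]:
            continue
        if np.isnan(first_rt[i]):
            first_rt[i] = t

    trials = stimuli.copy().reset_index(drop=True)
    trials["response_time_s"] = first_rt
    trials["rt_ms"] = (first_rt - onsets) * 1000.0

    outcome = np.empty(len(trials), dtype=object)
    responded = ~np.isnan(first_rt)
    fast = responded & (trials["rt_ms"].to_numpy() < RT_EXCLUSION_MS)
    is_nogo = trials["is_nogo"].to_numpy(dtype=bool)
    outcome[fast] = "excluded"
    outcome[responded & ~fast & ~is_nogo] = "correct_go"
    outcome[responded & ~fast & is_nogo] = "false_alarm"
    outcome[~responded & ~is_nogo] = "miss"
    outcome[~responded & is_nogo] = "correct_nogo"
    trials["outcome"] = outcome
    return trials


def _window_rates(win: pd.DataFrame) -> dict:
    """Miss/FA rates and mean RT within one set of trials; excluded trials
    enter no denominator."""
    go = win[(~win["is_nogo"]) & (win["outcome"] != "excluded")]
    nogo = win[(win["is_nogo"]) & (win["outcome"] != "excluded")]
    n_go, n_nogo = len(go), len(nogo)
    correct_go = go[go["outcome"] == "correct_go"]
    return {
        "n_go": n_go,
        "n_nogo": n_nogo,
        "miss_rate": (go["outcome"] == "miss").sum() / n_go if n_go else np.nan,
        "fa_rate": (nogo["outcome"] == "false_alarm").sum() / n_nogo if n_nogo else np.nan,
        "mean_rt_ms": correct_go["rt_ms"].mean() if len(correct_go) else np.nan,
    }


def preprobe_summary(trials: pd.DataFrame, probes: pd.DataFrame,
                     window_s: float = 20.0,
                     n_subwindows: int = 1) -> pd.DataFrame:
    """Behaviour in the window before each probe.

    With ``n_subwindows > 1`` the window is split into equal sub-windows
    ([-20, -15), ... [-5, 0) s for 4 x 5 s); trials partition exactly
    across sub-windows.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    rows = []
    sub_w = window_s / n_subwindows
    for probe in probes.itertuples(index=False):
        t_probe = probe.onset_s
        for j in range(n_subwindows):
            t0 = t_probe - window_s + j * sub_w
            t1 = t0 + sub_w
            win = trials[(trials["onset_s"] >= t0) & (trials["onset_s"] < t1)]
            row = {"probe": probe.probe, "window_s": sub_w,
                   "sub_window": j, "t0_s": t0, "t1_s": t1}
            for f in ("state", "vigilance", "task", "block"):
                if hasattr(probe, f):
                    row[f] = getattr(probe, f)
            row.update(_window_rates(win))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pupil
# ---------------------------------------------------------------------------

def preprocess_pupil(trace: PupilTrace,
                     blink_intervals: list[tuple[float, float]] | None = None,
                     margin_s: float = 0.1) -> PupilTrace:
    """Replace blink segments (± margin) by linear interpolation between the
    flanking valid samples.

    ``blink_intervals`` defaults to the intervals recorded on the trace;
    missing (NaN) samples outside listed intervals are interpolated too.
    """
    values = trace.values.astype(float).copy()
    n = values.size
    if blink_intervals is None:
        blink_intervals = trace.blink_intervals
    bad = np.isnan(values)
    for t0, t1 in blink_intervals:
        i0 = max(int((t0 - margin_s) * trace.rate_hz), 0)
        i1 = min(int(np.ceil((t1 + margin_s) * trace.rate_hz)), n)
        bad[i0:i1] = True
    if bad.all():
        raise ValueError("pupil trace entirely missing")
    if bad.any():
        t = np.arange(n)
        values[bad] = np.interp(t[bad], t[~bad], values[~bad])
    return PupilTrace(rate_hz=trace.rate_hz, values=values,
                      blink_intervals=list(blink_intervals))


def trial_pupil_means(trace: PupilTrace, trials: pd.DataFrame,
                      probes: pd.DataFrame | None = None,
                      window_s: float = 20.0
                      ) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Mean pupil size per trial over [stimulus onset, offset); optionally
    a per-probe mean over the trials within ``window_s`` of each probe."""
    fs = trace.rate_hz
    means = np.full(len(trials), np.nan)
    for k, tr in enumerate(trials.itertuples(index=False)):
        i0, i1 = int(tr.onset_s * fs), int(tr.offset_s * fs)
        seg = trace.values[i0:i1]
        if seg.size:
            means[k] = np.nanmean(seg)
    if probes is None:
        return means, None
    onset = trials["onset_s"].to_numpy()
    rows = []
    for probe in probes.itertuples(index=False):
        sel = (onset >= probe.onset_s - window_s) & (onset < probe.onset_s)
        rows.append({"probe": probe.probe,
                     "pupil_mean": np.nanmean(means[sel]) if sel.any() else np.nan})
    return means, pd.DataFrame(rows)


def discretize_pupil(per_probe_means: pd.DataFrame, n_bins: int = 5,
                     group_cols: list[str] | None = None,
                     value_col: str = "pupil_mean") -> pd.Series:
    """Quantile-discretize per-probe pupil means into bins 1..n_bins.

    Binning is rank-based within each group (participant x task when those
    columns are present): with distinct values, bin counts differ by at
    most one; tied values share the lower bin. Groups with fewer than
    ``n_bins`` non-null values get null bins with a warning.
    """
    if group_cols is None:
        group_cols = [c for c in ("participant", "task")
                      if c in per_probe_means.columns]
    out = pd.Series(np.nan, index=per_probe_means.index, name="pupil_bin")
    groups = (per_probe_means.groupby(group_cols, sort=False)
              if group_cols else [(None, per_probe_means)])
    for _, g in groups:
        vals = g[value_col]
        ok = vals.notna()
        if ok.sum() < n_bins:
            warnings.warn("too few non-null pupil values for binning; "
                          "bins set to null", stacklevel=2)
            continue
        v = vals[ok].to_numpy()
        order = np.argsort(v, kind="stable")
        m = v.size
        pos_bin = np.floor(np.arange(m) * n_bins / m).astype(int) + 1
        bins = np.empty(m, dtype=float)
        bins[order] = pos_bin
        # ties share the bin of their lowest-ranked member
        for val in np.unique(v):
            tie = v == val
            if tie.sum() > 1:
                bins[tie] = bins[tie].min()
        out.loc[vals.index[ok]] = bins
    return out
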