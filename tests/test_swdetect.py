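"""Slow-wave detector: filter contracts, wave delimitation, screening,
selection, summaries — each checked against analytic signals or an
independent brute-force sample-scan oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from wakewave.io import EEGRecording
from wakewave.montage import DEFAULT_MONTAGE
from wakewave.swdetect import (
    CandidateWave,
    DetectionParams,
    design_detection_filter,
    detect_slow_waves,
    event_locked_average,
    extract_candidate_waves,
    filter_waves,
    flag_trial_wave_presence,
    preprocess_for_detection,
    select_top_amplitude,
    summarize_waves,
)
from wakewave.synthgen import NoiseSpec, inject_slow_waves, wave_template

FS = 128.0


# ---------------------------------------------------------------------------
# band-pass filter
# ---------------------------------------------------------------------------

class TestDetectionFilter:
    def test_stopband_attenuation_at_least_25_db(self):
        filt = design_detection_filter(FS)
        att = filt.attenuation_db(np.array([0.1, 15.0]))
        assert att.min() >= 25.0

    def test_passband_loss_below_3_db_on_100_point_grid(self):
        filt = design_detection_filter(FS)
        grid = np.linspace(1.0, 10.0, 100)
        assert filt.attenuation_db(grid).max() < 3.0

    def test_filter_stable_and_impulse_response_decays(self):
        filt = design_detection_filter(FS)
        assert filt.is_stable()
        impulse = np.zeros(4096)
        impulse[0] = 1.0
        h = sps.sosfilt(filt.sos, impulse)
        assert np.max(np.abs(h[-256:])) < 1e-6 * np.max(np.abs(h))

    def test_long_signal_amplitude_ratio_matches_magnitude_response(self):
        # independent oracle: feed a long sinusoid through a single forward
        # pass and measure the steady-state amplitude ratio
        filt = design_detection_filter(FS)
        for f0 in (0.1, 2.0, 15.0):
            t = np.arange(int(600 * FS)) / FS
            x = np.sin(2 * np.pi * f0 * t)
            y = sps.sosfilt(filt.sos, x)
            measured = np.abs(y[len(y) // 2:]).max()
            expected = filt.magnitude(np.array([f0]))[0]
            assert measured == pytest.approx(expected, rel=0.02)

    def test_unsatisfiable_at_low_rate_raises(self):
        with pytest.raises(ValueError):
            design_detection_filter(20.0)


class TestPreprocess:
    def _recording(self, data, fs=500.0):
        return EEGRecording(data=data, sfreq=fs,
                            ch_names=list(DEFAULT_MONTAGE[: data.shape[0]]))

    def test_output_rate_is_128(self):
        rec = self._recording(np.random.default_rng(0).normal(size=(63, 5000)))
        out = preprocess_for_detection(rec)
        assert out.sfreq == 128.0

    def test_channels_equal_to_mastoid_mean_become_zero(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=5000)
        data = np.tile(base, (63, 1))
        rec = self._recording(data)
        out = preprocess_for_detection(rec)
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_stopband_sinusoid_suppressed(self):
        t = np.arange(int(120 * 500)) / 500.0
        data = np.zeros((63, t.size))
        data[0] = np.sin(2 * np.pi * 0.1 * t)   # stopband edge, unit amplitude
        rec = self._recording(data)
        out = preprocess_for_detection(rec)
        mid = out.data[0][out.n_samples // 4 : -out.n_samples // 4]
        assert np.abs(mid).max() <= 10 ** (-25 / 20)

    def test_missing_mastoids_named_in_error(self):
        rec = EEGRecording(data=np.zeros((2, 1000)), sfreq=500.0,
                           ch_names=["Fz", "Cz"])
        with pytest.raises(ValueError, match="TP9"):
            preprocess_for_detection(rec)


# ---------------------------------------------------------------------------
# candidate extraction vs analytic signals and brute-force oracle
# ---------------------------------------------------------------------------

def scan_waves_oracle(x, fs):
    """Independent brute-force delimitation by per-sample sign scanning."""
    waves = []
    n = len(x)
    i = 0
    while i < n:
        if x[i] < 0 and i > 0 and x[i - 1] >= 0:
            i0 = i
            while i < n and x[i] < 0:
                i += 1
            if i >= n:
                break
            j0 = i
            while i < n and x[i] >= 0:
                i += 1
            if i >= n:
                break
            j1 = i - 1  # last non-negative sample
            neg_idx = min(range(i0, j0), key=lambda k: (x[k], k))
            pos_idx = min(range(j0, j1 + 1), key=lambda k: (-x[k], k))
            start_i, end_i = i0 - 1, j1
            if start_i < neg_idx < pos_idx < end_i:
                waves.append((start_i / fs, neg_idx / fs, pos_idx / fs, end_i / fs,
                              x[neg_idx], x[pos_idx]))
        else:
            i += 1
    return waves


class TestExtraction:
    def test_flat_signal_yields_nothing(self):
        assert extract_candidate_waves(np.zeros(1000), FS) == []

    def test_pure_sinusoid_amplitude_and_spacing(self):
        t = np.arange(int(10 * FS)) / FS
        x = 40.0 * np.sin(2 * np.pi * 2.0 * t)
        waves = extract_candidate_waves(x, FS, channel="Cz")
        assert len(waves) >= 15
        p2p = np.array([w.p2p_amp for w in waves])
        assert np.all(np.abs(p2p - 80.0) <= 1.0)
        starts = np.array([w.start_s for w in waves])
        assert np.allclose(np.diff(starts), 0.5, atol=1 / FS)

    def test_negative_sine_first_wave_starts_at_zero(self):
        t = np.arange(int(4 * FS)) / FS
        x = -np.sin(2 * np.pi * 2.0 * t)
        waves = extract_candidate_waves(x, FS)
        assert waves[0].start_s == 0.0
        assert waves[0].neg_peak_s == pytest.approx(0.125, abs=1 / FS)

    def test_invariants_and_slopes(self):
        rng = np.random.default_rng(5)
        x = sps.sosfiltfilt(design := design_detection_filter(FS).sos,
                            rng.normal(size=int(60 * FS)) * 20)
        waves = extract_candidate_waves(x, FS)
        assert len(waves) > 20
        for w in waves:
            assert w.start_s < w.neg_peak_s < w.pos_peak_s < w.end_s
            assert w.neg_peak_amp < 0
            assert w.p2p_amp == pytest.approx(w.pos_peak_amp - w.neg_peak_amp)
            assert w.down_slope == pytest.approx(
                abs(w.neg_peak_amp) / (w.neg_peak_s - w.start_s))
            assert w.up_slope == pytest.approx(
                (w.pos_peak_amp - w.neg_peak_amp) / (w.pos_peak_s - w.neg_peak_s))
        # ordered and non-overlapping
        for a, b in zip(waves, waves[1:]):
            assert a.start_s < b.start_s
            assert a.end_s <= b.start_s + 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_agreement_with_sample_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        filt = design_detection_filter(FS)
        x = filt.apply(rng.normal(size=int(30 * FS)) * 15)
        waves = extract_candidate_waves(x, FS)
        oracle = scan_waves_oracle(x, FS)
        assert len(waves) == len(oracle)
        for w, (s, npk, ppk, e, namp, pamp) in zip(waves, oracle):
            assert w.start_s == s and w.end_s == e
            assert w.neg_peak_s == npk and w.pos_peak_s == ppk
            assert w.neg_peak_amp == namp and w.pos_peak_amp == pamp


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def _mk_wave(start, neg, pos, end, namp, pamp, channel="Cz"):
    return CandidateWave(channel=channel, start_s=start, neg_peak_s=neg,
                         pos_peak_s=pos, end_s=end, neg_peak_amp=namp,
                         pos_peak_amp=pamp, p2p_amp=pamp - namp,
                         down_slope=abs(namp) / (neg - start),
                         up_slope=(pamp - namp) / (pos - neg))


class TestScreening:
    def test_positive_peak_above_75_excluded(self):
        x = np.zeros(int(10 * FS))
        good = _mk_wave(1.0, 1.2, 1.4, 1.6, -40, 30)
        blinky = _mk_wave(3.0, 3.2, 3.4, 3.6, -40, 80)
        kept = filter_waves([good, blinky], x, FS)
        assert kept == [good]

    def test_short_wave_excluded(self):
        x = np.zeros(int(10 * FS))
        short = _mk_wave(1.0, 1.03, 1.06, 1.1, -40, 20)   # 100 ms
        ok = _mk_wave(3.0, 3.1, 3.2, 3.3, -40, 20)        # 300 ms
        kept = filter_waves([short, ok], x, FS)
        assert kept == [ok]

    def test_artifact_proximity_rule(self):
        x = np.zeros(int(20 * FS))
        x[int(5.0 * FS)] = 160.0                          # large-amplitude event
        near = _mk_wave(4.2, 4.3, 4.4, 4.5, -40, 20)      # ends 0.5 s before it
        far = _mk_wave(2.9, 3.0, 3.2, 3.5, -40, 20)       # ends 1.5 s before it
        kept = filter_waves([near, far], x, FS)
        assert kept == [far]

    def test_output_is_subset_of_input(self):
        rng = np.random.default_rng(7)
        filt = design_detection_filter(FS)
        x = filt.apply(rng.normal(size=int(60 * FS)) * 30)
        cands = extract_candidate_waves(x, FS)
        kept = filter_waves(cands, x, FS)
        assert set(id(w) for w in kept) <= set(id(w) for w in cands)


class TestSelection:
    def _random_waves(self, n, channel="Cz", seed=0):
        rng = np.random.default_rng(seed)
        out = []
        t = 0.0
        for _ in range(n):
            t += rng.uniform(0.5, 1.0)
            namp = -rng.uniform(10, 80)
            pamp = rng.uniform(2, 40)
            out.append(_mk_wave(t, t + 0.15, t + 0.3, t + 0.45, namp, pamp,
                                channel=channel))
        return out

    def test_top_10_percent_of_1000_is_100(self):
        waves = self._random_waves(1000)
        kept, thr = select_top_amplitude(waves, 0.10)
        assert len(kept) == 100

    def test_fraction_one_keeps_all(self):
        waves = self._random_waves(37)
        kept, _ = select_top_amplitude(waves, 1.0)
        assert len(kept) == 37

    def test_retained_amplitudes_dominate_discarded_per_channel(self):
        waves = self._random_waves(200, "Cz", 1) + self._random_waves(150, "Fz", 2)
        kept, thr = select_top_amplitude(waves, 0.10)
        kept_ids = {id(w) for w in kept}
        for ch in ("Cz", "Fz"):
            ch_kept = [w.p2p_amp for w in kept if w.channel == ch]
            ch_drop = [w.p2p_amp for w in waves
                       if w.channel == ch and id(w) not in kept_ids]
            assert min(ch_kept) >= max(ch_drop)
            assert thr[ch] == pytest.approx(min(ch_kept))

    def test_empty_input_gives_empty_output(self):
        kept, thr = select_top_amplitude([], 0.10)
        assert kept == [] and thr == {}

    def test_ceil_keeps_at_least_one(self):
        waves = self._random_waves(3)
        kept, _ = select_top_amplitude(waves, 0.10)
        assert len(kept) == 1


# ---------------------------------------------------------------------------
# summaries, flags, ERPs
# ---------------------------------------------------------------------------

class TestSummaries:
    def _waves_frame(self, starts, channel="Cz"):
        return pd.DataFrame({
            "channel": channel, "start_s": starts,
            "neg_peak_s": np.asarray(starts) + 0.1,
            "pos_peak_s": np.asarray(starts) + 0.2,
            "end_s": np.asarray(starts) + 0.3,
            "neg_peak_amp": -40.0, "pos_peak_amp": 20.0, "p2p_amp": 60.0,
            "down_slope": 400.0, "up_slope": 600.0})

    def test_three_waves_in_20s_is_9_per_minute(self):
        waves = self._waves_frame([1.0, 5.0, 15.0])
        out = summarize_waves(waves, [("w", 0.0, 20.0)], ["Cz"])
        assert out["density"].iloc[0] == pytest.approx(9.0)

    def test_empty_window_zero_density_null_means(self):
        waves = self._waves_frame([100.0])
        out = summarize_waves(waves, [("w", 0.0, 20.0)], ["Cz"])
        assert out["density"].iloc[0] == 0.0
        assert np.isnan(out["mean_p2p_amp"].iloc[0])

    def test_partition_into_5s_subwindows_conserves_count(self):
        rng = np.random.default_rng(3)
        waves = self._waves_frame(sorted(rng.uniform(0, 20, size=17)))
        full = summarize_waves(waves, [("full", 0.0, 20.0)], ["Cz"])
        quarters = summarize_waves(
            waves, [(k, 5.0 * k, 5.0 * (k + 1)) for k in range(4)], ["Cz"])
        assert quarters["n_waves"].sum() == full["n_waves"].iloc[0] == 17

    def test_zero_length_window_raises(self):
        with pytest.raises(ValueError):
            summarize_waves(self._waves_frame([1.0]), [("w", 5.0, 5.0)], ["Cz"])


class TestTrialFlags:
    def _trials(self):
        return pd.DataFrame({"onset_s": [0.0, 1.0, 2.0],
                             "offset_s": [0.9, 1.9, 2.9]})

    def _waves(self, starts, ch="Cz"):
        return pd.DataFrame({"channel": ch, "start_s": starts})

    def test_wave_after_offset_not_flagged(self):
        flags = flag_trial_wave_presence(self._trials(), self._waves([0.91]), ["Cz"])
        assert flags["Cz"].tolist() == [0, 0, 0]

    def test_two_waves_one_stimulus_still_binary(self):
        flags = flag_trial_wave_presence(self._trials(), self._waves([1.2, 1.5]), ["Cz"])
        assert flags["Cz"].tolist() == [0, 1, 0]

    def test_wave_exactly_at_onset_counts(self):
        flags = flag_trial_wave_presence(self._trials(), self._waves([1.0]), ["Cz"])
        assert flags["Cz"].tolist() == [0, 1, 0]


class TestEventLockedAverage:
    def _rec(self, data, fs=128.0):
        names = ["Fz", "Cz", "TP9", "TP10"][: data.shape[0]]
        return EEGRecording(data=data, sfreq=fs, ch_names=names)

    def test_single_event_equals_epoch(self):
        rng = np.random.default_rng(0)
        rec = self._rec(rng.normal(size=(2, 2000)))
        times, avg = event_locked_average(rec, [5.0], window=(-0.5, 0.5), band=None)
        i0 = int(4.5 * 128)
        assert np.allclose(avg, rec.data[:, i0:i0 + 128])

    def test_identical_epochs_average_to_one(self):
        period = 128
        one = np.random.default_rng(1).normal(size=(1, period))
        data = np.tile(one, (1, 20))
        rec = EEGRecording(data=data, sfreq=128.0, ch_names=["Cz"])
        events = [4.0, 6.0, 10.0]
        times, avg = event_locked_average(rec, events, window=(0.0, 1.0), band=None)
        assert np.allclose(avg, data[:, :period])

    def test_white_noise_average_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(2)
        rec = self._rec(rng.normal(size=(1, int(128 * 700))))
        events = rng.uniform(5, 690, size=500)
        _, avg = event_locked_average(rec, events, window=(-0.2, 0.2), band=None)
        ratio = np.std(avg) / 1.0
        assert ratio == pytest.approx(1 / np.sqrt(500), rel=0.35)

    def test_no_events_raises(self):
        rec = self._rec(np.zeros((1, 1000)))
        with pytest.raises(ValueError):
            event_locked_average(rec, [])


# ---------------------------------------------------------------------------
# detector validity on injected ground truth
# ---------------------------------------------------------------------------

class TestDetectorOnInjectedWaves:
    def _ground_truth(self, n=50, ch="Fz", seed=0, t_max=120.0):
        rng = np.random.default_rng(seed)
        onsets = np.sort(rng.uniform(5.0, t_max - 5.0, size=n))
        # enforce gaps so injected templates never overlap
        onsets = np.linspace(5.0, t_max - 5.0, n) + rng.uniform(-0.3, 0.3, n)
        return pd.DataFrame({"channel": ch, "onset_s": onsets,
                             "duration_s": 0.6, "p2p_amp_uv": 60.0})

    def _blank(self, duration=120.0, chs=("Fz", "Oz", "TP9", "TP10")):
        n = int(duration * 500)
        return EEGRecording(data=np.zeros((len(chs), n)), sfreq=500.0,
                            ch_names=list(chs))

    def test_injection_targets_only_listed_channels(self):
        gt = self._ground_truth()
        eeg = inject_slow_waves(self._blank(), gt, NoiseSpec(rms_uv=0.0), 0)
        assert np.abs(eeg.get_channel("Fz")).max() > 10
        assert np.allclose(eeg.get_channel("Oz"), 0.0)

    def test_template_survives_detection_band_within_20pc(self):
        filt = design_detection_filter(128.0)
        tpl = wave_template(0.6, 60.0, 128.0)
        padded = np.concatenate([np.zeros(640), tpl, np.zeros(640)])
        filtered = filt.apply(padded)
        p2p = filtered.max() - filtered.min()
        assert abs(p2p - 60.0) <= 0.2 * 60.0

    def test_noiseless_recall_at_least_95pc(self):
        gt = self._ground_truth(n=50)
        eeg = inject_slow_waves(self._blank(), gt, NoiseSpec(rms_uv=0.0), 0)
        waves, _ = detect_slow_waves(eeg, DetectionParams(top_fraction=1.0))
        det = waves[waves["channel"] == "Fz"]["start_s"].to_numpy()
        hits = sum(np.any(np.abs(det - o) <= 0.25) for o in gt["onset_s"])
        assert hits / len(gt) >= 0.95

    def test_selection_threshold_scales_with_noise_rms(self):
        thresholds = []
        for rms in (2.5, 5.0, 10.0):
            eeg = inject_slow_waves(self._blank(duration=120.0),
                                    pd.DataFrame(columns=["channel", "onset_s",
                                                          "duration_s", "p2p_amp_uv"]),
                                    NoiseSpec(rms_uv=rms), 42)
            _, thr = detect_slow_waves(eeg)
            thresholds.append(thr["Fz"])
        assert thresholds[0] < thresholds[1] < thresholds[2]
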