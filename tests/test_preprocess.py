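import numpy as np
import pytest

import wristbci as w
from wristbci.ica import ICADecomposition
from wristbci.io import ContinuousRecording, EventStream
from wristbci.preprocess import (ArtifactReport, TrialSet, baseline_correct,
                                 broadband_filter, build_datasets,
                                 detect_noisy_channels, flag_artifact_ics,
                                 remove_ics_and_reconstruct, segment_trials)

FS = 500.0


def _events(getready_times_ms, labels=None, stop_offset=8000.0):
    records = []
    for i, t in enumerate(getready_times_ms):
        lab = (labels or ["RH-WE"] * len(getready_times_ms))[i]
        records += [(t, "GetReady", lab), (t + 2000, "StartMoving", lab),
                    (t + 5000, "HoldMovement", lab),
                    (t + stop_offset, "Stop", lab)]
    return EventStream.from_records(records)


class TestDetectNoisyChannels:
    def test_all_zero_recording_is_clean(self, reduced_montage):
        rec = ContinuousRecording(np.zeros((32, 1000)), FS, reduced_montage,
                                  _events([]))
        assert detect_noisy_channels(rec) == []

    def test_constant_150uv_channel_flagged(self, reduced_montage):
        sig = np.zeros((32, 1000))
        sig[5] = 150.0
        rec = ContinuousRecording(sig, FS, reduced_montage, _events([]))
        assert detect_noisy_channels(rec) == [reduced_montage.labels[5]]

    def test_99uv_peak_sinusoid_passes(self, reduced_montage):
        t = np.arange(1000) / FS
        sig = np.tile(99.0 * np.sin(2 * np.pi * 10 * t), (32, 1))
        rec = ContinuousRecording(sig, FS, reduced_montage, _events([]))
        assert detect_noisy_channels(rec) == []


class TestSegmentTrials:
    def test_window_placement_and_length(self, reduced_montage, rng):
        """GetReady at 10 s, Stop at 18 s: trial covers 7–19 s, 6000 samples."""
        sig = rng.normal(0, 5, (32, 11000))
        rec = ContinuousRecording(sig, FS, reduced_montage, _events([10000.0]))
        ts = segment_trials(rec)
        assert ts.n_trials == 1
        assert ts.n_samples == 6000
        assert ts.duration_ms == pytest.approx(12000.0)
        assert np.array_equal(ts.data[0], sig[:, 3500:9500])
        assert ts.times_ms[0] == pytest.approx(-3000.0)

    def test_no_markers_gives_empty_set(self, reduced_montage):
        rec = ContinuousRecording(np.zeros((32, 1000)), FS, reduced_montage,
                                  _events([]))
        ts = segment_trials(rec)
        assert ts.n_trials == 0

    def test_one_trial_per_getready(self, reduced_montage, rng):
        n = 12
        times = [4000.0 + 13000.0 * k for k in range(n)]
        sig = rng.normal(0, 5, (32, int((times[-1] + 10000) * FS / 1000)))
        rec = ContinuousRecording(sig, FS, reduced_montage, _events(times))
        assert segment_trials(rec).n_trials == n

    def test_getready_without_stop_skipped(self, reduced_montage):
        ev = EventStream.from_records(
            [(4000.0, "GetReady", "RH-WE")]
            + list(_events([20000.0]).frame.itertuples(index=False)))
        rec = ContinuousRecording(np.zeros((32, 16000)), FS, reduced_montage,
                                  ev)
        with pytest.warns(UserWarning, match="no matching Stop"):
            ts = segment_trials(rec)
        assert ts.n_trials == 1

    def test_out_of_bounds_trial_dropped(self, reduced_montage):
        rec = ContinuousRecording(np.zeros((32, 5000)), FS, reduced_montage,
                                  _events([4000.0]))  # needs 6500 samples
        with pytest.warns(UserWarning, match="bounds"):
            ts = segment_trials(rec)
        assert ts.n_trials == 0


def _trialset(data, labels=None, montage=None):
    labels = labels if labels is not None else ["RH-WE"] * data.shape[0]
    return TrialSet(data, np.asarray(labels, dtype=object), FS, montage)


class TestBaselineCorrect:
    def test_constant_trial_becomes_zero(self, reduced_montage):
        ts = _trialset(np.full((2, 32, 6000), 7.5), montage=reduced_montage)
        out = baseline_correct(ts)
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_baseline_mean_zero_and_postcue_shift(self, reduced_montage):
        t = np.arange(6000) / FS * 1000.0 - 3000.0
        sig = np.where(t < 0, 5.0, 5.0 + np.sin(2 * np.pi * 0.01 * t))
        ts = _trialset(np.tile(sig, (1, 32, 1)).reshape(1, 32, 6000),
                       montage=reduced_montage)
        out = baseline_correct(ts)
        i0, i1 = ts.sample_of(-3000.0), ts.sample_of(0.0)
        assert np.allclose(out.data[:, :, i0:i1].mean(axis=2), 0.0, atol=1e-9)
        post = slice(ts.sample_of(0.0), None)
        assert np.allclose(out.data[0, :, post].mean() + 5.0,
                           ts.data[0, :, post].mean(), atol=1e-9)

    def test_idempotent_on_zero_mean_baseline(self, reduced_montage, rng):
        data = rng.normal(0, 3, (2, 32, 6000))
        once = baseline_correct(_trialset(data, montage=reduced_montage))
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data, atol=1e-9)


class TestBroadbandFilter:
    def test_removes_dc_offset(self, reduced_montage):
        ts = _trialset(np.full((1, 32, 6000), 10.0), montage=reduced_montage)
        out = broadband_filter(ts)
        assert np.abs(out.data.mean()) < 0.1

    def test_notch_attenuates_50hz_by_20db(self, reduced_montage):
        t = np.arange(6000) / FS
        sine = np.sin(2 * np.pi * 50.0 * t)
        ts = _trialset(np.tile(sine, (1, 32, 1)).reshape(1, 32, 6000),
                       montage=reduced_montage)
        out = broadband_filter(ts)
        spec_in = np.abs(np.fft.rfft(ts.data[0, 0]))
        spec_out = np.abs(np.fft.rfft(out.data[0, 0]))
        k = int(round(50.0 * 6000 / FS))
        atten_db = 20 * np.log10(spec_in[k] / max(spec_out[k], 1e-12))
        assert atten_db >= 20.0

    def test_zero_signal_stays_zero(self, reduced_montage):
        ts = _trialset(np.zeros((1, 32, 6000)), montage=reduced_montage)
        assert np.allclose(broadband_filter(ts).data, 0.0)

    def test_idempotent_within_passband(self, reduced_montage, rng):
        ts = _trialset(rng.normal(0, 5, (1, 32, 6000)),
                       montage=reduced_montage)
        once = broadband_filter(ts)
        twice = broadband_filter(once)
        # in-band (2-40 Hz) power changes by < 1% on re-application
        f = np.fft.rfftfreq(6000, 1 / FS)
        band = (f > 2) & (f < 40)
        p1 = (np.abs(np.fft.rfft(once.data, axis=-1)) ** 2)[..., band].sum()
        p2 = (np.abs(np.fft.rfft(twice.data, axis=-1)) ** 2)[..., band].sum()
        assert abs(p2 - p1) / p1 < 0.01

    def test_low_sampling_rate_rejected(self, reduced_montage):
        ts = TrialSet(np.zeros((1, 32, 600)), np.array(["RH-WE"], object),
                      150.0, reduced_montage)
        with pytest.raises(ValueError, match="sampling"):
            broadband_filter(ts)

    def test_label_agnostic(self, reduced_montage, rng):
        data = rng.normal(0, 5, (4, 32, 6000))
        a = _trialset(data, ["RH-WE"] * 4, reduced_montage)
        b = _trialset(data, ["LH-WF"] * 4, reduced_montage)
        assert np.array_equal(broadband_filter(a).data,
                              broadband_filter(b).data)


def _planted_decomposition(montage, rng, fs=FS, n_samples=6000, n_trials=4):
    """Hand-built decomposition: blink IC, EMG IC, neutral 10 Hz IC."""
    pos = montage.positions
    n_chan = len(montage)
    t = np.arange(n_samples) / fs

    blink_topo = np.exp(-((pos[:, 1] - 1.0) ** 2) / 0.05)      # frontal
    emg_topo = np.exp(-np.sum((pos - montage.position("T7")) ** 2,
                              axis=1) / 0.02)                  # lateral focus
    neutral_topo = np.exp(-np.sum((pos - montage.position("Cz")) ** 2,
                                  axis=1) / 0.3)               # central

    acts = np.zeros((n_trials, 3, n_samples))
    for tr in range(n_trials):
        blink = np.zeros(n_samples)
        for onset in (500, 2500, 4500):                        # periodic peaks
            blink[onset:onset + 150] += 80 * np.sin(2 * np.pi * t[:150] / 0.3)
        acts[tr, 0] = blink
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, (35, 95), btype="bandpass", fs=fs, output="sos")
        acts[tr, 1] = 20 * sosfiltfilt(sos, rng.standard_normal(n_samples))
        acts[tr, 2] = 10 * np.sin(2 * np.pi * 10.0 * t)
    mixing = np.column_stack([blink_topo, emg_topo, neutral_topo])
    unmixing = np.linalg.pinv(mixing)
    return ICADecomposition(unmixing, mixing, acts, np.zeros(n_chan), fs,
                            seed=0, n_iter=0)


class TestArtifactFlagging:
    def test_planted_sources_flagged_correctly(self, reduced_montage, rng):
        decomp = _planted_decomposition(reduced_montage, rng)
        report = flag_artifact_ics(decomp, reduced_montage)
        assert report.flags[0] == "EOG"
        assert report.flags[1] == "EMG"
        assert report.flags[2] == "none"
        assert np.isfinite(report.scores.to_numpy()).all()

    def test_reconstruction_drops_blink_power(self, reduced_montage, rng):
        decomp = _planted_decomposition(reduced_montage, rng)
        report = flag_artifact_ics(decomp, reduced_montage)
        ts = TrialSet(decomp.reconstruct(), np.array(["RH-WE"] * 4, object),
                      FS, reduced_montage)
        clean = remove_ics_and_reconstruct(ts, decomp, report)
        front = reduced_montage.index("Fpz")
        f = np.fft.rfftfreq(ts.n_samples, 1 / FS)
        low = (f >= 1) & (f <= 5)

        def low_power(x):
            return (np.abs(np.fft.rfft(x, axis=-1)) ** 2)[..., low].sum()

        assert low_power(clean.data[:, front]) \
            < 0.2 * low_power(ts.data[:, front])

    def test_no_flags_is_identity(self, reduced_montage, rng):
        decomp = _planted_decomposition(reduced_montage, rng)
        report = ArtifactReport(np.array(["none"] * 3, object),
                                flag_artifact_ics(decomp,
                                                  reduced_montage).scores, {})
        ts = TrialSet(decomp.reconstruct(), np.array(["RH-WE"] * 4, object),
                      FS, reduced_montage)
        out = remove_ics_and_reconstruct(ts, decomp, report)
        assert np.allclose(out.data, ts.data, atol=1e-6)

    def test_all_flagged_raises(self, reduced_montage, rng):
        decomp = _planted_decomposition(reduced_montage, rng)
        report = ArtifactReport(np.array(["EOG", "EMG", "EOG"], object),
                                flag_artifact_ics(decomp,
                                                  reduced_montage).scores, {})
        ts = TrialSet(decomp.reconstruct(), np.array(["RH-WE"] * 4, object),
                      FS, reduced_montage)
        with pytest.raises(ValueError, match="all components"):
            remove_ics_and_reconstruct(ts, decomp, report)

    def test_keep_single_ic_gives_rank_one(self, reduced_montage, rng):
        decomp = _planted_decomposition(reduced_montage, rng)
        report = ArtifactReport(np.array(["EOG", "EMG", "none"], object),
                                flag_artifact_ics(decomp,
                                                  reduced_montage).scores, {})
        ts = TrialSet(decomp.reconstruct(), np.array(["RH-WE"] * 4, object),
                      FS, reduced_montage)
        out = remove_ics_and_reconstruct(ts, decomp, report)
        s = np.linalg.svd(out.data[0], compute_uv=False)
        assert s[1] < 1e-8 * s[0]


class TestBuildDatasets:
    def _labelled(self, reduced_montage, counts):
        labels = sum(([lab] * n for lab, n in counts.items()), [])
        data = np.zeros((len(labels), 32, 100))
        return _trialset(data, labels, reduced_montage)

    def test_bundle_counts(self, reduced_montage):
        ts = self._labelled(reduced_montage, {"RH-WE": 5, "RH-WF": 5,
                                              "LH-WE": 5, "LH-WF": 5})
        bundle = build_datasets(ts)
        assert bundle.rli.n_trials == 20
        assert bundle.efi_rh.n_trials == 10
        assert bundle.efi_lh.n_trials == 10
        assert set(bundle.rli.labels) == {"RH", "LH"}
        assert set(bundle.efi_rh.labels) == {"WE", "WF"}

    def test_only_rh_gives_empty_efi_lh(self, reduced_montage):
        ts = self._labelled(reduced_montage, {"RH-WE": 3, "RH-WF": 3})
        with pytest.warns(UserWarning, match="EFI-LH"):
            bundle = build_datasets(ts)
        assert bundle.efi_lh.n_trials == 0
        assert bundle.rli.n_trials == 6

    def test_trials_per_class_cap(self, reduced_montage):
        ts = self._labelled(reduced_montage, {"RH-WE": 5, "RH-WF": 5,
                                              "LH-WE": 5, "LH-WF": 5})
        bundle = build_datasets(ts, trials_per_class=3)
        assert bundle.rli.n_trials == 12
        assert bundle.efi_rh.n_trials == 6
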