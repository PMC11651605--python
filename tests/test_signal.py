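"""Epidural signal synthesis, wave features, and the objective vector."""

import numpy as np
import pytest

from iwavesim.signal import (
    ObjectiveVector,
    WaveFeatures,
    Waveform,
    WaveWindows,
    bandpass,
    compute_objectives,
    epidural_signal,
    extract_wave_features,
    spikes_per_wave_histogram,
    wave_feature_errors,
    windows_from_latencies,
)
from iwavesim.simulate import SimulationProtocol, SpikeRecord

FS = 10000.0


def make_waveform(samples, t0=0.0):
    return Waveform(np.asarray(samples, dtype=float), FS, t0)


class TestWindows:
    def test_midpoint_boundaries_from_latencies(self):
        w = windows_from_latencies({"D": 2.0, "I1": 4.0, "I2": 6.0})
        assert w.windows["D"] == (1.0, 3.0)
        assert w.windows["I1"] == (3.0, 5.0)
        assert w.post_i3[0] == 7.0

    def test_non_increasing_latencies_rejected(self):
        with pytest.raises(ValueError):
            windows_from_latencies({"D": 4.0, "I1": 2.0})

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            WaveWindows({"D": (0, 2), "I1": (1, 3)}, (3, 5))


class TestEpiduralSignal:
    def test_zero_spikes_gives_zero_waveform(self):
        wf = epidural_signal([np.array([])], window_ms=10.0)
        assert np.allclose(wf.samples, 0.0)
        assert wf.times_ms[0] == 0.0

    def test_synchronous_volley_is_band_limited(self):
        # FFT oracle: after filtering a population impulse, almost all
        # energy sits in the pass band.  The second-order Butterworth edges
        # leak ~6% into the immediate rolloff region, and essentially
        # nothing beyond it.
        wf = epidural_signal([np.full(50, 5.0)], window_ms=30.0)
        spec = np.abs(np.fft.rfft(wf.samples)) ** 2
        freqs = np.fft.rfftfreq(len(wf.samples), 1.0 / FS)
        inside = (freqs >= 200.0) & (freqs <= 1500.0)
        assert spec[~inside].sum() < 0.07 * spec.sum()
        rolloff = (freqs >= 100.0) & (freqs <= 2500.0)
        assert spec[~rolloff].sum() < 0.005 * spec.sum()

    def test_filter_is_zero_phase(self):
        # time-reversing the input time-reverses the output away from the
        # finite-window edge transients
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        fwd = bandpass(x, FS)
        rev = bandpass(x[::-1], FS)[::-1]
        np.testing.assert_allclose(fwd[100:-100], rev[100:-100], atol=1e-3)

    def test_window_shorter_than_warmup_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            bandpass(np.zeros(5), FS)


class TestFeatureExtraction:
    def test_gaussian_bumps_recover_configured_latencies(self):
        t = np.arange(0.0, 12.0, 1000.0 / FS / 1000.0 * 1000.0) / 1000.0
        t = np.arange(0, 120) / FS * 1000.0  # 12 ms
        lats = [2.0, 4.0, 6.0, 8.0]
        x = sum(np.exp(-0.5 * ((t - m) / 0.2) ** 2) for m in lats)
        wf = make_waveform(x)
        wins = windows_from_latencies(
            {"D": 2.0, "I1": 4.0, "I2": 6.0, "I3": 8.0})
        feats = extract_wave_features(wf, wins)
        for wave, lat in zip(("D", "I1", "I2", "I3"), lats):
            assert feats[f"{wave}_time_to_peak"] == pytest.approx(
                lat, abs=1000.0 / FS)

    def test_flat_waveform_ties_break_to_window_start(self):
        wf = make_waveform(np.zeros(100))
        wins = WaveWindows({"D": (1.0, 3.0)}, (3.0, 5.0))
        feats = extract_wave_features(wf, wins)
        assert feats["D_peak"] == 0.0
        assert feats["D_time_to_peak"] == 1.0

    def test_window_outside_waveform_rejected(self):
        wf = make_waveform(np.zeros(10))
        wins = WaveWindows({"D": (5.0, 6.0)}, (6.0, 7.0))
        with pytest.raises(ValueError):
            extract_wave_features(wf, wins)


def two_neuron_record(protocol=None):
    """Hand-built record: neuron 0 fires at 600/800/1000 ms, neuron 1 at
    700/1300 ms inside a [500, 2000) ms steady-state window."""
    proto = protocol or SimulationProtocol(seed=0)
    ids = np.array([0, 1, 0, 0, 1])
    times = np.array([600.0, 700.0, 800.0, 1000.0, 1300.0])
    populations = {
        "L23_IT": np.array([0, 1]),
        "L23_BC": np.array([2]),
        "L5_PTN": np.array([3]),
        "L5_BC": np.array([4]),
        "L6_IT": np.array([5]),
        "L6_BC": np.array([6]),
    }
    return SpikeRecord(ids, times, 7, proto, populations)


class TestObjectives:
    def make_targets(self):
        feats = WaveFeatures({
            "I1_peak": 1.0, "I1_time_to_peak": 4.0,
            "I1_trough": -0.5, "I1_time_to_trough": 4.5,
        }, 0.0)
        rates = {p: (1.0, 200.0) for p in
                 ("L23_IT", "L23_BC", "L5_PTN", "L5_BC", "L6_IT")}
        noise = {p: dict(amplitude_nA=10.0, rate_scalar=0.5) for p in
                 ("L23_IT", "L23_BC", "L5_PTN", "L5_BC", "L6_IT", "L6_BC")}
        return feats, rates, noise

    def test_identical_features_have_zero_wave_error(self):
        feats, _, _ = self.make_targets()
        errs = wave_feature_errors(feats, feats)
        assert all(v == 0.0 for v in errs.values())
        assert len(errs) == 4  # only I1 rows present in the target

    def test_zero_target_uses_absolute_error(self):
        target = WaveFeatures({"I1_peak": 0.0}, 0.0)
        sim = WaveFeatures({"I1_peak": 0.3}, 0.0)
        errs = wave_feature_errors(sim, target)
        assert errs["corticospinal_wave.I1_peak"] == pytest.approx(0.3)

    def test_full_vector_has_51_entries_with_complete_target(self):
        feats, rates, noise = self.make_targets()
        # a 16-feature target (4 waves) completes the corticospinal group
        full = WaveFeatures({
            f"{w}_{f}": v for w in ("D", "I1", "I2", "I3")
            for f, v in (("peak", 1.0), ("time_to_peak", 3.0),
                         ("trough", -1.0), ("time_to_trough", 3.5))
        }, 0.0)
        obj = compute_objectives(full, two_neuron_record(), full, rates,
                                 noise)
        assert len(obj.errors) == 51
        assert obj.total == pytest.approx(sum(obj.errors.values()))
        groups = obj.group_sums()
        assert set(groups) == set(ObjectiveVector.GROUPS)
        assert sum(groups.values()) == pytest.approx(obj.total)

    def test_hand_computed_rate_and_isi_errors(self):
        feats, rates, noise = self.make_targets()
        record = two_neuron_record()
        obj = compute_objectives(feats, record, feats, rates, noise)
        # L2/3 IT: 5 spikes / 2 neurons / 1.5 s = 5/3 Hz vs target 1 Hz
        assert obj.errors["spiking_activity.L23_IT_firing_rate"] == \
            pytest.approx(abs(5 / 3 - 1.0))
        # pooled ISIs: neuron0 {200, 200}, neuron1 {600} -> mean 1000/3
        assert obj.errors["spiking_activity.L23_IT_mean_isi"] == \
            pytest.approx(abs(1000 / 3 - 200.0) / 200.0)
        # silent population: rate 0 (error 1), ISI = window length
        assert obj.errors["spiking_activity.L6_IT_firing_rate"] == 1.0
        assert obj.errors["spiking_activity.L6_IT_mean_isi"] == \
            pytest.approx((1500.0 - 200.0) / 200.0)

    def test_objectives_invariant_to_relabeling_within_population(self):
        feats, rates, noise = self.make_targets()
        rec = two_neuron_record()
        swapped = SpikeRecord(
            np.where(rec.ids == 0, 1, np.where(rec.ids == 1, 0, rec.ids)),
            rec.times, rec.n_neurons, rec.protocol, rec.populations)
        a = compute_objectives(feats, rec, feats, rates, noise)
        b = compute_objectives(feats, swapped, feats, rates, noise)
        assert a.errors == pytest.approx(b.errors)


def test_spikes_per_wave_histogram_counts_windows():
    proto = SimulationProtocol(
        dt=0.01, steady_state_window=(10, 20), tms_onset=20.0,
        inter_trial_interval=20.0, n_trials=1, total_time=40.0)
    wins = WaveWindows({"D": (0, 1), "I1": (1, 2), "I2": (2, 3),
                        "I3": (3, 4)}, (4, 6))
    ids = np.array([0, 0, 1])
    times = np.array([20.5, 22.5, 21.5])  # n0: D+I2, n1: I1
    rec = SpikeRecord(ids, times, 2, proto, {"L5_PTN": np.array([0, 1])})
    counts = spikes_per_wave_histogram(rec, [0, 1], wins)
    np.testing.assert_array_equal(counts, [0, 1, 1, 0, 0])
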