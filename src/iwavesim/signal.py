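"""Corticospinal signal synthesis, D-/I-wave features, and the objective set.

The simulated epidural signal is the band-pass filtered population spike
density of the L5 pyramidal tract neurons: per trial, spike times are binned
at the recording rate (10 kHz default), zero-phase band-pass filtered
(second-order Butterworth, 200-1500 Hz, mirroring the treatment of the
experimental recordings), and then averaged across trials.  Amplitudes are
in arbitrary units; all waveform objectives are relative errors, so the
overall scale cancels.

The optimization objective vector has 51 named entries in four groups:
corticospinal wave features, baseline spiking activity, synchrony, and
"well-behaved" regularizers.  The error of each entry is relative except
when its target is zero, in which case the absolute error is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

WAVES = ("D", "I1", "I2", "I3")
RATE_ISI_POPULATIONS = ("L23_IT", "L23_BC", "L5_PTN", "L5_BC", "L6_IT")
ALL_POPULATIONS = ("L23_IT", "L23_BC", "L5_PTN", "L5_BC", "L6_IT", "L6_BC")


@dataclass
class Waveform:
    """Uniformly sampled trace on a time base relative to the TMS pulse."""

    samples: np.ndarray
    fs_hz: float
    t0_ms: float = 0.0
    filter_desc: str = ""

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(len(self.samples)) * 1000.0 / self.fs_hz

    def slice(self, start_ms: float, stop_ms: float):
        t = self.times_ms
        mask = (t >= start_ms) & (t < stop_ms)
        if not mask.any():
            raise ValueError(f"window [{start_ms}, {stop_ms}) ms is empty")
        return t[mask], self.samples[mask]


@dataclass(frozen=True)
class WaveWindows:
    """Per-wave [start, end) intervals (ms after pulse) plus a post-I3 window."""

    windows: dict            # wave name -> (start, end)
    post_i3: tuple           # (start, end)

    def __post_init__(self):
        prev_end = -np.inf
        for w in WAVES:
            if w not in self.windows:
                continue
            a, b = self.windows[w]
            if not a < b:
                raise ValueError(f"window {w} is empty")
            if a < prev_end:
                raise ValueError(f"window {w} overlaps its predecessor")
            prev_end = b
        if self.post_i3[0] < prev_end:
            raise ValueError("post-I3 window overlaps the I3 window")

    @property
    def waves(self) -> tuple:
        return tuple(w for w in WAVES if w in self.windows)


def windows_from_latencies(latencies: dict, post_i3_end: float | None = None
                           ) -> WaveWindows:
    """Windows centered on target wave latencies, boundaries at midpoints."""
    waves = [w for w in WAVES if w in latencies]
    lats = [latencies[w] for w in waves]
    if sorted(lats) != lats:
        raise ValueError("wave latencies must be increasing")
    gaps = np.diff(lats)
    half = float(np.min(gaps)) / 2.0 if len(gaps) else 1.0
    bounds = [lats[0] - half]
    for i in range(len(lats) - 1):
        bounds.append((lats[i] + lats[i + 1]) / 2.0)
    bounds.append(lats[-1] + half)
    windows = {w: (bounds[i], bounds[i + 1]) for i, w in enumerate(waves)}
    end = bounds[-1]
    return WaveWindows(windows, (end, post_i3_end or end + 3 * half))


@dataclass
class WaveFeatures:
    """Peak/trough amplitudes and latencies per wave, plus the post-I3 peak."""

    features: dict           # e.g. "I1_peak", "I1_time_to_peak", ...
    post_i3_peak: float = 0.0

    def __getitem__(self, key):
        return self.features[key]

    def as_dict(self) -> dict:
        d = dict(self.features)
        d["post_I3_peak"] = self.post_i3_peak
        return d


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def bandpass(samples: np.ndarray, fs_hz: float,
             band=(200.0, 1500.0), order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    sos = sps.butter(order, band, btype="bandpass", fs=fs_hz, output="sos")
    padlen = 3 * (2 * order + 1)
    if len(samples) <= padlen:
        raise ValueError(
            f"window of {len(samples)} samples shorter than filter warm-up "
            f"({padlen} samples)"
        )
    return sps.sosfiltfilt(sos, samples)


def epidural_signal(
    spike_times_by_trial,
    window_ms: float = 30.0,
    fs_hz: float = 10000.0,
    band=(200.0, 1500.0),
    order: int = 2,
    pre_ms: float = 5.0,
) -> Waveform:
    """Trial-averaged, band-passed L5 PTN population spike density.

    ``spike_times_by_trial`` is a sequence of arrays of spike times in ms
    relative to the TMS pulse of each trial.  Filtering precedes trial
    averaging (each trial is filtered independently).  A silent pre-pulse
    margin of ``pre_ms`` is filtered together with the trace and trimmed
    afterwards so the response at the pulse is not distorted by filter edge
    effects; the returned time base starts at 0 (the pulse).
    """
    if window_ms <= 0:
        raise ValueError("analysis window must be positive")
    n_pre = int(round(pre_ms * fs_hz / 1000.0))
    n = int(round(window_ms * fs_hz / 1000.0))
    edges = (np.arange(n_pre + n + 1) - n_pre) / fs_hz * 1000.0
    acc = np.zeros(n)
    n_trials = 0
    for times in spike_times_by_trial:
        counts, _ = np.histogram(np.asarray(times, dtype=float), bins=edges)
        acc += bandpass(counts.astype(float), fs_hz, band, order)[n_pre:]
        n_trials += 1
    if n_trials == 0:
        raise ValueError("no trials provided")
    return Waveform(acc / n_trials, fs_hz, 0.0,
                    f"butter{order} {band[0]}-{band[1]}Hz zero-phase")


def trial_spike_times(record, l5_ids, window_ms: float = 30.0,
                      pre_ms: float = 5.0):
    """L5 PTN spike times per trial, relative to each trial's pulse.

    Includes ``pre_ms`` of pre-pulse activity (negative times) so the
    filtering margin of :func:`epidural_signal` sees real spiking.
    """
    proto = record.protocol
    out = []
    for t_pulse in proto.trial_times:
        ids, times = record.in_window(t_pulse - pre_ms, t_pulse + window_ms)
        mask = np.isin(ids, l5_ids)
        out.append(times[mask] - t_pulse)
    return out


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_wave_features(waveform: Waveform, windows: WaveWindows
                          ) -> WaveFeatures:
    """Per-window max/min amplitudes and their latencies.

    Ties (e.g. a flat trace) resolve to the earliest sample of the window.
    """
    feats = {}
    for w in windows.waves:
        a, b = windows.windows[w]
        t, x = waveform.slice(a, b)
        ip = int(np.argmax(x))
        it = int(np.argmin(x))
        feats[f"{w}_peak"] = float(x[ip])
        feats[f"{w}_time_to_peak"] = float(t[ip])
        feats[f"{w}_trough"] = float(x[it])
        feats[f"{w}_time_to_trough"] = float(t[it])
    a, b = windows.post_i3
    try:
        _, x = waveform.slice(a, b)
        post = float(np.max(x))
    except ValueError:
        post = 0.0
    return WaveFeatures(feats, post)


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------

@dataclass
class ObjectiveVector:
    """Named non-negative errors; total error is their sum."""

    errors: dict = field(default_factory=dict)

    GROUPS = ("corticospinal_wave", "spiking_activity", "synchrony",
              "well_behaved")

    @property
    def total(self) -> float:
        return float(sum(self.errors.values()))

    def group(self, name: str) -> float:
        return float(sum(v for k, v in self.errors.items()
                         if k.startswith(name + ".")))

    def group_sums(self) -> dict:
        return {g: self.group(g) for g in self.GROUPS}


def _error(simulated: float, target: float) -> float:
    """Relative error, or absolute error when the target is zero."""
    if target == 0:
        return abs(simulated)
    return abs(simulated - target) / abs(target)


def _per_neuron_isis(record, ids, start, stop):
    out = {}
    mask = np.isin(record.ids, ids) & (record.times >= start) \
        & (record.times < stop)
    rid, rt = record.ids[mask], record.times[mask]
    for i in ids:
        out[i] = np.diff(np.sort(rt[rid == i]))
    return out


def smoothed_population_density(times: np.ndarray, start: float, stop: float,
                                bin_ms: float = 1.0, sigma_ms: float = 1.0
                                ) -> np.ndarray:
    edges = np.arange(start, stop + bin_ms, bin_ms)
    counts, _ = np.histogram(times, bins=edges)
    return gaussian_filter1d(counts.astype(float), sigma_ms / bin_ms)


def wave_feature_errors(features: WaveFeatures, target: WaveFeatures,
                        waves=None) -> dict:
    """The corticospinal-wave rows of the objective vector.

    Waves absent from the target (a D- subject has no D-wave rows) are
    dropped entirely.
    """
    out = {}
    for w in (waves or WAVES):
        for f in ("peak", "time_to_peak", "trough", "time_to_trough"):
            key = f"{w}_{f}"
            if key not in target.features:
                continue
            out[f"corticospinal_wave.{key}"] = _error(
                features.features[key], target.features[key])
    return out


def compute_objectives(
    features: WaveFeatures,
    record,
    target_features: WaveFeatures,
    target_rates: dict,
    noise_params: dict,
    smoothing_sigma_ms: float = 1.0,
) -> ObjectiveVector:
    """Assemble the full 51-entry objective vector.

    ``target_rates`` maps population -> (rate_hz, mean_isi_ms) for the five
    populations with baseline-activity objectives.  ``noise_params`` maps
    population -> dict(amplitude_nA, rate_scalar); the noise-weight entries
    minimize amplitude x rate scalar normalized by the amplitude bound.
    Populations with no spikes in the steady-state window take the window
    length as their mean ISI (a maximally silent penalty) and rate 0.
    """
    errors = dict(wave_feature_errors(features, target_features))
    proto = record.protocol
    start, stop = proto.steady_state_window
    dur_s = (stop - start) / 1000.0

    for pop in RATE_ISI_POPULATIONS:
        ids = record.populations[pop]
        isis = _per_neuron_isis(record, ids, start, stop)
        n_spikes = sum(len(v) + 1 if len(v) else 0 for v in isis.values())
        rate = n_spikes / len(ids) / dur_s
        pooled = np.concatenate([v for v in isis.values()]) \
            if any(len(v) for v in isis.values()) else np.empty(0)
        mean_isi = float(pooled.mean()) if len(pooled) else stop - start
        t_rate, t_isi = target_rates[pop]
        errors[f"spiking_activity.{pop}_firing_rate"] = _error(rate, t_rate)
        errors[f"spiking_activity.{pop}_mean_isi"] = _error(mean_isi, t_isi)

    for pop in ALL_POPULATIONS:
        ids = record.populations[pop]
        mask = np.isin(record.ids, ids)
        times = record.times[mask]
        times = times[(times >= start) & (times < stop)]
        dens = smoothed_population_density(times, start, stop,
                                           sigma_ms=smoothing_sigma_ms)
        mean = dens.mean()
        ratio = dens.max() / mean if mean > 0 else 1.0
        cv = dens.std() / mean if mean > 0 else 0.0
        errors[f"synchrony.{pop}_peak_mean_ratio"] = _error(ratio, 1.0)
        errors[f"synchrony.{pop}_density_cv"] = _error(cv, 0.0)

    for pop in ALL_POPULATIONS:
        ids = record.populations[pop]
        isis = _per_neuron_isis(record, ids, start, stop)
        means = np.array([v.mean() for v in isis.values() if len(v)])
        spread = float(means.std()) if len(means) > 1 else 0.0
        errors[f"well_behaved.{pop}_population_isi_std"] = _error(spread, 0.0)

    for pop in ALL_POPULATIONS:
        p = noise_params[pop]
        weight = p["amplitude_nA"] * p["rate_scalar"] / 50.0
        errors[f"well_behaved.{pop}_noise_weight"] = _error(weight, 0.0)

    errors["well_behaved.post_I3_amplitude"] = _error(
        features.post_i3_peak, 0.0)
    return ObjectiveVector(errors)


# ---------------------------------------------------------------------------
# Spike-count-per-wave histogram
# ---------------------------------------------------------------------------

def spikes_per_wave_histogram(record, l5_ids, windows: WaveWindows
                              ) -> np.ndarray:
    """Histogram of how many wave windows each L5 PTN spiked in, per trial.

    Returns counts over 0..n_waves.  A neuron firing once per response, the
    population-oscillator signature, concentrates mass at 1.
    """
    n_waves = len(windows.waves)
    counts = np.zeros(n_waves + 1, dtype=int)
    proto = record.protocol
    for t_pulse in proto.trial_times:
        for nid in l5_ids:
            t = record.times[(record.ids == nid)
                             & (record.times >= t_pulse)
                             & (record.times < t_pulse
                                + proto.inter_trial_interval)] - t_pulse
            k = sum(
                1 for w in windows.waves
                if np.any((t >= windows.windows[w][0])
                          & (t < windows.windows[w][1]))
            )
            counts[k] += 1
    return counts
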