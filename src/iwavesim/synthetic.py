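"""Synthetic inputs: target waveforms, polynomial surrogates, feature tables.

No corticospinal recordings are publicly deposited, so the pipeline is
exercised end to end on synthetic stand-ins that emulate their statistical
structure:

* **Target waveforms** — a D-wave (optional) plus three I-waves as biphasic
  difference-of-Gaussians wavelets at configurable latencies, sampled at
  10 kHz, truncated 2 ms after the pulse and zero-phase band-pass filtered
  (200-1500 Hz, second-order Butterworth) exactly like the experimental
  pipeline.  The wavelet shape is chosen so the band-pass preserves peak
  latencies to within about one sample.
* **Polynomial surrogates** — explicit maps from a parameter vector to the
  four wave amplitudes with known coefficients, standing in for the
  simulator in sensitivity-analysis tests where ground-truth effect sizes
  must be computable in closed form.
* **Feature tables** — standardized node-feature matrices with planted
  label structure for classifier tests.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal import (
    WaveFeatures,
    Waveform,
    WaveWindows,
    bandpass,
    windows_from_latencies,
)

WAVES = ("D", "I1", "I2", "I3")


# ---------------------------------------------------------------------------
# Target waveforms
# ---------------------------------------------------------------------------

@dataclass
class WaveTemplate:
    """Ground-truth description of one synthetic corticospinal response.

    Latencies are times of the positive peaks in ms after the pulse; each
    wave's trough follows its peak by ``width/2``.  Amplitudes are arbitrary
    units.  The default latencies and the ~1.6 ms inter-wave spacing mimic
    the ~600 Hz periodicity of human I-waves but are free configuration, not
    measured values.
    """

    latencies: dict = field(default_factory=lambda: {
        "D": 2.8, "I1": 4.4, "I2": 6.0, "I3": 7.6})
    peak_amps: dict = field(default_factory=lambda: {
        "D": 0.6, "I1": 1.0, "I2": 0.8, "I3": 0.5})
    trough_amps: dict = field(default_factory=lambda: {
        "D": -0.5, "I1": -0.9, "I2": -0.7, "I3": -0.4})
    width_ms: float = 0.8
    noise_sd: float = 0.0
    fs_hz: float = 10000.0
    trace_ms: float = 20.0
    truncate_ms: float = 2.0
    d_present: bool = True

    def __post_init__(self):
        lats = [self.latencies[w] for w in WAVES if w in self.latencies]
        if sorted(lats) != lats:
            raise ValueError("wave latencies must be strictly increasing")
        for w, lat in self.latencies.items():
            if not (self.truncate_ms < lat < self.trace_ms):
                raise ValueError(
                    f"{w} latency {lat} ms outside trace "
                    f"({self.truncate_ms}-{self.trace_ms} ms)")

    @property
    def waves(self):
        return tuple(w for w in WAVES
                     if w in self.latencies
                     and (self.d_present or w != "D"))

    def windows(self) -> WaveWindows:
        lats = {w: self.latencies[w] for w in WAVES if w in self.latencies}
        return windows_from_latencies(lats)

    def expected_features(self) -> WaveFeatures:
        feats = {}
        for w in self.waves:
            feats[f"{w}_peak"] = self.peak_amps[w]
            feats[f"{w}_time_to_peak"] = self.latencies[w]
            feats[f"{w}_trough"] = self.trough_amps[w]
            feats[f"{w}_time_to_trough"] = (
                self.latencies[w] + self.width_ms / 2.0)
        if not self.d_present and "D" in self.latencies:
            feats["D_peak"] = 0.0
            feats["D_trough"] = 0.0
        return WaveFeatures(feats, 0.0)


def _dog_wavelet(t: np.ndarray, center: float, sigma: float,
                 k: float = 3.0) -> np.ndarray:
    """Zero-mean difference of Gaussians, unit positive peak at ``center``."""
    g1 = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    g2 = np.exp(-0.5 * ((t - center) / (k * sigma)) ** 2) / k
    return (g1 - g2) / (1.0 - 1.0 / k)


def synth_target_waveform(template: WaveTemplate, seed: int = 0,
                          n_trials: int = 1):
    """Render a template into a processed waveform plus its intended features.

    Each trial adds independent Gaussian noise before filtering; the returned
    waveform is the trial average of the filtered traces, truncated to begin
    ``truncate_ms`` after the pulse, mirroring the experimental processing.
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / template.fs_hz
    t = np.arange(0.0, template.trace_ms, dt)
    sigma = template.width_ms / 5.0
    clean = np.zeros_like(t)
    for w in template.waves:
        lat = template.latencies[w]
        clean += template.peak_amps[w] * _dog_wavelet(t, lat, sigma)
        clean -= abs(template.trough_amps[w]) * _dog_wavelet(
            t, lat + template.width_ms / 2.0, sigma)
    acc = np.zeros_like(t)
    for _ in range(n_trials):
        trial = clean + rng.normal(0.0, template.noise_sd, len(t)) \
            if template.noise_sd > 0 else clean
        acc += bandpass(trial, template.fs_hz)
    avg = acc / n_trials
    keep = t >= template.truncate_ms
    wf = Waveform(avg[keep], template.fs_hz, t0_ms=float(t[keep][0]),
                  filter_desc="butter2 200-1500Hz zero-phase, truncated 2ms")
    return wf, template.expected_features()


# ---------------------------------------------------------------------------
# Polynomial surrogates
# ---------------------------------------------------------------------------

@dataclass
class SurrogateResponse:
    """Explicit polynomial map from a parameter vector to wave amplitudes.

    ``terms[wave]`` is a list of (coefficient, ((index, power), ...)) items;
    an empty power tuple is a constant.  Parameters are expected on their
    native scale and internally normalized to [0, 1] by ``bounds`` so that
    coefficients refer to normalized parameters, matching how the
    sensitivity analysis normalizes its grids.
    """

    n_params: int
    terms: dict
    bounds: np.ndarray        # (n_params, 2)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self._rng = np.random.default_rng(self.seed)

    def _normalize(self, x):
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return (np.asarray(x, dtype=float) - lo) / (hi - lo)

    def __call__(self, x) -> dict:
        z = self._normalize(x)
        out = {}
        for wave, terms in self.terms.items():
            val = 0.0
            for coef, powers in terms:
                term = coef
                for idx, p in powers:
                    term *= z[idx] ** p
                val += term
            if self.noise_sd > 0:
                val += self._rng.normal(0.0, self.noise_sd)
            out[wave] = val
        return out

    def ground_truth_effects(self, wave_scales: dict | None = None
                             ) -> pd.DataFrame:
        """Sum of |coefficients| of terms involving each parameter, per wave.

        ``wave_scales`` divides each wave's column (use
        :meth:`campaign_wave_std` to express the truth on the same
        standardized scale the sensitivity analysis reports).  For linear
        surrogates the resulting ranking is exactly what the analysis
        recovers.
        """
        rows = np.zeros((self.n_params, len(self.terms)))
        waves = list(self.terms)
        for j, wave in enumerate(waves):
            for coef, powers in self.terms[wave]:
                for idx, _ in powers:
                    rows[idx, j] += abs(coef)
        df = pd.DataFrame(rows, columns=waves)
        if wave_scales is not None:
            for w in waves:
                df[w] /= wave_scales[w]
        return df

    def campaign_wave_std(self, n_levels: int) -> dict:
        """Closed-form per-wave amplitude std over a full pairwise campaign.

        Valid for linear surrogates on [0, 1]-normalized grids with the
        remaining parameters held at the mid-point: every pair grid then
        shares the same mean, and the campaign variance is the average of
        the per-pair variances.  Each parameter is active in (n-1) of the
        C(n, 2) pairs, so

            var_w = (2 / n) * var(levels) * sum_i c_iw^2.
        """
        levels = np.linspace(0.0, 1.0, n_levels)
        var_l = float(levels.var())
        out = {}
        for wave, terms in self.terms.items():
            for _, powers in terms:
                if any(p != 1 for _, p in powers) or len(powers) != 1:
                    raise ValueError("closed form requires a linear surrogate")
            ssq = sum(c ** 2 for c, _ in terms)
            out[wave] = float(np.sqrt(2.0 / self.n_params * var_l * ssq))
        return out


def synth_surrogate(
    n_params: int = 6,
    coefficients: np.ndarray | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    bounds: np.ndarray | None = None,
) -> SurrogateResponse:
    """Linear surrogate with one dominant wave per parameter.

    ``coefficients`` is an (n_params, 4) matrix of linear coefficients per
    wave; the default assigns each parameter a distinct dominant wave (its
    planted preference) with clearly separated magnitudes so the recovered
    effect-size ranking and preferential flags have an unambiguous truth.
    """
    rng = np.random.default_rng(seed)
    if coefficients is None:
        coefficients = np.zeros((n_params, 4))
        mags = np.linspace(2.0, 0.5, n_params)
        for i in range(n_params):
            dom = i % 4
            coefficients[i, dom] = mags[i]
            coefficients[i, (dom + 1) % 4] = mags[i] / 4.0
    coefficients = np.asarray(coefficients, dtype=float)
    if not np.all(np.isfinite(coefficients)):
        raise ValueError("surrogate coefficients must be finite")
    if bounds is None:
        bounds = np.tile([0.0, 1.0], (n_params, 1))
    terms = {}
    for j, wave in enumerate(WAVES):
        terms[wave] = [(float(coefficients[i, j]), ((i, 1),))
                       for i in range(n_params)
                       if coefficients[i, j] != 0.0]
    return SurrogateResponse(n_params, terms, np.asarray(bounds, dtype=float),
                             noise_sd, seed)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def synth_feature_table(
    n_nodes: int = 12,
    n_features: int = 10,
    planted_rule: dict | None = None,
    seed: int = 0,
):
    """Standardized feature matrix with labels planted on one feature.

    ``planted_rule`` options (all reference features by column index):

    * ``{"kind": "threshold", "feature": j, "margin": 1.0}`` — binary
      labels from the sign of feature j, whose values are pushed away from
      the boundary by half the margin so the classes are separable by
      construction.
    * ``{"kind": "centroid", "feature": j, "classes": k}`` — multiclass
      labels; feature j takes well-separated per-class centers plus small
      jitter (nearest-centroid structure).
    * ``{"kind": "random", "classes": k}`` — labels independent of every
      feature (the permutation null).

    Returns (features DataFrame, labels Series); columns are standardized.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_nodes, n_features))
    rule = planted_rule or {"kind": "threshold", "feature": 0}
    kind = rule["kind"]
    if kind in ("threshold", "centroid"):
        j = rule["feature"]
        if not 0 <= j < n_features:
            raise ValueError(f"planted feature {j} does not exist")
    if kind == "threshold":
        labels = (X[:, j] > 0).astype(int)
        margin = rule.get("margin", 1.0)
        X[:, j] += np.where(labels > 0, margin / 2.0, -margin / 2.0)
    elif kind == "centroid":
        k = rule.get("classes", 4)
        labels = rng.permutation(np.arange(n_nodes) % k)
        centers = np.linspace(-1.5, 1.5, k)
        X[:, j] = centers[labels] + rng.normal(0.0, 0.1, n_nodes)
    elif kind == "random":
        labels = rng.integers(0, rule.get("classes", 2), n_nodes)
    else:
        raise ValueError(f"unknown planted rule kind '{kind}'")
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    cols = [f"f{i}" for i in range(n_features)]
    df = pd.DataFrame(X, columns=cols,
                      index=[f"node{i}" for i in range(n_nodes)])
    return df, pd.Series(labels, index=df.index, name="label")
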