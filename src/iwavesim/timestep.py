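"""Time-step convergence analysis and the van Rossum spike-train distance.

The integration step is validated by driving a single default neuron with a
1000 Hz Poisson synaptic input (representative of the total drive a neuron
receives in the network) across a range of time-steps and comparing spike
count, mean/CV of the inter-spike interval, membrane-potential NRMSE and the
van Rossum distance against the smallest-dt baseline.  The same random seed
sequence is used for every time-step so trains are directly comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DEFAULT_NEURON, DEFAULT_RECEPTORS
from .simulate import _run_kernel, EV_CONDUCTANCE, RECEPTOR_NAMES

VAN_ROSSUM_TAU_MS = 500.0


def van_rossum_distance(u, v, tau: float = VAN_ROSSUM_TAU_MS) -> float:
    """Squared van Rossum distance between two spike trains.

    Both trains are convolved with the causal exponential kernel
    ``h(t) = exp(-(t - t_spike)/tau)`` and the L2 norm of the difference is
    scaled by 2/tau.  Computed by the exact closed-form double sum
    ``sum_ij exp(-|u_i - u_j|/tau)`` over the three train pairings, so two
    identical trains give 0 and a single unmatched spike contributes 1.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)

    def cross(a, b):
        if len(a) == 0 or len(b) == 0:
            return 0.0
        return float(np.exp(-np.abs(a[:, None] - b[None, :]) / tau).sum())

    val = cross(u, u) + cross(v, v) - 2.0 * cross(u, v)
    return max(val, 0.0)


# ---------------------------------------------------------------------------
# Single-neuron simulation
# ---------------------------------------------------------------------------

def simulate_single_neuron(
    dt: float,
    duration: float,
    input_times=(),
    input_weight: float = 0.0,
    current_nA: float = 0.0,
    neuron: dict | None = None,
    receptors: dict | None = None,
    record_v: bool = True,
):
    """One conductance-LIF neuron driven by AMPA events and/or a DC current.

    ``input_times`` are event times in ms (mapped to the nearest step, so the
    same times are usable at any dt); each event adds ``input_weight`` nS of
    AMPA conductance.  Returns (spike_times_ms, v_trace or None).
    """
    neuron = dict(DEFAULT_NEURON["E"] if neuron is None else neuron)
    receptors = DEFAULT_RECEPTORS if receptors is None else receptors
    n_steps = int(round(duration / dt))
    input_times = np.asarray(input_times, dtype=float)
    steps = np.round(input_times / dt).astype(np.int64)
    keep = (steps >= 0) & (steps < n_steps)
    steps = np.sort(steps[keep])
    n_ev = len(steps)

    rec_decay = np.array([np.exp(-dt / receptors[r]["tau"])
                          for r in RECEPTOR_NAMES])
    rec_E = np.array([receptors[r]["E"] for r in RECEPTOR_NAMES])

    one = np.ones(1)
    V = np.array([neuron["EL"]])
    g = np.zeros((1, 4))
    refrac = np.zeros(1)
    empty_i = np.empty(0, np.int64)
    cap = max(1000, int(duration))
    out_id = np.empty(cap, np.int64)
    out_t = np.empty(cap)
    vrec_idx = np.array([0], np.int64) if record_v else empty_i
    vrec = np.empty((n_steps if record_v else 0, len(vrec_idx)))

    n_out, err_i, err_t = _run_kernel(
        n_steps, dt, V, g, refrac,
        one * neuron["C"], one * neuron["C"] / neuron["tau_m"],
        one * neuron["EL"], one * neuron["Vth"], one * neuron["Vreset"],
        one * neuron["t_ref"], one * current_nA * 1000.0,
        rec_decay, rec_E,
        np.zeros(2, np.int64), empty_i, np.empty(0), np.empty(0),
        empty_i, empty_i, empty_i,
        np.zeros((2, 1, 4)),
        steps, np.full(n_ev, EV_CONDUCTANCE, np.int64),
        np.zeros(n_ev, np.int64), np.zeros(n_ev, np.int64),
        np.full(n_ev, float(input_weight)),
        out_id, out_t, vrec_idx, vrec,
    )
    if n_out < 0:
        raise FloatingPointError("single-neuron simulation diverged")
    spikes = out_t[:n_out].copy()
    return spikes, (vrec[:, 0] if record_v else None)


def lif_constant_current_period(current_nA: float,
                                neuron: dict | None = None) -> float:
    """Closed-form inter-spike interval of the LIF under DC current (ms)."""
    p = dict(DEFAULT_NEURON["E"] if neuron is None else neuron)
    gL = p["C"] / p["tau_m"]                     # nS
    dv = current_nA * 1000.0 / gL                # steady-state depolarization
    if p["EL"] + dv <= p["Vth"]:
        return np.inf
    t_charge = p["tau_m"] * np.log(
        (dv - (p["Vreset"] - p["EL"])) / (dv - (p["Vth"] - p["EL"]))
    )
    return p["t_ref"] + t_charge


# ---------------------------------------------------------------------------
# Sweep
# ---------------------------------------------------------------------------

def timestep_sweep(
    dts,
    duration: float = 20000.0,
    n_trials: int = 50,
    input_rate_hz: float = 1000.0,
    input_weight: float = 1.35,
    seed: int = 0,
    neuron: dict | None = None,
) -> pd.DataFrame:
    """Convergence metrics for each time-step against the smallest-dt baseline.

    Each trial draws one Poisson input train (identical across time-steps by
    construction); metrics are averaged across trials.  The van Rossum
    distance uses tau = 500 ms and membrane NRMSE interpolates the baseline
    trace onto the coarser grid.
    """
    dts = sorted(float(d) for d in dts)
    if len(dts) < 2:
        raise ValueError("need at least two time-steps to compare")
    base_dt = dts[0]
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n_trials):
        isi = rng.exponential(1000.0 / input_rate_hz,
                              int(duration / 1000.0 * input_rate_hz * 2 + 50))
        t = np.cumsum(isi)
        trains.append(t[t < duration])

    per_dt: dict[float, list[dict]] = {d: [] for d in dts}
    baselines = []
    for trial in range(n_trials):
        base_spikes, base_v = simulate_single_neuron(
            base_dt, duration, trains[trial], input_weight, neuron=neuron)
        baselines.append((base_spikes, base_v))
    base_times = np.arange(int(round(duration / base_dt))) * base_dt

    for d in dts:
        for trial in range(n_trials):
            base_spikes, base_v = baselines[trial]
            if d == base_dt:
                spikes, v = base_spikes, base_v
            else:
                spikes, v = simulate_single_neuron(
                    d, duration, trains[trial], input_weight, neuron=neuron)
            isis = np.diff(spikes)
            tgrid = np.arange(int(round(duration / d))) * d
            base_interp = np.interp(tgrid, base_times, base_v)
            span = base_v.max() - base_v.min()
            nrmse = (np.sqrt(np.mean((v - base_interp) ** 2)) / span
                     if span > 0 else 0.0)
            per_dt[d].append(dict(
                n_spikes=len(spikes),
                mean_isi=float(isis.mean()) if len(isis) else np.nan,
                cv_isi=(float(isis.std() / isis.mean())
                        if len(isis) and isis.mean() > 0 else np.nan),
                nrmse_v=float(nrmse),
                van_rossum=van_rossum_distance(spikes, base_spikes),
            ))

    rows = []
    for d in dts:
        df = pd.DataFrame(per_dt[d])
        rows.append(dict(dt=d, **df.mean(numeric_only=True).to_dict()))
    return pd.DataFrame(rows)
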