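"""Clock-driven simulation of the macrocolumn.

Neurons are conductance-based leaky integrate-and-fire point models with four
single-exponential receptor conductances (AMPA, NMDA with a sigmoidal
magnesium-block voltage dependence, GABA_A, GABA_B).  Integration uses fixed
time-step exponential Euler (default dt = 0.01 ms) with spike times aligned
to step boundaries.  This is a functional re-implementation of the source
model's dynamics — all constants live in the configuration — rather than a
line-for-line port.

Spikes are delivered through a circular conductance buffer after exactly the
per-synapse delay.  Afferent Poisson spikes, independent per-neuron noise
kicks (instantaneous charge injections at Poisson intervals), and the TMS
protocol (forced spikes for directly activated neurons, synaptic volleys for
activated afferent terminals) are precomputed as a sorted external event
stream, which makes runs bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import CORTICAL_POPULATIONS
from .network import Network

RECEPTOR_NAMES = ("AMPA", "NMDA", "GABA_A", "GABA_B")

# external event kinds
EV_CONDUCTANCE = 0   # add ev_amount (nS) to receptor ev_aux of target
EV_CHARGE = 1        # add ev_amount (mV) to membrane potential of target
EV_FORCE_SPIKE = 2   # make target fire this step unless refractory


@dataclass
class SimulationProtocol:
    """Timing of one simulation run (all times in ms)."""

    dt: float = 0.01
    steady_state_window: tuple[float, float] = (500.0, 2000.0)
    tms_onset: float = 2000.0
    inter_trial_interval: float = 200.0
    n_trials: int = 5
    total_time: float = 3000.0
    afferent_onset_jitter: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.tms_onset < self.steady_state_window[1]:
            raise ValueError("TMS onset precedes end of steady-state window")
        last = self.tms_onset + self.n_trials * self.inter_trial_interval
        if self.total_time < last:
            raise ValueError(
                f"total_time {self.total_time} ms too short for "
                f"{self.n_trials} trials ending at {last} ms"
            )

    @property
    def trial_times(self) -> np.ndarray:
        return self.tms_onset + self.inter_trial_interval * np.arange(
            self.n_trials
        )


@dataclass
class SpikeRecord:
    """Spike events of one run, sorted by time."""

    ids: np.ndarray            # neuron ids
    times: np.ndarray          # ms
    n_neurons: int
    protocol: SimulationProtocol
    populations: dict = field(default_factory=dict)  # pop -> id array

    def spikes_of(self, ids) -> np.ndarray:
        mask = np.isin(self.ids, np.asarray(ids))
        return self.times[mask]

    def population_spikes(self, population: str):
        ids = self.populations[population]
        mask = np.isin(self.ids, ids)
        return self.ids[mask], self.times[mask]

    def in_window(self, start: float, stop: float):
        mask = (self.times >= start) & (self.times < stop)
        return self.ids[mask], self.times[mask]


# ---------------------------------------------------------------------------
# Core kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_kernel(
    n_steps, dt,
    V, g, refrac,                       # state: (n,), (n,4), (n,)
    C, gL, EL, Vth, Vreset, tref,       # neuron constants (n,)
    Iext,                               # constant current, pA (n,)
    rec_decay, rec_E,                   # (4,)
    indptr, syn_post, syn_wf, syn_ws,   # CSR outgoing synapses
    syn_rf, syn_rs, syn_dsteps,
    buf,                                # (L, n, 4) pending conductance
    ev_step, ev_kind, ev_target, ev_aux, ev_amount,
    out_id, out_t,
    vrec_idx, vrec,                     # (m,), (n_steps, m)
):
    L = buf.shape[0]
    n = V.shape[0]
    ptr = 0
    n_ev = ev_step.shape[0]
    n_out = 0
    cap = out_id.shape[0]
    forced = np.zeros(n, np.bool_)
    for t in range(n_steps):
        row = buf[t % L]
        for i in range(n):
            for r in range(4):
                g[i, r] = g[i, r] * rec_decay[r] + row[i, r]
                row[i, r] = 0.0
        # external events scheduled for this step
        while ptr < n_ev and ev_step[ptr] == t:
            tgt = ev_target[ptr]
            k = ev_kind[ptr]
            if k == EV_CONDUCTANCE:
                g[tgt, ev_aux[ptr]] += ev_amount[ptr]
            elif k == EV_CHARGE:
                if refrac[tgt] <= 0.0:
                    V[tgt] += ev_amount[ptr]
            else:
                forced[tgt] = True
            ptr += 1
        # integrate
        for i in range(n):
            if refrac[i] > 0.0:
                refrac[i] -= dt
                V[i] = Vreset[i]
                continue
            s = 1.0 / (1.0 + 0.28 * np.exp(-0.062 * V[i]))
            gA = g[i, 0]
            gN = g[i, 1] * s
            gGa = g[i, 2]
            gGb = g[i, 3]
            G = gL[i] + gA + gN + gGa + gGb
            num = (gL[i] * EL[i] + gA * rec_E[0] + gN * rec_E[1]
                   + gGa * rec_E[2] + gGb * rec_E[3] + Iext[i])
            vinf = num / G
            vnew = vinf + (V[i] - vinf) * np.exp(-dt * G / C[i])
            if not np.isfinite(vnew):
                return -1, i, t
            V[i] = vnew
        # spikes
        for i in range(n):
            fire = forced[i]
            forced[i] = False
            if refrac[i] > 0.0:
                continue
            if fire or V[i] >= Vth[i]:
                if n_out >= cap:
                    return -2, i, t
                out_id[n_out] = i
                out_t[n_out] = t * dt
                n_out += 1
                V[i] = Vreset[i]
                refrac[i] = tref[i]
                for kk in range(indptr[i], indptr[i + 1]):
                    slot = (t + syn_dsteps[kk]) % L
                    j = syn_post[kk]
                    buf[slot, j, syn_rf[kk]] += syn_wf[kk]
                    buf[slot, j, syn_rs[kk]] += syn_ws[kk]
        for m in range(vrec_idx.shape[0]):
            vrec[t, m] = V[vrec_idx[m]]
    return n_out, -1, -1


# ---------------------------------------------------------------------------
# Event assembly
# ---------------------------------------------------------------------------

def _poisson_times(rng, rate_hz, t_start, t_stop):
    """Event times of a homogeneous Poisson process on [t_start, t_stop) ms."""
    if rate_hz <= 0 or t_stop <= t_start:
        return np.empty(0)
    mean_isi = 1000.0 / rate_hz
    n_max = int((t_stop - t_start) / mean_isi * 4 + 20)
    isis = rng.exponential(mean_isi, n_max)
    times = t_start + np.cumsum(isis)
    return times[times < t_stop]


def tms_activate(network: Network, activation: dict, rng,
                 n_trials: int) -> list[dict]:
    """Sample the TMS-activated members for each trial.

    For each population or afferent group with activation proportion p,
    round(p * N) members are drawn without replacement, independently for
    every presentation of the stimulus.
    """
    out = []
    for _ in range(n_trials):
        sel = {}
        for node, p in activation.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"activation proportion {p} for {node}")
            ids = network.population_ids(node)
            k = int(round(p * len(ids)))
            if k > 0:
                sel[node] = rng.choice(ids, size=k, replace=False)
        out.append(sel)
    return out


def _assemble_events(network: Network, protocol: SimulationProtocol, rng,
                     syn_by_pre: dict, dt: float, n_steps: int):
    """Afferent drive, noise kicks and TMS activations as a sorted stream."""
    cfg = network.config
    steps, kinds, targets, aux, amounts = [], [], [], [], []

    def add(step, kind, target, a, amount):
        steps.append(step)
        kinds.append(kind)
        targets.append(target)
        aux.append(a)
        amounts.append(amount)

    def deliver_afferent_spike(unit_id, t_ms):
        post, wf, ws, rf, rs, dly = syn_by_pre.get(unit_id, (None,) * 6)
        if post is None:
            return
        for j in range(len(post)):
            step = int(round((t_ms + dly[j]) / dt))
            if 0 <= step < n_steps:
                add(step, EV_CONDUCTANCE, post[j], rf[j], wf[j])
                add(step, EV_CONDUCTANCE, post[j], rs[j], ws[j])

    # spontaneous afferent Poisson drive
    aff_rate = cfg["afferents"]["rate_hz"]
    aff_mask = network.neurons["population"].str.endswith("_AFF").to_numpy()
    aff_ids = network.neurons["id"].to_numpy()[aff_mask]
    for uid in aff_ids:
        onset = rng.uniform(0.0, protocol.afferent_onset_jitter)
        for t in _poisson_times(rng, aff_rate, onset, protocol.total_time):
            deliver_afferent_spike(uid, t)

    # per-neuron noise: instantaneous charge kicks at Poisson intervals
    noise_cfg = cfg["noise"]
    for pop in CORTICAL_POPULATIONS:
        ids = network.population_ids(pop)
        if not len(ids):
            continue
        amp = network.noise[pop]["amplitude_nA"]
        rate = network.noise[pop]["rate_scalar"] * noise_cfg["base_rate_hz"]
        cls = "E" if pop in ("L23_IT", "L5_PTN", "L6_IT") else "I"
        C = cfg["neuron"][cls]["C"]
        dv = amp * noise_cfg["pulse_width_ms"] / C * 1000.0  # mV
        for nid in ids:
            for t in _poisson_times(rng, rate, 0.0, protocol.total_time):
                step = int(round(t / dt))
                if step < n_steps:
                    add(step, EV_CHARGE, nid, 0, dv)

    # TMS: fresh activation sample per trial
    trials = tms_activate(network, network.activation, rng, protocol.n_trials)
    for t_pulse, sel in zip(protocol.trial_times, trials):
        pulse_step = int(round(t_pulse / dt))
        for node, ids in sel.items():
            if node.endswith("_AFF"):
                for uid in ids:
                    deliver_afferent_spike(uid, t_pulse)
            else:
                for nid in ids:
                    if pulse_step < n_steps:
                        add(pulse_step, EV_FORCE_SPIKE, nid, 0, 0.0)

    if not steps:
        empty = np.empty(0, np.int64)
        return empty, empty.copy(), empty.copy(), empty.copy(), np.empty(0)
    order = np.argsort(np.asarray(steps), kind="stable")
    return (np.asarray(steps, np.int64)[order],
            np.asarray(kinds, np.int64)[order],
            np.asarray(targets, np.int64)[order],
            np.asarray(aux, np.int64)[order],
            np.asarray(amounts, float)[order])


# ---------------------------------------------------------------------------
# Public entry point
# ---------------------------------------------------------------------------

def _neuron_constants(network: Network, ids_pop: np.ndarray, n: int):
    cfg = network.config["neuron"]
    C = np.empty(n)
    gL = np.empty(n)
    EL = np.empty(n)
    Vth = np.empty(n)
    Vreset = np.empty(n)
    tref = np.empty(n)
    for i in range(n):
        pop = ids_pop[i]
        cls = "E" if pop in ("L23_IT", "L5_PTN", "L6_IT") else "I"
        p = cfg[cls]
        C[i] = p["C"]
        gL[i] = p["C"] / p["tau_m"]
        EL[i] = p["EL"]
        Vth[i] = p["Vth"]
        Vreset[i] = p["Vreset"]
        tref[i] = p["t_ref"]
    return C, gL, EL, Vth, Vreset, tref


def _split_weights(network: Network, syn):
    """Fast/slow receptor weights and indices for each synapse row."""
    sign = syn["sign"].to_numpy()
    w = syn["weight"].to_numpy()
    nmda = network.config["nmda_ratio"]
    gabab = network.config["gabab_ratio"]
    wf = np.abs(w)
    ws = np.where(sign > 0, wf * nmda, wf * gabab)
    rf = np.where(sign > 0, 0, 2).astype(np.int64)
    rs = np.where(sign > 0, 1, 3).astype(np.int64)
    return wf, ws, rf, rs


def simulate(
    network: Network,
    protocol: SimulationProtocol | None = None,
    record_v: np.ndarray | None = None,
    spike_capacity: int | None = None,
) -> tuple[SpikeRecord, np.ndarray | None]:
    """Run the full protocol; returns spikes and optional voltage traces.

    Deterministic given (network, protocol.seed).  Spikes are delivered to
    their targets after exactly the stored per-synapse delay (rounded to
    whole steps, minimum one step).
    """
    if protocol is None:
        protocol = SimulationProtocol()
    dt = protocol.dt
    n_steps = int(round(protocol.total_time / dt))
    rng = np.random.default_rng(protocol.seed)

    neurons = network.neurons
    cortical = ~neurons["population"].str.endswith("_AFF").to_numpy()
    n = int(cortical.sum())
    ids_pop = neurons["population"].to_numpy()

    syn = network.synapses
    syn_cort = syn[syn["pre"] < n]
    wf, ws, rf, rs = _split_weights(network, syn_cort)
    dsteps = np.maximum(1, np.round(
        syn_cort["delay_ms"].to_numpy() / dt).astype(np.int64))
    order = np.argsort(syn_cort["pre"].to_numpy(), kind="stable")
    pre_sorted = syn_cort["pre"].to_numpy()[order]
    indptr = np.searchsorted(pre_sorted, np.arange(n + 1))
    syn_post = syn_cort["post"].to_numpy()[order]
    syn_wf, syn_ws = wf[order], ws[order]
    syn_rf, syn_rs = rf[order], rs[order]
    syn_dsteps = dsteps[order]

    # afferent synapses, grouped by presynaptic unit for event assembly
    syn_aff = syn[syn["pre"] >= n]
    syn_by_pre: dict = {}
    if len(syn_aff):
        awf, aws, arf, ars = _split_weights(network, syn_aff)
        apre = syn_aff["pre"].to_numpy()
        apost = syn_aff["post"].to_numpy()
        adly = syn_aff["delay_ms"].to_numpy()
        for uid in np.unique(apre):
            m = apre == uid
            syn_by_pre[int(uid)] = (apost[m], awf[m], aws[m],
                                    arf[m], ars[m], adly[m])

    ev = _assemble_events(network, protocol, rng, syn_by_pre, dt, n_steps)

    rec = network.config["receptors"]
    rec_decay = np.array([np.exp(-dt / rec[r]["tau"]) for r in RECEPTOR_NAMES])
    rec_E = np.array([rec[r]["E"] for r in RECEPTOR_NAMES])
    C, gL, EL, Vth, Vreset, tref = _neuron_constants(network, ids_pop, n)

    max_d = int(syn_dsteps.max()) if len(syn_dsteps) else 1
    L = max_d + 1
    buf = np.zeros((L, n, 4))
    V = EL.copy()
    g = np.zeros((n, 4))
    refrac = np.zeros(n)

    if spike_capacity is None:
        spike_capacity = max(10000, int(n * protocol.total_time / 1000.0 * 200))
    out_id = np.empty(spike_capacity, np.int64)
    out_t = np.empty(spike_capacity)
    if record_v is None:
        vrec_idx = np.empty(0, np.int64)
    else:
        vrec_idx = np.asarray(record_v, np.int64)
    vrec = np.empty((n_steps if len(vrec_idx) else 0, len(vrec_idx)))

    n_out, err_i, err_t = _run_kernel(
        n_steps, dt, V, g, refrac, C, gL, EL, Vth, Vreset, tref,
        np.zeros(n), rec_decay, rec_E, indptr, syn_post, syn_wf, syn_ws,
        syn_rf, syn_rs, syn_dsteps, buf,
        *ev, out_id, out_t, vrec_idx, vrec,
    )
    if n_out == -1:
        raise FloatingPointError(
            f"non-finite membrane potential: neuron {err_i} at "
            f"{err_t * dt:.3f} ms"
        )
    if n_out == -2:
        raise RuntimeError(
            f"spike capacity {spike_capacity} exhausted at "
            f"{err_t * dt:.3f} ms; raise spike_capacity"
        )
    pops = {
        p: network.population_ids(p)
        for p in neurons["population"].unique()
    }
    record = SpikeRecord(
        ids=out_id[:n_out].copy(),
        times=out_t[:n_out].copy(),
        n_neurons=n,
        protocol=protocol,
        populations=pops,
    )
    return record, (vrec if len(vrec_idx) else None)
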