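"""Macrocolumn construction: lattice geometry, neuron placement, wiring.

The network is represented by two tables.  ``neurons`` holds one row per
cortical neuron or afferent unit (id, population, microcolumn, 3-D position in
um).  ``synapses`` holds one row per connection with its base weight, the
conduction component of its delay, and group labels that the 98-dimensional
optimization vector addresses (one weight scalar per projection, one velocity
scalar per pre-population x target-layer or per afferent group).

Every synaptic delay is ``synaptic_delay + conduction`` where the synaptic
transmission delay is 0.2 ms and the conduction component is the 3-D soma
distance divided by the conduction velocity (0.570 m/s by default) for
intracortical connections, or a normally distributed latency for afferents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    AFFERENT_GROUPS,
    ALL_NODES,
    CORTICAL_POPULATIONS,
    LAYER_OF,
    config_from_yaml,
    config_to_yaml,
    default_config,
    is_excitatory,
)

SYNAPTIC_DELAY_MS = 0.2
DEFAULT_VELOCITY_M_S = 0.570


# ---------------------------------------------------------------------------
# Lattice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrocolumnLattice:
    """Triangular lattice of microcolumn sites within the column footprint."""

    positions: np.ndarray        # (n, 2) um, centered on the column axis
    spacing: float               # um
    footprint_diameter: float    # um

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def generate_lattice(
    spacing: float = 50.0,
    footprint_diameter: float = 500.0,
    n_target: int = 79,
) -> MicrocolumnLattice:
    """Place ``n_target`` microcolumn sites on a centered triangular lattice.

    A triangular lattice of the requested pitch inside the footprint contains
    more sites than the canonical count, so the lattice is generated
    generously and trimmed to the ``n_target`` sites nearest the column axis
    (ties broken by polar angle).  The construction is deterministic.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if n_target < 1:
        raise ValueError("n_target must be at least 1")
    radius = footprint_diameter / 2.0
    n_span = int(np.ceil(radius / spacing)) + 2
    rows = np.arange(-n_span, n_span + 1)
    pts = []
    dy = spacing * np.sqrt(3.0) / 2.0
    for j in rows:
        y = j * dy
        x0 = (j % 2) * spacing / 2.0
        xs = x0 + np.arange(-n_span, n_span + 1) * spacing
        pts.append(np.column_stack([xs, np.full_like(xs, y, dtype=float)]))
    pts = np.vstack(pts)
    r = np.hypot(pts[:, 0], pts[:, 1])
    inside = pts[r <= radius + 1e-9]
    if len(inside) < n_target:
        raise ValueError(
            f"only {len(inside)} lattice sites fit inside the "
            f"{footprint_diameter} um footprint; {n_target} requested "
            f"(short by {n_target - len(inside)})"
        )
    rr = np.hypot(inside[:, 0], inside[:, 1])
    theta = np.mod(np.arctan2(inside[:, 1], inside[:, 0]), 2 * np.pi)
    order = np.lexsort((theta, np.round(rr, 6)))
    chosen = inside[order[:n_target]]
    return MicrocolumnLattice(chosen, spacing, footprint_diameter)


# ---------------------------------------------------------------------------
# Delays
# ---------------------------------------------------------------------------

def conduction_delay(
    pre_position,
    post_position,
    velocity: float = DEFAULT_VELOCITY_M_S,
    synaptic_delay: float = SYNAPTIC_DELAY_MS,
) -> float:
    """Total delay in ms: 3-D soma distance / velocity + synaptic delay.

    ``velocity`` is in m/s, which equals um/ms x 1000; positions are in um.
    """
    if velocity <= 0:
        raise ValueError("conduction velocity must be positive")
    dist = float(np.linalg.norm(np.asarray(post_position, dtype=float)
                                - np.asarray(pre_position, dtype=float)))
    return dist / (velocity * 1000.0) + synaptic_delay


# ---------------------------------------------------------------------------
# Parameter space (Table-4 categories)
# ---------------------------------------------------------------------------

_CATEGORY_BOUNDS = {
    "weight": (0.1, 10.0),
    "velocity": (0.25, 2.0),
    "aff_delay_mean": (0.2, 2.0),
    "aff_delay_sd": (0.1, 1.0),
    "activation": (0.0, 1.0),
    "noise_amp": (1.0, 50.0),
    "noise_rate": (0.0, 1.0),
}
_CATEGORY_ORDER = tuple(_CATEGORY_BOUNDS)


class ParameterSpace:
    """Fixed enumeration of the 98 open model parameters.

    Parameters are grouped by category (synaptic weight scalars, conduction
    velocity scalars, afferent delay mean/sd, TMS activation proportions,
    noise amplitude and rate) and sorted alphabetically by projection or
    group name within each category, giving a stable, diffable ordering.
    """

    def __init__(self, network: "Network"):
        # enumerate from the rule set, not realized synapses, so the
        # ordering is independent of sampling outcomes and network size
        rules = network.config["rules"]
        proj = sorted(f"{r.pre}->{r.post}" for r in rules)
        vel = sorted({
            r.pre if r.pre.endswith("_AFF")
            else f"{r.pre}->{LAYER_OF[r.post]}"
            for r in rules
        })
        names: list[str] = []
        names += [f"weight:{p}" for p in proj]
        names += [f"velocity:{g}" for g in vel]
        names += [f"aff_delay_mean:{g}" for g in sorted(AFFERENT_GROUPS)]
        names += [f"aff_delay_sd:{g}" for g in sorted(AFFERENT_GROUPS)]
        names += [f"activation:{n}" for n in sorted(ALL_NODES)]
        names += [f"noise_amp:{p}" for p in sorted(CORTICAL_POPULATIONS)]
        names += [f"noise_rate:{p}" for p in sorted(CORTICAL_POPULATIONS)]
        self.names = names
        self.categories = [n.split(":", 1)[0] for n in names]
        self.lower = np.array([_CATEGORY_BOUNDS[c][0] for c in self.categories])
        self.upper = np.array([_CATEGORY_BOUNDS[c][1] for c in self.categories])

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def default_values(self, network: "Network") -> np.ndarray:
        """Vector that reproduces the base network (identity scalars)."""
        aff = network.config["afferents"]
        noise = network.config["noise"]
        out = np.empty(len(self.names))
        for i, name in enumerate(self.names):
            cat, key = name.split(":", 1)
            if cat in ("weight", "velocity"):
                out[i] = 1.0
            elif cat == "aff_delay_mean":
                out[i] = aff["delay_mean_ms"]
            elif cat == "aff_delay_sd":
                out[i] = aff["delay_sd_ms"]
            elif cat == "activation":
                out[i] = network.activation.get(key, 0.0)
            elif cat == "noise_amp":
                out[i] = noise["amplitude_nA"]
            else:
                out[i] = noise["rate_scalar"]
        return out

    def validate(self, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.names),):
            raise ValueError(
                f"parameter vector has length {values.size}, "
                f"expected {len(self.names)}"
            )
        bad = np.where((values < self.lower) | (values > self.upper))[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"parameter '{self.names[i]}'={values[i]:g} outside "
                f"[{self.lower[i]:g}, {self.upper[i]:g}]"
            )


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """A built macrocolumn: neuron table, synapse table, per-node settings."""

    config: dict
    seed: int
    neurons: pd.DataFrame         # id, population, microcolumn, x, y, z
    synapses: pd.DataFrame        # pre, post, projection, vel_group, ...
    activation: dict = field(default_factory=dict)   # node -> proportion
    noise: dict = field(default_factory=dict)        # pop -> dict(amp, rate)

    @property
    def n_cortical(self) -> int:
        return int((~self.neurons["population"].str.endswith("_AFF")).sum())

    @property
    def parameter_space(self) -> ParameterSpace:
        return ParameterSpace(self)

    def population_ids(self, population: str) -> np.ndarray:
        mask = self.neurons["population"].to_numpy() == population
        return self.neurons["id"].to_numpy()[mask]

    def copy(self) -> "Network":
        return Network(
            config=self.config,
            seed=self.seed,
            neurons=self.neurons.copy(),
            synapses=self.synapses.copy(),
            activation=dict(self.activation),
            noise={k: dict(v) for k, v in self.noise.items()},
        )


def build_macrocolumn(config: dict | None = None, seed: int = 0) -> Network:
    """Construct the full macrocolumn network from a configuration.

    Per microcolumn and layer: 2 excitatory neurons and 1 basket cell, with
    depths drawn uniformly within the layer's bounds.  Synapses are sampled
    independently per connection rule (no autapses); afferent groups of
    ``n_units`` Poisson fibers are attached to every cortical population.
    The result is reproducible given the seed.
    """
    if config is None:
        config = default_config()
    rules = config["rules"]
    if not rules:
        raise ValueError("connection-rule set is empty")
    geom = config["geometry"]
    height = geom["column_height"]
    for layer in config["layers"]:
        if layer.depth_bottom > height + 1e-9:
            raise ValueError(
                f"layer {layer.name} bottom {layer.depth_bottom} um exceeds "
                f"column height {height} um"
            )
    rng = np.random.default_rng(seed)
    lattice = generate_lattice(
        geom["spacing"], geom["footprint_diameter"], geom["n_microcolumns"]
    )

    # --- neurons ------------------------------------------------------
    rows = []
    nid = 0
    for mc, (x, y) in enumerate(lattice.positions):
        for layer in config["layers"]:
            for pop, count in ((layer.excitatory_type, 2),
                               (layer.inhibitory_type, 1)):
                for _ in range(count):
                    z = rng.uniform(layer.depth_top, layer.depth_bottom)
                    rows.append((nid, pop, mc, x, y, z))
                    nid += 1
    n_cortical = nid
    aff_units = config["afferents"]["n_units"]
    for group in AFFERENT_GROUPS:
        for _ in range(aff_units):
            rows.append((nid, group, -1, np.nan, np.nan, np.nan))
            nid += 1
    neurons = pd.DataFrame(
        rows, columns=["id", "population", "microcolumn", "x", "y", "z"]
    )

    # --- synapses -----------------------------------------------------
    pos = neurons[["x", "y", "z"]].to_numpy()
    ids_by_pop = {
        p: neurons.loc[neurons["population"] == p, "id"].to_numpy()
        for p in neurons["population"].unique()
    }
    syn_delay = config["synaptic_delay_ms"]
    parts = []
    for rule in rules:
        pre_ids = ids_by_pop.get(rule.pre)
        post_ids = ids_by_pop.get(rule.post)
        if pre_ids is None or post_ids is None or not len(pre_ids):
            raise ValueError(f"rule {rule.pre}->{rule.post}: empty population")
        mask = rng.random((len(pre_ids), len(post_ids))) < rule.p
        if rule.pre == rule.post:
            np.fill_diagonal(mask, False)
        pre_idx, post_idx = np.nonzero(mask)
        pre = pre_ids[pre_idx]
        post = post_ids[post_idx]
        afferent = rule.pre.endswith("_AFF")
        if afferent:
            dist = np.full(len(pre), np.nan)
            zscore = rng.standard_normal(len(pre))
            aff_cfg = config["afferents"]
            cond = np.maximum(
                0.0,
                aff_cfg["delay_mean_ms"] + aff_cfg["delay_sd_ms"] * zscore,
            )
            vel_group = rule.pre
        else:
            dist = np.linalg.norm(pos[pre] - pos[post], axis=1)
            zscore = np.zeros(len(pre))
            cond = dist / (rule.velocity * 1000.0)
            vel_group = f"{rule.pre}->{LAYER_OF[rule.post]}"
        parts.append(pd.DataFrame({
            "pre": pre,
            "post": post,
            "projection": f"{rule.pre}->{rule.post}",
            "vel_group": vel_group,
            "sign": rule.sign,
            "base_weight": rule.weight,
            "dist_um": dist,
            "zscore": zscore,
            "cond_base_ms": cond,
            "weight": rule.weight,
            "delay_ms": syn_delay + cond,
        }))
    synapses = pd.concat(parts, ignore_index=True)

    noise_cfg = config["noise"]
    noise = {
        p: dict(amplitude_nA=noise_cfg["amplitude_nA"],
                rate_scalar=noise_cfg["rate_scalar"])
        for p in CORTICAL_POPULATIONS
    }
    activation = {n: 0.0 for n in ALL_NODES}
    return Network(config, seed, neurons, synapses, activation, noise)


def apply_parameter_vector(network: Network, values: np.ndarray) -> Network:
    """Return a copy of ``network`` with a full parameter vector applied.

    Weight scalars multiply base synaptic weights; velocity scalars divide
    the conduction component of delays; afferent delay mean/sd re-derive the
    per-synapse latencies from their frozen standard-normal draws (so the
    mapping is deterministic); activation proportions and per-population
    noise settings are stored for the simulator.
    """
    space = network.parameter_space
    values = np.asarray(values, dtype=float)
    space.validate(values)
    by_name = dict(zip(space.names, values))
    net = network.copy()
    syn = net.synapses
    syn_delay = net.config["synaptic_delay_ms"]

    wscal = syn["projection"].map(
        lambda p: by_name[f"weight:{p}"]).to_numpy()
    syn["weight"] = syn["base_weight"].to_numpy() * wscal

    afferent = syn["vel_group"].str.endswith("_AFF").to_numpy()
    cond = syn["cond_base_ms"].to_numpy().copy()
    for g in AFFERENT_GROUPS:
        gm = (syn["vel_group"] == g).to_numpy()
        if not gm.any():
            continue
        mean = by_name[f"aff_delay_mean:{g}"]
        sd = by_name[f"aff_delay_sd:{g}"]
        cond[gm] = np.maximum(0.0, mean + sd * syn["zscore"].to_numpy()[gm])
    vscal = syn["vel_group"].map(
        lambda g: by_name[f"velocity:{g}"]).to_numpy()
    syn["cond_base_ms"] = np.where(afferent, cond, syn["cond_base_ms"])
    syn["delay_ms"] = syn_delay + cond / vscal

    net.activation = {
        n: by_name[f"activation:{n}"] for n in ALL_NODES
    }
    net.noise = {
        p: dict(amplitude_nA=by_name[f"noise_amp:{p}"],
                rate_scalar=by_name[f"noise_rate:{p}"])
        for p in CORTICAL_POPULATIONS
    }
    return net


# ---------------------------------------------------------------------------
# Plain-text export / import
# ---------------------------------------------------------------------------

def save_network(network: Network, directory: str | Path) -> None:
    """Write neurons.csv, synapses.csv, and a JSON sidecar of config + seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    network.neurons.to_csv(directory / "neurons.csv", index=False)
    network.synapses.to_csv(directory / "synapses.csv", index=False)
    sidecar = {
        "seed": network.seed,
        "config_yaml": config_to_yaml(network.config),
        "activation": network.activation,
        "noise": network.noise,
    }
    (directory / "network.json").write_text(json.dumps(sidecar, indent=2))


def load_network(directory: str | Path) -> Network:
    directory = Path(directory)
    sidecar = json.loads((directory / "network.json").read_text())
    return Network(
        config=config_from_yaml(sidecar["config_yaml"]),
        seed=sidecar["seed"],
        neurons=pd.read_csv(directory / "neurons.csv"),
        synapses=pd.read_csv(directory / "synapses.csv"),
        activation=sidecar["activation"],
        noise=sidecar["noise"],
    )
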