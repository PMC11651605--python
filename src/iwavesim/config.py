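"""Default model configuration.

The macrocolumn is a 500 um diameter, 2700 um tall cylinder of motor cortex
containing three layers (L2/3, L5, L6), each with two excitatory neurons and
one fast-spiking basket cell (BC) per microcolumn.  Microcolumns sit on a
triangular lattice with 50 um pitch (79 sites by default).  Excitatory
afferent fiber groups (one per cortical population, 79 units each) provide
extracortical drive.

Biophysical constants, connection probabilities and layer depth boundaries
below are Esser-derived defaults: the source model's values are not reprinted
in full anywhere convenient, so this block is a documented, editable set of
assumptions.  Everything here can be overridden through the keyword arguments
of :func:`default_config` or by editing the returned dictionary before
building a network.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

# ---------------------------------------------------------------------------
# Population naming
# ---------------------------------------------------------------------------

EXCITATORY_POPULATIONS = ("L23_IT", "L5_PTN", "L6_IT")
INHIBITORY_POPULATIONS = ("L23_BC", "L5_BC", "L6_BC")
CORTICAL_POPULATIONS = (
    "L23_IT", "L23_BC", "L5_PTN", "L5_BC", "L6_IT", "L6_BC",
)
AFFERENT_GROUPS = tuple(f"{p}_AFF" for p in CORTICAL_POPULATIONS)
ALL_NODES = CORTICAL_POPULATIONS + AFFERENT_GROUPS

LAYER_OF = {
    "L23_IT": "L2/3", "L23_BC": "L2/3",
    "L5_PTN": "L5", "L5_BC": "L5",
    "L6_IT": "L6", "L6_BC": "L6",
}
LAYERS = ("L2/3", "L5", "L6")


def is_excitatory(pop: str) -> bool:
    """Excitatory cortical populations and all afferent groups carry sign +1."""
    return pop in EXCITATORY_POPULATIONS or pop.endswith("_AFF")


# ---------------------------------------------------------------------------
# Structural specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """Depth band of one cortical layer within the 2700 um column."""

    name: str
    depth_top: float      # um, from pia
    depth_bottom: float   # um
    excitatory_type: str
    inhibitory_type: str

    def __post_init__(self):
        if not (0.0 <= self.depth_top < self.depth_bottom):
            raise ValueError(
                f"layer {self.name}: bad depth interval "
                f"[{self.depth_top}, {self.depth_bottom}]"
            )


@dataclass(frozen=True)
class ConnectionRule:
    """One projection between populations (or afferent group -> population).

    ``velocity`` is the axonal conduction velocity in m/s; the non-human
    primate measurement of 0.570 m/s is the default everywhere.
    """

    pre: str
    post: str
    p: float                 # connection probability
    weight: float            # base synaptic conductance, nS
    velocity: float = 0.570  # m/s

    @property
    def sign(self) -> int:
        return +1 if is_excitatory(self.pre) else -1

    @property
    def receptors(self) -> tuple[str, ...]:
        return ("AMPA", "NMDA") if self.sign > 0 else ("GABA_A", "GABA_B")

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.pre}->{self.post}: p={self.p} not in (0,1]")
        if self.velocity <= 0:
            raise ValueError("conduction velocity must be positive")


# Intracortical edge list (Fig-3-style block diagram, Esser-derived defaults).
# Every excitatory population projects to all six populations; basket cells
# project within their own layer, to the excitatory populations of the other
# layers, and between L2/3 and L5 BCs.  38 weight-scalar projections in total
# once the 6 afferent projections are added.
_E_TARGET_P = {  # (same_layer, other_layer) connection probabilities
    "E": (0.12, 0.06),
    "I": (0.20, 0.10),
}
_BC_OWN_P = {"E": 0.25, "I": 0.20}
_BC_CROSS_P = 0.10


def _default_rules() -> list[ConnectionRule]:
    rules: list[ConnectionRule] = []
    for pre in EXCITATORY_POPULATIONS:
        for post in CORTICAL_POPULATIONS:
            kind = "E" if post in EXCITATORY_POPULATIONS else "I"
            same = LAYER_OF[pre] == LAYER_OF[post]
            p = _E_TARGET_P[kind][0 if same else 1]
            w = 1.6 if kind == "E" else 1.2
            rules.append(ConnectionRule(pre, post, p, w))
    for pre in INHIBITORY_POPULATIONS:
        layer = LAYER_OF[pre]
        for post in CORTICAL_POPULATIONS:
            if LAYER_OF[post] == layer:
                kind = "E" if post in EXCITATORY_POPULATIONS else "I"
                rules.append(ConnectionRule(pre, post, _BC_OWN_P[kind], 2.5))
        for post in EXCITATORY_POPULATIONS:
            if LAYER_OF[post] != layer:
                rules.append(ConnectionRule(pre, post, _BC_CROSS_P, 1.5))
    rules.append(ConnectionRule("L23_BC", "L5_BC", _BC_CROSS_P, 1.5))
    rules.append(ConnectionRule("L5_BC", "L23_BC", _BC_CROSS_P, 1.5))
    # afferent projections, one per cortical population
    for post in CORTICAL_POPULATIONS:
        rules.append(ConnectionRule(f"{post}_AFF", post, 0.25, 2.0))
    return rules


# ---------------------------------------------------------------------------
# Neuron / synapse biophysics (conductance-based LIF; editable assumptions)
# ---------------------------------------------------------------------------

DEFAULT_NEURON = {
    # per population class: excitatory pyramidal vs fast-spiking basket cell
    "E": dict(C=150.0, tau_m=15.0, EL=-70.0, Vth=-50.0, Vreset=-65.0,
              t_ref=2.0),
    "I": dict(C=100.0, tau_m=10.0, EL=-70.0, Vth=-50.0, Vreset=-65.0,
              t_ref=1.0),
    # units: C pF, tau_m ms, potentials mV, t_ref ms
}

DEFAULT_RECEPTORS = {
    # single-exponential conductance decay; E_rev mV, tau ms
    "AMPA":   dict(tau=2.0,   E=0.0),
    "NMDA":   dict(tau=100.0, E=0.0),
    "GABA_A": dict(tau=6.0,   E=-70.0),
    "GABA_B": dict(tau=150.0, E=-90.0),
}

# fraction of the base weight routed to the slow receptor of each class
NMDA_RATIO = 0.5
GABAB_RATIO = 0.2


# ---------------------------------------------------------------------------
# Top-level configuration
# ---------------------------------------------------------------------------

def default_config(
    n_microcolumns: int = 79,
    spacing: float = 50.0,
    footprint_diameter: float = 500.0,
    column_height: float = 2700.0,
) -> dict:
    """Build the default model configuration dictionary.

    Layer boundaries follow the relative thicknesses of human motor cortex
    (assumption: L2/3 occupies the upper ~37% below L1, L5 the middle, L6 the
    deepest band; exact boundaries were measured ex vivo and are not
    tabulated in an accessible form, so these fractions are flagged defaults).
    """
    h = column_height
    layers = [
        LayerSpec("L2/3", 0.10 * h, 0.45 * h, "L23_IT", "L23_BC"),
        LayerSpec("L5", 0.45 * h, 0.80 * h, "L5_PTN", "L5_BC"),
        LayerSpec("L6", 0.80 * h, 1.00 * h, "L6_IT", "L6_BC"),
    ]
    return {
        "geometry": {
            "spacing": spacing,
            "footprint_diameter": footprint_diameter,
            "column_height": column_height,
            "n_microcolumns": n_microcolumns,
        },
        "layers": layers,
        "rules": _default_rules(),
        "afferents": {
            "n_units": n_microcolumns,   # 79 per group under defaults
            "rate_hz": 0.25,
            "delay_mean_ms": 1.0,        # optimizable, Table-4 range [0.2, 2]
            "delay_sd_ms": 0.3,
        },
        "synaptic_delay_ms": 0.2,
        "neuron": copy.deepcopy(DEFAULT_NEURON),
        "receptors": copy.deepcopy(DEFAULT_RECEPTORS),
        "nmda_ratio": NMDA_RATIO,
        "gabab_ratio": GABAB_RATIO,
        "noise": {
            # independent per-neuron suprathreshold kicks (Poisson intervals)
            "amplitude_nA": 10.0,        # Table-4 range [1, 50]
            "rate_scalar": 0.5,          # Table-4 range [0, 1]
            "base_rate_hz": 5.0,         # desired firing rate the scalar multiplies
            "pulse_width_ms": 1.0,       # effective width of the charge kick
        },
    }


def config_to_yaml(config: dict) -> str:
    """Serialize a config to YAML (dataclasses flattened to dicts)."""
    def _plain(obj):
        if isinstance(obj, (LayerSpec, ConnectionRule)):
            return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        return obj
    return yaml.safe_dump(_plain(config), sort_keys=False)


def config_from_yaml(text: str) -> dict:
    """Inverse of :func:`config_to_yaml`."""
    raw = yaml.safe_load(text)
    raw["layers"] = [LayerSpec(**d) for d in raw["layers"]]
    raw["rules"] = [ConnectionRule(**d) for d in raw["rules"]]
    return raw
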