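"""Two-variable-at-a-time (TVAT) sensitivity analysis.

Every unordered pair of the configured parameters is varied on a full
factorial grid (21 equally spaced levels from 0 to each parameter's upper
bound by default) while the remaining parameters stay at their unified-model
values.  The wave-amplitude surface of each pair is fitted with an
elastic-net-regularized full bivariate cubic polynomial (9 non-constant
terms); parameters are range-normalized to [0, 1] and amplitudes
standardized before fitting.  Fits with R^2 < 0.5 are excluded.  The effect
size of a parameter on a wave is the sum of the absolute values of all
fitted coefficients of terms involving that parameter, accumulated over all
included pair fits — interaction terms count toward both parameters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.preprocessing import PolynomialFeatures

R2_THRESHOLD = 0.5
PREFERENTIAL_FACTOR = 1.5

# exponents of the 9 non-constant bivariate terms of total degree <= 3
_TERM_POWERS = [
    (1, 0), (0, 1), (2, 0), (1, 1), (0, 2),
    (3, 0), (2, 1), (1, 2), (0, 3),
]
TERM_NAMES = tuple(
    " ".join(filter(None, [
        f"x^{px}" if px > 1 else ("x" if px else ""),
        f"y^{py}" if py > 1 else ("y" if py else ""),
    ])) for px, py in _TERM_POWERS
)


# ---------------------------------------------------------------------------
# Design and enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TVATDesign:
    """Parameter subset, bounds and grid resolution of a TVAT campaign."""

    names: tuple                 # parameter names
    lower: np.ndarray            # grid minimum per parameter (0 by default)
    upper: np.ndarray            # grid maximum per parameter
    n_levels: int = 21

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            dupes = [n for n in self.names if list(self.names).count(n) > 1]
            raise ValueError(f"duplicate parameter names: {sorted(set(dupes))}")
        if len(self.names) < 2:
            raise ValueError("TVAT needs at least two parameters")
        if self.n_levels < 2:
            raise ValueError("need at least two levels")

    @property
    def n_params(self) -> int:
        return len(self.names)

    @property
    def n_pairs(self) -> int:
        n = self.n_params
        return n * (n - 1) // 2

    @property
    def n_simulations(self) -> int:
        return self.n_pairs * self.n_levels ** 2

    def levels(self, i: int) -> np.ndarray:
        return np.linspace(self.lower[i], self.upper[i], self.n_levels)


def default_tvat_design(parameter_space, n_levels: int = 21) -> TVATDesign:
    """The default 42-parameter subset: all 12 TMS activation proportions
    plus 30 synaptic weight scalars (6 afferent projections, the 18
    excitatory intracortical projections, and the 6 within-layer basket-cell
    projections).  Grids span 0 to each parameter's optimization maximum.
    """
    names = [n for n in parameter_space.names if n.startswith("activation:")]
    weights = [n for n in parameter_space.names if n.startswith("weight:")]
    for n in weights:
        proj = n.split(":", 1)[1]
        pre, post = proj.split("->")
        if pre.endswith("_AFF"):
            names.append(n)
        elif not pre.endswith("_BC"):
            names.append(n)
        else:
            # within-layer BC projections only (cross-layer BC edges excluded)
            if pre.split("_")[0] == post.split("_")[0]:
                names.append(n)
    upper = np.array([
        1.0 if n.startswith("activation:") else 10.0 for n in names
    ])
    return TVATDesign(tuple(names), np.zeros(len(names)), upper, n_levels)


def tvat_enumerate(design: TVATDesign):
    """Yield ((i, j), grid) for every unordered parameter pair.

    ``grid`` is an (n_levels^2, 2) full factorial of the two parameters'
    level values; remaining parameters are meant to stay at their
    unified-model values.
    """
    out = []
    for i, j in itertools.combinations(range(design.n_params), 2):
        gx, gy = np.meshgrid(design.levels(i), design.levels(j),
                             indexing="ij")
        out.append(((i, j), np.column_stack([gx.ravel(), gy.ravel()])))
    return out


def run_tvat(design: TVATDesign, response_fn, base_values: np.ndarray,
             pairs=None) -> pd.DataFrame:
    """Evaluate the response on every pair grid; long-format result.

    ``response_fn(values) -> {wave: amplitude}`` receives the full parameter
    vector with the active pair replaced by grid values.  ``pairs`` can
    restrict the run (resume support).  Columns: i, j, x, y, wave, amplitude.
    """
    base_values = np.asarray(base_values, dtype=float)
    rows = []
    for (i, j), grid in tvat_enumerate(design):
        if pairs is not None and (i, j) not in pairs:
            continue
        for x, y in grid:
            v = base_values.copy()
            v[i], v[j] = x, y
            amps = response_fn(v)
            for wave, amp in amps.items():
                rows.append((i, j, x, y, wave, amp))
    return pd.DataFrame(rows, columns=["i", "j", "x", "y", "wave",
                                       "amplitude"])


# ---------------------------------------------------------------------------
# Surface fitting
# ---------------------------------------------------------------------------

@dataclass
class SurfaceFit:
    """Cubic-polynomial fit of one (pair, wave) amplitude surface."""

    pair: tuple
    wave: str
    coefficients: dict = field(default_factory=dict)  # term name -> value
    r2: float = 0.0
    included: bool = False
    alpha: float = np.nan
    l1_ratio: float = np.nan


def fit_surface(
    levels_x, levels_y, amplitudes,
    bounds_x=(0.0, 1.0), bounds_y=(0.0, 1.0),
    pair=(0, 1), wave="",
    cv: int = 10,
    l1_ratios=(0.1, 0.5, 0.9),
    r2_threshold: float = R2_THRESHOLD,
    amp_stats: tuple | None = None,
) -> SurfaceFit:
    """Elastic-net cubic fit of one amplitude surface.

    Parameters are normalized to [0, 1] by their bound ranges and amplitudes
    standardized to zero mean, unit variance; the penalty is chosen by
    10-fold cross-validation.  ``amp_stats`` supplies the (mean, sd) used
    for standardization — in a full campaign they are the per-wave
    statistics across *all* pair grids, which keeps coefficient magnitudes
    comparable between pairs (standardizing each surface by its own spread
    would erase exactly the scale information the effect sizes accumulate).
    A constant surface carries no information and is returned as excluded
    rather than raising.
    """
    x = np.asarray(levels_x, dtype=float)
    y = np.asarray(levels_y, dtype=float)
    z = np.asarray(amplitudes, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("amplitudes must be finite on the full grid")
    if z.std() == 0:
        return SurfaceFit(pair, wave, {t: 0.0 for t in TERM_NAMES}, 0.0,
                          False)
    mean, sd = amp_stats if amp_stats is not None else (z.mean(), z.std())
    zn = (z - mean) / sd
    xn = (x - bounds_x[0]) / (bounds_x[1] - bounds_x[0])
    yn = (y - bounds_y[0]) / (bounds_y[1] - bounds_y[0])
    basis = PolynomialFeatures(degree=3, include_bias=False)
    X = basis.fit_transform(np.column_stack([xn, yn]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = ElasticNetCV(l1_ratio=list(l1_ratios), cv=cv, alphas=30,
                             max_iter=5000)
        model.fit(X, zn)
        r2 = float(model.score(X, zn))
    coefs = dict(zip(TERM_NAMES, model.coef_))
    return SurfaceFit(tuple(pair), wave, coefs, r2, r2 >= r2_threshold,
                      float(model.alpha_), float(model.l1_ratio_))


def fit_all_surfaces(results: pd.DataFrame, design: TVATDesign,
                     cv: int = 10) -> list[SurfaceFit]:
    """Fit every (pair, wave) surface in a long-format TVAT result table.

    Amplitudes are standardized per wave across the entire campaign so that
    fitted coefficients — and hence effect sizes — are on one common scale
    for all pairs.
    """
    stats = {
        wave: (float(sub["amplitude"].mean()), float(sub["amplitude"].std()))
        for wave, sub in results.groupby("wave")
    }
    fits = []
    for (i, j), sub in results.groupby(["i", "j"]):
        bx = (design.lower[i], design.upper[i])
        by = (design.lower[j], design.upper[j])
        for wave, ws in sub.groupby("wave"):
            fits.append(fit_surface(
                ws["x"], ws["y"], ws["amplitude"], bx, by,
                pair=(i, j), wave=wave, cv=cv,
                amp_stats=stats[wave],
            ))
    return fits


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

def _partial_effects(fit: SurfaceFit) -> tuple[float, float]:
    """|coefficient| sums of terms involving x and involving y.

    Interaction terms contribute to both parameters of the pair.
    """
    ex = ey = 0.0
    for (px, py), name in zip(_TERM_POWERS, TERM_NAMES):
        c = abs(fit.coefficients.get(name, 0.0))
        if px > 0:
            ex += c
        if py > 0:
            ey += c
    return ex, ey


def effect_sizes(fits: list[SurfaceFit], names) -> pd.DataFrame:
    """Total effect size per (parameter, wave): sum of partial effects over
    all included pair fits containing the parameter.  Excluded fits
    contribute nothing.
    """
    waves = sorted({f.wave for f in fits})
    table = pd.DataFrame(0.0, index=list(names), columns=waves)
    for f in fits:
        if not f.included:
            continue
        ex, ey = _partial_effects(f)
        i, j = f.pair
        table.loc[names[i], f.wave] += ex
        table.loc[names[j], f.wave] += ey
    table["total"] = table[waves].sum(axis=1)
    return table


def preferential_flags(effects_by_wave: pd.DataFrame) -> pd.DataFrame:
    """Flag parameters whose largest per-wave effect is >= 1.5x the second.

    An all-zero row is not preferential; a positive maximum with a zero
    runner-up is (the ratio is unbounded).
    """
    waves = [c for c in effects_by_wave.columns if c != "total"]
    if len(waves) < 2:
        raise ValueError("need at least two waves")
    rows = []
    for name, row in effects_by_wave[waves].iterrows():
        vals = row.to_numpy(dtype=float)
        order = np.argsort(vals)[::-1]
        top, second = vals[order[0]], vals[order[1]]
        pref = top > 0 and top >= PREFERENTIAL_FACTOR * second
        rows.append((name, bool(pref), waves[order[0]] if pref else None))
    return pd.DataFrame(rows, columns=["parameter", "preferential",
                                       "preferred_wave"]).set_index(
                                           "parameter")


def grouped_sensitivity(effects_by_wave: pd.DataFrame,
                        grouping: dict) -> pd.DataFrame:
    """Mean effect size per (wave, group) for a partition of the parameters.

    ``grouping`` maps group name -> list of parameter names (e.g. activation
    vs synaptic strength, feedforward vs feedback, excitatory vs
    inhibitory).
    """
    waves = [c for c in effects_by_wave.columns if c != "total"]
    out = {}
    for group, members in grouping.items():
        if not len(members):
            raise ValueError(f"group '{group}' is empty")
        missing = [m for m in members if m not in effects_by_wave.index]
        if missing:
            raise ValueError(f"group '{group}' references unknown "
                             f"parameters {missing}")
        out[group] = effects_by_wave.loc[list(members), waves].mean(axis=0)
    return pd.DataFrame(out).T


def default_groupings(names) -> dict:
    """The eight dichotomies used to summarize sensitivities.

    Activation vs synaptic strength; within activation, feedforward
    (afferent terminals) vs feedback (cortical neurons) and excitatory vs
    inhibitory; the analogous splits for synaptic weights.
    """
    act = [n for n in names if n.startswith("activation:")]
    wt = [n for n in names if n.startswith("weight:")]
    act_ff = [n for n in act if n.endswith("_AFF")]
    act_fb = [n for n in act if not n.endswith("_AFF")]
    wt_ff = [n for n in wt if "_AFF->" in n]
    wt_fb = [n for n in wt if "_AFF->" not in n]

    def _exc(n):
        src = n.split(":", 1)[1].split("->")[0]
        return not src.endswith("_BC")

    return {
        "activation_vs_weight": {"activation": act, "weight": wt},
        "activation_ff_vs_fb": {"feedforward": act_ff, "feedback": act_fb},
        "weight_ff_vs_fb": {"feedforward": wt_ff, "feedback": wt_fb},
        "excitatory_vs_inhibitory": {
            "excitatory": [n for n in act + wt if _exc(n)],
            "inhibitory": [n for n in act + wt if not _exc(n)],
        },
        "act_ff_exc_vs_inh": {
            "excitatory_targets": [n for n in act_ff
                                   if not n.split(":")[1][:-4].endswith("_BC")],
            "inhibitory_targets": [n for n in act_ff
                                   if n.split(":")[1][:-4].endswith("_BC")],
        },
        "wt_ff_exc_vs_inh": {
            "excitatory_targets": [n for n in wt_ff
                                   if not n.split("->")[1].endswith("_BC")],
            "inhibitory_targets": [n for n in wt_ff
                                   if n.split("->")[1].endswith("_BC")],
        },
        "act_fb_exc_vs_inh": {
            "excitatory": [n for n in act_fb if _exc(n)],
            "inhibitory": [n for n in act_fb if not _exc(n)],
        },
        "wt_fb_exc_vs_inh": {
            "excitatory": [n for n in wt_fb if _exc(n)],
            "inhibitory": [n for n in wt_fb if not _exc(n)],
        },
    }
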