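"""Particle swarm optimization with scheduled hyperparameters.

The swarm is Sobol-initialized inside the parameter bounds, uses local
(ring) neighborhoods sized at 5% of the swarm, and evolves its five
hyperparameters — inertial, cognitive and social weights, velocity gain,
and Gaussian mutation noise — along sigmoid schedules

    y(x) = A + K / (1 + exp((a x - b N) / N))

so the search transitions from an exploratory stage (high inertia,
cognition, gain and noise) to a convergent stage (high social weight) over
roughly the first third of the run.  Positions that leave the bounds are
reflected back with a random damping factor:

    x_reflect = bound - U(0,1) * (x_new - bound).

Note on schedule direction: with the published constants the sigmoid as
printed starts each weight at A + K and ends at A, which makes the
cognitive weight *low* during early iterations — the opposite of the
described exploration/convergence progression.  Both conventions are
implemented; the default ``direction="described"`` flips the exponent's
sign so the curves match the described behavior, and
``direction="as_printed"`` evaluates the formula literally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import qmc


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleSpec:
    """One sigmoid-scheduled hyperparameter."""

    A: float                  # offset (late-stage value in described mode)
    K: float                  # amplitude and direction
    a: float                  # transition steepness
    b: float                  # transition midpoint (iteration = b N / a)
    N: int = 300              # total iterations
    direction: str = "described"   # or "as_printed"

    def __post_init__(self):
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.direction not in ("described", "as_printed"):
            raise ValueError(f"unknown direction '{self.direction}'")


def schedule_weight(x: float, spec: ScheduleSpec) -> float:
    """Evaluate the sigmoid schedule at iteration ``x`` in [0, N]."""
    expo = (spec.a * x - spec.b * spec.N) / spec.N
    if spec.direction == "described":
        expo = -expo
    return spec.A + spec.K / (1.0 + np.exp(expo))


# Published schedule constants (A, K, a, b) and whether the literal formula
# runs opposite to the described exploration->convergence progression.  With
# these constants the printed sigmoid starts at A + K and ends at A, which is
# correct for the inertial/gain/noise weights (high early, low late) but
# backwards for the cognitive and social weights.
_SCHEDULE_TABLE = {
    "cognitive": (2.5, -2.4, 20.0, 7.2, True),
    "social": (0.1, 2.4, 20.0, 7.2, True),
    "inertial": (0.5, 2.0, 15.0, 4.2, False),
    "gain": (0.5, 1.5, 10.0, 2.4, False),
    "noise": (0.005, 0.195, 15.0, 4.2, False),
}


def default_schedules(n_iterations: int = 300,
                      direction: str = "described") -> dict:
    """Schedules for all five weights at a given run length.

    ``direction="described"`` (default) flips the exponent sign for the
    cognitive and social weights so every curve follows the described
    exploration-to-convergence progression; ``"as_printed"`` evaluates the
    published formula literally for all five.
    """
    out = {}
    for name, (A, K, a, b, flips) in _SCHEDULE_TABLE.items():
        d = "described" if (direction == "described" and flips) \
            else "as_printed"
        out[name] = ScheduleSpec(A, K, a, b, n_iterations, d)
    return out


# ---------------------------------------------------------------------------
# Boundary handling
# ---------------------------------------------------------------------------

def reflect(position: np.ndarray, lower: np.ndarray, upper: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Damped reflection of out-of-bounds coordinates.

    Each overshooting coordinate is mapped to
    ``bound - U(0,1) * (x - bound)`` with a fresh uniform draw per
    coordinate; in-bounds coordinates are untouched.  The result is clipped
    as a safeguard against overshoots larger than the parameter range.
    """
    x = np.asarray(position, dtype=float).copy()
    over = x > upper
    if over.any():
        u = rng.uniform(size=int(over.sum()))
        x[over] = upper[over] - u * (x[over] - upper[over])
    under = x < lower
    if under.any():
        u = rng.uniform(size=int(under.sum()))
        x[under] = lower[under] - u * (x[under] - lower[under])
    return np.clip(x, lower, upper)


# ---------------------------------------------------------------------------
# Swarm
# ---------------------------------------------------------------------------

@dataclass
class Swarm:
    positions: np.ndarray          # (n, d)
    velocities: np.ndarray         # (n, d)
    pbest_pos: np.ndarray          # (n, d)
    pbest_err: np.ndarray          # (n,)
    neighborhoods: list            # index arrays, ring topology
    lower: np.ndarray
    upper: np.ndarray

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def neighborhood_best(self, i: int, hub: int | None = None) -> np.ndarray:
        """Best personal best among particle i's neighbors (plus the hub).

        The neighborhood realizes a star topology: each particle sees a
        local segment sized at 5% of the swarm, and the swarm's current
        best particle acts as the star's hub, visible to everyone.
        """
        nbr = self.neighborhoods[i]
        if hub is None:
            hub = int(np.argmin(self.pbest_err))
        best = nbr[np.argmin(self.pbest_err[nbr])]
        if self.pbest_err[hub] < self.pbest_err[best]:
            best = hub
        return self.pbest_pos[best]


def _ring_neighborhoods(n: int, fraction: float = 0.05) -> list:
    k = max(1, int(round(fraction * n)))
    half = k // 2
    out = []
    for i in range(n):
        idx = (np.arange(i - half, i - half + max(k, 1)) % n)
        out.append(np.unique(np.append(idx, i)))
    return out


def init_swarm(n_particles: int, lower, upper, seed: int = 0,
               neighborhood_fraction: float = 0.05) -> Swarm:
    """Sobol-initialized swarm with zero velocities."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = len(lower)
    sampler = qmc.Sobol(d, scramble=True, seed=seed)
    m = int(np.ceil(np.log2(max(n_particles, 2))))
    pts = sampler.random_base2(m)[:n_particles]
    positions = qmc.scale(pts, lower, upper)
    return Swarm(
        positions=positions,
        velocities=np.zeros_like(positions),
        pbest_pos=positions.copy(),
        pbest_err=np.full(n_particles, np.inf),
        neighborhoods=_ring_neighborhoods(n_particles, neighborhood_fraction),
        lower=lower,
        upper=upper,
    )


def pso_step(swarm: Swarm, errors: np.ndarray, iteration: int,
             schedules: dict, rng: np.random.Generator,
             vmax_fraction: float = 0.1) -> None:
    """One in-place swarm update after the objectives have been evaluated.

    Personal bests absorb finite improvements (particles with non-finite
    objectives keep their previous best).  The new velocity is the
    inertia-damped previous velocity plus the gain-scaled cognitive and
    social pulls, each pull scaled per coordinate by an independent U(0,1)
    draw; velocities are clamped to ``vmax_fraction`` of the parameter range
    per coordinate (a standard stabilizer — the published update has no
    explicit clamp, and without one the early high-inertia stage can grow
    velocities beyond any useful scale).  Positions then receive zero-mean
    Gaussian mutation noise before the reflecting boundary is applied.
    """
    errors = np.asarray(errors, dtype=float)
    finite = np.isfinite(errors)
    improved = finite & (errors < swarm.pbest_err)
    swarm.pbest_err[improved] = errors[improved]
    swarm.pbest_pos[improved] = swarm.positions[improved]
    if not finite.all():
        warnings.warn(
            f"iteration {iteration}: {int((~finite).sum())} particle(s) "
            "returned non-finite objectives; keeping previous bests"
        )

    w = schedule_weight(iteration, schedules["inertial"])
    c = schedule_weight(iteration, schedules["cognitive"])
    s = schedule_weight(iteration, schedules["social"])
    gain = schedule_weight(iteration, schedules["gain"])
    noise = schedule_weight(iteration, schedules["noise"])

    n, d = swarm.positions.shape
    vmax = vmax_fraction * (swarm.upper - swarm.lower)
    hub = int(np.argmin(swarm.pbest_err))
    for i in range(n):
        r1 = rng.uniform(size=d)
        r2 = rng.uniform(size=d)
        nbest = swarm.neighborhood_best(i, hub)
        v = (w * swarm.velocities[i]
             + gain * (c * r1 * (swarm.pbest_pos[i] - swarm.positions[i])
                       + s * r2 * (nbest - swarm.positions[i])))
        v = np.clip(v, -vmax, vmax)
        x = swarm.positions[i] + v + rng.normal(0.0, noise, d)
        swarm.velocities[i] = v
        swarm.positions[i] = reflect(x, swarm.lower, swarm.upper, rng)


@dataclass
class PSOResult:
    best_position: np.ndarray
    best_error: float
    history: list                    # per-iteration dicts
    pbest_pos: np.ndarray
    pbest_err: np.ndarray


def save_checkpoint(path, swarm: Swarm, iteration: int, history: list,
                    rng: np.random.Generator) -> None:
    """Persist the full swarm state (including RNG) as JSON."""
    state = {
        "iteration": iteration,
        "positions": swarm.positions.tolist(),
        "velocities": swarm.velocities.tolist(),
        "pbest_pos": swarm.pbest_pos.tolist(),
        "pbest_err": swarm.pbest_err.tolist(),
        "lower": swarm.lower.tolist(),
        "upper": swarm.upper.tolist(),
        "history": history,
        "rng_state": rng.bit_generator.state,
    }
    Path(path).write_text(json.dumps(state))


def load_checkpoint(path):
    """Restore (swarm, next_iteration, history, rng) from a checkpoint."""
    state = json.loads(Path(path).read_text())
    n = len(state["positions"])
    swarm = Swarm(
        positions=np.asarray(state["positions"], dtype=float),
        velocities=np.asarray(state["velocities"], dtype=float),
        pbest_pos=np.asarray(state["pbest_pos"], dtype=float),
        pbest_err=np.asarray(state["pbest_err"], dtype=float),
        neighborhoods=_ring_neighborhoods(n),
        lower=np.asarray(state["lower"], dtype=float),
        upper=np.asarray(state["upper"], dtype=float),
    )
    rng = np.random.default_rng()
    rng.bit_generator.state = state["rng_state"]
    return swarm, state["iteration"] + 1, state["history"], rng


def run_pso(
    objective_fn,
    n_particles: int,
    n_iterations: int,
    lower,
    upper,
    schedules: dict | None = None,
    seed: int = 0,
    callback=None,
    checkpoint_path=None,
    resume: bool = False,
) -> PSOResult:
    """Full optimization loop; deterministic given the seed.

    ``objective_fn`` maps a position vector to a scalar error.  A failing or
    non-finite evaluation is retried once, after which the particle is
    frozen for the iteration (its previous best stands).  The per-iteration
    history records the swarm's best error so far.  With
    ``checkpoint_path`` the swarm state is written after every iteration;
    ``resume=True`` continues from an existing checkpoint and reproduces
    the uninterrupted run exactly.
    """
    if schedules is None:
        schedules = default_schedules(n_iterations)
    if resume and checkpoint_path and Path(checkpoint_path).exists():
        swarm, start, history, rng = load_checkpoint(checkpoint_path)
    else:
        rng = np.random.default_rng(seed)
        swarm = init_swarm(n_particles, lower, upper, seed=seed)
        history = []
        start = 0
    for it in range(start, n_iterations):
        errors = np.empty(n_particles)
        for i in range(n_particles):
            val = np.nan
            for _ in range(2):       # one retry on failure
                try:
                    val = float(objective_fn(swarm.positions[i]))
                except Exception:
                    val = np.nan
                if np.isfinite(val):
                    break
            errors[i] = val
        pso_step(swarm, errors, it, schedules, rng)
        best = int(np.argmin(swarm.pbest_err))
        history.append(dict(
            iteration=it,
            best_error=float(swarm.pbest_err[best]),
            mean_error=float(np.nanmean(errors)),
        ))
        if checkpoint_path is not None:
            save_checkpoint(checkpoint_path, swarm, it, history, rng)
        if callback is not None:
            callback(it, swarm)
    best = int(np.argmin(swarm.pbest_err))
    return PSOResult(
        best_position=swarm.pbest_pos[best].copy(),
        best_error=float(swarm.pbest_err[best]),
        history=history,
        pbest_pos=swarm.pbest_pos.copy(),
        pbest_err=swarm.pbest_err.copy(),
    )


# ---------------------------------------------------------------------------
# Unified-model interpolation search
# ---------------------------------------------------------------------------

@dataclass
class UnifiedSearchResult:
    weights: np.ndarray
    errors_dplus: np.ndarray
    errors_dminus: np.ndarray
    costs: np.ndarray
    selected_weight: float
    selected_cost: float


def unified_model_search(
    params_dplus: np.ndarray,
    params_dminus: np.ndarray,
    evaluate_fn,
    grid,
    response_specific_mask: np.ndarray | None = None,
) -> UnifiedSearchResult:
    """Interpolate between two fitted parameter vectors and pick the blend
    that reproduces both response types without favoring either.

    For each interpolation weight w the shared coordinates become
    ``(1-w) * dplus + w * dminus``; coordinates flagged in
    ``response_specific_mask`` (typically the TMS activation proportions)
    keep their subject-specific values.  ``evaluate_fn(vector, response)``
    returns the total error for response ``"D+"`` or ``"D-"``; the cost of a
    weight is ``mean(e+, e-) + |e+ - e-|`` and the grid argmin is selected.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("interpolation grid is empty")
    pd_, pm = (np.asarray(params_dplus, dtype=float),
               np.asarray(params_dminus, dtype=float))
    if pd_.shape != pm.shape:
        raise ValueError("parameter vectors must share the enumeration")
    mask = (np.zeros(len(pd_), dtype=bool)
            if response_specific_mask is None
            else np.asarray(response_specific_mask, dtype=bool))
    ep = np.empty(len(grid))
    em = np.empty(len(grid))
    for k, w in enumerate(grid):
        base = (1.0 - w) * pd_ + w * pm
        vplus = base.copy()
        vplus[mask] = pd_[mask]
        vminus = base.copy()
        vminus[mask] = pm[mask]
        ep[k] = float(evaluate_fn(vplus, "D+"))
        em[k] = float(evaluate_fn(vminus, "D-"))
    costs = (ep + em) / 2.0 + np.abs(ep - em)
    sel = int(np.argmin(costs))
    return UnifiedSearchResult(grid, ep, em, costs,
                               float(grid[sel]), float(costs[sel]))


# ---------------------------------------------------------------------------
# Robustness reporting
# ---------------------------------------------------------------------------

def normalized_solution_distance(a, b, lower, upper) -> float:
    """Euclidean distance between solutions over the maximal possible one."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    span = np.asarray(upper, dtype=float) - np.asarray(lower, dtype=float)
    return float(np.linalg.norm(a - b) / np.linalg.norm(span))


def pareto_front(points: np.ndarray) -> np.ndarray:
    """Boolean mask of non-dominated rows (minimization on every column).

    Used post hoc on category-summed (4-D) objective groups of saved swarm
    history, not inside the update loop.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not keep[i]:
            continue
        dominates = (
            (pts <= pts[i]).all(axis=1) & (pts < pts[i]).any(axis=1)
        )
        if dominates.any():
            keep[i] = False
    return keep
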