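"""Estimation of the five free rates by simulated annealing.

The free parameters are the attachment, endocytosis and lysis rates, the
endosome degradation rate and the GFP maturation rate (k_A, k_E, k_L, d_E,
k_M).  Each candidate is scored against five experimental determinants: the
mean number of lipoplexes attached per cell, the dose-response curve, the
mean and width of the expression-onset-time distribution, and the mean
maximum GFP level.  Because every determinant is an ensemble statistic of a
stochastic model, the objective is noisy; annealing uses Metropolis
acceptance exp(-delta/T) with geometric cooling and a fresh simulation
sub-seed per evaluation so the optimizer cannot overfit one realization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ensemble import simulate_ensemble
from .expression import fit_onset_maxgfp, onset_distribution
from .network import build_network
from .parameters import ExperimentDesign, RateConstants
from .response import dose_response

__all__ = [
    "FREE_PARAMS",
    "DEFAULT_BOUNDS",
    "GoalSummary",
    "AnnealConfig",
    "FitResult",
    "compute_goals",
    "objective",
    "metropolis_accept",
    "anneal",
]

FREE_PARAMS = ("k_A", "k_E", "k_L", "d_E", "k_M")

#: search bounds (1/h), spanning the literature ranges of the five rates
DEFAULT_BOUNDS = {
    "k_A": (1e-3, 10.0),
    "k_E": (1e-3, 10.0),
    "k_L": (1e-3, 10.0),
    "d_E": (1e-3, 10.0),
    "k_M": (0.5, 20.0),
}


@dataclass
class GoalSummary:
    """The five optimization determinants."""

    mean_attached: float
    dose_response: np.ndarray      # TE on the dose grid
    onset_mean: float
    onset_width: float
    mean_maxgfp: float
    unconverged_fraction: float = 0.0

    def finite(self) -> bool:
        scalars = (self.mean_attached, self.onset_mean, self.onset_width, self.mean_maxgfp)
        return (all(map(math.isfinite, scalars))
                and np.all(np.isfinite(self.dose_response))
                and np.all((self.dose_response >= 0) & (self.dose_response <= 1)))


def compute_goals(
    params: dict,
    design: ExperimentDesign,
    n_cells: int = 1000,
    seed=0,
    dose_grid=(0.25, 0.5, 1.0, 2.0, 4.0),
    dose_cells: int = 300,
    variant: str = "multilipoplex",
    fixed: RateConstants | None = None,
) -> GoalSummary:
    """Simulate the determinants for one candidate parameter set.

    ``params`` holds the five free rates; the fixed rates are taken from
    ``fixed`` (defaults to the standard literature values).  Hybrid-engine
    ensembles are used: one at the design dose for attachment/onset/maxGFP,
    one sweep over ``dose_grid`` for the dose-response determinant.
    """
    unknown = set(params) - set(FREE_PARAMS)
    if unknown:
        raise ValueError(f"unknown free parameters {sorted(unknown)}")
    base = fixed if fixed is not None else RateConstants(k_A=1, k_E=1, k_L=1, d_E=1, k_M=1)
    rates = base.replace(**{k: float(v) for k, v in params.items()})
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    main_seed, dose_seed = ss.spawn(2)

    net = build_network(variant, rates, design)
    ens = simulate_ensemble(net, n_cells, seed=main_seed, engine="hybrid")
    # onsets trail the wash by at most a dozen mean delivery times; a bounded
    # search window keeps the per-cell fit cheap inside the optimizer loop
    t0_max = min(design.t_end, design.t_inc + 14.0)
    fits = [fit_onset_maxgfp(ens.times[::2], ens.gfp[i, ::2], rates, coarse=90, t0_max=t0_max)
            for i in np.flatnonzero(ens.transfected)]
    converged = [f for f in fits if f.converged]
    if len(converged) >= 2:
        onset = onset_distribution(converged)
        onset_mean, onset_width = onset.location, onset.width
        mean_maxgfp = float(np.mean([f.maxGFP for f in converged]))
    else:
        onset_mean = onset_width = mean_maxgfp = float("nan")
    te = dose_response(variant, rates, design, dose_grid, dose_cells, seed=dose_seed)
    return GoalSummary(
        mean_attached=ens.mean_attached,
        dose_response=np.array([p.TE for p in te]),
        onset_mean=onset_mean,
        onset_width=onset_width,
        mean_maxgfp=mean_maxgfp,
        unconverged_fraction=(1.0 - len(converged) / len(fits)) if fits else 1.0,
    )


_SCALARS = ("mean_attached", "onset_mean", "onset_width", "mean_maxgfp")


def objective(goals: GoalSummary, targets: GoalSummary, weights: dict | None = None) -> float:
    """Weighted sum of squared relative deviations over the five determinants.

    The dose-response determinant contributes the mean squared TE deviation
    across the grid (TE is already a bounded, dimensionless fraction).
    Returns 0 iff all determinants match; +inf for non-finite candidate
    goals (e.g. no converged onset fits).
    """
    if weights is None:
        weights = {}
    unknown = set(weights) - set(_SCALARS) - {"dose_response"}
    if unknown:
        raise ValueError(f"unknown weight keys {sorted(unknown)}")
    for name in _SCALARS:
        if not math.isfinite(getattr(targets, name)):
            raise ValueError(f"target determinant {name} is not finite")
    if np.shape(goals.dose_response) != np.shape(targets.dose_response):
        raise ValueError("dose_response grids of goals and targets differ in shape")
    if not goals.finite():
        return float("inf")
    score = 0.0
    for name in _SCALARS:
        g, t = getattr(goals, name), getattr(targets, name)
        ref = t if t != 0 else 1.0
        score += weights.get(name, 1.0) * ((g - t) / ref) ** 2
    score += weights.get("dose_response", 1.0) * float(
        np.mean((goals.dose_response - targets.dose_response) ** 2)
    )
    return score


@dataclass
class AnnealConfig:
    x0: dict
    design: ExperimentDesign
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    t0: float | None = None          # None -> set from a pilot scan
    cooling: float = 0.95
    steps: int = 300
    sigma: float = 0.2               # log-space proposal SD
    n_cells: int = 1000
    dose_grid: tuple = (0.25, 0.5, 1.0, 2.0, 4.0)
    dose_cells: int = 300
    variant: str = "multilipoplex"
    fixed: RateConstants | None = None
    weights: dict | None = None
    seed: int = 0
    pilot: int = 20
    final_n_cells: int | None = None

    def __post_init__(self):
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling factor must be in (0, 1)")
        if self.n_cells < 100:
            raise ValueError("ensemble size per evaluation must be >= 100")
        for k, (lo, hi) in self.bounds.items():
            if lo <= 0 or hi <= lo:
                raise ValueError(f"bounds for {k} must satisfy 0 < lo < hi")
        missing = set(FREE_PARAMS) - set(self.x0)
        if missing:
            raise ValueError(f"x0 missing parameters {sorted(missing)}")


@dataclass
class FitResult:
    best_params: dict
    best_score: float
    trace: list                       # (step, score, accepted)
    n_evals: int
    final_goals: GoalSummary | None = None


def metropolis_accept(delta: float, temperature: float, u: float) -> bool:
    """Boltzmann acceptance: always for improvements, else prob exp(-d/T)."""
    if delta <= 0:
        return True
    if temperature <= 0:
        return False
    return u < math.exp(-delta / temperature)


def _reflect(v, lo, hi):
    # reflect a log-space coordinate into [lo, hi]
    span = hi - lo
    v = (v - lo) % (2 * span)
    return lo + (span - abs(v - span) if v > span else v)


def _propose(x, bounds, sigma, rng):
    out = {}
    for k, v in x.items():
        lo, hi = np.log(bounds[k])
        step = np.log(v) + rng.normal(0.0, sigma)
        out[k] = float(np.exp(_reflect(step, lo, hi)))
    return out


def anneal(config: AnnealConfig, targets: GoalSummary, score_fn=None) -> FitResult:
    """Simulated annealing over the five free rates.

    ``score_fn(params, seed) -> float`` defaults to simulating the
    determinants with :func:`compute_goals` and scoring them with
    :func:`objective` against ``targets``.  Fully reproducible given
    ``config.seed``.
    """
    if score_fn is None:
        def score_fn(params, seed):
            goals = compute_goals(
                params, config.design, n_cells=config.n_cells, seed=seed,
                dose_grid=config.dose_grid, dose_cells=config.dose_cells,
                variant=config.variant, fixed=config.fixed,
            )
            return objective(goals, targets, config.weights)

    ss = np.random.SeedSequence(config.seed)
    walk_rng = np.random.default_rng(ss.spawn(1)[0])
    eval_seeds = iter(ss.spawn(config.pilot + 2 * config.steps + 4))
    n_evals = 0

    def evaluate(params):
        nonlocal n_evals
        n_evals += 1
        return score_fn(params, next(eval_seeds))

    x = {k: float(config.x0[k]) for k in FREE_PARAMS}
    s = evaluate(x)
    best_x, best_s = dict(x), s

    if config.t0 is not None:
        T = config.t0
    else:
        deltas = []
        for _ in range(config.pilot):
            cand = _propose(x, config.bounds, config.sigma, walk_rng)
            deltas.append(abs(evaluate(cand) - s))
        T = float(np.median(deltas)) or 1e-3

    trace = [(0, s, True)]
    for step in range(1, config.steps + 1):
        cand = _propose(x, config.bounds, config.sigma, walk_rng)
        s_new = evaluate(cand)
        accepted = metropolis_accept(s_new - s, T, walk_rng.random())
        if accepted:
            x, s = cand, s_new
        if s_new < best_s:
            best_x, best_s = dict(cand), s_new
        trace.append((step, s_new, accepted))
        T *= config.cooling

    final_goals = None
    if config.final_n_cells:
        final_goals = compute_goals(
            best_x, config.design, n_cells=config.final_n_cells,
            seed=next(eval_seeds), dose_grid=config.dose_grid,
            dose_cells=config.dose_cells, variant=config.variant,
            fixed=config.fixed,
        )
    return FitResult(best_params=best_x, best_score=best_s, trace=trace,
                     n_evals=n_evals, final_goals=final_goals)
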