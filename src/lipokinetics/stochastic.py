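"""Exact stochastic simulation (Gillespie direct method).

Propensities are recomputed from the current integer state at every step,
including the pit-normalised attachment channels.  The wash is a timed
event: by default the remaining external lipoplexes are removed at t_inc
(large-k_W limit); the explicit finite washing rate is available for
validation.  Identical seeds give bit-identical event sequences.
"""

from __future__ import annotations

import warnings

import numpy as np

from .network import ReactionNetwork
from .trajectory import CellTrajectory

__all__ = ["simulate_ssa", "draw_initial_count", "EventBudgetWarning"]


class EventBudgetWarning(UserWarning):
    """Raised (as a warning) when a simulation exceeds its event budget."""


def draw_initial_count(L_ex0: float, mode: str, rng: np.random.Generator) -> int:
    """Integer initial external lipoplex count for one cell.

    ``fractional`` (default elsewhere) is stochastic rounding,
    floor(L_ex0) + Bernoulli(frac): it preserves the mean dose exactly while
    adding the least possible variance.  ``round`` and ``poisson`` are the
    deterministic and fully Poissonised alternatives.
    """
    if mode == "fractional":
        base = int(np.floor(L_ex0))
        frac = L_ex0 - base
        return base + int(rng.random() < frac)
    if mode == "round":
        return int(round(L_ex0))
    if mode == "poisson":
        return int(rng.poisson(L_ex0))
    raise ValueError(f"unknown init_mode {mode!r}")


def simulate_ssa(
    network: ReactionNetwork,
    seed=None,
    rng: np.random.Generator | None = None,
    wash_mode: str = "instant",
    init_mode: str = "fractional",
    record_events: bool = True,
    max_events: int = 5_000_000,
) -> CellTrajectory:
    """Run one exact SSA realisation of ``network`` on its output grid."""
    if wash_mode not in ("instant", "exact"):
        raise ValueError(f"unknown wash_mode {wash_mode!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    cn = network.compiled()
    design = network.design
    grid = design.times
    G = len(grid)
    x = np.zeros(cn.n_species, dtype=np.int64)
    x[cn.lex] = draw_initial_count(design.L_ex0, init_mode, rng)
    L0 = int(x[cn.lex])
    counts = np.empty((G, cn.n_species), dtype=np.int64)
    fires = np.zeros(len(cn.k), dtype=np.int64)
    events: list[tuple[float, str]] = []
    event_times: list[list[float]] = [[] for _ in cn.labels]
    washed = 0
    n_events = 0
    warned = False
    gi = 0
    t = 0.0

    # (phase_end, wash reaction active): wash reaction only fires in phase 2
    # of "exact" mode; "instant" mode empties L_ex between the phases.
    phases = [(design.t_inc, False), (design.t_end, wash_mode == "exact")]

    for phase, (phase_end, wash_on) in enumerate(phases):
        while t < phase_end:
            a = cn.propensities(x.astype(np.float64), wash_on)
            total = a.sum()
            if total <= 0.0:
                break
            t_next = t + rng.exponential(1.0 / total)
            if t_next >= phase_end:
                # thinning: no reaction fires before the phase boundary
                t = phase_end
                break
            while gi < G and grid[gi] < t_next:
                counts[gi] = x
                gi += 1
            j = int(np.searchsorted(np.cumsum(a), rng.random() * total, side="right"))
            j = min(j, len(a) - 1)
            x += cn.delta[j]
            fires[j] += 1
            t = t_next
            if cn.record_mask[j]:
                event_times[j].append(t)
                if record_events:
                    events.append((t, cn.labels[j]))
            n_events += 1
            if n_events > max_events and not warned:
                warnings.warn(
                    f"SSA exceeded the event budget of {max_events} events "
                    f"(t={t:.3g} h); continuing",
                    EventBudgetWarning,
                )
                warned = True
        # advance the sample pointer through any quiescent stretch
        while gi < G and grid[gi] < phase_end:
            counts[gi] = x
            gi += 1
        t = phase_end
        if phase == 0 and wash_mode == "instant":
            washed = int(x[cn.lex])
            x[cn.lex] = 0
    while gi < G:
        counts[gi] = x
        gi += 1

    derived = _delivery_record(cn, fires, event_times, washed, L0, design)
    derived["n_events"] = n_events
    return CellTrajectory(
        times=grid, species=list(cn.species), counts=counts, engine="ssa",
        events=events if record_events else None, derived=derived,
    )


def _delivery_record(cn, fires, event_times, washed, L0, design):
    """Per-cell bookkeeping summaries from the reaction firing counts."""
    attach_ids = [j for j, lbl in enumerate(cn.labels) if lbl.startswith("attach")]
    endo_ids = cn.ids_with_prefix("endocytosis")
    lysis_ids = cn.ids_with_prefix("lysis")
    deg_ids = cn.ids_with_prefix("endosome_degradation")
    unpack = cn.label_index.get("unpacking")
    dl = cn.label_index.get("lipoplex_degradation")
    wash_fires = int(fires[cn.wash_ids].sum()) if len(cn.wash_ids) else 0

    def cargo(ids):
        # lipoplexes carried by the endosome the reaction consumes
        total = 0
        for j in ids:
            lbl = cn.labels[j]
            size = int(lbl.rsplit("_", 1)[1]) if lbl.rsplit("_", 1)[-1].isdigit() else 1
            total += size * int(fires[j])
        return total

    release_times = sorted(event_times[unpack]) if unpack is not None else []
    return {
        "L_ex0": L0,
        "washed": washed + wash_fires,
        "n_attached": int(sum(fires[j] for j in attach_ids)),
        "attach_times": sorted(tt for j in attach_ids for tt in event_times[j]),
        "n_endosomes": int(fires[endo_ids].sum()),
        "endocytosis_times": sorted(tt for j in endo_ids for tt in event_times[j]),
        "n_lysed": int(fires[lysis_ids].sum()),
        "lysis_times": sorted(tt for j in lysis_ids for tt in event_times[j]),
        "n_degraded": int(fires[deg_ids].sum()),
        "degraded_cargo": cargo(deg_ids),
        "released_lipoplexes": cargo(lysis_ids),
        "n_packets": int(fires[unpack]) if unpack is not None else 0,
        "release_events": [(tt, design.S) for tt in release_times],
        "n_lipoplex_degraded": int(fires[dl]) if dl is not None else 0,
        "fires": fires.copy(),
    }
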