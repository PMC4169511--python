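"""Dose-response curves and Poissonian transfection-efficiency models.

Transfection is an all-or-none readout of a chain of Poisson processes, so
the dose-response curve TE(D) is modelled through the zero class:

  single Poissonian   TE(D) = 1 - exp(-a * D / D_ref)
      one Poisson process (delivered packets) whose mean scales with dose;
      the expected shape when every endosome carries one lipoplex.

  double Poissonian   TE(D) = 1 - exp(-N * (1 - exp(-L * D / D_ref)))
      two nested processes: N endosome "slots" per cell (dose-independent
      capacity, set by the pit-normalised attachment rule) each loaded with
      a Poisson number of lipoplexes whose mean L scales with dose.  As
      L -> 0 with N*L fixed this reduces to the single form, so the double
      family nests the single one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .ensemble import simulate_ensemble
from .expression import transfection_efficiency
from .network import build_network
from .parameters import ExperimentDesign, RateConstants

__all__ = [
    "DoseResponsePoint",
    "PoissonFit",
    "dose_response",
    "fit_poissonian",
    "te_single",
    "te_double",
]


@dataclass(frozen=True)
class DoseResponsePoint:
    dose: float          # relative dose, multiples of the reference L_ex0
    TE: float            # transfection efficiency in [0, 1]
    n_cells: int

    def __post_init__(self):
        if not 0.0 <= self.TE <= 1.0:
            raise ValueError(f"TE must be in [0, 1], got {self.TE}")


def te_single(d, a):
    return -np.expm1(-a * np.asarray(d, dtype=float))


def te_double(d, N, L):
    return -np.expm1(-N * -np.expm1(-L * np.asarray(d, dtype=float)))


def dose_response(
    variant: str,
    rates: RateConstants,
    design: ExperimentDesign,
    dose_grid,
    n_cells: int,
    seed,
    engine: str = "hybrid",
    init_mode: str = "fractional",
) -> list[DoseResponsePoint]:
    """TE at each relative dose, from an independent ensemble per dose.

    ``design.L_ex0`` is the reference dose; ``dose_grid`` multiplies it.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(list(dose_grid)))
    points = []
    for d, child in zip(dose_grid, children):
        if d < 0:
            raise ValueError("relative doses must be >= 0")
        des = replace(design, L_ex0=design.L_ex0 * d)
        net = build_network(variant, rates, des)
        ens = simulate_ensemble(net, n_cells, seed=child, engine=engine,
                                keep_traces=False, init_mode=init_mode)
        points.append(DoseResponsePoint(dose=float(d),
                                        TE=transfection_efficiency(ens),
                                        n_cells=n_cells))
    return points


@dataclass(frozen=True)
class PoissonFit:
    form: str
    params: tuple[float, ...]    # (a,) or (N, L)
    ssr: float
    identifiable: bool


_BOUNDS = (1e-9, 1e3)


def _near_bounds(v):
    return v <= _BOUNDS[0] * 10 or v >= _BOUNDS[1] / 10


def fit_poissonian(points, form: str) -> PoissonFit:
    """Least-squares fit of a Poissonian TE model to dose-response points.

    ``form`` is ``"single"`` or ``"double"``.  Fits with a parameter pinned
    against its bounds (e.g. the double form on data that is actually single
    Poissonian, where L runs away) are flagged as non-identifiable.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 dose points")
    d = np.array([p.dose for p in points])
    y = np.array([p.TE for p in points])

    if form == "single":
        starts = [(0.3,), (1.0,), (3.0,)]
        model = te_single
    elif form == "double":
        starts = [(1.0, 1.0), (2.0, 0.5), (0.5, 2.0), (5.0, 0.2), (0.2, 5.0)]
        model = te_double
    else:
        raise ValueError(f"unknown form {form!r}")

    best = None
    for x0 in starts:
        res = least_squares(
            lambda p: model(d, *p) - y, x0=np.array(x0),
            bounds=(np.full(len(x0), _BOUNDS[0]), np.full(len(x0), _BOUNDS[1])),
        )
        ssr = float(res.cost * 2)
        if best is None or ssr < best[1] - 1e-15:
            best = (tuple(float(v) for v in res.x), ssr)
    params, ssr = best
    identifiable = not any(_near_bounds(v) for v in params)
    return PoissonFit(form=form, params=params, ssr=ssr, identifiable=identifiable)
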