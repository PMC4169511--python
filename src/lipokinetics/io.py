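"""CSV/YAML writers and readers for trajectories, ensembles and fits.

CSV files are UTF-8, comma-separated, with a header row and shortest
round-trip float formatting, so write->read round trips are lossless.  Run metadata
(seed, package version, config hash) goes to a YAML sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annealing import FitResult
from .ensemble import EnsembleResult
from .response import DoseResponsePoint
from .trajectory import CellTrajectory

__all__ = [
    "trajectory_frame",
    "ensemble_summary_frame",
    "dose_response_frame",
    "write_trajectory",
    "write_ensemble_summary",
    "write_dose_response",
    "write_fit_result",
    "write_metadata",
    "read_csv",
]

def trajectory_frame(traj: CellTrajectory, observables: dict | None = None) -> pd.DataFrame:
    """time_h plus one column per observable (default: every species)."""
    data = {"time_h": traj.times}
    if observables:
        for name, combo in observables.items():
            data[name] = traj.observable(combo)
    else:
        for sp in traj.species:
            data[sp] = traj[sp]
    return pd.DataFrame(data)


def ensemble_summary_frame(ens: EnsembleResult, fits=None) -> pd.DataFrame:
    """One row per cell: delivery counts and, if given, the onset fits."""
    df = pd.DataFrame({
        "cell_id": np.arange(ens.n_cells),
        "n_attached": ens.n_attached,
        "n_delivered": ens.released_lipoplexes,
        "transfected": ens.transfected.astype(int),
    })
    if fits is not None:
        full = pd.DataFrame({
            "onset_h": np.nan, "maxgfp": np.nan, "converged": 0,
        }, index=df.index)
        rows = np.flatnonzero(ens.transfected)
        for i, f in zip(rows, fits):
            full.loc[i, ["onset_h", "maxgfp", "converged"]] = (f.t0, f.maxGFP, int(f.converged))
        df = pd.concat([df, full], axis=1)
    return df


def dose_response_frame(points: list[DoseResponsePoint]) -> pd.DataFrame:
    return pd.DataFrame({
        "dose": [p.dose for p in points],
        "TE": [p.TE for p in points],
        "n_cells": [p.n_cells for p in points],
    })


def _write(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_trajectory(traj, path, observables=None) -> Path:
    return _write(trajectory_frame(traj, observables), path)


def write_ensemble_summary(ens, path, fits=None) -> Path:
    return _write(ensemble_summary_frame(ens, fits), path)


def write_dose_response(points, path) -> Path:
    return _write(dose_response_frame(points), path)


def write_fit_result(result: FitResult, path) -> Path:
    """Structured YAML report of an annealing run."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "best_params": {k: float(v) for k, v in result.best_params.items()},
        "best_score": float(result.best_score),
        "n_evals": int(result.n_evals),
        "score_trace": [
            {"step": int(s), "score": float(v), "accepted": bool(a)}
            for s, v, a in result.trace
        ],
    }
    if result.final_goals is not None:
        g = result.final_goals
        doc["final_goals"] = {
            "mean_attached": float(g.mean_attached),
            "dose_response": [float(v) for v in g.dose_response],
            "onset_mean": float(g.onset_mean),
            "onset_width": float(g.onset_width),
            "mean_maxgfp": float(g.mean_maxgfp),
        }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def write_metadata(path, seed, config: dict | None = None, extra: dict | None = None) -> Path:
    """YAML sidecar with the master seed, version and a config hash."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"seed": seed, "version": __version__}
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        doc["config"] = config
        doc["config_sha256"] = hashlib.sha256(blob).hexdigest()
    if extra:
        doc.update(extra)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_csv(path) -> pd.DataFrame:
    # the default (fast) float parser is up to 1 ulp lossy; results files
    # promise exact write->read round trips
    return pd.read_csv(path, float_precision="round_trip")
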