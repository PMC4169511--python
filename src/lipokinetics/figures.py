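"""Result-reproduction pipelines: time courses, distributions and sweeps.

Each pipeline returns plain tables (DataFrames) first; plotting is a
convenience layer on top so everything runs headless.  The descriptive
names map the published panels: ``timecourse`` (deterministic vs one
stochastic cell), ``traces`` (ensemble GFP time courses), ``onset`` (onset
distributions for slow/fast maturation), ``expression_level`` (max-GFP
lognormal summaries per variant), ``dose_response`` (dose sweep plus
Poissonian fits), and predictive sweeps over incubation time, endosome
stability, lysis rate and lipoplex size at constant total mRNA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .deterministic import simulate_deterministic
from .ensemble import simulate_ensemble
from .expression import fit_onset_maxgfp, maxgfp_distribution, onset_distribution, transfection_efficiency
from .network import build_network
from .parameters import PRESET_VARIANT, PRESETS, make_reference_design
from .hybrid import simulate_hybrid
from .response import dose_response, fit_poissonian

__all__ = ["reproduce_figures", "PIPELINES"]

#: aliases for the published panel numbers
_ALIASES = {
    "fig3": "timecourse", "fig4": "traces", "fig5": "onset",
    "fig6a": "expression_level", "fig6b": "dose_response",
    "fig7a": "incubation_sweep", "fig7b": "stability_sweep",
    "fig7c": "lysis_sweep", "fig7d": "size_sweep",
}


def _reference(preset: str, **changes):
    rates = PRESETS[preset]
    return rates, PRESET_VARIANT[preset], make_reference_design(rates, **changes)


def timecourse(seed=0, preset="multilipoplex_slow", **_):
    """Deterministic solution vs one stochastic cell, delivery observables."""
    rates, variant, design = _reference(preset)
    net = build_network(variant, rates, design)
    det = simulate_deterministic(net)
    # hybrid engine: exact SSA for the low-copy delivery chain, analytic
    # expression on top of it -- the stochastic character lives upstream
    sto = simulate_hybrid(net, seed=seed, init_mode="round")
    frames = {}
    for name in ("attached", "in_endosomes", "mrna", "gfp"):
        frames[name] = pd.DataFrame({
            "time_h": det.times,
            "deterministic": det.observable(net.observables[name]),
            "stochastic": sto.observable(net.observables[name]),
        })
    return frames


def traces(seed=0, n_cells=200, preset="multilipoplex_slow", **_):
    """Ensemble of single-cell mature-GFP time courses (long format)."""
    rates, variant, design = _reference(preset)
    net = build_network(variant, rates, design)
    ens = simulate_ensemble(net, n_cells, seed=seed)
    rows = [pd.DataFrame({"cell_id": i, "time_h": ens.times, "gfp": ens.gfp[i]})
            for i in range(n_cells)]
    return {"gfp_traces": pd.concat(rows, ignore_index=True)}


def _onset_fits(preset, n_cells, seed):
    rates, variant, design = _reference(preset)
    net = build_network(variant, rates, design)
    ens = simulate_ensemble(net, n_cells, seed=seed)
    fits = [fit_onset_maxgfp(ens.times, ens.gfp[i], rates)
            for i in np.flatnonzero(ens.transfected)]
    return ens, [f for f in fits if f.converged]


def onset(seed=0, n_cells=1500, **_):
    """Onset-time Gaussian summaries, slow vs fast maturation."""
    out = {}
    summary = []
    for preset in ("multilipoplex_slow", "multilipoplex_fast"):
        _, fits = _onset_fits(preset, n_cells, seed)
        dist = onset_distribution(fits)
        out[f"onset_{preset}"] = pd.DataFrame({"t0_h": [f.t0 for f in fits]})
        summary.append((preset, PRESETS[preset].k_M, dist.location, dist.width, dist.n))
    out["summary"] = pd.DataFrame(
        summary, columns=["preset", "k_M", "onset_mean_h", "onset_width_h", "n"])
    return out


def expression_level(seed=0, n_cells=1500, **_):
    """Max-GFP lognormal summaries, streamlined vs multiple-lipoplex."""
    out = {}
    summary = []
    for preset in ("streamlined_slow", "multilipoplex_slow"):
        _, fits = _onset_fits(preset, n_cells, seed)
        dist = maxgfp_distribution(fits)
        out[f"maxgfp_{preset}"] = pd.DataFrame({"maxgfp": [f.maxGFP for f in fits]})
        summary.append((preset, dist.location, dist.width, dist.n))
    out["summary"] = pd.DataFrame(
        summary, columns=["preset", "lognormal_location", "lognormal_width", "n"])
    return out


_DOSE_GRID = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


def dose_response_panel(seed=0, n_cells=600, dose_grid=_DOSE_GRID, **_):
    """TE vs relative dose for both variants, with Poissonian fits."""
    out = {}
    fit_rows = []
    for preset in ("streamlined_slow", "multilipoplex_slow"):
        rates, variant, design = _reference(preset)
        points = dose_response(variant, rates, design, dose_grid, n_cells, seed=seed)
        out[f"te_{preset}"] = pd.DataFrame(
            {"dose": [p.dose for p in points], "TE": [p.TE for p in points]})
        for form in ("single", "double"):
            fit = fit_poissonian(points, form)
            fit_rows.append((preset, form, fit.params, fit.ssr, fit.identifiable))
    out["fits"] = pd.DataFrame(
        fit_rows, columns=["preset", "form", "params", "ssr", "identifiable"])
    return out


def _sweep(preset, n_cells, seed, param_grid, modify):
    """TE and mean max GFP (over transfected cells) along a parameter grid."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for value, child in zip(param_grid, ss.spawn(len(param_grid))):
        rates, variant, design = _reference(preset)
        rates, design = modify(rates, design, value)
        net = build_network(variant, rates, design)
        ens = simulate_ensemble(net, n_cells, seed=child)
        te = transfection_efficiency(ens)
        maxgfp = float(np.mean(ens.peak_values())) if np.any(ens.transfected) else np.nan
        rows.append((value, te, maxgfp))
    return pd.DataFrame(rows, columns=["value", "TE", "mean_maxgfp"])


def incubation_sweep(seed=0, n_cells=500, grid=(0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0), **_):
    """TE vs incubation time; approximately linear in a limited window."""
    df = _sweep("multilipoplex_slow", n_cells, seed, grid,
                lambda r, d, v: (r, d.replace(t_inc=v)))
    return {"incubation": df.rename(columns={"value": "t_inc_h"})}


def stability_sweep(seed=0, n_cells=500, grid=(0.1, 0.25, 0.45, 0.67, 0.9, 1.2, 1.6), **_):
    """TE vs endosome degradation rate (mRNA stability proxy)."""
    df = _sweep("multilipoplex_slow", n_cells, seed, grid,
                lambda r, d, v: (r.replace(d_E=v), d))
    return {"stability": df.rename(columns={"value": "d_E_per_h"})}


def lysis_sweep(seed=0, n_cells=500, grid=(0.03, 0.06, 0.11, 0.2, 0.35, 0.6), **_):
    """TE vs endosomal lysis (escape) rate."""
    df = _sweep("multilipoplex_slow", n_cells, seed, grid,
                lambda r, d, v: (r.replace(k_L=v), d))
    return {"lysis": df.rename(columns={"value": "k_L_per_h"})}


def size_sweep(seed=0, n_cells=500, grid=(50, 100, 175, 350, 700), **_):
    """Lipoplex size sweep at constant total mRNA (dose rescaled by 350/S)."""
    def modify(r, d, S):
        return r, d.replace(S=int(S), L_ex0=d.L_ex0 * 350.0 / S)

    df = _sweep("multilipoplex_slow", n_cells, seed, grid, modify)
    return {"size": df.rename(columns={"value": "mrna_per_lipoplex"})}


PIPELINES = {
    "timecourse": timecourse,
    "traces": traces,
    "onset": onset,
    "expression_level": expression_level,
    "dose_response": dose_response_panel,
    "incubation_sweep": incubation_sweep,
    "stability_sweep": stability_sweep,
    "lysis_sweep": lysis_sweep,
    "size_sweep": size_sweep,
}


def reproduce_figures(which: str, seed=0, out_dir=None, plot=False, **kwargs):
    """Run one reproduction pipeline; returns a dict of DataFrames.

    If ``out_dir`` is given the tables are written as CSV first; with
    ``plot=True`` a quick-look PNG is saved alongside (headless backend).
    """
    name = _ALIASES.get(which, which)
    if name not in PIPELINES:
        raise ValueError(f"unknown pipeline {which!r}; available: "
                         f"{sorted(PIPELINES) + sorted(_ALIASES)}")
    tables = PIPELINES[name](seed=seed, **kwargs)
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, df in tables.items():
            df.to_csv(out / f"{name}_{key}.csv", index=False)
        if plot:
            _quick_plot(name, tables, out)
    return tables


def _quick_plot(name, tables, out):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for key, df in tables.items():
        num = df.select_dtypes("number")
        if num.shape[1] >= 2:
            ax.plot(num.iloc[:, 0], num.iloc[:, 1], marker="o", label=key)
    ax.set_title(name)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / f"{name}.png", dpi=120)
    plt.close(fig)
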