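"""Configuration, CSV round trips, SBML export and fixture generation."""

import numpy as np
import pandas as pd
import pytest
import yaml

import lipokinetics as lk
from lipokinetics.io import (read_csv, write_dose_response, write_ensemble_summary,
                             write_fit_result, write_metadata, write_trajectory)
from lipokinetics.sbml import read_sbml_summary

RATES = lk.get_preset("multilipoplex_slow")
DESIGN = lk.ExperimentDesign(L_ex0=25.36, t_end=10.0)


# -- presets: single source of rate truth -----------------------------------

PUBLISHED = {
    "streamlined_slow": dict(k_A=0.03, k_E=0.8, k_L=0.065, k_M=5.5, d_E=0.65),
    "multilipoplex_fast": dict(k_A=0.26, k_E=0.73, k_L=0.10, k_M=9.23, d_E=0.60),
    "multilipoplex_slow": dict(k_A=0.27, k_E=0.81, k_L=0.11, k_M=5.5, d_E=0.67),
}
FIXED = dict(k_U=1e6, d_L=1e-6, k_TL=170.0, d_M=0.062, d_G=0.056)


@pytest.mark.parametrize("name", sorted(PUBLISHED))
def test_presets_value_by_value(name):
    rates = lk.get_preset(name)
    for key, value in {**PUBLISHED[name], **FIXED}.items():
        assert getattr(rates, key) == value, (name, key)


def test_unknown_preset():
    with pytest.raises(KeyError):
        lk.get_preset("fully_nested")


# -- configuration ----------------------------------------------------------

def _write_cfg(tmp_path, doc):
    p = tmp_path / "run.yaml"
    p.write_text(yaml.safe_dump(doc))
    return p


def test_load_config_preset(tmp_path):
    cfg = lk.load_config(_write_cfg(tmp_path, {
        "rates": "multilipoplex_slow",
        "design": {"L_ex0": 25.36, "t_end": 30.0},
        "n_cells": 500, "seed": 4,
    }))
    assert cfg.variant == "multilipoplex" and cfg.preset == "multilipoplex_slow"
    assert cfg.rates.k_A == 0.27 and cfg.rates.k_U == 1e6
    assert cfg.design.L_ex0 == 25.36 and cfg.engine == "hybrid"


def test_load_config_explicit_rates(tmp_path):
    cfg = lk.load_config(_write_cfg(tmp_path, {
        "rates": {"k_A": 0.1, "k_E": 0.5, "k_L": 0.05, "d_E": 0.5, "k_M": 5.0},
        "variant": "streamlined",
        "design": {"L_ex0": 100},
    }))
    assert cfg.rates.k_TL == 170.0  # fixed defaults fill in


@pytest.mark.parametrize("doc,fragment", [
    ({"rates": "multilipoplex_slow", "design": {"L_ex0": 1}, "cells": 3}, "cells"),
    ({"rates": "nope", "design": {"L_ex0": 1}}, "nope"),
    ({"rates": {"k_A": -0.1, "k_E": 1, "k_L": 1, "d_E": 1, "k_M": 1},
      "variant": "streamlined", "design": {"L_ex0": 1}}, "rates.k_A"),
    ({"rates": "streamlined_slow", "variant": "multilipoplex",
      "design": {"L_ex0": 1}}, "conflicts"),
    ({"rates": "streamlined_slow", "design": {}}, "L_ex0"),
    ({"rates": "streamlined_slow", "design": {"L_ex0": 1}, "engine": "exact"}, "engine"),
    ({"design": {"L_ex0": 1}}, "rates"),
])
def test_load_config_schema_errors_name_the_key(tmp_path, doc, fragment):
    with pytest.raises(lk.ConfigError, match=fragment):
        lk.load_config(_write_cfg(tmp_path, doc))


# -- CSV / YAML round trips --------------------------------------------------

def test_trajectory_round_trip(tmp_path):
    net = lk.build_network("multilipoplex", RATES, DESIGN)
    traj = lk.simulate_hybrid(net, seed=1)
    path = write_trajectory(traj, tmp_path / "traj.csv")
    df = read_csv(path)
    assert list(df.columns) == ["time_h"] + traj.species
    np.testing.assert_array_equal(df["Gstar"].to_numpy(), traj["Gstar"])


def test_ensemble_summary_round_trip(tmp_path):
    net = lk.build_network("multilipoplex", RATES, DESIGN)
    ens = lk.simulate_ensemble(net, 25, seed=2)
    fits = [lk.fit_onset_maxgfp(ens.times, ens.gfp[i], RATES)
            for i in np.flatnonzero(ens.transfected)]
    path = write_ensemble_summary(ens, tmp_path / "cells.csv", fits)
    df = read_csv(path)
    assert len(df) == 25
    np.testing.assert_array_equal(df.n_attached.to_numpy(), ens.n_attached)
    assert df.transfected.sum() == ens.transfected.sum()


def test_dose_response_and_metadata_round_trip(tmp_path):
    pts = [lk.DoseResponsePoint(0.5, 0.21234567890123456, 100),
           lk.DoseResponsePoint(1.0, 0.4, 100)]
    df = read_csv(write_dose_response(pts, tmp_path / "dr.csv"))
    assert df.TE[0] == 0.21234567890123456  # full double precision
    meta = write_metadata(tmp_path / "meta.yaml", seed=9, config={"n_cells": 10})
    doc = yaml.safe_load(meta.read_text())
    assert doc["seed"] == 9 and len(doc["config_sha256"]) == 64


def test_fit_result_report(tmp_path):
    result = lk.FitResult(best_params={"k_A": 0.27}, best_score=0.01,
                          trace=[(0, 0.02, True), (1, 0.01, True)], n_evals=2)
    doc = yaml.safe_load(write_fit_result(result, tmp_path / "fit.yaml").read_text())
    assert doc["best_params"]["k_A"] == 0.27
    assert doc["score_trace"][1]["score"] == 0.01


# -- SBML --------------------------------------------------------------------

def test_sbml_streamlined_species_count(tmp_path):
    net = lk.build_network("streamlined", lk.get_preset("streamlined_slow"), DESIGN)
    summary = read_sbml_summary(lk.export_sbml(net, tmp_path / "s.xml"))
    assert summary["n_species"] == 7
    assert summary["n_events"] == 1  # the wash


def test_sbml_multilipoplex_lists_all_sizes(tmp_path):
    net = lk.build_network("multilipoplex", RATES, DESIGN)
    summary = read_sbml_summary(lk.export_sbml(net, tmp_path / "m.xml"))
    for i in range(1, 11):
        assert f"P_{i}" in summary["species"]
        assert f"E_{i}" in summary["species"]
    # wash is exported as an event, not a reaction
    assert summary["n_reactions"] == len(net.reactions) - 1


def test_sbml_rejects_non_sbml(tmp_path):
    p = tmp_path / "x.xml"
    p.write_text("<notSBML/>")
    with pytest.raises(ValueError):
        read_sbml_summary(p)


# -- fixtures ----------------------------------------------------------------

def test_fixtures_noise_free_traces_are_exact_curves():
    table = lk.make_fixtures(5, RATES, seed=1, noise_sigma=0.0, noise_floor=0.0)
    for cid in table.cell_ids:
        t, y = table.trace(cid)
        truth = table.truth.loc[table.truth.cell_id == cid].iloc[0]
        np.testing.assert_allclose(y, lk.expression_curve(t, truth.t0, truth.m0, RATES))


def test_fixtures_deterministic_given_seed():
    a = lk.make_fixtures(10, RATES, seed=3)
    b = lk.make_fixtures(10, RATES, seed=3)
    pd.testing.assert_frame_equal(a.traces, b.traces)
    assert not a.traces.equals(lk.make_fixtures(10, RATES, seed=4).traces)


def test_fixture_recovery_on_noise_free_data():
    table = lk.make_fixtures(10, RATES, seed=7, noise_sigma=0.0)
    for cid in table.cell_ids:
        t, y = table.trace(cid)
        truth = table.truth.loc[table.truth.cell_id == cid].iloc[0]
        fit = lk.fit_onset_maxgfp(t, y, RATES, include_maturation=True)
        assert abs(fit.t0 - truth.t0) < 0.01
        assert fit.m0_eff == pytest.approx(truth.m0, rel=1e-3)


# -- CLI (thin layer) --------------------------------------------------------

def test_cli_simulate_and_fit_traces(tmp_path):
    from click.testing import CliRunner
    from lipokinetics.cli import main

    cfg = tmp_path / "run.yaml"
    cfg.write_text(yaml.safe_dump({
        "rates": "multilipoplex_slow",
        "design": {"L_ex0": 25.36, "t_end": 10.0},
        "n_cells": 5, "seed": 1,
    }))
    runner = CliRunner()
    out = tmp_path / "out"
    res = runner.invoke(main, ["simulate", "--config", str(cfg), "--engine", "ode",
                               "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert (out / "trajectory.csv").exists() and (out / "metadata.yaml").exists()

    fx = tmp_path / "fx"
    res = runner.invoke(main, ["make-fixtures", "--cells", "5", "--seed", "2",
                               "--out", str(fx)])
    assert res.exit_code == 0, res.output
    res = runner.invoke(main, ["fit-traces", "--traces", str(fx / "traces.csv"),
                               "--out", str(tmp_path / "fits.csv")])
    assert res.exit_code == 0, res.output
    assert len(read_csv(tmp_path / "fits.csv")) == 5

    res = runner.invoke(main, ["export-sbml", "--config", str(cfg),
                               "--out", str(tmp_path / "model.xml")])
    assert res.exit_code == 0, res.output
    assert read_sbml_summary(tmp_path / "model.xml")["n_species"] == 25
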