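"""Reaction-network construction: counts, channels, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lipokinetics as lk
from lipokinetics.network import DEGRADATION_LABELS, Reaction, mrna_equivalent_change

RATES = lk.get_preset("multilipoplex_slow")
DESIGN = lk.ExperimentDesign(L_ex0=25.0)


def test_streamlined_counts():
    net = lk.build_network("streamlined", lk.get_preset("streamlined_slow"), DESIGN)
    assert len(net.species) == 7
    assert set(net.species) == {"L_ex", "P", "E", "L_in", "M", "G", "Gstar"}
    assert len(net.reactions) == 12


@pytest.mark.parametrize("n_max", [1, 2, 5, 10])
def test_multilipoplex_counts_closed_form(n_max):
    # 1 new-pit + (N-1) join + 1 wash + 3N per-size + 7 downstream = 4N + 8
    net = lk.build_network("multilipoplex", RATES, DESIGN.replace(N_max=n_max))
    assert len(net.species) == 2 * n_max + 5
    assert len(net.reactions) == 4 * n_max + 8


def test_capacity_one_reduces_to_streamlined_topology():
    net = lk.build_network("multilipoplex", RATES, DESIGN.replace(N_max=1))
    assert not any("join" in r.label for r in net.reactions)
    assert len(net.reactions) == 12


def test_build_rejects_bad_inputs():
    with pytest.raises(ValueError):
        lk.build_network("nested", RATES, DESIGN)
    with pytest.raises(ValueError):
        lk.ExperimentDesign(L_ex0=10, N_max=0)
    with pytest.raises(ValueError):
        lk.RateConstants(k_A=-0.1, k_E=1, k_L=1, d_E=1, k_M=1)


def test_attach_propensity_rule():
    k_AX, per, n, total = lk.attach_propensity(0.27, 10, 0)
    assert n == 1 and total == pytest.approx(2.7)
    k_AX, per, n, total = lk.attach_propensity(0.27, 10, 2)
    assert n == 3 and per == pytest.approx(0.9) and total == pytest.approx(2.7)
    assert lk.attach_propensity(0.5, 0, 7)[3] == 0.0
    with pytest.raises(ValueError):
        lk.attach_propensity(0.27, -1, 0)


@given(n_pits=st.integers(0, 50), lex=st.integers(0, 1000))
@settings(max_examples=50, deadline=None)
def test_attach_total_independent_of_pit_count(n_pits, lex):
    """Below capacity, total attachment propensity is k_A * L_ex exactly."""
    _, _, _, total = lk.attach_propensity(0.27, lex, n_pits)
    assert total == pytest.approx(0.27 * lex)


@given(occ=st.lists(st.integers(0, 9), min_size=0, max_size=12))
@settings(max_examples=30, deadline=None)
def test_compiled_attach_propensity_matches_rule(occ):
    """Compiled network channels reproduce the pit-normalised rule state-wise."""
    net = lk.build_network("multilipoplex", RATES, DESIGN)
    cn = net.compiled()
    x = np.zeros(cn.n_species)
    x[cn.lex] = 17
    for size in occ:  # occupancies 0..9 => no pit at capacity 10
        if size >= 1:
            x[net.index(f"P_{size}")] += 1
    a = cn.propensities(x, wash_on=False)
    attach_total = a[cn.new_ids].sum() + a[cn.join_ids].sum()
    assert attach_total == pytest.approx(RATES.k_A * 17)


def test_full_pits_disable_join_but_not_new_pit():
    net = lk.build_network("multilipoplex", RATES, DESIGN)
    cn = net.compiled()
    x = np.zeros(cn.n_species)
    x[cn.lex] = 10
    x[net.index("P_10")] = 3  # every pit at capacity
    a = cn.propensities(x, wash_on=False)
    assert a[cn.join_ids].sum() == 0.0
    assert a[cn.new_ids].sum() == pytest.approx(RATES.k_A * 10 / 4.0)


def test_wash_rate_step():
    assert lk.wash_rate(0.5, 1.0, 1e6) == 0.0
    assert lk.wash_rate(1.0, 1.0, 1e6) == 1e6  # boundary inclusive
    assert lk.wash_rate(2.0, 1.0, 0.0) == 0.0


def test_count_full_nested_species_exact():
    assert lk.count_full_nested_species(175, 10) == 175**10
    assert lk.count_full_nested_species(175, 10) > 2.6e22
    assert lk.count_full_nested_species(1, 10) == 1
    assert lk.count_full_nested_species(176, 10) > lk.count_full_nested_species(175, 10)
    with pytest.raises(ValueError):
        lk.count_full_nested_species(0, 10)


@pytest.mark.parametrize("variant,preset", [
    ("streamlined", "streamlined_slow"),
    ("multilipoplex", "multilipoplex_slow"),
])
def test_mrna_equivalent_conservation(variant, preset):
    """Only the degradation channels change the mRNA-equivalent total."""
    net = lk.build_network(variant, lk.get_preset(preset), DESIGN)
    for r in net.reactions:
        change = mrna_equivalent_change(r, DESIGN.S)
        base = r.label.rsplit("_", 1)[0] if r.label.rsplit("_", 1)[-1].isdigit() else r.label
        if base in DEGRADATION_LABELS:
            assert change < 0, r.label
        else:
            assert change == 0, r.label


def test_delivery_subnetwork_drops_expression():
    net = lk.build_network("multilipoplex", RATES, DESIGN)
    sub = net.delivery_subnetwork()
    assert set(sub.species) == set(net.species) - {"M", "G", "Gstar"}
    labels = [r.label for r in sub.reactions]
    assert "unpacking" in labels and "translation" not in labels


def test_reaction_validation():
    with pytest.raises(ValueError):
        Reaction({"A": 2}, {}, "mass_action_first_order", 1.0, "bad_stoich")
    with pytest.raises(ValueError):
        Reaction({"A": 1}, {}, "second_order", 1.0, "bad_kind")
    with pytest.raises(ValueError):
        lk.ReactionNetwork("streamlined", ["A"],
                           [Reaction({"B": 1}, {}, "mass_action_first_order", 1.0, "x")],
                           {}, RATES, DESIGN)
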