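"""Model library: parameter tables, propensity forms, network builders."""

from __future__ import annotations

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from stochmi import models


@pytest.mark.parametrize("table", ["table1", "table2", "table3"])
def test_parameter_tables_round_trip_bit_exact(table, tmp_path):
    params = models.load_table(table)
    assert all(v >= 0 for k, v in params.items())
    path = tmp_path / "p.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump({"parameters": params}, fh)
    with open(path) as fh:
        back = yaml.safe_load(fh)["parameters"]
    assert back == params  # YAML float round-trip is exact for these literals


def test_table1_values_as_printed(table1):
    assert table1["beta_y1s"] == 0.01
    assert table1["gamma_y1s"] == 0.0000067
    assert table1["theta_x"] == 0.001
    assert table1["n1"] == 3
    assert table1["y1_0"] == 85
    assert table1["beta_m2"] == 0.1583


def test_cascade_structure(cascade):
    assert cascade.species == ("Y1*", "Y1", "My2", "Y2")
    assert cascade.n_reactions == 9
    # stoichiometry: every reaction changes the state by its own nu_j
    S = cascade.stoich_matrix
    assert S.shape == (9, 4)
    assert np.all(np.abs(S).sum(axis=1) <= 2)


def test_hill_half_saturation(cascade, table1):
    """f1 at y1 = y1_0 sits exactly halfway up the inducible range."""
    y = np.array([0.0, 85.0, 0.0, 0.0])
    a = cascade.propensities(y, x=0.0)
    f1 = a[list(r.name for r in cascade.reactions).index("my2_transcription")]
    assert f1 == pytest.approx(0.0083 + 0.1583 / 2.0, rel=1e-12)


def test_activation_propensity_scales_with_input_and_state(cascade):
    y = np.array([1500.0, 0.0, 0.0, 0.0])
    a = dict(zip((r.name for r in cascade.reactions), cascade.propensities(y, x=250.0)))
    assert a["activation"] == pytest.approx(0.001 * 250.0 * 1500.0)


def test_zero_state_propensities(cascade, table1):
    a = dict(zip((r.name for r in cascade.reactions), cascade.propensities(np.zeros(4), x=0.0)))
    assert a["y1s_synthesis"] == table1["beta_y1s"]
    assert a["my2_transcription"] == table1["beta_m2s"]  # f1(0) = beta_m2*
    for name in ("y1s_degradation", "deactivation", "y1_degradation", "my2_degradation",
                 "y2_translation", "y2_degradation", "activation"):
        assert a[name] == 0.0


def test_missing_parameter_raises_named_error(table1):
    broken = dict(table1)
    del broken["theta_x"]
    with pytest.raises(models.MissingParameterError, match="theta_x"):
        models.build_simple_cascade(broken)


class TestGlobalVariable:
    def test_mean_and_noise_relations(self):
        g = models.GlobalVariableSpec(1.5e-6, 3e-8, models.CASCADE_COUPLED)
        assert g.gbar == pytest.approx(50.0)
        assert g.eta_g * np.sqrt(g.gbar) == pytest.approx(1.0)
        g2 = models.GlobalVariableSpec.from_mean(50.0, 6e-8, models.CASCADE_COUPLED)
        assert g2.beta_g == pytest.approx(3e-6)

    def test_pinned_at_mean_recovers_nominal_propensities(self, cascade, cascade_slow_g, rng):
        """With G held at gbar every coupled propensity equals its nominal value."""
        for _ in range(25):
            y = rng.uniform(0, 2000, size=4)
            yg = np.append(y, 50.0)
            a_nom = cascade.propensities(y, x=37.5)
            a_g = cascade_slow_g.propensities(yg, x=37.5)
            np.testing.assert_allclose(a_g[:9], a_nom, rtol=1e-13)

    def test_unknown_coupled_name_rejected(self, cascade):
        bad = models.GlobalVariableSpec(1.5e-6, 3e-8, ("nonexistent_reaction",))
        with pytest.raises(KeyError, match="nonexistent_reaction"):
            models.attach_global_variable(cascade, bad)


class TestCircuit:
    def test_adh1_estradiol_dependence(self, circuit_sgf, table2):
        """beta_m1*(x): beta_m1 at x = 0, half repression at x = x_e, floor at saturation."""
        m1 = next(r for r in circuit_sgf.reactions if r.name == "m1_transcription").propensity
        y = np.zeros(circuit_sgf.n_species)
        b = table2["beta_m1"]
        assert m1.value(y, 0.0) == pytest.approx(b)
        assert m1.value(y, 45.0) == pytest.approx(b * (1 - 0.35 / 2))  # = 0.825 beta_m1
        assert m1.value(y, 1e9) == pytest.approx(b * (1 - 0.35), rel=1e-6)

    def test_adh1_flag_off_gives_constant(self, table2):
        net = models.build_synthetic_circuit(table2, "global", adh1_estradiol_dependence=False)
        m1 = next(r for r in net.reactions if r.name == "m1_transcription").propensity
        assert isinstance(m1, models.Constant)

    def test_intrinsic_variant_has_no_G(self, circuit_intrinsic, table3):
        assert "G" not in circuit_intrinsic.species
        assert circuit_intrinsic.global_spec is None
        tr = next(r for r in circuit_intrinsic.reactions if r.name == "y1s_translation").propensity
        assert tr.c == table3["beta_y1s"] == 0.0000019

    def test_global_variant_couples_all_translations(self, circuit_sgf):
        assert circuit_sgf.global_spec.coupled == models.CIRCUIT_COUPLED
        gi = circuit_sgf.species_index("G")
        for name in models.CIRCUIT_COUPLED:
            p = next(r for r in circuit_sgf.reactions if r.name == name).propensity
            assert isinstance(p, models.Bilinear) and gi in (p.i, p.j)

    def test_variant_validation(self, table2):
        with pytest.raises(ValueError):
            models.build_synthetic_circuit(table2, "nonsense")


class TestStepProtocol:
    def test_estradiol_12_doses(self):
        p = models.StepInputProtocol.estradiol_12()
        assert len(p.amplitudes) == 12
        assert p.amplitudes[0] == 100.0  # c = 1 exactly
        assert p.amplitudes[-1] == 0.0
        assert all(a > b for a, b in zip(p.amplitudes[:-2], p.amplitudes[1:-1]))
        assert p.weights.sum() == pytest.approx(1.0)
        assert np.all(p.doses >= 0) and np.all(p.doses <= p.xmax)

    def test_amplitudes_outside_range_rejected(self):
        with pytest.raises(ValueError):
            models.StepInputProtocol(amplitudes=(300.0,), xmax=250.0)


@settings(max_examples=60, deadline=None)
@given(
    y=st.lists(st.floats(min_value=0, max_value=1e5), min_size=4, max_size=4),
    x=st.floats(min_value=0, max_value=250),
)
def test_propensities_nonnegative_everywhere(y, x):
    net = models.build_simple_cascade(models.load_table("table1"))
    assert np.all(net.propensities(np.array(y), x) >= 0)


def test_network_config_round_trip(tmp_path, cascade_slow_g, circuit_sgf, circuit_intrinsic):
    for net in (cascade_slow_g, circuit_sgf, circuit_intrinsic):
        path = tmp_path / f"{net.model}.yaml"
        models.save_config(net, path)
        back = models.load_config(path)
        assert back.species == net.species
        assert back.params == net.params
        assert [r.name for r in back.reactions] == [r.name for r in net.reactions]
        y = np.linspace(1, 40, net.n_species)
        np.testing.assert_array_equal(back.propensities(y, 10.0), net.propensities(y, 10.0))
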