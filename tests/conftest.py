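"""Shared model fixtures; expensive propagations are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from stochmi import models, populations


@pytest.fixture(scope="session")
def table1():
    return models.load_table("table1")


@pytest.fixture(scope="session")
def table2():
    return models.load_table("table2")


@pytest.fixture(scope="session")
def table3():
    return models.load_table("table3")


@pytest.fixture(scope="session")
def cascade(table1):
    return models.build_simple_cascade(table1)


@pytest.fixture(scope="session")
def cascade_slow_g(cascade):
    """Table 1 cascade with the slow global variable (gbar = 50, gamma_g = 3e-8)."""
    gspec = models.GlobalVariableSpec(1.5e-6, 3e-8, models.CASCADE_COUPLED)
    return models.attach_global_variable(cascade, gspec)


@pytest.fixture(scope="session")
def circuit_sgf(table2):
    return models.build_synthetic_circuit(table2, "global")


@pytest.fixture(scope="session")
def circuit_intrinsic(table3):
    return models.build_synthetic_circuit(table3, "intrinsic")


@pytest.fixture(scope="session")
def estradiol_protocol():
    return models.StepInputProtocol.estradiol_12()


@pytest.fixture(scope="session")
def sgf_heterogeneous(circuit_sgf):
    return populations.make_initial("heterogeneous", circuit_sgf)


@pytest.fixture(scope="session")
def sgf_s1(circuit_sgf):
    return populations.make_initial("S1", circuit_sgf)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250922)


@pytest.fixture(scope="session")
def sgf_table():
    from stochmi import cytometry

    return cytometry.generate("SGF", n_cells=3000, seed=11)


@pytest.fixture(scope="session")
def fast_table():
    from stochmi import cytometry

    return cytometry.generate("fast-global", n_cells=3000, seed=12)


@pytest.fixture(scope="session")
def intrinsic_table():
    from stochmi import cytometry

    return cytometry.generate("intrinsic", n_cells=3000, seed=13)
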