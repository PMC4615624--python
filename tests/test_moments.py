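"""Moment engine: linearization oracle, closed-form transients, stationary states."""

from __future__ import annotations

import numpy as np
import pytest

from stochmi import models, moments
from stochmi.models import Bilinear, Constant, HillActivation, Linear


def _birth_death(beta, gamma):
    return models.ReactionNetwork(
        species=("G",),
        reactions=(
            models.Reaction("g_birth", (1,), Constant(beta)),
            models.Reaction("g_death", (-1,), Linear(gamma, 0)),
        ),
        model="birth_death",
    )


class TestLinearize:
    def test_birth_death_values_and_gradients(self):
        net = _birth_death(1.5e-6, 3e-8)
        a, J = moments.linearize_propensities(net, np.array([50.0]))
        assert a[0] == pytest.approx(1.5e-6)
        assert a[1] == pytest.approx(3e-8 * 50.0)
        assert J[0, 0] == 0.0
        assert J[1, 0] == pytest.approx(3e-8)

    def test_hill_gradient_at_half_saturation(self, cascade, table1):
        """d f1/d y1 at y1 = y1_0 equals beta_m2 * n1 / (4 y1_0)."""
        z = np.array([0.0, 85.0, 0.0, 0.0])
        _, J = moments.linearize_propensities(cascade, z)
        k = [r.name for r in cascade.reactions].index("my2_transcription")
        expected = table1["beta_m2"] * table1["n1"] / (4.0 * table1["y1_0"])
        assert J[k, 1] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("x", [0.0, 37.5, 250.0])
    def test_gradients_match_finite_differences(self, cascade_slow_g, circuit_sgf, x):
        """Analytic Jacobians agree with central differences to 1e-6 relative."""
        for net, z0 in (
            (cascade_slow_g, np.array([1200.0, 150.0, 80.0, 900.0, 50.0])),
            (circuit_sgf, np.array([995.0, 250.0, 30.0, 260.0, 12.0, 300.0, 42.0])),
        ):
            _, J = moments.linearize_propensities(net, z0, x)
            h = 1e-4
            for i in range(net.n_species):
                zp, zm = z0.copy(), z0.copy()
                zp[i] += h * max(z0[i], 1.0)
                zm[i] -= h * max(z0[i], 1.0)
                fd = (net.propensities(zp, x) - net.propensities(zm, x)) / (zp[i] - zm[i])
                np.testing.assert_allclose(J[:, i], fd, rtol=1e-6, atol=1e-12)

    def test_bilinear_translation_value_and_gradient(self):
        p = Bilinear(0.0014 / 50.0, 0, 1)
        y = np.array([200.0, 50.0])
        assert p.value(y, 0.0) == pytest.approx(0.0014 * 200.0)
        g = p.grad(y, 0.0)
        assert g[0] == pytest.approx(0.0014)
        assert g[1] == pytest.approx(0.0014 * 200.0 / 50.0)

    def test_non_finite_mean_rejected(self, cascade):
        with pytest.raises(ValueError):
            moments.linearize_propensities(cascade, np.array([np.nan, 0, 0, 0]))


class TestIntegrate:
    def test_poisson_transient_matches_closed_form(self):
        """Birth/death from zero: z(t) = (beta/gamma)(1 - e^(-gamma t)) = C(t)."""
        beta, gamma = 0.05, 1e-3
        net = _birth_death(beta, gamma)
        init = moments.MomentState(0.0, np.zeros(1), np.zeros((1, 1)))
        times = np.array([0.0, 5.0, 20.0, 60.0, 240.0])
        traj = moments.integrate_moments(net, init, times)
        t_s = times * 60.0
        z_exact = beta / gamma * (1 - np.exp(-gamma * t_s))
        np.testing.assert_allclose(traj.means[:, 0], z_exact, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(traj.covs[:, 0, 0], z_exact, rtol=1e-8, atol=1e-10)

    def test_first_entry_is_initial_condition(self, cascade):
        init = moments.MomentState(0.0, np.array([10.0, 0, 0, 0]), np.zeros((4, 4)))
        traj = moments.integrate_moments(cascade, init, [0.0, 10.0], x=100.0)
        np.testing.assert_array_equal(traj.states[0].mean, init.mean)

    def test_zeroed_covariance_means_equal_rate_equations(self, cascade, table1):
        """With C = 0 the mean flow is the deterministic ODE (hand-written oracle)."""
        from scipy.integrate import solve_ivp

        p = table1
        x = 150.0

        def ode(t, z):
            y1s, y1, m, y2 = z
            f1 = p["beta_m2s"] + p["beta_m2"] * y1 ** p["n1"] / (y1 ** p["n1"] + p["y1_0"] ** p["n1"])
            return [
                p["beta_y1s"] - p["gamma_y1s"] * y1s - p["theta_x"] * x * y1s + p["theta_y1"] * y1,
                p["theta_x"] * x * y1s - p["theta_y1"] * y1 - p["gamma_y1s"] * y1,
                f1 - p["gamma_m2"] * m,
                p["beta_y2"] * m - p["gamma_y2"] * y2,
            ]

        z0 = np.array([1492.5, 0.0, 10.0, 100.0])
        ref = solve_ivp(ode, (0, 45000.0), z0, rtol=1e-10, atol=1e-12, dense_output=True)
        init = moments.MomentState(0.0, z0, np.zeros((4, 4)))
        traj = moments.integrate_moments(cascade, init, [0.0, 750.0], x=x)
        np.testing.assert_allclose(traj.at(750.0).mean, ref.sol(45000.0), rtol=1e-6)

    def test_covariance_stays_psd_along_trajectory(self, circuit_sgf, sgf_heterogeneous):
        traj = moments.integrate_moments(
            circuit_sgf, sgf_heterogeneous.state, [0, 65, 165, 330, 580], x=100.0
        )
        for s in traj.states:
            w = np.linalg.eigvalsh(s.cov)
            assert w.min() >= -1e-8 * np.trace(s.cov)

    def test_times_must_increase(self, cascade):
        init = moments.MomentState(0.0, np.zeros(4), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            moments.integrate_moments(cascade, init, [0.0, 10.0, 5.0])


class TestStationary:
    def test_cascade_at_zero_input(self, cascade):
        """Linear chain at x = 0: My2 = beta_m2*/gamma_m2 = 10, Y2 = 10 beta_y2/gamma_y2 = 100."""
        st = moments.stationary_moments(cascade, x=0.0)
        mean = dict(zip(cascade.species, st.mean))
        assert mean["Y1*"] + mean["Y1"] == pytest.approx(0.01 / 0.0000067, rel=1e-6)
        assert mean["My2"] == pytest.approx(10.0, rel=1e-6)
        assert mean["Y2"] == pytest.approx(100.0, rel=1e-6)

    def test_birth_death_poisson_stationary(self):
        st = moments.stationary_moments(_birth_death(1.5e-6, 3e-8))
        assert st.mean[0] == pytest.approx(50.0, rel=1e-9)
        assert st.cov[0, 0] == pytest.approx(50.0, rel=1e-6)

    def test_zero_synthesis_gives_zero_state(self, table1):
        params = dict(table1, beta_y1s=0.0, beta_m2s=0.0, beta_m2=0.0)
        st = moments.stationary_moments(models.build_simple_cascade(params))
        np.testing.assert_allclose(st.mean, 0.0, atol=1e-12)

    def test_direct_and_integrated_routes_agree(self):
        net = _birth_death(2e-4, 1e-5)
        direct = moments.stationary_moments(net, method="direct")
        integrated = moments.stationary_moments(net, method="integrate")
        # the drift criterion (1e-9 /s relative) resolves the state to ~1e-4
        np.testing.assert_allclose(integrated.mean, direct.mean, rtol=3e-4)
        np.testing.assert_allclose(integrated.cov, direct.cov, rtol=1e-3)

    def test_saturating_input_maxima(self, cascade):
        """Saturating f1 drives My2 to (beta_m2* + beta_m2)/gamma_m2 ~ 200, Y2 ~ 2000."""
        st = moments.stationary_moments(cascade, x=1e4)
        assert st.mean[2] == pytest.approx(200.7, rel=0.01)
        assert st.mean[3] == pytest.approx(2007.0, rel=0.01)


def test_affine_networks_have_exact_moments_vs_analytic():
    """Two-stage linear birth/death (mRNA -> protein): closure is exact;
    compare against the analytic stationary variance with burst amplification."""
    bm, gm, bp, gp = 0.02, 1e-3, 0.05, 1e-4
    net = models.ReactionNetwork(
        species=("M", "P"),
        reactions=(
            models.Reaction("tx", (1, 0), Constant(bm)),
            models.Reaction("dm", (-1, 0), Linear(gm, 0)),
            models.Reaction("tl", (0, 1), Linear(bp, 0)),
            models.Reaction("dp", (0, -1), Linear(gp, 1)),
        ),
        model="two_stage",
    )
    st = moments.stationary_moments(net)
    m_mean = bm / gm
    p_mean = m_mean * bp / gp
    fano = 1.0 + bp / (gm + gp)  # classic two-stage expression result
    assert st.mean[0] == pytest.approx(m_mean, rel=1e-9)
    assert st.mean[1] == pytest.approx(p_mean, rel=1e-9)
    assert st.cov[1, 1] / st.mean[1] == pytest.approx(fano, rel=1e-9)


def test_trajectory_export_schema(cascade):
    init = moments.MomentState(0.0, np.array([1492.5, 0, 10.0, 100.0]), np.zeros((4, 4)))
    traj = moments.integrate_moments(cascade, init, [0.0, 75.0], x=50.0)
    frame = traj.to_frame(cascade)
    assert list(frame.columns) == ["time_min", "species", "mean", "variance"]
    assert set(frame["species"]) == set(cascade.species)
    cov = traj.cov_frame(cascade)
    assert list(cov.columns) == ["time_min", "species_i", "species_j", "covariance"]
    # symmetric pairs stored once: N(N+1)/2 rows per time
    assert len(cov) == 2 * (4 * 5 // 2)
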