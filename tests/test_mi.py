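"""MI pipeline: surfaces, interpolation, estimators, decompositions."""

from __future__ import annotations

import numpy as np
import pytest

from stochmi import mi, models, moments, populations


def _manual_surface(doses, mus, variances, t=100.0, name="Y"):
    """Surface with hand-set scalar moments at a single nonzero time."""
    doses = np.asarray(doses, dtype=float)
    D = doses.size
    means = np.zeros((D, 2, 1))
    covs = np.zeros((D, 2, 1, 1))
    means[:, 1, 0] = mus
    covs[:, 1, 0, 0] = variances
    covs[:, 0, 0, 0] = variances[0]
    means[:, 0, 0] = mus[0]
    return mi.DoseResponseSurface(doses, np.array([0.0, t]), (name,), means, covs)


class TestSurface:
    def test_t0_rows_dose_independent(self, cascade):
        init = populations.make_initial("S1", cascade)
        surf = mi.build_surface(cascade, [0.0, 50.0, 250.0], [0.0, 75.0], init, ["Y2"])
        assert np.ptp(surf.means[:, 0, 0]) == 0.0
        assert np.ptp(surf.covs[:, 0, 0, 0]) == 0.0

    def test_response_grows_with_time(self, cascade):
        """Mean y2 at the top dose keeps rising between 75 and 750 minutes."""
        init = populations.make_initial("S1", cascade)
        surf = mi.build_surface(cascade, [0.0, 250.0], [0.0, 75.0, 750.0], init, ["Y2"])
        assert surf.means[1, 2, 0] > surf.means[1, 1, 0] > surf.means[1, 0, 0]

    def test_interpolation_exact_at_grid_and_linear_between(self):
        surf = _manual_surface([0.0, 10.0], np.array([5.0, 15.0]), np.array([1.0, 3.0]))
        mu, C = surf.interpolate(10.0, 100.0)
        assert mu[0] == 15.0 and C[0, 0] == 3.0
        mu, C = surf.interpolate(5.0, 100.0)
        assert mu[0] == pytest.approx(10.0)
        assert C[0, 0] == pytest.approx(2.0)

    def test_extrapolation_rejected(self):
        surf = _manual_surface([0.0, 10.0], np.array([5.0, 15.0]), np.array([1.0, 3.0]))
        with pytest.raises(ValueError):
            surf.interpolate(11.0, 100.0)


class TestScalarMI:
    def test_identical_outputs_carry_no_information(self):
        surf = _manual_surface([0, 1, 2, 3], np.full(4, 50.0), np.full(4, 25.0))
        assert mi.mutual_information(surf, 100.0) == 0.0

    def test_step_input_not_yet_applied_gives_zero(self):
        surf = _manual_surface([0, 1, 2, 3], np.array([10.0, 20, 30, 40]), np.full(4, 4.0))
        assert mi.mutual_information(surf, 0.0) == 0.0

    def test_four_disjoint_doses_give_two_bits(self):
        """Perfect 4-symbol channel: disjoint output laws resolve log2(4) bits."""
        surf = _manual_surface([0, 1, 2, 3], np.array([100.0, 500, 900, 1300]), np.full(4, 9.0))
        bits = mi.mutual_information(surf, 100.0, n_grid=4)
        assert bits == pytest.approx(2.0, abs=1e-6)

    def test_two_dose_gaussian_channel_vs_quadrature_oracles(self):
        """Two-dose Gaussian channel against independent brute-force oracles.

        The pipeline evaluates the discrete molecular channel (probabilities
        summed over integer counts), so the exact oracle is the hand-computed
        sum over the binned laws; it matches to near machine precision.  When
        the output is well resolved (SD >> one molecule) the count
        quantization is immaterial and the continuous MI integral agrees to
        within 1e-3 bits."""
        from scipy import stats

        # exact discrete oracle at sd = 1 (quantization matters here)
        mus, sd = np.array([20.0, 23.0]), 1.0
        ks = np.arange(0, 44)
        binned = [stats.norm(m, sd).cdf(ks + 0.5) - stats.norm(m, sd).cdf(ks - 0.5) for m in mus]
        binned = [p / p.sum() for p in binned]
        pbar = 0.5 * (binned[0] + binned[1])
        oracle_disc = sum(
            0.5 * np.sum(p[p > 0] * np.log2(p[p > 0] / pbar[p > 0])) for p in binned
        )
        surf = _manual_surface([0.0, 1.0], mus, np.full(2, sd**2))
        bits = mi.mutual_information(surf, 100.0, n_grid=2)
        assert bits == pytest.approx(oracle_disc, abs=1e-9)

        # continuous oracle in the well-resolved regime (means 3 SD apart)
        mus, sd = np.array([200.0, 230.0]), 10.0
        ys = np.linspace(100.0, 330.0, 40001)
        p = np.stack(
            [np.exp(-0.5 * (ys - m) ** 2 / sd**2) / np.sqrt(2 * np.pi * sd**2) for m in mus]
        )
        pbar = p.mean(axis=0)
        integrand = 0.5 * sum(
            pk * np.log2(np.where(pk > 0, pk / np.maximum(pbar, 1e-300), 1.0)) for pk in p
        )
        oracle_cont = np.trapezoid(integrand, ys)
        surf = _manual_surface([0.0, 1.0], mus, np.full(2, sd**2))
        bits = mi.mutual_information(surf, 100.0, n_grid=2)
        assert bits == pytest.approx(oracle_cont, abs=1e-3)

    def test_mi_bounded_by_log2_doses_and_nonnegative(self, circuit_sgf, sgf_heterogeneous,
                                                      estradiol_protocol):
        surf = mi.build_surface(
            circuit_sgf, estradiol_protocol.doses, [0.0, 65.0, 580.0], sgf_heterogeneous, ["Y2"]
        )
        for n_grid in (12, 101, 501):
            for t in (0.0, 65.0, 580.0):
                b = mi.mutual_information(surf, t, n_grid=n_grid)
                assert 0.0 <= b <= np.log2(n_grid)

    def test_resolution_refinement_stable(self, circuit_sgf, sgf_heterogeneous, estradiol_protocol):
        """Doubling the interpolated dose grid moves the reported (measured-
        channel) MI by under 0.1 %; the bare molecular channel, whose
        zero-dose laws collapse to point masses, converges a little slower
        and is held to 0.5 %."""
        surf = mi.build_surface(
            circuit_sgf, estradiol_protocol.doses, [0.0, 580.0], sgf_heterogeneous, ["Y2"]
        )
        bare_a = mi.mutual_information(surf, 580.0, n_grid=501)
        bare_b = mi.mutual_information(surf, 580.0, n_grid=1001)
        assert abs(bare_a - bare_b) / bare_a < 5e-3
        meas = mi.add_measurement_background(surf, {"Y2": (74.3, 24.8)})
        a = mi.mutual_information(meas, 580.0, n_grid=501)
        b = mi.mutual_information(meas, 580.0, n_grid=1001)
        assert abs(a - b) / a < 1e-3


class TestChooseN:
    def test_exact_geometric_sequence_extrapolates_exactly(self):
        ns = list(range(3, 15))
        mis = [3.0 - 2.0 * 0.5**n for n in ns]
        n, mi_inf, ok = mi.converged_n(ns, mis)
        assert ok
        assert mi_inf == pytest.approx(3.0, rel=1e-9)
        # first accepted N satisfies 2 * 0.5^N <= 0.01 * 3 within the window rule
        assert 2.0 * 0.5**n <= 0.03 + 1e-12

    def test_constant_sequence_converges_immediately(self):
        n, mi_inf, ok = mi.converged_n([3, 4, 5, 6], [1.5, 1.5, 1.5, 1.5])
        assert ok and n == 5 and mi_inf == 1.5

    def test_diverging_ratio_defers(self):
        ns = [3, 4, 5, 6]
        mis = [1.0, 1.1, 1.3, 1.7]  # differences double: r = 2 always
        n, mi_inf, ok = mi.converged_n(ns, mis)
        assert not ok and n == 6

    def test_needs_three_candidates(self):
        with pytest.raises(ValueError):
            mi.converged_n([3, 4], [1.0, 1.1])


@pytest.fixture(scope="module")
def joint_surface(circuit_sgf, sgf_heterogeneous, estradiol_protocol):
    surf = mi.build_surface(
        circuit_sgf, estradiol_protocol.doses, [0.0, 580.0], sgf_heterogeneous, ["Y1r", "Y2"]
    )
    return mi.add_measurement_background(surf, {"Y1r": (14.9, 5.0), "Y2": (74.3, 24.8)})


class TestEqualization:
    def test_reporter_information_removed(self, joint_surface):
        eq = mi.equalize_reporter_means(joint_surface)
        assert mi.mutual_information(eq, 580.0, observable="Y1r") < 1e-5

    def test_noise_and_correlation_preserved(self, joint_surface):
        eq = mi.equalize_reporter_means(joint_surface)
        for di in range(joint_surface.doses.size):
            m, c = joint_surface.means[di, 1], joint_surface.covs[di, 1]
            me, ce = eq.means[di, 1], eq.covs[di, 1]
            assert np.sqrt(ce[0, 0]) / me[0] == pytest.approx(np.sqrt(c[0, 0]) / m[0], rel=1e-12)
            rho = c[0, 1] / np.sqrt(c[0, 0] * c[1, 1])
            rho_e = ce[0, 1] / np.sqrt(ce[0, 0] * ce[1, 1])
            assert rho_e == pytest.approx(rho, rel=1e-12, abs=1e-12)

    def test_zero_dose_column_required(self, circuit_sgf, sgf_heterogeneous):
        surf = mi.build_surface(
            circuit_sgf, [10.0, 100.0], [0.0, 580.0], sgf_heterogeneous, ["Y1r", "Y2"]
        )
        with pytest.raises(ValueError):
            mi.equalize_reporter_means(surf)


class TestConditionalDecompositions:
    def test_single_node_grid_equals_sg_conditional(self, cascade_slow_g):
        """A one-node G grid degenerates to the G = gbar subpopulation, i.e.
        the Sg regime (conditional laws keep their intrinsic spread)."""
        doses = models.StepInputProtocol.geometric(250.0, 8).doses
        grid = populations.g_grid(cascade_slow_g.global_spec, n_nodes=1)
        econd = mi.expected_conditional_mi(cascade_slow_g, doses, [0.0, 300.0], grid=grid)
        cond = populations.conditional_stationary(cascade_slow_g, 50.0)
        pinned = cascade_slow_g.pin_global()
        surf = mi.build_surface(pinned, doses, [0.0, 300.0], cond, ["Y2"])
        direct = mi.mutual_information(surf, 300.0)
        assert econd.bits[1] == pytest.approx(direct, abs=1e-6)
        # the point-state S1 conditioning is strictly more informative
        s1 = populations.make_initial("S1", cascade_slow_g)
        surf1 = mi.build_surface(pinned, doses, [0.0, 300.0], s1, ["Y2"])
        assert mi.mutual_information(surf1, 300.0) > direct

    def test_diversity_metric_grows_with_time(self, cascade_slow_g):
        """I(y2; G | x+) increases over the sampling times as the slow
        variable imprints on the output.  It is small but nonzero at t = 0:
        the pre-stimulus y2 level is itself G-coupled through translation."""
        res = mi.conditional_mi_given_input(
            cascade_slow_g, 150.0, [0.0, 65.0, 165.0, 330.0, 750.0], n_nodes=15
        )
        assert 0.0 < res.bits[0] < 0.5
        assert np.all(np.diff(res.bits) > 0)
        assert res.bits[-1] > 0.5

    def test_requires_global_variable(self, cascade):
        with pytest.raises(ValueError):
            mi.conditional_mi_given_input(cascade, 150.0, [0.0, 65.0])
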