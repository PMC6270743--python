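"""Decay model curves: exponentials, FRET quenching, convolution, lifetimes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fretwav.decay_model import (
    ExponentialComponents,
    FretDecayParams,
    GaussianDistanceDistribution,
    InvalidParameterError,
    TCSPCHistogram,
    TimeGrid,
    amplitude_averaged_lifetime_and_qy,
    convolve_with_irf,
    delta_irf,
    distance_integration_grid,
    evaluate_multiexponential,
    fret_quenched_decay,
    gaussian_distance_pdf,
    gaussian_irf,
    total_donor_model,
    transfer_efficiency,
)


def _params(mean=60.0, sigma=6.0, x_d0=0.0, i0=1.0, bg=0.0, comp=None, r0=53.6):
    return FretDecayParams(
        donor_components=comp or ExponentialComponents((1.0,), (4.0,)),
        distance=GaussianDistanceDistribution(mean, sigma),
        forster_radius=r0,
        donor_only_fraction=x_d0,
        peak_amplitude=i0,
        background=bg,
    )


class TestMultiExponential:
    def test_origin_and_one_lifetime(self):
        grid = TimeGrid(bin_width=4.025, n_bins=2)
        comp = ExponentialComponents((1.0,), (4.025,))
        curve = evaluate_multiexponential(comp, 1.0, grid).counts
        assert curve[0] == pytest.approx(1.0)
        assert curve[1] == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_two_component_scalar_oracle(self):
        # donor-only 10-bp construct components evaluated at t = 2 ns
        grid = TimeGrid(bin_width=2.0, n_bins=2)
        comp = ExponentialComponents((0.94, 0.06), (4.06, 1.38))
        expected = 0.94 * math.exp(-2 / 4.06) + 0.06 * math.exp(-2 / 1.38)
        assert evaluate_multiexponential(comp, 1.0, grid).counts[1] == pytest.approx(expected)

    def test_invalid_components_rejected(self):
        with pytest.raises(InvalidParameterError):
            ExponentialComponents((1.0,), (-1.0,))
        with pytest.raises(InvalidParameterError):
            ExponentialComponents((0.5, 0.4), (4.0, 1.0))  # amplitudes must sum to 1


class TestTransferEfficiency:
    def test_symmetry_point_and_limits(self):
        assert transfer_efficiency(53.6, 53.6) == pytest.approx(0.5)
        assert transfer_efficiency(1e6, 53.6) < 1e-12
        assert transfer_efficiency(1e-6, 53.6) > 1 - 1e-12

    def test_table_values(self):
        # 17-bp filtered-measurement distance at the matching Forster radius
        assert transfer_efficiency(62.7, 53.6) == pytest.approx(0.281, abs=5e-4)

    def test_domain_error(self):
        with pytest.raises(InvalidParameterError):
            transfer_efficiency(-1.0, 53.6)


class TestGaussianDistance:
    def test_peak_density(self):
        dist = GaussianDistanceDistribution(60.0, 6.0)
        assert gaussian_distance_pdf(dist, 60.0) == pytest.approx(
            1.0 / (math.sqrt(2 * math.pi) * 6.0)
        )

    def test_one_sigma_ratio_and_normalization(self):
        dist = GaussianDistanceDistribution(60.0, 6.0)
        R, w = distance_integration_grid(dist)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        w54 = w[np.argmin(np.abs(R - 54.0))]
        w60 = w[np.argmin(np.abs(R - 60.0))]
        assert w54 / w60 == pytest.approx(math.exp(-0.5), rel=1e-6)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        mean=st.floats(20.0, 120.0),
        sigma=st.floats(0.5, 15.0),
    )
    def test_weights_always_normalized(self, mean, sigma):
        R, w = distance_integration_grid(GaussianDistanceDistribution(mean, sigma))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(R >= 1.0)


class TestFretQuenchedDecay:
    def test_delta_distribution_at_forster_radius_doubles_rate(self, grid_short):
        p = _params(mean=53.6, sigma=0.0)
        curve = fret_quenched_decay(p, grid_short).counts
        t = grid_short.times
        expected = np.exp(-2.0 * t / 4.0)  # E = 0.5 doubles the decay rate
        np.testing.assert_allclose(curve, expected, rtol=1e-12)

    def test_matches_fine_grid_quadrature(self, grid_short):
        p = _params(mean=60.0, sigma=6.0)
        curve = fret_quenched_decay(p, grid_short).counts
        # independent oracle: brute-force quadrature at 0.01 A over +-8 sigma
        R = np.arange(60.0 - 48.0, 60.0 + 48.0 + 1e-9, 0.01)
        w = np.exp(-0.5 * ((R - 60.0) / 6.0) ** 2)
        w /= w.sum()
        rate = (1.0 + (53.6 / R) ** 6) / 4.0
        oracle = np.exp(-np.outer(grid_short.times, rate)) @ w
        np.testing.assert_allclose(curve, oracle, rtol=1e-3)

    def test_sigma_to_zero_limit(self, grid_short):
        p0 = _params(mean=60.0, sigma=0.0)
        p1 = _params(mean=60.0, sigma=0.01)
        c0 = fret_quenched_decay(p0, grid_short).counts
        c1 = fret_quenched_decay(p1, grid_short).counts
        np.testing.assert_allclose(c1, c0, rtol=1e-4)

    def test_monotone_in_mean_distance(self, grid_short):
        t_idx = 600  # ~9.6 ns
        values = [
            fret_quenched_decay(_params(mean=m, sigma=4.0), grid_short).counts[t_idx]
            for m in (35.0, 45.0, 55.0, 65.0, 80.0)
        ]
        assert np.all(np.diff(values) > 0)  # larger distance -> less quenching

    def test_interval_below_floor_rejected(self):
        with pytest.raises(InvalidParameterError):
            distance_integration_grid(GaussianDistanceDistribution(0.5, 0.01), r_min=1.0)


class TestTotalModel:
    def test_pure_donor_only_mixture(self, grid_short, donor_components):
        p = _params(x_d0=1.0, i0=100.0, bg=5.0, comp=donor_components)
        total = total_donor_model(p, grid_short).counts
        d0 = evaluate_multiexponential(donor_components, 100.0, grid_short).counts
        np.testing.assert_allclose(total, d0 + 5.0, rtol=1e-12)

    def test_no_donor_only_no_background(self, grid_short):
        p = _params(x_d0=0.0, i0=50.0)
        total = total_donor_model(p, grid_short).counts
        fda = fret_quenched_decay(p, grid_short).counts
        np.testing.assert_allclose(total, 50.0 * fda, rtol=1e-12)

    def test_study_configuration_peak_value(self, grid_full, low_fret_params):
        # both mixture components equal 1 at t=0: peak = I0 + BG
        total = total_donor_model(low_fret_params, grid_full).counts
        assert total[0] == pytest.approx(1.0e4 + 20.0)


class TestConvolution:
    def test_identity_kernel(self, grid_short):
        model = TCSPCHistogram(grid_short, np.exp(-grid_short.times / 4.0))
        out = convolve_with_irf(model, delta_irf(grid_short))
        np.testing.assert_array_equal(out.counts, model.counts)

    def test_mass_conservation(self, grid_short, rng):
        # kernel well inside the grid, signal decayed at the end: no truncation
        model = TCSPCHistogram(grid_short, np.exp(-grid_short.times / 1.0))
        irf = gaussian_irf(grid_short, fwhm=0.3, t0=1.0)
        out = convolve_with_irf(model, irf)
        assert out.total == pytest.approx(model.total, rel=1e-6)

    def test_tail_slope_preserved(self, grid_short):
        # Gaussian IRF (544 ps FWHM) must not change the asymptotic lifetime
        model = TCSPCHistogram(grid_short, np.exp(-grid_short.times / 4.0))
        out = convolve_with_irf(model, gaussian_irf(grid_short, fwhm=0.544, t0=2.0))
        t = grid_short.times
        sel = (t > 5.0) & (t < 18.0)
        slope = np.polyfit(t[sel], np.log(out.counts[sel]), 1)[0]
        assert slope == pytest.approx(-1.0 / 4.0, rel=0.01)

    def test_grid_mismatch(self, grid_short, grid_full):
        model = TCSPCHistogram(grid_short, np.ones(grid_short.n_bins))
        with pytest.raises(Exception):
            convolve_with_irf(model, delta_irf(grid_full))


class TestAmplitudeAveragedLifetime:
    @pytest.mark.parametrize(
        "amps, taus, ref_tau, ref_qy, expected_phi",
        [
            ((0.91, 0.09), (4.09, 1.52), 4.025, 0.92, 0.88),  # donor-only 17-bp
            ((0.28, 0.72), (1.38, 0.88), 1.053, 0.33, 0.32),  # acceptor-only
        ],
    )
    def test_quantum_yields_from_reference_dyes(self, amps, taus, ref_tau, ref_qy, expected_phi):
        comp = ExponentialComponents(amps, taus)
        tau_avg, phi = amplitude_averaged_lifetime_and_qy(comp, ref_tau, ref_qy)
        assert tau_avg == pytest.approx(np.dot(amps, taus))
        assert round(phi, 2) == expected_phi

    def test_single_component(self):
        comp = ExponentialComponents((1.0,), (4.025,))
        tau_avg, _ = amplitude_averaged_lifetime_and_qy(comp, 4.025, 0.92)
        assert tau_avg == 4.025
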