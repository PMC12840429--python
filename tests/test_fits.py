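"""Exponent and curve fits on synthetic, exactly known inputs."""

import numpy as np
import pandas as pd
import pytest

from gradperc import (
    InsufficientDataError,
    estimate_tau,
    fit_pc_polynomial,
    fit_smax_line,
    tau_by_row,
)


def power_law_histogram(tau, s_max=4096, scale=1e9):
    return {s: scale * s ** (-tau) for s in range(1, s_max + 1)}


class TestEstimateTau:
    def test_exact_inverse_square_law(self):
        fit = estimate_tau(power_law_histogram(2.0), fit_range=(1, 4096))
        assert fit.tau == pytest.approx(2.00, abs=0.01)

    @pytest.mark.parametrize("tau_true", [1.5, 2.055, 3.0])
    def test_recovers_other_exponents(self, tau_true):
        fit = estimate_tau(power_law_histogram(tau_true), fit_range=(1, 4096))
        assert fit.tau == pytest.approx(tau_true, abs=0.02)

    def test_invariant_under_count_rescaling(self):
        h = power_law_histogram(2.3)
        a = estimate_tau(h, fit_range=(1, 4096))
        b = estimate_tau({s: 0.001 * c for s, c in h.items()}, fit_range=(1, 4096))
        assert a.tau == pytest.approx(b.tau, abs=1e-12)
        assert a.n_bins == b.n_bins

    def test_too_few_bins_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_tau({1: 10, 2: 5, 3: 3}, fit_range=(1, 4))

    def test_empty_histogram_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_tau({})

    def test_default_range_uses_mass_percentile(self):
        fit = estimate_tau(power_law_histogram(2.0))
        assert fit.fit_range[0] == 5.0
        assert fit.fit_range[1] > fit.fit_range[0]
        assert fit.tau == pytest.approx(2.0, abs=0.01)


def make_table(x, y, se=None):
    data = {"one_minus_qp": x, "mean_pc": y, "mean_smax_norm": y}
    if se is not None:
        data["se_pc"] = se
    return pd.DataFrame(data)


class TestPcPolynomial:
    COEFFS = (0.5902, 0.1555, -1.1787, 2.3102, -1.7327)

    def test_noiseless_quartic_recovered_to_6_decimals(self):
        x = np.linspace(0, 0.99, 11)
        y = sum(c * x**i for i, c in enumerate(self.COEFFS))
        fit = fit_pc_polynomial(make_table(x, y))
        np.testing.assert_allclose(fit.coefficients, self.COEFFS, atol=1e-6)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.reduced_chi_square is None  # no errors supplied

    def test_weighted_fit_reports_reduced_chi_square(self):
        x = np.linspace(0, 0.99, 11)
        y = sum(c * x**i for i, c in enumerate(self.COEFFS))
        fit = fit_pc_polynomial(make_table(x, y, se=np.full(11, 1e-3)))
        np.testing.assert_allclose(fit.coefficients, self.COEFFS, atol=1e-6)
        assert fit.reduced_chi_square == pytest.approx(0.0, abs=1e-6)

    def test_constant_input_gives_constant_polynomial(self):
        x = np.linspace(0, 1, 9)
        fit = fit_pc_polynomial(make_table(x, np.full(9, 0.42)))
        assert fit.coefficients[0] == pytest.approx(0.42, abs=1e-9)
        np.testing.assert_allclose(fit.coefficients[1:], 0.0, atol=1e-7)

    def test_too_few_points_rejected(self):
        x = np.linspace(0, 1, 5)
        with pytest.raises(InsufficientDataError):
            fit_pc_polynomial(make_table(x, x))

    def test_parameter_recovery_under_noise(self):
        """Coefficients recovered from noisy resamples of the fitted curve
        scatter around the truth."""
        x = np.linspace(0, 0.99, 11)
        y = sum(c * x**i for i, c in enumerate(self.COEFFS))
        rng = np.random.default_rng(0)
        recovered = []
        for _ in range(50):
            noisy = y + rng.normal(0, 2e-3, size=len(x))
            recovered.append(fit_pc_polynomial(make_table(x, noisy)).coefficients)
        recovered = np.array(recovered)
        mean, sd = recovered.mean(axis=0), recovered.std(axis=0, ddof=1)
        for m, s, truth in zip(mean, sd, self.COEFFS):
            assert abs(m - truth) < 3 * s / np.sqrt(50) + 1e-9


class TestSmaxLine:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 0.9, 10)
        fit = fit_smax_line(make_table(x, -0.2 * x + 0.3))
        assert fit.coefficients == pytest.approx((0.3, -0.2))
        assert fit.r_squared == pytest.approx(1.0)

    def test_permutation_invariance(self):
        x = np.array([0.0, 0.3, 0.6, 0.9])
        y = np.array([0.30, 0.25, 0.17, 0.12])
        a = fit_smax_line(make_table(x, y))
        rng = np.random.default_rng(1)
        idx = rng.permutation(4)
        b = fit_smax_line(make_table(x[idx], y[idx]))
        assert a.coefficients == pytest.approx(b.coefficients)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_smax_line(make_table([0.0, 0.5], [0.3, 0.2]))


def test_tau_by_row_marks_insufficient_histograms():
    table = tau_by_row({0.5: power_law_histogram(2.0), 0.9: {1: 3, 2: 1}})
    row_ok = table[table.qp == 0.5].iloc[0]
    row_bad = table[table.qp == 0.9].iloc[0]
    assert row_ok.tau == pytest.approx(2.0, abs=0.02)
    assert np.isnan(row_bad.tau)
    assert table.one_minus_qp.is_monotonic_increasing
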