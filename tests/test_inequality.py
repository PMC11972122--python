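"""Unit tests for the 1-D inequality and coverage machinery."""

import math

import numpy as np
import pytest

from s2map import (
    AltMetricParams,
    DegenerateSignalWarning,
    InvalidSignalError,
    alternative_metric,
    center_weights,
    cwsnr,
    degree_of_inequality,
    di_derivative,
    signal_noise_ratio,
)
from conftest import brute_force_di

SQRT3_2 = math.sqrt(3) / 2


class TestDegreeOfInequality:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([0, 0, 0, 0, 0, 0, 0, 1, 0, 0], -0.5),
            ([0] * 14 + [1, 1] + [0] * 4, -0.5),
            ([1, 1, 1, 1, 1], 0.0),
            ([1, 0, 0, 0, 0], 0.8),  # single unit at position p: (n+1-2p)/n
            ([0, 0, 0, 0, 1], -0.8),
            ([0, 0, 1, 0, 0], 0.0),
        ],
    )
    def test_known_profiles(self, x, expected):
        assert degree_of_inequality(x) == pytest.approx(expected, abs=1e-12)

    def test_single_unit_closed_form(self):
        # mass at 1-based position p of n pixels gives (n + 1 - 2p) / n
        for n in (3, 7, 12):
            for p in range(1, n + 1):
                x = np.zeros(n)
                x[p - 1] = 3.5
                assert degree_of_inequality(x) == pytest.approx(
                    (n + 1 - 2 * p) / n, abs=1e-12
                )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            x = rng.random(int(rng.integers(1, 30))) * 10
            assert degree_of_inequality(x) == pytest.approx(
                brute_force_di(x), abs=1e-12
            )

    def test_all_zero_convention(self):
        assert degree_of_inequality([0.0, 0.0, 0.0]) == 0.0

    @pytest.mark.parametrize("bad", [[], [1.0, -0.5], [np.nan, 1.0]])
    def test_invalid_inputs_raise(self, bad):
        with pytest.raises(InvalidSignalError):
            degree_of_inequality(bad)


class TestDerivativeAndSnr:
    def test_worked_example(self):
        d = di_derivative([0, 0, 3, 2, 1])
        assert d == pytest.approx([-0.2, -0.2, 0.3, 2 / 15, -1 / 30], abs=1e-12)

    def test_uniform_and_spike(self):
        assert di_derivative([1, 1, 1, 1]) == pytest.approx([0, 0, 0, 0], abs=1e-15)
        assert di_derivative([5, 0, 0, 0, 0]) == pytest.approx(
            [0.8, -0.2, -0.2, -0.2, -0.2], abs=1e-12
        )

    def test_finite_difference_oracle(self, rng):
        # dDI(k) must equal the difference of consecutive Lorenz prefix terms
        for _ in range(50):
            x = rng.random(int(rng.integers(2, 50)))
            n = x.size
            prefix = np.cumsum(x) / x.sum() - np.arange(1, n + 1) / n
            oracle = np.diff(prefix, prepend=0.0)
            assert di_derivative(x) == pytest.approx(oracle, abs=1e-12)

    def test_snr_counts(self):
        c_s, c_n, snr = signal_noise_ratio(di_derivative([0, 0, 3, 2, 1]))
        assert (c_s, c_n) == (2, 3)
        assert snr == pytest.approx(2 / 3)
        assert signal_noise_ratio(di_derivative([1, 1, 1]))[2] == 0.0
        assert signal_noise_ratio(di_derivative([5, 0, 0, 0, 0])) == (1, 4, 0.25)

    def test_all_positive_capped_with_warning(self):
        with pytest.warns(DegenerateSignalWarning):
            c_s, c_n, snr = signal_noise_ratio([0.1, 0.2])
        assert (c_s, c_n, snr) == (2, 0, 2.0)


class TestCenterWeights:
    def test_odd_profiles(self):
        assert center_weights(5) == pytest.approx([0, SQRT3_2, 1, SQRT3_2, 0])
        assert center_weights(3) == pytest.approx([0, 1, 0])
        assert center_weights(1) == pytest.approx([1.0])

    def test_even_profile_symmetry_and_center(self):
        n = 8
        w = center_weights(n)
        assert w == pytest.approx(w[::-1])
        expected_center = math.sqrt(1 - (1 / (n - 1)) ** 2)
        assert w[3] == pytest.approx(expected_center)
        assert w[0] == w[-1] == 0.0

    def test_monotone_from_center(self):
        w = center_weights(11)
        assert np.all(np.diff(w[:6]) >= 0) and np.all(np.diff(w[5:]) <= 0)

    def test_zero_length_rejected(self):
        with pytest.raises(InvalidSignalError):
            center_weights(0)


class TestCwsnr:
    def test_worked_example_composed_and_brute_forced(self):
        dec = cwsnr([0, 0, 3, 2, 1])
        expected = (2 / 3) * (0.3 * 1.0 + (2 / 15) * SQRT3_2)
        assert dec.cwsnr == pytest.approx(expected, abs=1e-12)
        assert dec.cwsnr == pytest.approx(0.2770, abs=5e-5)
        # independent recomposition from the returned intermediates
        assert dec.cwsnr == pytest.approx(dec.snr * float(np.sum(dec.v * dec.w)))
        assert dec.c_signal + dec.c_noise == 5

    def test_uniform_and_zero_are_degenerate_zero(self):
        assert cwsnr([2, 2, 2, 2]).cwsnr == 0.0
        dec = cwsnr([0, 0, 0])
        assert dec.cwsnr == 0.0 and dec.di == 0.0 and dec.snr == 0.0

    def test_positive_part_relation(self, rng):
        x = rng.random(15)
        dec = cwsnr(x)
        assert dec.v == pytest.approx(np.maximum(dec.d_di, 0.0))
        assert dec.cwsnr >= 0.0


class TestAlternativeMetrics:
    def test_shannon_uniform_attains_log_n(self):
        assert alternative_metric([1, 1, 1, 1], "shannon") == pytest.approx(2.0)

    def test_simpson_is_one_minus_hhi(self, rng):
        x = rng.random(12)
        assert alternative_metric(x, "simpson") == pytest.approx(
            1.0 - alternative_metric(x, "hhi")
        )

    def test_atkinson_zero_at_equality(self):
        assert alternative_metric([2, 2, 2, 2], "atkinson") == pytest.approx(0.0)

    def test_theil_positive_and_matches_literal_transcription(self):
        eps = 0.01
        x = np.array([1.0, 2.0, 3.0])
        shifted = x + eps
        mu = shifted.mean()
        oracle = np.mean((shifted / mu) * np.log(shifted / mu))
        value = alternative_metric(x, AltMetricParams(method="theil"))
        assert value == pytest.approx(oracle, abs=1e-14)
        assert value > 0

    def test_theil_zero_at_equality(self):
        assert alternative_metric([3, 3, 3], "theil") == pytest.approx(0.0, abs=1e-15)

    def test_all_zero_warns_and_returns_zero(self):
        with pytest.warns(DegenerateSignalWarning):
            assert alternative_metric([0, 0, 0], "shannon") == 0.0

    def test_bad_params_rejected(self):
        with pytest.raises(InvalidSignalError):
            alternative_metric([1, 2], "gini")
        with pytest.raises(InvalidSignalError):
            AltMetricParams(method="atkinson", atkinson_aversion=1.0)
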