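"""Kinetic model: closed forms, maximum condition, MACC score."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from qnuc.kinetics import (
    DigestionParams,
    apparent_occupancy,
    bound_fraction,
    canonicalize_rates,
    fit_macc,
    macc_model_score,
    time_of_maximum,
)


def ode_solution(d, p, rtol=1e-11):
    """Independent oracle: numerically integrate dB/dd=-k1*B, dN/dd=k1*B-k2*N."""
    if d == 0:
        return p.O, 0.0

    def rhs(_, y):
        B, N = y
        return [-p.k1 * B, p.k1 * B - p.k2 * N]

    sol = solve_ivp(rhs, (0.0, d), [p.O, 0.0], rtol=rtol, atol=1e-14, method="LSODA")
    return sol.y[0, -1], sol.y[1, -1]


def random_params(rng, n=50, min_separation=0.0):
    """Log-uniform rates in [0.01, 100] with the k2 <= k1 tail convention.

    ``min_separation`` redraws pairs with (k1-k2)/k1 below the given value:
    tail-slope convergence is governed by 1/(k1-k2), so tests of the
    asymptotic -k2 slope need non-degenerate pairs (the k1 == k2 limit has
    its own form, d*exp(-k*d), and is tested separately).
    """
    out = []
    while len(out) < n:
        k1, k2 = np.exp(rng.uniform(np.log(0.01), np.log(100.0), size=2))
        O = rng.uniform(0.05, 1.0)
        O, k1, k2 = canonicalize_rates(O, k1, k2)
        if (k1 - k2) < min_separation * k1:
            continue
        out.append(DigestionParams(O=O, k1=k1, k2=k2))
    return out


class TestBoundFraction:
    @pytest.mark.parametrize(
        "d,p,expected",
        [
            (0.0, DigestionParams(1, 1, 0.1), 1.0),
            (1.0, DigestionParams(1, 1, 0.1), math.exp(-1)),
            (0.0, DigestionParams(0.3, 7, 0.0), 1.0),
        ],
    )
    def test_values(self, d, p, expected):
        assert bound_fraction(d, p) == pytest.approx(expected, rel=1e-12)

    def test_decreasing_to_zero(self):
        p = DigestionParams(1, 2, 0.1)
        d = np.linspace(0, 50, 200)
        f = bound_fraction(d, p)
        assert np.all(np.diff(f) < 0)
        assert f[-1] < 1e-10

    def test_negative_d_rejected(self):
        with pytest.raises(ValueError):
            bound_fraction(-0.1, DigestionParams(1, 1, 0.1))


class TestApparentOccupancy:
    def test_zero_at_start(self):
        assert apparent_occupancy(0.0, DigestionParams(0.7, 3, 0.2)) == 0.0

    def test_reference_value_at_maximum(self):
        # at d* the curve equals O*exp(-k2*d*) analytically
        p = DigestionParams(1, 1, 0.1)
        d_star = math.log(10) / 0.9
        assert apparent_occupancy(d_star, p) == pytest.approx(
            math.exp(-0.1 * d_star), rel=1e-10
        )
        assert apparent_occupancy(d_star, p) == pytest.approx(0.7744, abs=5e-4)

    def test_degenerate_rates_limiting_form(self):
        # k1 == k2 exercises the O*k1*d*exp(-k1*d) branch
        val = apparent_occupancy(0.5, DigestionParams(0.5, 2, 2))
        assert val == pytest.approx(0.5 * (2 * 0.5) * math.exp(-1), rel=1e-10)
        assert val == pytest.approx(0.18394, abs=1e-5)

    def test_continuity_at_degeneracy(self):
        lim = apparent_occupancy(0.5, DigestionParams(1, 2, 2))
        for sign in (+1, -1):
            near = apparent_occupancy(
                0.5, DigestionParams(1, 2, 2 * (1 + sign * 1e-9))
            )
            assert near == pytest.approx(lim, rel=1e-6)

    def test_unimodal_and_bounded_by_O(self):
        p = DigestionParams(0.8, 1.5, 0.2)
        d = np.linspace(0, 40, 4000)
        f = np.asarray(apparent_occupancy(d, p))
        peak = np.argmax(f)
        assert 0 < peak < d.size - 1
        assert np.all(np.diff(f[: peak + 1]) > 0)
        assert np.all(np.diff(f[peak + 1 :]) < 0)
        assert f.max() <= p.O

    def test_linear_in_O(self):
        base = DigestionParams(0.25, 1.2, 0.07)
        triple = DigestionParams(0.75, 1.2, 0.07)
        d = np.array([0.3, 1.0, 4.0])
        np.testing.assert_allclose(
            apparent_occupancy(d, triple), 3 * np.asarray(apparent_occupancy(d, base))
        )

    def test_monotone_when_no_decay(self):
        # k2 = 0: N/C = O*(1 - exp(-k1*d)), rising to O
        p = DigestionParams(0.6, 1.3, 0.0)
        d = np.linspace(0, 20, 100)
        f = np.asarray(apparent_occupancy(d, p))
        np.testing.assert_allclose(f, 0.6 * (1 - np.exp(-1.3 * d)), rtol=1e-12)
        assert np.all(np.diff(f) > 0)

    def test_matches_ode_integration(self):
        """Closed form vs numerical integration of the rate equations."""
        rng = np.random.default_rng(42)
        for p in random_params(rng, n=50):
            for frac in (0.2, 1.0, 5.0):
                d = frac / max(p.k2, 1e-2)
                _, n_ode = ode_solution(d, p)
                n_cf = apparent_occupancy(d, p)
                assert n_cf == pytest.approx(n_ode, rel=1e-6, abs=1e-12 * p.O)

    def test_bound_fraction_matches_ode(self):
        rng = np.random.default_rng(7)
        for p in random_params(rng, n=10):
            d = 2.0 / p.k1
            b_ode, _ = ode_solution(d, p)
            assert bound_fraction(d, p) * p.O == pytest.approx(b_ode, rel=1e-6)

    def test_mass_bookkeeping(self):
        """f_B + f_N <= 1; equality only at d=0 or with no decay."""
        rng = np.random.default_rng(3)
        for p in random_params(rng, n=25):
            d = np.linspace(0.01, 5 / max(p.k2, 0.01), 50)
            total = bound_fraction(d, p) + np.asarray(apparent_occupancy(d, p)) / p.O
            assert np.all(total <= 1 + 1e-12)
            assert np.all(total < 1) or p.k2 == 0
        p0 = DigestionParams(0.5, 2, 0.0)
        d = np.linspace(0, 10, 20)
        np.testing.assert_allclose(
            bound_fraction(d, p0) + np.asarray(apparent_occupancy(d, p0)) / p0.O, 1.0
        )

    def test_asymptotic_log_slope_is_minus_k2(self):
        """For d >> 1/k2 the log-curve slope identifies k2, whatever k1 and O."""
        rng = np.random.default_rng(11)
        for p in random_params(rng, n=20, min_separation=0.05):
            d1 = max(20.0 / p.k2, 8.0 / (p.k1 - p.k2))
            d2 = 1.25 * d1
            slope = (
                math.log(apparent_occupancy(d2, p)) - math.log(apparent_occupancy(d1, p))
            ) / (d2 - d1)
            assert -slope == pytest.approx(p.k2, rel=0.01)


class TestTimeOfMaximum:
    def test_closed_form(self):
        p = DigestionParams(1, 1, 0.1)
        assert time_of_maximum(p) == pytest.approx(math.log(10) / 0.9, rel=1e-12)
        assert time_of_maximum(p) == pytest.approx(2.5584, abs=1e-4)

    def test_equal_rates_limit(self):
        assert time_of_maximum(DigestionParams(1, 2, 2)) == pytest.approx(0.5)

    def test_rate_time_rescaling(self):
        p = DigestionParams(1, 1.7, 0.3)
        p2 = DigestionParams(1, 3.4, 0.6)
        assert time_of_maximum(p2) == pytest.approx(time_of_maximum(p) / 2, rel=1e-12)

    def test_no_decay_gives_infinite_sentinel(self):
        assert time_of_maximum(DigestionParams(1, 1, 0.0)) == math.inf

    def test_maximizes_apparent_occupancy(self):
        """Grid + golden-section oracle locates the same maximum."""
        rng = np.random.default_rng(5)
        for p in random_params(rng, n=20):
            d_star = time_of_maximum(p)
            grid = np.linspace(d_star / 10, d_star * 10, 2001)
            i = int(np.argmax(apparent_occupancy(grid, p)))
            res = minimize_scalar(
                lambda d: -apparent_occupancy(d, p),
                bounds=(grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]),
                method="bounded",
                options={"xatol": d_star * 1e-10},
            )
            assert res.x == pytest.approx(d_star, rel=1e-6)


class TestMacc:
    def test_increasing_counts_are_inaccessible(self):
        fit = fit_macc([10, 20, 30], [1, 2, 4])
        assert fit.a == pytest.approx(10 / math.log(2), rel=1e-9)
        assert fit.macc == pytest.approx(-14.427, abs=1e-3)
        assert fit.label == "inaccessible"

    def test_decreasing_counts_are_accessible(self):
        fit = fit_macc([30, 20, 10], [1, 2, 4])
        assert fit.macc == pytest.approx(14.427, abs=1e-3)
        assert fit.label == "accessible"

    def test_flat_counts(self):
        fit = fit_macc([5, 5, 5], [1, 2, 4])
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        assert fit.macc == pytest.approx(0.0, abs=1e-12)

    def test_macc_is_negative_slope_exactly(self):
        fit = fit_macc([3, 1, 4, 1], [1, 2, 4, 8])
        assert fit.macc == -fit.a

    def test_requires_two_distinct_levels(self):
        with pytest.raises(ValueError):
            fit_macc([1, 2], [3, 3])
        with pytest.raises(ValueError):
            fit_macc([1, 2], [1, -2])

    def test_model_score_sign_flips_once_at_maximum(self):
        p = DigestionParams(1, 1, 0.1)
        d_star = time_of_maximum(p)
        assert macc_model_score(1.0, p) < 0
        assert macc_model_score(d_star, p) == pytest.approx(0.0, abs=1e-10)
        assert macc_model_score(10.0, p) > 0

    def test_model_score_matches_finite_difference(self):
        # score = -d * dN/dd, checked against a central difference
        p = DigestionParams(0.8, 2.0, 0.3)
        for d in (0.2, 1.0, 4.0):
            h = 1e-6
            fd = (apparent_occupancy(d + h, p) - apparent_occupancy(d - h, p)) / (2 * h)
            assert macc_model_score(d, p) == pytest.approx(-d * fd, rel=1e-5)

    def test_model_score_sign_flip_for_random_params(self):
        rng = np.random.default_rng(19)
        for p in random_params(rng, n=20):
            d_star = time_of_maximum(p)
            assert macc_model_score(0.5 * d_star, p) < 0
            assert macc_model_score(2.0 * d_star, p) > 0

    def test_rejects_nonpositive_d(self):
        with pytest.raises(ValueError):
            macc_model_score(0.0, DigestionParams(1, 1, 0.1))


class TestParams:
    @pytest.mark.parametrize("O,k1,k2", [(-0.1, 1, 0.1), (1, 0, 0.1), (1, 1, -0.2)])
    def test_invalid_params_rejected(self, O, k1, k2):
        with pytest.raises(ValueError):
            DigestionParams(O, k1, k2)

    def test_canonicalization_preserves_curve(self):
        O, k1, k2 = 0.4, 0.3, 5.0  # tail rate is k1 here
        Oc, k1c, k2c = canonicalize_rates(O, k1, k2)
        assert k2c <= k1c
        d = np.array([0.1, 1.0, 7.0])
        np.testing.assert_allclose(
            apparent_occupancy(d, DigestionParams(O, k1, k2)),
            apparent_occupancy(d, DigestionParams(Oc, k1c, k2c)),
            rtol=1e-10,
        )
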