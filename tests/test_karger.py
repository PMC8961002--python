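import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

import sandix as sx
from sandix.karger import (ExchangePair, exchange_rate_quadratic,
                           karger_largeb_series, karger_narrow_pulse,
                           karger_ode_signal, karger_pgse_fast,
                           karger_time_derivative, powder_quadrature,
                           stick_exchange_powder, stick_exchange_powder_bgrid)
from sandix.protocol import make_pgse


def matrix_exponential_oracle(seq, pair, n=10**4):
    """Product of exact matrix exponentials on a piecewise-constant
    (midpoint) discretization of q^2(t)."""
    h = seq.duration / n
    tm = (np.arange(n) + 0.5) * h
    q2 = seq.q2(tm)
    y = np.array([pair.f1, pair.f2])
    for k in range(n):
        A = np.array([[-pair.r1 - q2[k] * pair.D1, pair.r2],
                      [pair.r1, -pair.r2 - q2[k] * pair.D2]])
        y = expm(A * h) @ y
    return float(y.sum())


def powder_narrow_pulse(b, t, Dn, De, fn, rn):
    """Orientation quadrature of the closed-form narrow-pulse solution."""
    re = rn * fn / (1 - fn)

    def integrand(e):
        pair = ExchangePair(D1=Dn * e * e, D2=De, f1=fn, f2=1 - fn,
                            r1=rn, r2=re)
        return karger_narrow_pulse(b, t, pair)[0]

    return quad(integrand, 0, 1, epsabs=1e-12, epsrel=1e-12, limit=200)[0]


PAIR = ExchangePair.from_residence_time(0.5, 0.5, 0.85, 4.0)


class TestExchangePair:
    def test_detailed_balance_enforced(self):
        with pytest.raises(ValueError):
            ExchangePair(D1=1, D2=1, f1=0.5, f2=0.5, r1=0.2, r2=0.3)

    def test_from_residence_time(self):
        p = ExchangePair.from_residence_time(0.3, 1.0, 0.8, 5.0)
        assert p.r1 * p.f1 == pytest.approx(p.r2 * p.f2, abs=1e-15)
        assert p.tau1 == pytest.approx(5.0)


class TestOdeSignal:
    def test_no_exchange_is_biexponential(self):
        seq = make_pgse(5.0, 16.0, 4.5)
        pair = ExchangePair.from_residence_time(0.4, 0.6, 1.2, None)
        expect = 0.4 * np.exp(-5 * 0.6) + 0.6 * np.exp(-5 * 1.2)
        assert karger_ode_signal(seq, pair) == pytest.approx(expect, rel=1e-8)

    def test_equal_diffusivities_hide_exchange(self):
        seq = make_pgse(3.0, 16.0, 4.5)
        pair = ExchangePair.from_residence_time(0.5, 1.1, 1.1, 2.0)
        assert karger_ode_signal(seq, pair) == pytest.approx(
            np.exp(-3 * 1.1), rel=1e-8)

    def test_mass_conserved_without_gradient(self):
        seq = make_pgse(0.0, 16.0, 4.5)
        assert karger_ode_signal(seq, PAIR) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("b,tau", [(10.0, 4.0), (30.0, 12.0)])
    def test_matrix_exponential_oracle(self, b, tau):
        seq = make_pgse(b, 16.0, 4.5)
        pair = ExchangePair.from_residence_time(0.55, 0.5, 0.85, tau)
        oracle = matrix_exponential_oracle(seq, pair)
        assert abs(karger_ode_signal(seq, pair) - oracle) < 1e-8

    def test_fast_path_matches_ode(self):
        for b, tau in [(5.0, 2.0), (50.0, 8.0), (100.0, 50.0)]:
            seq = make_pgse(b, 16.0, 4.5)
            pair = ExchangePair.from_residence_time(0.5, 0.4, 1.0, tau)
            fast = karger_pgse_fast(seq, pair.D1, pair.D2, pair.r1, pair.r2,
                                    pair.f1, pair.f2, n_ramp=64)
            assert abs(fast - karger_ode_signal(seq, pair)) < 1e-7

    def test_decreasing_in_time_at_fixed_b(self):
        signals = [karger_ode_signal(make_pgse(25.0, D, 4.5), PAIR)
                   for D in (7.5, 11.0, 16.0)]
        assert np.all(np.diff(signals) < 0)


class TestNarrowPulse:
    def test_normalization_at_b0(self):
        S, sol = karger_narrow_pulse(0.0, 16.0, PAIR)
        assert S == pytest.approx(1.0, abs=1e-14)
        assert sol.fp1 + sol.fp2 == pytest.approx(1.0, abs=1e-12)

    def test_no_exchange_biexponential(self):
        pair = ExchangePair.from_residence_time(0.3, 0.5, 1.5, None)
        S, _ = karger_narrow_pulse(4.0, 16.0, pair)
        assert S == pytest.approx(0.3 * np.exp(-2.0) + 0.7 * np.exp(-6.0),
                                  rel=1e-12)

    def test_degenerate_exponents(self):
        # D1 = D2 and r1 = r2 = 0 makes a1 = a2; handled by the limit
        pair = ExchangePair.from_residence_time(0.5, 1.0, 1.0, None)
        S, _ = karger_narrow_pulse(2.0, 16.0, pair)
        assert S == pytest.approx(np.exp(-2.0), rel=1e-12)

    def test_ode_agreement_in_narrow_pulse_limit(self):
        """delta/Delta = 1e-3 reproduces the closed form to 1e-4."""
        seq = make_pgse(10.0, 16.0, 0.016)
        S, _ = karger_narrow_pulse(10.0, 16.0, PAIR)
        assert karger_ode_signal(seq, PAIR) == pytest.approx(S, rel=1e-4)

    def test_exponent_ordering(self):
        _, sol = karger_narrow_pulse(12.0, 10.0, PAIR)
        assert sol.a1 >= sol.a2
        assert sol.s == pytest.approx(sol.a1 - sol.a2, rel=1e-12)


class TestLargebSeries:
    def test_no_exchange_reduces_to_stick_term(self):
        fn = 0.6
        got = karger_largeb_series(100.0, 16.0, 0.5, 1.0, fn, 0.0, 0.0)
        assert got == pytest.approx(
            fn * np.sqrt(np.pi / (4 * 100 * 0.5)), rel=1e-12)

    def test_slow_exchange_accuracy(self):
        """Within 5% of the powder-integrated closed form at b=100,
        tau_n = 50 ms."""
        rn = 1 / 50.0
        fn = 0.5
        got = karger_largeb_series(100.0, 16.0, 0.5, 1.0, fn, rn,
                                   rn * fn / (1 - fn))
        oracle = powder_narrow_pulse(100.0, 16.0, 0.5, 1.0, fn, rn)
        assert got == pytest.approx(oracle, rel=0.05)

    def test_convergence_scan(self):
        """series/closed-form ratio approaches 1 monotonically in b."""
        rn, fn = 1 / 50.0, 0.5
        bs = np.geomspace(50, 5000, 7)
        ratios = []
        for b in bs:
            s = karger_largeb_series(b, 16.0, 0.5, 1.0, fn, rn,
                                     rn * fn / (1 - fn))
            ratios.append(s / powder_narrow_pulse(b, 16.0, 0.5, 1.0, fn, rn))
        err = np.abs(np.array(ratios) - 1.0)
        assert np.all(np.diff(err) < 0)
        assert err[-1] < 5e-3

    def test_warns_at_small_b(self):
        with pytest.warns(UserWarning):
            karger_largeb_series(1.0, 16.0, 0.5, 1.0, 0.5, 0.1, 0.1)


class TestTimeDerivative:
    def test_zero_cases(self):
        pair_eq = ExchangePair.from_residence_time(0.5, 1.0, 1.0, 4.0)
        assert karger_time_derivative(10.0, 16.0, pair_eq) == 0.0
        pair_norate = ExchangePair.from_residence_time(0.5, 0.5, 1.5, None)
        assert karger_time_derivative(10.0, 16.0, pair_norate) == 0.0

    def test_sign_and_finite_difference_grid(self):
        """Nonpositive everywhere; matches central differences of the
        closed form to 1e-6 relative on a random grid."""
        rng = np.random.default_rng(7)
        n = 1000
        for _ in range(n):
            b = rng.uniform(0.1, 60)
            t = rng.uniform(1, 40)
            f1 = rng.uniform(0.05, 0.95)
            pair = ExchangePair.from_residence_time(
                f1, rng.uniform(0.05, 3), rng.uniform(0.05, 3),
                rng.uniform(1, 100))
            d = karger_time_derivative(b, t, pair)
            assert d <= 0
            eps = 1e-4 * t
            fd = (karger_narrow_pulse(b, t + eps, pair)[0]
                  - karger_narrow_pulse(b, t - eps, pair)[0]) / (2 * eps)
            assert d == pytest.approx(fd, rel=1e-6, abs=1e-12)


class TestStickExchangePowder:
    def test_no_exchange_reduction(self):
        seq = make_pgse(20.0, 16.0, 4.5)
        got = stick_exchange_powder(seq, 1.9, 0.6, 0.45, 0.0)
        from sandix.compartments import gaussian_signal, stick_powder_signal
        expect = 0.45 * stick_powder_signal(20.0, 1.9) \
            + 0.55 * gaussian_signal(20.0, 0.6)
        assert got == pytest.approx(float(expect), rel=1e-12)

    def test_fast_exchange_limit(self):
        """rn -> inf surrogate: each spin sees the orientation-dependent
        mixed diffusivity fn Dn eps^2 + (1-fn) De, so the powder signal
        collapses to exp(-b (1-fn) De) * stick_powder(b, fn Dn); at small
        b this equals the single Gaussian with the powder-mixed
        diffusivity fn Dn/3 + (1-fn) De."""
        from sandix.compartments import stick_powder_signal
        fn, Dn, De = 0.5, 1.5, 0.9
        for b in (1.0, 3.0, 5.0):
            seq = make_pgse(b, 16.0, 4.5)
            got = stick_exchange_powder(seq, Dn, De, fn, 1e3)
            mixed = np.exp(-b * (1 - fn) * De) \
                * stick_powder_signal(b, fn * Dn)
            assert got == pytest.approx(float(mixed), rel=0.01)
        b = 0.3
        Dbar = fn * Dn / 3 + (1 - fn) * De
        got = stick_exchange_powder(make_pgse(b, 16.0, 4.5), Dn, De, fn, 1e3)
        assert got == pytest.approx(np.exp(-b * Dbar), rel=0.01)

    def test_delta_refinement_toward_narrow_pulse(self):
        """The finite-delta deviation from the narrow-pulse powder
        integral is bounded by the delta-halving difference and vanishes
        as delta -> 0."""
        b, Dn, De, fn, rn = 100.0, 0.5, 0.85, 0.5, 0.25
        oracle = powder_narrow_pulse(b, 16.0, Dn, De, fn, rn)

        def S(delta):
            return stick_exchange_powder(make_pgse(b, 16.0, delta),
                                         Dn, De, fn, rn)

        bound = 2.0 * abs(S(4.5) - S(2.25))
        assert abs(S(4.5) - oracle) <= bound
        assert abs(S(0.02) - oracle) / oracle < 2e-3

    def test_bgrid_consistency(self):
        b = np.array([1.0, 10.0, 100.0])
        grid = stick_exchange_powder_bgrid(b, 16.0, 4.5, 0.5, 0.85, 0.5, 0.25)
        for i, bv in enumerate(b):
            one = stick_exchange_powder(make_pgse(bv, 16.0, 4.5),
                                        0.5, 0.85, 0.5, 0.25)
            assert grid[i] == pytest.approx(one, rel=1e-12)

    def test_quadrature_order_doubling(self):
        """Order-doubling stability < 1e-6 relative at b = 100."""
        seq = make_pgse(100.0, 16.0, 4.5)
        a = stick_exchange_powder(seq, 0.5, 0.85, 0.5, 0.25,
                                  quad=powder_quadrature(64))
        c = stick_exchange_powder(seq, 0.5, 0.85, 0.5, 0.25,
                                  quad=powder_quadrature(128))
        assert abs(a - c) / c < 1e-6

    def test_signal_in_unit_interval_and_monotone_in_b(self):
        b = np.geomspace(0.1, 100, 30)
        s = stick_exchange_powder_bgrid(b, 16.0, 4.5, 0.5, 0.85, 0.55, 0.25)
        assert np.all((s > 0) & (s <= 1))
        assert np.all(np.diff(s) < 0)


class TestExchangeRateQuadratic:
    def test_recovers_rate_from_series(self):
        """Signals generated from the large-b series with slow exchange
        return rn within 10%."""
        rn, fn, Dn, De, b = 0.02, 0.7, 0.5, 1.0, 100.0
        re = rn * fn / (1 - fn)
        times = np.linspace(60.0, 75.0, 6)
        signals = np.array([karger_largeb_series(b, t, Dn, De, fn, rn, re)
                            for t in times])
        got = exchange_rate_quadratic(times, signals, b=b, De=De)
        assert got == pytest.approx(rn, rel=0.10)

    def test_zero_rate_input(self):
        times = np.array([10.0, 15.0, 20.0, 25.0])
        signals = np.full(4, 0.123)
        assert exchange_rate_quadratic(times, signals, b=50.0, De=1.0) == \
            pytest.approx(0.0, abs=1e-12)

    def test_noisy_replicates_no_crash(self):
        rng = np.random.default_rng(11)
        rn, fn, Dn, De, b = 0.02, 0.7, 0.5, 1.0, 100.0
        re = rn * fn / (1 - fn)
        times = np.linspace(60.0, 75.0, 6)
        clean = np.array([karger_largeb_series(b, t, Dn, De, fn, rn, re)
                          for t in times])
        est = []
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(100):
                noisy = clean * (1 + 0.01 * rng.standard_normal(len(clean)))
                est.append(exchange_rate_quadratic(times, noisy, b=b, De=De))
        bias = np.median(est) - rn
        assert np.isfinite(bias)
        assert abs(bias) < rn  # noise does not destroy the estimate

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            exchange_rate_quadratic([1.0, 2.0], [0.5, 0.4], b=50.0, De=1.0)
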