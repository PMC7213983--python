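"""Exponential-decay and two-state unfolding fit behavior."""

import numpy as np
import pandas as pd
import pytest

from calgevo import (
    DecayDataset,
    DenaturationCurve,
    KineticTrace,
    SimSpec,
    compare_rates,
    fit_exponential_decay,
    fit_two_state,
    fit_unfolding_kinetics,
    simulate_decay_dataset,
    simulate_denaturation,
    simulate_kinetic_trace,
    two_state_signal,
)
from calgevo.biophys import FitError, R_KCAL, T_STANDARD

RT = R_KCAL * T_STANDARD
TRUTH = dict(b_f=-20.0, m_f=0.1, b_u=-2.0, m_u=0.05, dG=8.0, m=1.6)


def _decay_table(k, A0=1.0, times=None, reps=3):
    times = np.linspace(0, 60, 10) if times is None else np.asarray(times)
    rows = [
        {"replicate": r, "time_min": t, "fraction_intact": A0 * np.exp(-k * t)}
        for r in range(reps)
        for t in times
    ]
    return DecayDataset(pd.DataFrame(rows))


class TestDecayFit:
    def test_noiseless_recovery(self):
        fit = fit_exponential_decay(_decay_table(0.05))
        assert fit.rate == pytest.approx(0.05, abs=1e-8)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-8)

    def test_two_point_closed_form(self):
        """(0, 1) and (t*, 1/e) pin k = 1/t* exactly."""
        t_star = 37.0
        rows = [
            {"replicate": 0, "time_min": t, "fraction_intact": f}
            for t, f in [(0, 1.0), (t_star, np.exp(-1)), (2 * t_star, np.exp(-2)),
                         (3 * t_star, np.exp(-3))]
        ]
        fit = fit_exponential_decay(DecayDataset(pd.DataFrame(rows)))
        assert fit.rate == pytest.approx(1.0 / t_star, rel=1e-6)

    def test_noisy_recovery_within_15_percent(self):
        spec = SimSpec(seed=1234)
        data, truth = simulate_decay_dataset(spec, k=0.1)
        fit = fit_exponential_decay(data)
        assert fit.rate == pytest.approx(truth["k_per_min"], rel=0.15)

    def test_per_replicate_amplitudes(self):
        data = _decay_table(0.05)
        fit = fit_exponential_decay(data, shared_amplitude=False)
        assert set(fit.per_replicate_amplitudes) == {0, 1, 2}
        assert fit.rate == pytest.approx(0.05, abs=1e-8)

    def test_too_few_time_points_rejected(self):
        with pytest.raises(FitError, match="4 distinct"):
            fit_exponential_decay(_decay_table(0.1, times=[0, 10, 20]))

    def test_all_zero_fractions_rejected(self):
        rows = [
            {"replicate": 0, "time_min": t, "fraction_intact": 0.0}
            for t in (0, 1, 2, 3)
        ]
        with pytest.raises(FitError, match="zero"):
            fit_exponential_decay(DecayDataset(pd.DataFrame(rows)))

    def test_parameter_recovery_and_coverage(self):
        """Median |k_hat/k - 1| < 0.1 and ~2-sigma coverage >= 80% across
        seeded simulations at rates spanning three orders of magnitude."""
        for k in (1e-3, 1e-2, 1e-1, 1.0):
            errors, covered = [], 0
            n_sim = 50
            for i in range(n_sim):
                spec = SimSpec(seed=9000 + i)
                data, _ = simulate_decay_dataset(spec, k=k)
                fit = fit_exponential_decay(data)
                errors.append(abs(fit.rate / k - 1.0))
                if abs(fit.rate - k) <= 2 * fit.sd_rate:
                    covered += 1
            assert np.median(errors) < 0.1, f"k={k}"
            assert covered / n_sim >= 0.8, f"k={k}"


class TestCompareRates:
    def test_three_orders_of_magnitude(self):
        fits = [
            fit_exponential_decay(_decay_table(1.0)),
            fit_exponential_decay(_decay_table(0.001, times=np.linspace(0, 3000, 10))),
        ]
        table = compare_rates(fits)
        assert table["log10_ratio"].iloc[0] == pytest.approx(3.0, abs=1e-6)

    def test_identical_rates_give_zero(self):
        fits = [fit_exponential_decay(_decay_table(0.05))] * 2
        assert compare_rates(fits)["log10_ratio"].iloc[0] == pytest.approx(0.0)

    def test_single_fit_rejected(self):
        with pytest.raises(FitError, match="at least two"):
            compare_rates([fit_exponential_decay(_decay_table(0.05))])


class TestTwoStateFit:
    def test_noiseless_recovery_all_parameters(self):
        x = np.linspace(0, 9, 25)
        y = two_state_signal(x, **TRUTH)
        fit = fit_two_state(DenaturationCurve(x, y))
        for name, value in TRUTH.items():
            assert getattr(fit, name) == pytest.approx(value, rel=1e-6), name

    def test_midpoint_is_baseline_mean(self):
        """At x = dG/m the exponent vanishes and the model sits exactly
        midway between the folded and unfolded baselines."""
        cm = TRUTH["dG"] / TRUTH["m"]
        y_mid = two_state_signal(np.array([cm]), **TRUTH)[0]
        folded = TRUTH["b_f"] + TRUTH["m_f"] * cm
        unfolded = TRUTH["b_u"] + TRUTH["m_u"] * cm
        assert y_mid == pytest.approx((folded + unfolded) / 2.0, abs=1e-12)

    def test_ddG_maps_to_midpoint_shift(self):
        """Two curves sharing baselines and m but dG apart by 4 kcal/mol
        show a fitted midpoint difference of 4/m molar."""
        x = np.linspace(0, 12, 35)
        lo = fit_two_state(
            DenaturationCurve(x, two_state_signal(x, **TRUTH))
        )
        hi_params = dict(TRUTH, dG=TRUTH["dG"] + 4.0)
        hi = fit_two_state(
            DenaturationCurve(x, two_state_signal(x, **hi_params))
        )
        assert hi.c_m - lo.c_m == pytest.approx(4.0 / TRUTH["m"], rel=0.01)

    def test_cm_times_m_equals_dG(self):
        spec = SimSpec(seed=5)
        curve, _ = simulate_denaturation(spec)
        fit = fit_two_state(curve)
        assert fit.c_m * fit.m == pytest.approx(fit.dG, abs=1e-9)

    def test_affine_rescaling_leaves_thermodynamics_unchanged(self):
        spec = SimSpec(seed=8)
        curve, _ = simulate_denaturation(spec)
        fit = fit_two_state(curve)
        scaled = DenaturationCurve(curve.x_molar, 3.0 * curve.signal + 100.0)
        fit2 = fit_two_state(scaled)
        assert fit2.dG == pytest.approx(fit.dG, rel=1e-4)
        assert fit2.m == pytest.approx(fit.m, rel=1e-4)
        assert fit2.c_m == pytest.approx(fit.c_m, rel=1e-4)
        assert fit2.b_f == pytest.approx(3.0 * fit.b_f + 100.0, rel=1e-3)

    def test_sd_matches_finite_difference_hessian(self):
        """Reported sds equal sqrt(diag(cov)) with cov ~ 2 s^2 H^-1 for the
        finite-difference Hessian H of the residual sum of squares."""
        spec = SimSpec(seed=77)
        curve, _ = simulate_denaturation(spec, noise_sigma=0.3)
        fit = fit_two_state(curve)
        popt = np.array([fit.b_f, fit.m_f, fit.b_u, fit.m_u, fit.dG, fit.m])

        def rss(p):
            resid = curve.signal - two_state_signal(curve.x_molar, *p)
            return float(resid @ resid)

        n, k = curve.x_molar.size, 6
        s2 = rss(popt) / (n - k)
        h = 1e-5 * np.maximum(np.abs(popt), 1.0)
        H = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                pp = popt.copy(); pp[i] += h[i]; pp[j] += h[j]
                pm = popt.copy(); pm[i] += h[i]; pm[j] -= h[j]
                mp = popt.copy(); mp[i] -= h[i]; mp[j] += h[j]
                mm = popt.copy(); mm[i] -= h[i]; mm[j] -= h[j]
                H[i, j] = (rss(pp) - rss(pm) - rss(mp) + rss(mm)) / (
                    4 * h[i] * h[j]
                )
        cov_fd = 2.0 * s2 * np.linalg.inv(H)
        sd_fd = np.sqrt(np.diag(cov_fd))
        sd_fit = np.array(
            [fit.sd_b_f, fit.sd_m_f, fit.sd_b_u, fit.sd_m_u, fit.sd_dG, fit.sd_m]
        )
        np.testing.assert_allclose(sd_fit, sd_fd, rtol=0.15)

    def test_sd_cm_propagates_covariance(self):
        spec = SimSpec(seed=12)
        curve, _ = simulate_denaturation(spec)
        fit = fit_two_state(curve)
        naive = np.sqrt(
            (fit.sd_dG / fit.m) ** 2 + (fit.dG * fit.sd_m / fit.m**2) ** 2
        )
        # with the (anti)correlated dG-m pair the propagated sd differs from
        # the no-covariance estimate and stays positive
        assert fit.sd_c_m > 0
        assert fit.sd_c_m != pytest.approx(naive, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError, match="8 points"):
            DenaturationCurve(np.arange(5), np.arange(5.0))


class TestUnfoldingKinetics:
    def test_slow_rate_recovered_and_resolvable(self):
        spec = SimSpec(seed=4)
        trace, truth = simulate_kinetic_trace(spec, k_u=0.01, dead_time=10.0,
                                              noise_sigma=0.05)
        fit = fit_unfolding_kinetics(trace)
        assert fit.rate == pytest.approx(truth["k_u_per_s"], rel=0.1)
        assert not fit.within_dead_time

    def test_flat_trace_flags_dead_time(self):
        t = np.linspace(0, 100, 30)
        trace = KineticTrace(t, np.full_like(t, -5.0), dead_time=10.0)
        assert fit_unfolding_kinetics(trace).within_dead_time

    def test_fast_rate_flags_dead_time(self):
        t = np.linspace(0, 20, 40)
        y = -5.0 - 10.0 * np.exp(-0.5 * t)
        fit = fit_unfolding_kinetics(KineticTrace(t, y, dead_time=10.0))
        assert fit.rate == pytest.approx(0.5, rel=1e-4)
        assert fit.within_dead_time  # 1/k = 2 s < 10 s dead time
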