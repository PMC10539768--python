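"""Monte Carlo verification of the CRLB, noise titration, SNR_lim fitting."""

import math
import warnings

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

import dosyres as dr
from dosyres import DecayCurve, fit_exponential, mc_resolution, simulate_decay
from dosyres.montecarlo import _batch_fit_exponential


def chi_inverse_inflation(dof: int) -> float:
    """E[1/sqrt(chi2_k/k)]: the factor by which the mean of beta/sigma_beta
    exceeds the true beta/sigma_beta when sigma_beta is estimated from k
    residual degrees of freedom."""
    return math.sqrt(dof / 2.0) * gamma_fn((dof - 1) / 2.0) / gamma_fn(dof / 2.0)


class TestSimulateDecay:
    def test_noiseless_flag(self, quinine_design):
        c = simulate_decay(quinine_design, snr=math.inf, s0=2.0)
        np.testing.assert_allclose(c.amplitudes, 2.0 * np.exp(-quinine_design.epsilons))

    def test_determinism_under_seed(self, quinine_design):
        c1 = simulate_decay(quinine_design, snr=100.0, seed=42)
        c2 = simulate_decay(quinine_design, snr=100.0, seed=42)
        np.testing.assert_array_equal(c1.amplitudes, c2.amplitudes)

    def test_noise_standard_deviation(self):
        """Residual sd over 1e5 points matches s0/(2 SNR) within 1%."""
        eps = np.linspace(0.0, 1.0, 100_000)
        c = simulate_decay(eps, snr=50.0, s0=3.0, seed=1)
        resid = c.amplitudes - 3.0 * np.exp(-eps)
        assert np.std(resid) == pytest.approx(3.0 / (2 * 50.0), rel=0.01)


class TestFitExponential:
    def test_noiseless_exact_recovery(self, quinine_design):
        c = simulate_decay(quinine_design, snr=math.inf, s0=1.0)
        res = fit_exponential(c)
        assert res.alpha == pytest.approx(1.0, abs=1e-9)
        assert res.beta == pytest.approx(1.0, abs=1e-9)

    def test_constant_curve_zero_rate(self):
        eps = np.array([0.1, 0.5, 1.0, 2.0])
        res = fit_exponential(DecayCurve(eps, np.ones(4)))
        assert res.beta == pytest.approx(0.0, abs=1e-10)
        assert res.r_d == 0.0

    def test_against_grid_search_oracle(self, quinine_design):
        """NLS optimum matches a brute-force 2-D grid search refined to 1e-6."""
        c = simulate_decay(quinine_design, snr=100.0, seed=2024)
        res = fit_exponential(c)
        eps, S = c.epsilons, c.amplitudes

        def ssr(a, b):
            return np.sum((S - a * np.exp(-b * eps)) ** 2)

        a_lo, a_hi, b_lo, b_hi = 0.5, 1.5, 0.5, 1.5
        for _ in range(12):  # bisect the grid window down to ~1e-6
            aa = np.linspace(a_lo, a_hi, 21)
            bb = np.linspace(b_lo, b_hi, 21)
            vals = np.array([[ssr(a, b) for b in bb] for a in aa])
            i, j = np.unravel_index(np.argmin(vals), vals.shape)
            da, db = (a_hi - a_lo) / 20, (b_hi - b_lo) / 20
            a_lo, a_hi = aa[i] - 2 * da, aa[i] + 2 * da
            b_lo, b_hi = bb[j] - 2 * db, bb[j] + 2 * db
        a_star, b_star = (a_lo + a_hi) / 2, (b_lo + b_hi) / 2
        assert res.alpha == pytest.approx(a_star, abs=1e-5)
        assert res.beta == pytest.approx(b_star, abs=1e-5)
        # sigma_beta from the normal-equations covariance at the optimum
        E = np.exp(-res.beta * eps)
        J = np.column_stack([E, -res.alpha * eps * E])
        cov = np.linalg.inv(J.T @ J) * ssr(res.alpha, res.beta) / (eps.size - 2)
        assert res.sigma_beta == pytest.approx(math.sqrt(cov[1, 1]), rel=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(DecayCurve(np.array([0.1, 0.2]), np.array([1.0, 0.9])))

    def test_duplicate_epsilons_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(DecayCurve(np.array([0.1, 0.1, 0.3]), np.ones(3)))

    def test_batch_fitter_matches_scipy(self, quinine_design):
        """The vectorized Gauss-Newton path agrees with the reference fitter."""
        eps = quinine_design.epsilons
        rng = np.random.default_rng(5)
        S = np.exp(-eps)[None, :] + rng.normal(0, 1 / 200, size=(10, eps.size))
        alpha, beta, sigma_beta, conv = _batch_fit_exponential(eps, S, 1 / 200)
        assert conv.all()
        for i in range(10):
            ref = fit_exponential(DecayCurve(eps, S[i], snr=100.0))
            assert beta[i] == pytest.approx(ref.beta, abs=1e-8)
            assert sigma_beta[i] == pytest.approx(ref.sigma_beta, rel=1e-6)


class TestMcResolution:
    def test_tiny_n_against_crlb(self):
        """1e5-replicate ensemble at N=3 sits within 2% of the analytic bound."""
        sched = dr.epsilon_schedule("linear", 3, 0.05, 1.0)
        res = mc_resolution(sched, 50.0, n_reps=100_000, seed=9)
        crlb = dr.crlb_resolution(sched, 50.0)
        assert abs(res.r_d / crlb - 1.0) < 0.02
        assert res.n_failures == 0

    def test_linearity_in_snr(self):
        sched = dr.epsilon_schedule("linear", 37, 0.05, 2.0)
        r1 = mc_resolution(sched, 100.0, n_reps=2000, seed=3).r_d
        r2 = mc_resolution(sched, 200.0, n_reps=2000, seed=3).r_d
        assert r2 == pytest.approx(2 * r1, rel=0.02)

    def test_ensemble_vs_per_fit_sigma(self):
        """Covariance-based per-fit errors agree with the ensemble spread."""
        sched = dr.epsilon_schedule("quadratic", 16, 0.05, 1.5)
        res = mc_resolution(sched, 100.0, n_reps=5000, seed=4)
        assert res.mean_sigma_beta == pytest.approx(1.0 / res.r_d, rel=0.05)

    def test_replicate_stability_under_n_reps(self):
        """Growing the ensemble does not reshuffle earlier replicates: the
        smaller run's R_D is reproduced by the first part of the larger one."""
        sched = dr.epsilon_schedule("linear", 10, 0.05, 1.0)
        small = mc_resolution(sched, 100.0, n_reps=500, seed=7)
        large = mc_resolution(sched, 100.0, n_reps=1000, seed=7)
        # the two estimates share their first 500 replicates, so they differ
        # by far less than two independent runs would
        assert abs(small.r_d / large.r_d - 1.0) < 0.08

    def test_rejects_tiny_ensembles(self, quinine_design):
        with pytest.raises(ValueError):
            mc_resolution(quinine_design, 100.0, n_reps=10, seed=0)


class TestTitration:
    def test_zero_added_noise_is_idempotent(self, quinine_design):
        curve = simulate_decay(quinine_design, snr=200.0, seed=12)
        tit = dr.titrate_noise(curve, [200.0], n_additions=50, seed=1)
        single = fit_exponential(curve)
        assert tit.mean_r_d[0] == pytest.approx(single.r_d, rel=1e-9)

    def test_target_above_intrinsic_rejected(self, quinine_design):
        curve = simulate_decay(quinine_design, snr=100.0, seed=0)
        with pytest.raises(ValueError):
            dr.titrate_noise(curve, [150.0], seed=0)

    def test_low_snr_limb_follows_crlb(self, quinine_design, quadratic_params):
        """Noise-dominated levels track the unmodified CRLB line (times the
        known chi-inverse inflation of the per-fit estimator)."""
        curve = simulate_decay(quinine_design, snr=14400.0, seed=7, snr_lim=300.0)
        levels = np.array([20.0, 40.0, 80.0])
        tit = dr.titrate_noise(curve, levels, n_additions=100, seed=11)
        infl = chi_inverse_inflation(quinine_design.N - 2)
        for s, m in zip(tit.snr_levels, tit.mean_r_d):
            crlb = dr.crlb_resolution(quinine_design, s)
            assert m / (crlb * infl) == pytest.approx(1.0, abs=0.10)

    def test_plateau_levels_off(self, quinine_design):
        """R_D saturates once added noise is negligible against the floor."""
        curve = simulate_decay(quinine_design, snr=14400.0, seed=7, snr_lim=300.0)
        levels = np.array([50.0, 200.0, 1000.0, 5000.0, 14400.0])
        tit = dr.titrate_noise(curve, levels, n_additions=60, seed=3)
        # monotone rise then near-flat: last two levels within 10%
        assert tit.mean_r_d[-1] == pytest.approx(tit.mean_r_d[-2], rel=0.10)
        # and far below the noise-only expectation at full SNR
        assert tit.mean_r_d[-1] < 0.2 * dr.crlb_resolution(quinine_design, 14400.0)


class TestFitSnrLim:
    @pytest.mark.parametrize("snr_lim", [100.0, 300.0, 1000.0])
    def test_parameter_recovery(self, snr_lim, quadratic_params):
        """Titrations drawn around the effective-SNR model return the ceiling
        with < 5% bias at 100 additions per level."""
        levels = np.geomspace(snr_lim / 10, snr_lim * 30, 10)
        tit = dr.simulate_titration_from_model(
            levels, snr_lim, N=12, eps_max=0.76, params=quadratic_params,
            n_additions=100, seed=5,
        )
        est = dr.fit_snr_lim(tit, N=12, eps_max=0.76, params=quadratic_params)
        assert abs(est.value / snr_lim - 1.0) < 0.05

    def test_recovery_within_two_stderr(self, quadratic_params):
        levels = np.geomspace(50.0, 15000.0, 12)
        tit = dr.simulate_titration_from_model(
            levels, 500.0, N=12, eps_max=0.76, params=quadratic_params,
            n_additions=100, seed=17,
        )
        est = dr.fit_snr_lim(tit, N=12, eps_max=0.76, params=quadratic_params)
        assert abs(est.value - 500.0) <= 2 * est.stderr + 1e-9

    def test_unbracketed_knee_warns(self, quadratic_params):
        """All levels far below the ceiling leave it unidentifiable."""
        levels = np.geomspace(5.0, 50.0, 6)
        tit = dr.simulate_titration_from_model(
            levels, 5000.0, N=12, eps_max=0.76, params=quadratic_params,
            n_additions=100, seed=2,
        )
        with pytest.warns(UserWarning, match="not bracketed"):
            dr.fit_snr_lim(tit, N=12, eps_max=0.76, params=quadratic_params)

    def test_needs_four_levels(self, quadratic_params):
        tit = dr.TitrationResult(
            snr_levels=np.array([10.0, 20.0, 40.0]),
            mean_r_d=np.array([1.0, 2.0, 4.0]),
            n_additions=10,
        )
        with pytest.raises(ValueError):
            dr.fit_snr_lim(tit, N=12, eps_max=0.76, params=quadratic_params)
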