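import numpy as np
import pytest
from scipy import integrate, stats

from aerotax import navigation as nav

REF_DET = dict(eps_d=0.28, dr=0.52)
REF_STO = dict(eps_s=0.55, dr=0.33)
DELTA_T = 0.65


# ---------------------------------------------------------------------------
# Parameters

class TestStrategyParams:
    def test_kd_derived(self):
        p = nav.StrategyParams(dr=0.52, eps_d=0.28)
        assert p.kd == pytest.approx(0.28 / 0.52)

    def test_validation(self):
        with pytest.raises(ValueError):
            nav.StrategyParams(dr=0.0)
        with pytest.raises(ValueError):
            nav.StrategyParams(dr=1.0, eps_s=1.5)
        with pytest.raises(ValueError):
            nav.StrategyParams(dr=1.0, eps_d=-0.1)


# ---------------------------------------------------------------------------
# Analytic steady states

class TestSteadyPDFs:
    @pytest.mark.parametrize("eps_d,dr", [(0.28, 0.52), (1.0, 0.2), (0.0, 1.0)])
    def test_deterministic_normalized(self, eps_d, dr):
        val, _ = integrate.quad(
            lambda th: nav.steady_pdf_deterministic(th, eps_d, dr),
            -np.pi, np.pi)
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("eps_s", [0.0, 0.3, 0.55, 0.9, -0.5])
    def test_stochastic_normalized(self, eps_s):
        val, _ = integrate.quad(
            lambda th: nav.steady_pdf_stochastic(th, eps_s), -np.pi, np.pi)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_zero_bias_uniform(self):
        th = np.linspace(-np.pi, np.pi, 7)
        assert np.allclose(nav.steady_pdf_deterministic(th, 0.0, 1.0),
                           1 / (2 * np.pi))
        assert np.allclose(nav.steady_pdf_stochastic(th, 0.0),
                           1 / (2 * np.pi))

    def test_mode_at_up_direction(self):
        th = np.linspace(-np.pi, np.pi, 1001)
        for pdf in (nav.steady_pdf_deterministic(th, 0.28, 0.52),
                    nav.steady_pdf_stochastic(th, 0.55)):
            assert th[np.argmax(pdf)] == pytest.approx(np.pi / 2, abs=0.01)

    def test_cdfs_match_pdfs(self):
        th = np.linspace(-np.pi, np.pi, 2001)
        for cdf_fn, pdf in [
            (lambda x: nav.steady_cdf_deterministic(x, 0.28, 0.52),
             nav.steady_pdf_deterministic(th, 0.28, 0.52)),
            (lambda x: nav.steady_cdf_stochastic(x, 0.55),
             nav.steady_pdf_stochastic(th, 0.55)),
        ]:
            numeric = integrate.cumulative_trapezoid(pdf, th, initial=0.0)
            assert np.abs(cdf_fn(th) - numeric).max() < 1e-4

    def test_mean_sin_closed_form(self):
        # <sin theta> under the stochastic steady state equals the
        # drift-velocity closed form (unit speed), across the bias range
        for eps in (0.1, 0.3, 0.55, 0.8, 0.95):
            quad_val = nav.mean_sin_steady_stochastic(eps)
            assert quad_val == pytest.approx(nav.drift_velocity(eps, 1.0),
                                             abs=1e-9)

    def test_degenerate_eps_rejected(self):
        with pytest.raises(ValueError):
            nav.steady_pdf_stochastic(0.0, 1.0)


# ---------------------------------------------------------------------------
# Closed forms

class TestDriftVelocity:
    def test_reference_value(self):
        assert nav.drift_velocity(0.55, 1.0) == pytest.approx(0.2997,
                                                              abs=1e-4)
        assert nav.drift_velocity(0.55, 16.5) == pytest.approx(4.95,
                                                               abs=0.01)

    def test_limits(self):
        assert nav.drift_velocity(0.0, 5.0) == 0.0
        assert nav.drift_velocity(1.0, 5.0) == pytest.approx(5.0)
        assert nav.drift_velocity(1e-8, 5.0) == pytest.approx(0.0, abs=1e-6)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            nav.drift_velocity(1.5, 1.0)


class TestVelocityModulationGamma:
    def test_two_dimensional(self):
        assert nav.velocity_modulation_gamma(1 / 3, 2) == pytest.approx(2 / 3)

    def test_three_dimensional(self):
        assert nav.velocity_modulation_gamma(1 / 3, 3) == pytest.approx(1.0)

    def test_zero(self):
        assert nav.velocity_modulation_gamma(0.0, 2) == 0.0

    def test_monte_carlo_sphere_average(self):
        # independent oracle: drift of v(1 + gamma cos psi) over the sphere
        rng = np.random.default_rng(7)
        cos_psi = rng.uniform(-1, 1, 200_000)  # uniform on the sphere
        gamma = 1.0
        drift_frac = np.mean((1 + gamma * cos_psi) * cos_psi)
        assert drift_frac == pytest.approx(1 / 3, abs=0.005)
        assert nav.velocity_modulation_gamma(drift_frac, 3) == pytest.approx(
            gamma, abs=0.02)

    def test_bad_dimension(self):
        with pytest.raises(ValueError):
            nav.velocity_modulation_gamma(0.5, 4)


# ---------------------------------------------------------------------------
# Simulators

class TestSimulators:
    def test_seed_reproducibility(self):
        p = nav.StrategyParams(dr=0.33, eps_s=0.55)
        a = nav.simulate_stochastic(p, 10, 1e-2, 1.0, seed=3)
        b = nav.simulate_stochastic(p, 10, 1e-2, 1.0, seed=3)
        assert np.array_equal(a.theta, b.theta)

    def test_noiseless_limit_converges_to_up(self):
        # tiny dr: steering dominates and theta approaches pi/2
        p = nav.StrategyParams(dr=1e-6, eps_d=1.0)
        ens = nav.simulate_deterministic(p, 5, 1e-2, 30.0, seed=0,
                                         theta0=0.0, save_every=100)
        assert np.allclose(ens.theta[:, -1], np.pi / 2, atol=0.05)

    def test_orientation_autocorrelation_pure_diffusion(self):
        # eps_d = 0: <cos(theta(t) - theta(0))> = exp(-dr t)
        dr = 0.5
        p = nav.StrategyParams(dr=dr)
        ens = nav.simulate_deterministic(p, 4000, 1e-3, 2.0, seed=1,
                                         save_every=500)
        for i, t in enumerate(ens.t):
            expected = np.exp(-dr * t)
            observed = np.mean(np.cos(ens.theta[:, i] - ens.theta[:, 0]))
            assert observed == pytest.approx(expected, abs=0.03)

    def test_stochastic_zero_bias_uniform(self):
        p = nav.StrategyParams(dr=0.5)
        th = nav.sample_steady_theta("stochastic", p, 20000, seed=4,
                                     n_traj=1000, spacing=2.0, burn=10.0)
        ks = stats.ks_1samp(th, lambda x: (x + np.pi) / (2 * np.pi))
        assert ks.statistic < 0.02

    def test_stochastic_matches_analytic_steady_state(self):
        p = nav.StrategyParams(dr=0.33, eps_s=0.55)
        th = nav.sample_steady_theta("stochastic", p, 20000, seed=5,
                                     n_traj=1000, spacing=3.0)
        ks = stats.ks_1samp(th,
                            lambda x: nav.steady_cdf_stochastic(x, 0.55))
        assert ks.statistic < 0.02

    def test_deterministic_matches_analytic_steady_state(self):
        p = nav.StrategyParams(dr=0.52, eps_d=0.28)
        th = nav.sample_steady_theta("deterministic", p, 20000, seed=6,
                                     n_traj=1000, spacing=3.0)
        ks = stats.ks_1samp(
            th, lambda x: nav.steady_cdf_deterministic(x, 0.28, 0.52))
        assert ks.statistic < 0.02

    def test_mean_sin_at_reference_bias(self):
        # ensemble <sin theta> at eps_s = 0.55 is ~0.3
        p = nav.StrategyParams(dr=0.33, eps_s=0.55)
        th = nav.sample_steady_theta("stochastic", p, 30000, seed=7,
                                     n_traj=1500, spacing=3.0)
        assert np.mean(np.sin(th)) == pytest.approx(0.2997, abs=0.02)

    def test_dt_too_large_rejected(self):
        p = nav.StrategyParams(dr=5.0)
        with pytest.raises(ValueError):
            nav.simulate_stochastic(p, 10, 0.1, 1.0, seed=0)

    def test_seed_required(self):
        p = nav.StrategyParams(dr=0.5)
        with pytest.raises(ValueError):
            nav.simulate_stochastic(p, 10, 1e-3, 0.1, seed=None)

    def test_degenerate_noise_rejected(self):
        p = nav.StrategyParams(dr=0.5, eps_s=1.0)
        with pytest.raises(ValueError):
            nav.simulate_stochastic(p, 10, 1e-3, 0.1, seed=0)

    def test_positions_integrated(self):
        p = nav.StrategyParams(dr=1e-6, eps_d=1.0, v=10.0)
        ens = nav.simulate_deterministic(p, 3, 1e-2, 10.0, seed=0,
                                         theta0=np.pi / 2,
                                         with_positions=True)
        x, y = ens.positions
        # swimming straight up at 10 um/s
        assert np.allclose(y[:, -1], 100.0, atol=1.0)
        assert np.allclose(x[:, -1], 0.0, atol=1.0)


# ---------------------------------------------------------------------------
# Turn-angle densities

class TestDeltaPhiPDFs:
    def test_zero_bias_gaussian(self):
        x = np.linspace(-2, 2, 101)
        for pdf in (nav.delta_phi_pdf_deterministic(x, 0.0, 0.52, DELTA_T),
                    nav.delta_phi_pdf_stochastic(x, 0.0, 0.52, DELTA_T)):
            expected = stats.norm.pdf(x, scale=np.sqrt(2 * 0.52 * DELTA_T))
            assert np.allclose(pdf, expected, atol=1e-9)

    def test_normalized(self):
        f_det = lambda x: float(nav.delta_phi_pdf_deterministic(
            x, **REF_DET, dt=DELTA_T))
        f_sto = lambda x: float(nav.delta_phi_pdf_stochastic(
            x, **REF_STO, dt=DELTA_T))
        for f in (f_det, f_sto):
            val, _ = integrate.quad(f, -8, 8, limit=200)
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_mean_positive(self):
        x = np.linspace(-6, 6, 2001)
        pdf = nav.delta_phi_pdf_deterministic(x, **REF_DET, dt=DELTA_T)
        mean = np.trapezoid(x * pdf, x)
        assert mean > 0.05

    def test_stochastic_symmetric_zero_mean(self):
        x = np.linspace(0.01, 5, 50)
        p_pos = nav.delta_phi_pdf_stochastic(x, **REF_STO, dt=DELTA_T)
        p_neg = nav.delta_phi_pdf_stochastic(-x, **REF_STO, dt=DELTA_T)
        assert np.allclose(p_pos, p_neg, rtol=1e-12)

    @pytest.mark.parametrize("model,params", [
        ("deterministic", REF_DET), ("stochastic", REF_STO)])
    def test_quadrature_matches_monte_carlo(self, model, params):
        sp = nav.StrategyParams(dr=params["dr"],
                                eps_d=params.get("eps_d", 0.0),
                                eps_s=params.get("eps_s", 0.0))
        samples = nav.sample_delta_phi(model, sp, DELTA_T, 500_000, seed=8)
        edges = np.linspace(-3, 3, 61)
        hist, _ = np.histogram(samples, bins=edges, density=True)
        mid = 0.5 * (edges[:-1] + edges[1:])
        if model == "deterministic":
            pdf = nav.delta_phi_pdf_deterministic(mid, **params, dt=DELTA_T)
        else:
            pdf = nav.delta_phi_pdf_stochastic(mid, **params, dt=DELTA_T)
        assert np.abs(hist - pdf).max() / pdf.max() < 0.05

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            nav.delta_phi_pdf_deterministic(0.0, 0.28, -1.0, DELTA_T)
        with pytest.raises(ValueError):
            nav.delta_phi_pdf_stochastic(0.0, 1.0, 0.33, DELTA_T)


# ---------------------------------------------------------------------------
# Fitting

def _stochastic_theta_samples(eps_s, n, seed):
    """Inverse-CDF sampling from the stochastic steady state (exact)."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(-np.pi, np.pi, 20001)
    cdf = nav.steady_cdf_stochastic(grid, eps_s)
    u = rng.uniform(0, 1, n)
    return np.interp(u, cdf, grid)


class TestFitAngleModel:
    def test_uniform_samples_zero_bias(self):
        rng = np.random.default_rng(9)
        th = rng.uniform(-np.pi, np.pi, 20000)
        assert abs(nav.fit_angle_model(th, "deterministic").param) < 0.05
        assert abs(nav.fit_angle_model(th, "stochastic").param) < 0.05

    def test_stochastic_recovery(self):
        th = _stochastic_theta_samples(0.55, 10000, seed=10)
        fit = nav.fit_angle_model(th, "stochastic")
        assert fit.param == pytest.approx(0.55, abs=0.05)

    def test_deterministic_recovery(self):
        rng = np.random.default_rng(11)
        kd = 0.28 / 0.52
        th = stats.vonmises(kappa=kd, loc=np.pi / 2).rvs(10000,
                                                         random_state=rng)
        fit = nav.fit_angle_model(th, "deterministic")
        assert fit.param == pytest.approx(kd, rel=0.15)

    def test_model_discrimination_on_von_mises_data(self):
        rng = np.random.default_rng(12)
        th = stats.vonmises(kappa=2.0, loc=np.pi / 2).rvs(20000,
                                                          random_state=rng)
        det = nav.fit_angle_model(th, "deterministic")
        sto = nav.fit_angle_model(th, "stochastic")
        assert det.log_likelihood > sto.log_likelihood

    def test_model_discrimination_on_stochastic_data(self):
        th = _stochastic_theta_samples(0.8, 20000, seed=13)
        det = nav.fit_angle_model(th, "deterministic")
        sto = nav.fit_angle_model(th, "stochastic")
        assert sto.log_likelihood > det.log_likelihood

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            nav.fit_angle_model(np.zeros(3), "stochastic")


class TestFitDeltaPhi:
    def test_stochastic_dr_recovery(self):
        sp = nav.StrategyParams(dr=0.33, eps_s=0.55)
        dphi = nav.sample_delta_phi("stochastic", sp, DELTA_T, 50_000,
                                    seed=14)
        fit = nav.fit_delta_phi(dphi, "stochastic", 0.55, DELTA_T)
        assert fit.dr == pytest.approx(0.33, rel=0.05)

    def test_deterministic_dr_recovery(self):
        sp = nav.StrategyParams(dr=0.52, eps_d=0.28)
        dphi = nav.sample_delta_phi("deterministic", sp, DELTA_T, 50_000,
                                    seed=15)
        fit = nav.fit_delta_phi(dphi, "deterministic", 0.28 / 0.52, DELTA_T)
        assert fit.dr == pytest.approx(0.52, rel=0.05)

    def test_stochastic_beats_constrained_deterministic(self):
        sp = nav.StrategyParams(dr=0.33, eps_s=0.55)
        dphi = nav.sample_delta_phi("stochastic", sp, DELTA_T, 50_000,
                                    seed=16)
        sto = nav.fit_delta_phi(dphi, "stochastic", 0.55, DELTA_T)
        det = nav.fit_delta_phi(dphi, "deterministic", 0.28 / 0.52, DELTA_T)
        assert sto.log_likelihood > det.log_likelihood

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            nav.fit_delta_phi(np.zeros(100), "stochastic", 0.55, DELTA_T)
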