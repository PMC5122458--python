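"""Deterministic vs stochastic navigation strategies on the circle.

Heading dynamics (theta = pi/2 points up the attractant gradient):

- deterministic steering:   d(theta) = eps_d cos(theta) dt + sqrt(2 dr) dW
- stochastic reorientation: d(theta) = sqrt(2 dr (1 - eps_s sin(theta))) dW
  (multiplicative noise in the Ito convention, no spurious drift added)

Analytic steady states of the corresponding Fokker-Planck equations:

- deterministic: von Mises about pi/2 with concentration kd = eps_d / dr
  (the zero-flux steady state of the Fokker-Planck equation of the steering
  Langevin dynamics above)
- stochastic:    p(theta) = sqrt(1 - eps_s^2) / (2 pi (1 - eps_s sin(theta)))

Turn-angle statistics use the angle turned toward the gradient in a lag
Delta t,  dphi = |theta(t) - pi/2| - |theta(t + Delta t) - pi/2|  (positive
for turns toward the gradient), with angular distances measured on the
circle.  Their short-lag densities are evaluated by Gauss-Legendre
quadrature and fitted by maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, special, stats

from ._util import wrap_angle

__all__ = [
    "StrategyParams", "AngleEnsemble",
    "simulate_deterministic", "simulate_stochastic", "sample_steady_theta",
    "steady_pdf_deterministic", "steady_pdf_stochastic",
    "steady_cdf_deterministic", "steady_cdf_stochastic",
    "delta_phi_pdf_deterministic", "delta_phi_pdf_stochastic",
    "sample_delta_phi", "drift_velocity", "velocity_modulation_gamma",
    "fit_angle_model", "fit_delta_phi",
]


@dataclass(frozen=True)
class StrategyParams:
    """Parameters shared by the navigation simulators and analytic PDFs."""

    dr: float                 # rotational diffusion, 1/s
    v: float = 16.5           # swimming speed, um/s
    eps_d: float = 0.0        # deterministic steering rate, 1/s
    eps_s: float = 0.0        # stochastic bias, dimensionless in [-1, 1]

    def __post_init__(self):
        if self.dr <= 0:
            raise ValueError("dr must be positive")
        if abs(self.eps_s) > 1:
            raise ValueError("eps_s must lie in [-1, 1]")
        if self.eps_d < 0:
            raise ValueError("eps_d must be nonnegative")

    @property
    def kd(self) -> float:
        """Von Mises concentration of the deterministic steady state.

        The steering Langevin dynamics have angular diffusion coefficient
        dr, so the zero-flux steady state is von Mises with concentration
        eps_d / dr.
        """
        return self.eps_d / self.dr


@dataclass
class AngleEnsemble:
    """Uniformly sampled heading series for a set of trajectories.

    ``theta`` has shape (n_traj, n_samples), wrapped to (-pi, pi];
    ``positions`` optionally holds (x, y) arrays of the same shape (um).
    """

    theta: np.ndarray
    dt: float
    seed: int | None = None
    positions: tuple | None = field(default=None, repr=False)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.theta.shape[1]) * self.dt

    def to_csv(self, path) -> None:
        import pandas as pd

        n, m = self.theta.shape
        cols = {
            "traj_id": np.repeat(np.arange(n), m),
            "t": np.tile(self.t, n),
            "theta": self.theta.reshape(-1),
        }
        if self.positions is not None:
            cols["x"] = self.positions[0].reshape(-1)
            cols["y"] = self.positions[1].reshape(-1)
        pd.DataFrame(cols).to_csv(path, index=False)


def _check_dt(dt: float, rates) -> None:
    fastest = max(r for r in rates)
    if fastest > 0 and dt * fastest > 0.1:
        raise ValueError(
            f"dt={dt} too large for rate {fastest}/s; need dt*rate <= 0.1"
        )


def _integrate(params, n, dt, t_end, seed, mode, theta0, save_every,
               with_positions):
    if seed is None:
        raise ValueError("a seed is required")
    _check_dt(dt, (params.dr, params.eps_d))
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt))
    theta = (rng.uniform(-np.pi, np.pi, size=n) if theta0 is None
             else np.full(n, float(theta0)))
    n_saved = n_steps // save_every + 1
    out = np.empty((n, n_saved))
    out[:, 0] = theta
    if with_positions:
        x = np.zeros((n, n_saved))
        y = np.zeros((n, n_saved))
        xc = np.zeros(n)
        yc = np.zeros(n)
    sq = np.sqrt(dt)
    col = 1
    for k in range(1, n_steps + 1):
        dw = rng.standard_normal(n) * sq
        if mode == "deterministic":
            theta = theta + params.eps_d * np.cos(theta) * dt \
                + np.sqrt(2.0 * params.dr) * dw
        else:  # Ito: amplitude evaluated at the interval start
            amp = 2.0 * params.dr * (1.0 - params.eps_s * np.sin(theta))
            theta = theta + np.sqrt(np.maximum(amp, 0.0)) * dw
        theta = wrap_angle(theta)
        if with_positions:
            xc += params.v * np.cos(theta) * dt
            yc += params.v * np.sin(theta) * dt
        if k % save_every == 0:
            out[:, col] = theta
            if with_positions:
                x[:, col] = xc
                y[:, col] = yc
            col += 1
    pos = (x, y) if with_positions else None
    return AngleEnsemble(theta=out[:, :col], dt=dt * save_every, seed=seed,
                         positions=pos)


def simulate_deterministic(params: StrategyParams, n: int, dt: float,
                           t_end: float, seed: int, *, theta0=None,
                           save_every: int = 1,
                           with_positions: bool = False) -> AngleEnsemble:
    """Euler-Maruyama integration of the deterministic-steering dynamics."""
    return _integrate(params, n, dt, t_end, seed, "deterministic", theta0,
                      save_every, with_positions)


def simulate_stochastic(params: StrategyParams, n: int, dt: float,
                        t_end: float, seed: int, *, theta0=None,
                        save_every: int = 1,
                        with_positions: bool = False) -> AngleEnsemble:
    """Ito Euler-Maruyama integration of modulated rotational diffusion."""
    if abs(params.eps_s) >= 1:
        raise ValueError("|eps_s| must be < 1 for nondegenerate noise")
    return _integrate(params, n, dt, t_end, seed, "stochastic", theta0,
                      save_every, with_positions)


def sample_steady_theta(model: str, params: StrategyParams, n_samples: int,
                        seed: int, *, dt: float = 1e-3, burn: float = 20.0,
                        spacing: float = 2.0,
                        n_traj: int = 2000) -> np.ndarray:
    """Pool approximately stationary heading samples from long simulations.

    Runs ``n_traj`` trajectories past a burn-in and records headings every
    ``spacing`` seconds until ``n_samples`` values are pooled.
    """
    per_traj = int(np.ceil(n_samples / n_traj))
    t_end = burn + per_traj * spacing
    sim = (simulate_deterministic if model == "deterministic"
           else simulate_stochastic)
    save_every = max(1, int(round(spacing / dt)))
    ens = sim(params, n_traj, dt, t_end, seed, save_every=save_every)
    n_burn = int(np.ceil(burn / spacing))
    pooled = ens.theta[:, n_burn:].reshape(-1)
    return pooled[:n_samples]


# ---------------------------------------------------------------------------
# Analytic steady states

def steady_pdf_deterministic(theta, eps_d: float, dr: float) -> np.ndarray:
    """Von Mises steady state about pi/2, concentration kd = eps_d/dr."""
    if dr <= 0:
        raise ValueError("dr must be positive")
    kd = eps_d / dr
    theta = np.asarray(theta, dtype=float)
    return np.exp(kd * np.sin(theta)) / (2.0 * np.pi * special.i0(kd))


def steady_pdf_stochastic(theta, eps_s: float) -> np.ndarray:
    """Steady state of the modulated-diffusion model; independent of dr."""
    if abs(eps_s) >= 1:
        raise ValueError("|eps_s| must be < 1")
    theta = np.asarray(theta, dtype=float)
    return np.sqrt(1.0 - eps_s**2) / (
        2.0 * np.pi * (1.0 - eps_s * np.sin(theta))
    )


def steady_cdf_deterministic(theta, eps_d: float, dr: float) -> np.ndarray:
    """CDF on (-pi, pi] of the deterministic (von Mises) steady state."""
    kd = eps_d / dr
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    vm = stats.vonmises(kappa=max(kd, 1e-12), loc=np.pi / 2)
    return vm.cdf(theta) - vm.cdf(-np.pi)


def steady_cdf_stochastic(theta, eps_s: float) -> np.ndarray:
    """CDF on (-pi, pi] of the stochastic steady state (closed form)."""
    if abs(eps_s) >= 1:
        raise ValueError("|eps_s| must be < 1")
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if eps_s == 0:
        return (theta + np.pi) / (2 * np.pi)
    s = np.sqrt(1.0 - eps_s**2)

    def anti(th):
        # d/dth [ (1/pi) atan((tan(th/2) - eps)/s) ] = ps(th) on (-pi, pi)
        return np.arctan((np.tan(th / 2.0) - eps_s) / s) / np.pi

    val = anti(np.clip(theta, -np.pi + 1e-12, np.pi - 1e-12)) - anti(-np.pi + 1e-12)
    return np.where(theta >= np.pi - 1e-12, 1.0, np.clip(val, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Turn-angle (dphi) densities

def _gauss_legendre(n):
    return np.polynomial.legendre.leggauss(n)


def delta_phi_pdf_deterministic(dphi, eps_d: float, dr: float, dt: float,
                                n_quad: int = 64) -> np.ndarray:
    """Short-lag turn-angle density of the deterministic strategy.

    Convolution of the steering contribution |eps_d cos(theta) dt| (theta
    uniform pre-swap) with the Gaussian diffusion increment, evaluated by
    Gauss-Legendre quadrature after the substitution delta = A sin(u) that
    removes the arcsine endpoint singularity.
    """
    if dr <= 0 or dt <= 0:
        raise ValueError("dr and dt must be positive")
    dphi = np.atleast_1d(np.asarray(dphi, dtype=float))
    a = eps_d * dt
    var2 = 4.0 * dr * dt  # = 2 * variance of the diffusion increment
    nodes, weights = _gauss_legendre(n_quad)
    u = (nodes + 1.0) * (np.pi / 4.0)       # map [-1,1] -> [0, pi/2]
    w = weights * (np.pi / 4.0)
    delta = a * np.sin(u)
    integrand = np.exp(-((dphi[:, None] - delta[None, :]) ** 2) / var2)
    out = integrand @ w / (np.pi ** 1.5 * np.sqrt(dr * dt))
    return out if out.size > 1 else out.reshape(())


def delta_phi_pdf_stochastic(dphi, eps_s: float, dr: float, dt: float,
                             n_quad: int = 64) -> np.ndarray:
    """Short-lag turn-angle density of the stochastic strategy.

    Marginalizes the theta-conditional Gaussian increment (variance
    2 dr (1 - eps_s sin(theta)) dt) over theta uniform on (-pi, pi].
    Symmetric in dphi, hence zero mean.
    """
    if dr <= 0 or dt <= 0:
        raise ValueError("dr and dt must be positive")
    if abs(eps_s) >= 1:
        raise ValueError("|eps_s| must be < 1")
    dphi = np.atleast_1d(np.asarray(dphi, dtype=float))
    nodes, weights = _gauss_legendre(n_quad)
    th = nodes * np.pi
    w = weights * np.pi
    s2 = dr * (1.0 - eps_s * np.sin(th)) * dt  # = var/2 per theta
    integrand = np.exp(-(dphi[:, None] ** 2) / (4.0 * s2[None, :])) \
        / np.sqrt(16.0 * np.pi**3 * s2[None, :])
    out = integrand @ w
    return out if out.size > 1 else out.reshape(())


def sample_delta_phi(model: str, params: StrategyParams, dt: float, n: int,
                     seed: int) -> np.ndarray:
    """Monte-Carlo sampler of the short-lag turn-angle generative model.

    Draws theta uniform and applies one increment with coefficients frozen
    at theta (the same approximation under which the analytic densities are
    derived), so it serves as an independent oracle for the quadrature
    evaluations and as a generator for fitting tests.
    """
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-np.pi, np.pi, size=n)
    if model == "deterministic":
        delta = np.abs(params.eps_d * np.cos(theta)) * dt
        xi = rng.standard_normal(n) * np.sqrt(2.0 * params.dr * dt)
        return delta + xi
    if model == "stochastic":
        amp = 2.0 * params.dr * (1.0 - params.eps_s * np.sin(theta)) * dt
        return rng.standard_normal(n) * np.sqrt(amp)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Closed forms

def drift_velocity(eps_s: float, v: float) -> float:
    """Stationary-approximation drift velocity v <sin theta>.

    Closed form v (1/eps_s - sqrt(1/eps_s^2 - 1)); continuous limits 0 at
    eps_s -> 0 and v at eps_s -> 1.
    """
    if not 0 <= eps_s <= 1:
        raise ValueError("eps_s must lie in [0, 1]")
    if eps_s == 0:
        return 0.0
    return v * (1.0 / eps_s - np.sqrt(1.0 / eps_s**2 - 1.0))


def velocity_modulation_gamma(drift_fraction: float, dim: int) -> float:
    """Speed-modulation amplitude needed for a given drift fraction.

    Under v(p) = v (1 + gamma p.g) with isotropic headings, the mean drift
    is v gamma / 2 in 2D and v gamma / 3 in 3D; invert for gamma.
    """
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    return float(dim * drift_fraction)


# ---------------------------------------------------------------------------
# Fitting

@dataclass
class AngleFit:
    model: str
    param: float       # kd (deterministic) or eps_s (stochastic)
    log_likelihood: float
    n: int


def fit_angle_model(theta_samples, model: str) -> AngleFit:
    """Maximum-likelihood fit of a steady-state heading distribution.

    The deterministic family is the von Mises about pi/2 (single parameter
    kd); the stochastic family is the modulated-diffusion steady state
    (single parameter eps_s).
    """
    theta = np.asarray(theta_samples, dtype=float).reshape(-1)
    if theta.size < 10:
        raise ValueError("need at least 10 samples")
    if model == "deterministic":
        m = np.mean(np.sin(theta))

        def nll(kd):
            return -(kd * m - np.log(special.i0(kd)))

        res = optimize.minimize_scalar(nll, bounds=(0.0, 50.0),
                                       method="bounded")
        kd = float(res.x)
        ll = float(theta.size * (kd * m - np.log(special.i0(kd)))
                   - theta.size * np.log(2 * np.pi))
        return AngleFit("deterministic", kd, ll, theta.size)
    if model == "stochastic":
        sin_t = np.sin(theta)

        def nll(eps):
            return -np.sum(np.log(steady_pdf_stochastic_raw(sin_t, eps)))

        def steady_pdf_stochastic_raw(s, eps):
            return np.sqrt(1 - eps**2) / (2 * np.pi * (1 - eps * s))

        res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999),
                                       method="bounded")
        eps = float(res.x)
        return AngleFit("stochastic", eps, -float(res.fun), theta.size)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class DeltaPhiFit:
    model: str
    dr: float
    fixed_param: float  # eps_s (stochastic) or kd (deterministic)
    log_likelihood: float
    n: int

    @property
    def mean_log_likelihood(self) -> float:
        return self.log_likelihood / self.n


def fit_delta_phi(dphi_samples, model: str, fixed_param: float,
                  dt: float) -> DeltaPhiFit:
    """One-parameter maximum-likelihood fit of dr to turn-angle samples.

    For the stochastic family ``fixed_param`` is eps_s (from the steady-state
    fit); for the deterministic family it is the steady-state concentration
    kd, which constrains eps_d = kd dr as dr varies.
    """
    dphi = np.asarray(dphi_samples, dtype=float).reshape(-1)
    if dphi.size < 10:
        raise ValueError("need at least 10 samples")
    if np.var(dphi) == 0:
        raise ValueError("zero-variance turn-angle sample")

    if model == "stochastic":
        def nll(log_dr):
            p = delta_phi_pdf_stochastic(dphi, fixed_param, np.exp(log_dr), dt)
            return -np.sum(np.log(np.maximum(p, 1e-300)))
    elif model == "deterministic":
        def nll(log_dr):
            dr = np.exp(log_dr)
            p = delta_phi_pdf_deterministic(dphi, fixed_param * dr, dr, dt)
            return -np.sum(np.log(np.maximum(p, 1e-300)))
    else:
        raise ValueError(f"unknown model {model!r}")

    res = optimize.minimize_scalar(nll, bounds=(np.log(1e-3), np.log(50.0)),
                                   method="bounded")
    dr = float(np.exp(res.x))
    return DeltaPhiFit(model, dr, fixed_param, -float(res.fun), dphi.size)


def mean_sin_steady_stochastic(eps_s: float) -> float:
    """<sin theta> under the stochastic steady state, by quadrature."""
    f = lambda th: np.sin(th) * steady_pdf_stochastic(th, eps_s)
    val, _ = integrate.quad(f, -np.pi, np.pi, limit=200)
    return val
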