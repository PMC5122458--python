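"""1D Keller-Segel population dynamics across the observation chamber.

The colony density rho(y, t) obeys

    d(rho)/dt = D d2(rho)/dy2 - d(V[c] rho)/dy

with no-flux walls, where the drift velocity V is a functional of the local
oxygen profile.  Supported response kinds:

- ``constant``:    V = vdrift * sign(dc/dy)
- ``linear``:      V = beta * dc/dy
- ``tanh_abs``:    V = vdrift * tanh(alpha * |dc/dy|) * sign(dc/dy)
- ``tanh_linear``: V = vdrift * tanh(alpha * dc/dy)  (identical to tanh_abs in 1D)
- ``tanh_log``:    V = vdrift * tanh(alpha * (dc/dy) / max(c, c_floor))

The ``tanh_log`` kind implements relative-gradient (logarithmic, Weber-law)
sensing; ``alpha`` then carries units of length (um).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import minimize

RESPONSE_KINDS = ("constant", "linear", "tanh_abs", "tanh_log", "tanh_linear")


@dataclass(frozen=True)
class ResponseModel:
    """Gradient-response functional mapping (c, dc/dy) to a drift velocity."""

    kind: str
    vdrift: float = 0.0   # um/s, saturation drift speed
    alpha: float = 0.0    # um (tanh_log) or um/% (tanh_abs, tanh_linear)
    beta: float = 0.0     # um^2/(s %) taxis coefficient for kind="linear"
    c_floor: float = 1e-3  # % O2, lower cutoff inside dc/dy / c

    def __post_init__(self):
        if self.kind not in RESPONSE_KINDS:
            raise ValueError(f"unknown response kind {self.kind!r}")
        if self.vdrift < 0 or self.alpha < 0:
            raise ValueError("vdrift and alpha must be nonnegative")
        if self.c_floor <= 0:
            raise ValueError("c_floor must be positive")


def response_velocity(model: ResponseModel, c: np.ndarray,
                      dc_dy: np.ndarray) -> np.ndarray:
    """Signed drift velocity V(y) (um/s) for concentration profile ``c``.

    Guarantees |V| <= vdrift for the saturating kinds, sign(V) = sign(dc/dy),
    and V = 0 where dc/dy = 0.
    """
    c = np.asarray(c, dtype=float)
    dc = np.asarray(dc_dy, dtype=float)
    if np.any(c < -10 * model.c_floor):
        raise ValueError("negative concentrations beyond floor tolerance")
    kind = model.kind
    if kind == "constant":
        return model.vdrift * np.sign(dc)
    if kind == "linear":
        return model.beta * dc
    if kind in ("tanh_abs", "tanh_linear"):
        return model.vdrift * np.tanh(model.alpha * dc)
    # tanh_log: relative-gradient input with a concentration floor
    rel = dc / np.maximum(c, model.c_floor)
    return model.vdrift * np.tanh(model.alpha * rel)


@dataclass(frozen=True)
class KSParams:
    """Population-level parameters of the Keller-Segel model."""

    D: float  # colony diffusion constant, um^2/s

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("D must be positive")

    def dr_effective(self, v: float) -> float:
        """Effective rotational diffusion Dr = v^2 / (2 D) in 1/s."""
        return v * v / (2.0 * self.D)


@dataclass
class DensityProfile:
    """Per-frame-normalized colony density on a y grid.

    ``rho`` has shape (nt, ny); each time slice integrates to 1 (units 1/um).
    """

    y: np.ndarray
    t: np.ndarray
    rho: np.ndarray

    def normalize(self) -> "DensityProfile":
        h = float(self.y[1] - self.y[0])
        mass = self.rho.sum(axis=1, keepdims=True) * h
        return DensityProfile(self.y, self.t, self.rho / mass)

    def to_csv(self, path) -> None:
        import pandas as pd

        nt, ny = self.rho.shape
        pd.DataFrame({
            "t": np.repeat(self.t, ny),
            "y": np.tile(self.y, nt),
            "rho": self.rho.reshape(-1),
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DensityProfile":
        import pandas as pd

        df = pd.read_csv(path).sort_values(["t", "y"])
        t = np.unique(df["t"].to_numpy())
        y = np.unique(df["y"].to_numpy())
        rho = df["rho"].to_numpy().reshape(len(t), len(y))
        return cls(y=y, t=t, rho=rho)


class KSSolverError(RuntimeError):
    pass


def solve_ks(
    params: KSParams,
    model: ResponseModel,
    c_field,
    *,
    dt: float = 1.0,
    t_end: float | None = None,
    rho0: np.ndarray | None = None,
    output_times: np.ndarray | None = None,
) -> DensityProfile:
    """Integrate the population equation on the grid of ``c_field``.

    ``c_field`` is any object with attributes ``y``, ``t`` and a method
    ``at_time(t) -> (c, dc_dy)`` (e.g. :class:`~aerotax.oxygen_sim.ChamberProfile`).
    Finite-volume scheme: implicit (backward-Euler) diffusion + first-order
    upwind advection, zero total flux at the walls.  Mass is conserved to
    solver precision and the scheme is positivity-preserving.
    """
    y = np.asarray(c_field.y, dtype=float)
    ny = y.size
    h = float(y[1] - y[0])
    if t_end is None:
        t_end = float(c_field.t[-1])
    if dt <= 0:
        raise ValueError("dt must be positive")
    if output_times is None:
        output_times = np.asarray(c_field.t, dtype=float)
    output_times = output_times[output_times <= t_end + 1e-9]

    if rho0 is None:
        rho = np.full(ny, 1.0 / (ny * h))
    else:
        rho = np.asarray(rho0, dtype=float).copy()
        mass = rho.sum() * h
        if not np.isclose(mass, 1.0, atol=1e-6):
            raise ValueError("initial density must be normalized")

    d_coef = params.D * dt / h**2

    n_steps = int(np.ceil(t_end / dt))
    out = np.empty((len(output_times), ny))
    out_idx = 0
    t = 0.0
    # record t=0 if requested
    while out_idx < len(output_times) and output_times[out_idx] <= 1e-12:
        out[out_idx] = rho
        out_idx += 1

    ab = np.zeros((3, ny))  # banded (upper, diag, lower)
    for k in range(1, n_steps + 1):
        t_new = min(k * dt, t_end)
        step = t_new - t
        c, dc = c_field.at_time(t_new)
        v_cells = response_velocity(model, c, dc)
        v_face = 0.5 * (v_cells[:-1] + v_cells[1:])  # interior faces
        vp = np.maximum(v_face, 0.0)
        vm = np.minimum(v_face, 0.0)
        lam = step / h
        dd = params.D * step / h**2

        # implicit matrix rows: rho_j + lam*(F_out - F_in) = rho_old
        diag = np.ones(ny)
        upper = np.zeros(ny)
        lower = np.zeros(ny)
        # face f between j and j+1: F_f = vp*rho_j + vm*rho_{j+1} - D (rho_{j+1}-rho_j)/h
        diag[:-1] += lam * vp + dd
        upper[1:] = lam * vm - dd          # coefficient of rho_{j+1} in row j
        diag[1:] += -lam * vm + dd
        lower[:-1] = -lam * vp - dd        # coefficient of rho_j in row j+1

        ab[0] = upper
        ab[1] = diag
        ab[2] = lower
        rho = solve_banded((1, 1), ab, rho)
        t = t_new

        if np.any(~np.isfinite(rho)):
            raise KSSolverError(
                f"solution lost finiteness at t={t}; try a smaller timestep"
            )
        neg = rho.min()
        if neg < -1e-10:
            warnings.warn(
                f"clamping negative density {neg:.3e} at t={t}", RuntimeWarning
            )
            rho = np.clip(rho, 0.0, None)
            rho /= rho.sum() * h

        while out_idx < len(output_times) and output_times[out_idx] <= t + 1e-9:
            out[out_idx] = rho
            out_idx += 1

    if out_idx < len(output_times):  # pragma: no cover - defensive
        out[out_idx:] = rho
    return DensityProfile(y=y.copy(), t=np.asarray(output_times, float), rho=out)


# ---------------------------------------------------------------------------
# Fitting

_FIT_PARAMS = {
    "tanh_log": ("D", "alpha", "vdrift"),
    "tanh_abs": ("D", "alpha", "vdrift"),
    "tanh_linear": ("D", "alpha", "vdrift"),
    "linear": ("D", "beta"),
    "constant": ("D", "vdrift"),
}

_DEFAULT_BOUNDS = {
    "D": (50.0, 5000.0),
    "alpha": (1.0, 2e4),
    "vdrift": (0.1, 20.0),
    "beta": (1.0, 1e6),
}


@dataclass
class KSFitResult:
    kind: str
    params: dict
    objective: float
    n_starts: int
    converged: bool

    @property
    def D(self):
        return self.params["D"]


def _ks_objective(theta, names, kind, observed, c_field, dt):
    kwargs = dict(zip(names, theta))
    d_val = kwargs.pop("D")
    model = ResponseModel(kind=kind, **kwargs)
    try:
        sol = solve_ks(KSParams(D=d_val), model, c_field, dt=dt,
                       t_end=float(observed.t[-1]),
                       output_times=np.asarray(observed.t, float),
                       rho0=observed.rho[0])
    except (KSSolverError, ValueError):
        return 1e6
    resid = sol.rho - observed.rho
    return float(np.mean(resid**2)) * 1e6  # um^-2 scale -> O(1) numbers


def fit_ks(
    observed: DensityProfile,
    c_field,
    kind: str,
    *,
    dt: float = 2.0,
    n_starts: int = 8,
    seed: int = 0,
    bounds: dict | None = None,
    maxiter: int = 200,
) -> KSFitResult:
    """Fit response/diffusion parameters to an observed density kymograph.

    Bounded local minimization (L-BFGS-B) of the space-time mean squared
    density discrepancy, restarted from ``n_starts`` seeded log-uniform draws.
    """
    if kind not in _FIT_PARAMS:
        raise ValueError(f"unknown response kind {kind!r}")
    names = _FIT_PARAMS[kind]
    bnds = dict(_DEFAULT_BOUNDS)
    bnds.update(bounds or {})
    lo = np.array([bnds[n][0] for n in names])
    hi = np.array([bnds[n][1] for n in names])

    rng = np.random.default_rng(seed)
    starts = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=(n_starts, len(names)))
    )

    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            _ks_objective, x0,
            args=(names, kind, observed, c_field, dt),
            method="L-BFGS-B", bounds=list(zip(lo, hi)),
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10},
        )
        # status 1 = iteration limit with a usable iterate; only status 2
        # (abnormal termination) counts as a failed start
        any_converged = any_converged or res.success or res.status == 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or not any_converged:
        msg = best.message if best is not None else "no result"
        raise KSSolverError(f"optimizer failed from all starts: {msg}")
    return KSFitResult(
        kind=kind,
        params=dict(zip(names, best.x)),
        objective=float(best.fun),
        n_starts=n_starts,
        converged=bool(any_converged),
    )
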