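"""Oxygen diffusion in a 2D cross-section of a PDMS microfluidic device.

The device is a PDMS slab bonded between glass slides.  A water-filled sample
channel sits at the center, flanked symmetrically by two gas channels in which
air (20% O2) or nitrogen (0% O2) can be flowed.  Oxygen diffuses through PDMS
and water; glass is impermeable (no-flux).  The field is assumed constant
along the channel direction, so the computation is on the (y, z) cross-section
with y the gradient axis (0 at the chamber center) and z the height above the
bottom glass.

Concentration is expressed in % O2, lengths in micrometers, time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

# Material codes for the cross-section grid.
PDMS = 0
WATER = 1
GAS_LEFT = 2
GAS_RIGHT = 3

#: O2 diffusivity in PDMS, um^2/s (3.55e-3 mm^2/s).
D_PDMS = 3550.0
#: O2 diffusivity in water, um^2/s (2.10e-3 mm^2/s).
D_WATER = 2100.0

#: Boundary concentration imposed by each gas, % O2.
GAS_CONCENTRATION = {"air": 20.0, "nitrogen": 0.0}


class GeometryError(ValueError):
    """Raised for impossible or unresolved device geometries."""


@dataclass(frozen=True)
class DeviceGeometry:
    """Cross-section geometry of the device with a rasterized material map.

    All lengths in micrometers.  The sample channel is centered at y = 0 and
    the two gas channels flank it symmetrically.  Channels sit on the bottom
    glass (z = 0) and share the nominal channel thickness.
    """

    slab_width: float = 4500.0
    slab_height: float = 500.0
    channel_thickness: float = 115.0
    sample_width: float = 1000.0
    gas_width: float = 1000.0
    gas_gap: float = 500.0  # PDMS between the sample channel and each gas channel
    dy: float = 25.0
    dz: float = 25.0
    material: np.ndarray = field(default=None, repr=False, compare=False)
    y: np.ndarray = field(default=None, repr=False, compare=False)
    z: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self._validate()
        if self.material is None:
            y, z, mat = self._rasterize()
            object.__setattr__(self, "y", y)
            object.__setattr__(self, "z", z)
            object.__setattr__(self, "material", mat)

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        for name in ("slab_width", "slab_height", "channel_thickness",
                     "sample_width", "gas_width", "gas_gap", "dy", "dz"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.channel_thickness > self.slab_height:
            raise GeometryError("channel thickness exceeds slab height")
        if self.sample_width >= self.slab_width:
            raise GeometryError("sample channel wider than the slab")
        outer = self.sample_width / 2 + self.gas_gap + self.gas_width
        if outer > self.slab_width / 2:
            raise GeometryError(
                "gas channels extend beyond the slab; channels overlap or "
                "slab too narrow"
            )

    # -- rasterization ----------------------------------------------------
    def _rasterize(self):
        ny = int(round(self.slab_width / self.dy))
        nz = int(round(self.slab_height / self.dz))
        if ny % 2:  # keep the grid mirror-symmetric about y = 0
            ny += 1
        y = (np.arange(ny) + 0.5) * self.slab_width / ny - self.slab_width / 2
        z = (np.arange(nz) + 0.5) * self.slab_height / nz
        mat = np.full((nz, ny), PDMS, dtype=np.int8)

        in_channel_z = z < self.channel_thickness
        half_s = self.sample_width / 2
        mat[np.ix_(in_channel_z, np.abs(y) < half_s)] = WATER
        g0 = half_s + self.gas_gap
        g1 = g0 + self.gas_width
        mat[np.ix_(in_channel_z, (y < -g0) & (y > -g1))] = GAS_LEFT
        mat[np.ix_(in_channel_z, (y > g0) & (y < g1))] = GAS_RIGHT

        narrow_y = min(self.sample_width, self.gas_width, self.gas_gap)
        if narrow_y / self.dy < 4 or self.channel_thickness / self.dz < 4:
            raise GeometryError(
                "grid does not resolve the narrowest feature with >= 4 cells"
            )
        return y, z, mat

    @property
    def sample_y_extent(self) -> tuple[float, float]:
        return (-self.sample_width / 2, self.sample_width / 2)

    @property
    def sample_z_extent(self) -> tuple[float, float]:
        return (0.0, self.channel_thickness)

    def with_resolution(self, dy: float, dz: float) -> "DeviceGeometry":
        return replace(self, dy=dy, dz=dz, material=None, y=None, z=None)


def build_geometry(config: dict | None = None) -> DeviceGeometry:
    """Build a validated :class:`DeviceGeometry` from a config mapping.

    Unspecified keys fall back to the documented defaults.  Raises
    :class:`GeometryError` for impossible configurations.
    """
    config = dict(config or {})
    allowed = {"slab_width", "slab_height", "channel_thickness",
               "sample_width", "gas_width", "gas_gap", "dy", "dz"}
    unknown = set(config) - allowed
    if unknown:
        raise GeometryError(f"unknown geometry keys: {sorted(unknown)}")
    return DeviceGeometry(**config)


@dataclass(frozen=True)
class DiffusivityMap:
    """Per-cell O2 diffusivity (um^2/s) for a device cross-section."""

    values: np.ndarray

    @classmethod
    def from_geometry(cls, geometry: DeviceGeometry,
                      d_pdms: float = D_PDMS,
                      d_water: float = D_WATER) -> "DiffusivityMap":
        if d_pdms <= 0 or d_water <= 0:
            raise ValueError("diffusivities must be strictly positive")
        vals = np.where(geometry.material == WATER, d_water, d_pdms)
        return cls(values=vals.astype(float))


@dataclass(frozen=True)
class GasProtocol:
    """Time-ordered gas schedule for the two channels.

    ``segments`` is a list of ``(t_start, left_gas, right_gas)`` with gas in
    {"air", "nitrogen"}.  The first segment must start at t = 0.
    """

    segments: tuple

    def __post_init__(self):
        segs = tuple((float(t), str(l), str(r)) for t, l, r in self.segments)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        if segs[0][0] != 0.0:
            raise ValueError("first protocol segment must start at t=0")
        times = [s[0] for s in segs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("protocol segments must be strictly time-ordered")
        for _, l, r in segs:
            if l not in GAS_CONCENTRATION or r not in GAS_CONCENTRATION:
                raise ValueError(f"unknown gas in protocol: {l!r}/{r!r}")
        object.__setattr__(self, "segments", segs)

    def boundary_values(self, t: float) -> tuple[float, float]:
        """Dirichlet concentrations (left, right) in effect at time t."""
        left, right = self.segments[0][1], self.segments[0][2]
        for t0, l, r in self.segments:
            if t >= t0:
                left, right = l, r
        return GAS_CONCENTRATION[left], GAS_CONCENTRATION[right]

    def mirrored(self) -> "GasProtocol":
        """Protocol with the two channels swapped."""
        return GasProtocol(tuple((t, r, l) for t, l, r in self.segments))

    @classmethod
    def from_list(cls, entries) -> "GasProtocol":
        """Build from ``[{"t": 0, "left": "air", "right": "nitrogen"}, ...]``."""
        return cls(tuple((e["t"], e["left"], e["right"]) for e in entries))


@dataclass
class OxygenField:
    """Space-time oxygen concentration on the cross-section grid.

    ``c`` has shape (nt, nz, ny) in % O2.
    """

    y: np.ndarray
    z: np.ndarray
    t: np.ndarray
    c: np.ndarray
    geometry: DeviceGeometry | None = None

    def save_npz(self, path) -> None:
        np.savez_compressed(path, y=self.y, z=self.z, t=self.t, c=self.c)

    @classmethod
    def load_npz(cls, path) -> "OxygenField":
        data = np.load(path)
        return cls(y=data["y"], z=data["z"], t=data["t"], c=data["c"])


class SolverError(RuntimeError):
    """Raised when the linear solve fails to produce a valid field."""


def _build_operator(dmap: DiffusivityMap, geometry: DeviceGeometry,
                    dt: float) -> tuple[sparse.csc_matrix, np.ndarray]:
    """Backward-Euler matrix (I + dt*A) with Dirichlet rows for gas cells.

    Conservative finite-volume Laplacian with harmonic-mean face
    diffusivities; outer boundaries are no-flux (glass / sealed PDMS edges).
    """
    mat = geometry.material
    nz, ny = mat.shape
    hy = geometry.slab_width / ny
    hz = geometry.slab_height / nz
    n = nz * ny
    idx = np.arange(n).reshape(nz, ny)
    dirichlet = (mat == GAS_LEFT) | (mat == GAS_RIGHT)
    d = dmap.values

    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    def add_faces(da, db, ia, ib, h):
        dface = 2.0 * da * db / (da + db)
        w = dt * dface / h**2
        free_a = ~dirichlet.reshape(-1)[ia]
        free_b = ~dirichlet.reshape(-1)[ib]
        # row a: -(flux in from b)
        sel = free_a
        rows.append(ia[sel]); cols.append(ib[sel]); vals.append(-w[sel])
        np.add.at(diag, ia[sel], w[sel])
        sel = free_b
        rows.append(ib[sel]); cols.append(ia[sel]); vals.append(-w[sel])
        np.add.at(diag, ib[sel], w[sel])

    # y-faces
    add_faces(d[:, :-1].ravel(), d[:, 1:].ravel(),
              idx[:, :-1].ravel(), idx[:, 1:].ravel(), hy)
    # z-faces
    add_faces(d[:-1, :].ravel(), d[1:, :].ravel(),
              idx[:-1, :].ravel(), idx[1:, :].ravel(), hz)

    diag += 1.0  # identity part; Dirichlet rows end up as pure identity
    rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
    a = sparse.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return a, dirichlet.reshape(-1)


def solve_diffusion(
    geometry: DeviceGeometry,
    dmap: DiffusivityMap | None,
    protocol: GasProtocol,
    *,
    dt: float = 1.0,
    t_end: float,
    c0: float | np.ndarray = 20.0,
    output_every: float = 10.0,
) -> OxygenField:
    """Integrate the diffusion equation with backward-Euler time stepping.

    ``c0`` is a uniform initial % O2 or a full (nz, ny) array.  The field is
    stored at t = 0 and every ``output_every`` seconds (plus t_end).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dmap is None:
        dmap = DiffusivityMap.from_geometry(geometry)
    mat = geometry.material
    nz, ny = mat.shape
    a, dirichlet = _build_operator(dmap, geometry, dt)
    try:
        lu = splu(a)
    except RuntimeError as exc:  # pragma: no cover - singular matrix guard
        raise SolverError(f"sparse factorization failed: {exc}") from exc

    c = (np.full((nz, ny), float(c0)) if np.isscalar(c0)
         else np.array(c0, dtype=float))
    if c.shape != (nz, ny):
        raise ValueError("initial field shape mismatch")

    left_mask = (mat == GAS_LEFT).reshape(-1)
    right_mask = (mat == GAS_RIGHT).reshape(-1)

    def apply_bc(vec, t):
        cl, cr = protocol.boundary_values(t)
        vec[left_mask] = cl
        vec[right_mask] = cr

    x = c.reshape(-1).copy()
    apply_bc(x, 0.0)

    n_steps = int(np.ceil(t_end / dt))
    out_stride = max(1, int(round(output_every / dt)))
    ts = [0.0]
    frames = [x.copy()]
    for k in range(1, n_steps + 1):
        t = k * dt
        apply_bc(x, t)  # rhs carries the Dirichlet values for this step
        rhs = x
        x = lu.solve(rhs)
        if not np.all(np.isfinite(x)):
            residual = float(np.abs(a @ x - rhs).max())
            raise SolverError(f"non-finite solution at t={t} (residual {residual:g})")
        if k % out_stride == 0 or k == n_steps:
            ts.append(t)
            frames.append(x.copy())

    cube = np.array(frames).reshape(len(frames), nz, ny)
    return OxygenField(y=geometry.y.copy(), z=geometry.z.copy(),
                       t=np.array(ts), c=cube, geometry=geometry)


@dataclass
class ChamberProfile:
    """1D concentration profile across the sample channel over time.

    ``c`` and ``dc_dy`` have shape (nt, ny); % O2 and %/um respectively.
    """

    y: np.ndarray
    t: np.ndarray
    c: np.ndarray
    dc_dy: np.ndarray

    def at_time(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Linear-in-time interpolation of (c, dc_dy) at time t (clamped)."""
        tt = np.clip(t, self.t[0], self.t[-1])
        i = int(np.searchsorted(self.t, tt, side="right") - 1)
        i = min(max(i, 0), len(self.t) - 2) if len(self.t) > 1 else 0
        if len(self.t) == 1:
            return self.c[0], self.dc_dy[0]
        w = (tt - self.t[i]) / (self.t[i + 1] - self.t[i])
        return ((1 - w) * self.c[i] + w * self.c[i + 1],
                (1 - w) * self.dc_dy[i] + w * self.dc_dy[i + 1])

    def to_csv(self, path) -> None:
        import pandas as pd

        nt, ny = self.c.shape
        df = pd.DataFrame({
            "t": np.repeat(self.t, ny),
            "y": np.tile(self.y, nt),
            "c": self.c.reshape(-1),
            "dc_dy": self.dc_dy.reshape(-1),
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChamberProfile":
        import pandas as pd

        df = pd.read_csv(path)
        t = np.unique(df["t"].to_numpy())
        y = np.unique(df["y"].to_numpy())
        nt, ny = len(t), len(y)
        df = df.sort_values(["t", "y"])
        c = df["c"].to_numpy().reshape(nt, ny)
        dc = df["dc_dy"].to_numpy().reshape(nt, ny)
        return cls(y=y, t=t, c=c, dc_dy=dc)


def chamber_profile(field: OxygenField, z_eval: float,
                    geometry: DeviceGeometry | None = None) -> ChamberProfile:
    """Extract c(y, t) across the sample channel at height ``z_eval``.

    Linear interpolation between the two grid rows bracketing ``z_eval``;
    the y-gradient is computed by centered differences.
    """
    geometry = geometry or field.geometry
    if geometry is None:
        raise ValueError("geometry required to locate the sample channel")
    z0, z1 = geometry.sample_z_extent
    if not (z0 <= z_eval <= z1):
        raise ValueError(f"z_eval={z_eval} outside the sample channel [{z0}, {z1}]")
    y0, y1 = geometry.sample_y_extent
    ysel = (field.y > y0) & (field.y < y1)
    y = field.y[ysel]

    zi = np.interp(z_eval, field.z, np.arange(len(field.z)))
    i0 = int(np.floor(zi))
    i1 = min(i0 + 1, len(field.z) - 1)
    w = zi - i0
    c = (1 - w) * field.c[:, i0, ysel] + w * field.c[:, i1, ysel]
    dc = np.gradient(c, y, axis=1)
    return ChamberProfile(y=y, t=field.t.copy(), c=c, dc_dy=dc)
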