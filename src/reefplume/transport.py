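"""Passive-tracer transport on a 2D depth-averaged coastal grid.

Conservative river tracers are advected by a prescribed flow field and
spread by horizontal diffusion; there are no sink or source terms in the
transport equation apart from river injection at the mouth cells and
(optionally) outflow through open boundaries.  The solver is a desk-scale
stand-in for a regional hydrodynamic model: flux-form first-order upwind
advection plus explicit centred diffusion, chosen for monotonicity and
exact mass conservation in closed basins.

Concentrations are dimensionless fractions of the source concentration
(each river releases its tracer at unit concentration), so a value of
0.01 means 1% river water.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "FlowField",
    "RiverSource",
    "TransportParams",
    "TracerSeries",
    "step_transport",
    "run_simulation",
    "ConfigError",
]

ML_PER_DAY_TO_M3_PER_S = 1000.0 / 86400.0  # 1 megalitre = 1000 m3


class ConfigError(ValueError):
    """Raised when a scenario or solver configuration is invalid."""


@dataclass(frozen=True)
class Grid:
    """Regular rectangular grid with a land/water mask.

    Parameters
    ----------
    nx, ny : int
        Number of cells in x (along-shore) and y (cross-shore).
    dx, dy : float
        Cell size in metres.
    mask : ndarray of bool, shape (ny, nx)
        True for water cells, False for land.  Immutable after construction.
    depth : float
        Effective water-column depth (m) used to convert river volume flux
        into a concentration tendency for the depth-averaged layer.
    """

    nx: int
    ny: int
    dx: float
    dy: float
    mask: np.ndarray
    depth: float = 10.0

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ConfigError("grid must be at least 3 x 3 cells")
        if self.dx <= 0 or self.dy <= 0 or self.depth <= 0:
            raise ConfigError("dx, dy and depth must be positive")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (self.ny, self.nx):
            raise ConfigError(f"mask shape {mask.shape} != (ny, nx) = {(self.ny, self.nx)}")
        if not mask.any():
            raise ConfigError("grid has no water cells")
        mask.setflags(write=False)
        object.__setattr__(self, "mask", mask)

    @classmethod
    def open_water(cls, nx: int, ny: int, dx: float, dy: float, depth: float = 10.0) -> "Grid":
        """All-water grid (no land)."""
        return cls(nx=nx, ny=ny, dx=dx, dy=dy, mask=np.ones((ny, nx), dtype=bool), depth=depth)

    @property
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of cell centres in metres."""
        x = (np.arange(self.nx) + 0.5) * self.dx
        y = (np.arange(self.ny) + 0.5) * self.dy
        return x, y

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def cell_volume(self) -> float:
        return self.dx * self.dy * self.depth


@dataclass(frozen=True)
class FlowField:
    """Prescribed cell-centred velocity field (m/s); zero on land.

    The flow is exogenous: tracers do not affect it.  ``description``
    records the provenance of the field, e.g. the direction of the
    residual coastal current it represents.
    """

    u: np.ndarray
    v: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if u.shape != v.shape:
            raise ConfigError("u and v must have identical shapes")
        if not (np.isfinite(u).all() and np.isfinite(v).all()):
            raise ConfigError("flow field contains non-finite values")
        u.setflags(write=False)
        v.setflags(write=False)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    def validate_on(self, grid: Grid) -> None:
        if self.u.shape != grid.mask.shape:
            raise ConfigError("flow field shape does not match grid")
        land = ~grid.mask
        if np.any(self.u[land] != 0) or np.any(self.v[land] != 0):
            raise ConfigError("flow must be zero on land cells")


@dataclass
class RiverSource:
    """A river mouth releasing a unique tracer at unit concentration.

    ``discharge`` is either a constant (ML/d) or a pandas Series indexed
    by date giving the daily hydrograph.
    """

    name: str
    cell: tuple[int, int]  # (j, i) row/col index of the mouth cell
    discharge: float | pd.Series = 0.0
    source_concentration: float = 1.0

    def discharge_on(self, when: date | None) -> float:
        """Discharge (ML/d) on a given date; constant sources ignore the date."""
        if isinstance(self.discharge, pd.Series):
            if when is None:
                raise ConfigError(f"source {self.name!r} has a dated hydrograph; a date is required")
            key = pd.Timestamp(when)
            if key in self.discharge.index:
                q = float(self.discharge.loc[key])
            else:
                q = 0.0
        else:
            q = float(self.discharge)
        if q < 0:
            raise ConfigError(f"negative discharge for source {self.name!r}")
        return q

    def validate_on(self, grid: Grid) -> None:
        j, i = self.cell
        if not (0 <= j < grid.ny and 0 <= i < grid.nx):
            raise ConfigError(f"source {self.name!r} mouth cell {self.cell} is off-grid")
        if not grid.mask[j, i]:
            raise ConfigError(f"source {self.name!r} mouth cell {self.cell} is on land")


@dataclass(frozen=True)
class TransportParams:
    """Solver parameters with explicit-scheme stability constraints.

    K : horizontal diffusivity (m^2/s); dt : time step (s);
    boundary_mode : 'closed' (no flux through domain edges) or
    'open-outflow' (zero-gradient outflow; mass leaving is lost).
    """

    K: float = 50.0
    dt: float = 600.0
    boundary_mode: str = "closed"

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ConfigError("diffusivity K must be >= 0")
        if self.dt <= 0:
            raise ConfigError("time step dt must be > 0")
        if self.boundary_mode not in ("closed", "open-outflow"):
            raise ConfigError(f"unknown boundary_mode {self.boundary_mode!r}")

    def check_stability(self, grid: Grid, flow: FlowField) -> None:
        cfl = max(
            float(np.abs(flow.u).max(initial=0.0)) * self.dt / grid.dx,
            float(np.abs(flow.v).max(initial=0.0)) * self.dt / grid.dy,
        )
        if cfl > 1.0:
            raise ConfigError(f"CFL number {cfl:.3f} exceeds 1; reduce dt or velocities")
        dnum = self.K * self.dt * (1.0 / grid.dx**2 + 1.0 / grid.dy**2)
        if dnum > 0.5:
            raise ConfigError(f"diffusion number {dnum:.3f} exceeds 0.5; reduce dt or K")
        # positivity (monotonicity) of the combined upwind + centred-diffusion
        # update requires the outflow coefficients to sum below 1
        combined = (
            float(np.abs(flow.u).max(initial=0.0)) * self.dt / grid.dx
            + float(np.abs(flow.v).max(initial=0.0)) * self.dt / grid.dy
            + 2.0 * dnum
        )
        if combined > 1.0:
            raise ConfigError(
                f"combined advection-diffusion number {combined:.3f} exceeds 1; reduce dt"
            )


@dataclass
class TracerSeries:
    """Daily concentration fields, one tracer per river source.

    conc has shape (n_times, n_tracers, ny, nx); values are fractions of
    the source concentration, zero on land.
    """

    times: pd.DatetimeIndex
    tracer_names: list[str]
    conc: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        if len(self.times) != self.conc.shape[0]:
            raise ConfigError("times and conc leading dimension differ")
        if not self.times.is_monotonic_increasing or self.times.has_duplicates:
            raise ConfigError("times must be strictly increasing")
        if (self.conc < 0).any():
            raise ConfigError("negative concentrations in TracerSeries")

    @property
    def combined(self) -> np.ndarray:
        """Sum over tracers, shape (n_times, ny, nx)."""
        return self.conc.sum(axis=1)

    def total_mass(self) -> np.ndarray:
        """Tracer mass (conc * cell volume) per time and tracer."""
        return self.conc.sum(axis=(2, 3)) * self.grid.cell_volume

    def at_cell(self, cell: tuple[int, int], tracer: int | str = 0) -> pd.Series:
        j, i = cell
        k = self.tracer_names.index(tracer) if isinstance(tracer, str) else tracer
        return pd.Series(self.conc[:, k, j, i], index=self.times)

    def to_dataset(self) -> "xarray.Dataset":  # noqa: F821 - imported lazily
        import xarray as xr

        x, y = self.grid.cell_centers
        return xr.Dataset(
            {"conc": (("time", "tracer", "y", "x"), self.conc)},
            coords={
                "time": self.times,
                "tracer": self.tracer_names,
                "y": ("y", y, {"units": "m"}),
                "x": ("x", x, {"units": "m"}),
            },
            attrs={
                "description": "passive river-tracer concentration (fraction of source concentration)",
                "dx": self.grid.dx,
                "dy": self.grid.dy,
                "depth": self.grid.depth,
            },
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")


def _face_velocities(grid: Grid, flow: FlowField, boundary_mode: str):
    """Velocities at cell faces; zero through land faces.

    Returns (uf, vf): uf has shape (ny, nx+1) for x-normal faces, vf has
    shape (ny+1, nx) for y-normal faces.  Domain-edge faces carry the
    boundary cell's velocity in open-outflow mode (inflow contributes
    nothing because the outside concentration is zero under upwinding)
    and zero in closed mode.
    """
    mask = grid.mask
    u, v = flow.u, flow.v

    uf = np.zeros((grid.ny, grid.nx + 1))
    uf[:, 1:-1] = 0.5 * (u[:, :-1] + u[:, 1:])
    wet_x = mask[:, :-1] & mask[:, 1:]
    uf[:, 1:-1] *= wet_x
    vf = np.zeros((grid.ny + 1, grid.nx))
    vf[1:-1, :] = 0.5 * (v[:-1, :] + v[1:, :])
    wet_y = mask[:-1, :] & mask[1:, :]
    vf[1:-1, :] *= wet_y

    if boundary_mode == "open-outflow":
        uf[:, 0] = np.where(mask[:, 0], u[:, 0], 0.0)
        uf[:, -1] = np.where(mask[:, -1], u[:, -1], 0.0)
        vf[0, :] = np.where(mask[0, :], v[0, :], 0.0)
        vf[-1, :] = np.where(mask[-1, :], v[-1, :], 0.0)
    return uf, vf


def step_transport(
    state: np.ndarray,
    flow: FlowField,
    params: TransportParams,
    sources: Sequence[RiverSource] = (),
    *,
    grid: Grid,
    when: date | None = None,
    source_channels: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Advance tracer field(s) one explicit step.

    ``state`` has shape (..., ny, nx); any leading dimensions (e.g. one
    channel per tracer) are carried through the linear advection-diffusion
    operator unchanged.  River injection relaxes the mouth-cell
    concentration toward 1.0 at a rate equal to the volume flux divided by
    the cell volume, clipped to [0, 1].  When ``state`` holds one channel
    per source, pass ``source_channels`` mapping source name -> channel.
    """
    state = np.asarray(state, dtype=float)
    if not np.isfinite(state).all():
        raise ConfigError("state contains non-finite values")
    if (state < 0).any():
        raise ConfigError("state contains negative concentrations")
    flow.validate_on(grid)
    params.check_stability(grid, flow)

    mask = grid.mask
    dt, K = params.dt, params.K
    uf, vf = _face_velocities(grid, flow, params.boundary_mode)

    c = np.where(mask, state, 0.0)

    # upwind advective fluxes at faces (conc * velocity); outside conc = 0
    cx = np.zeros(c.shape[:-2] + (grid.ny, grid.nx + 1))
    cx[..., 1:-1] = np.where(uf[:, 1:-1] > 0, c[..., :-1], c[..., 1:])
    cx[..., 0] = np.where(uf[:, 0] < 0, c[..., 0], 0.0)  # outflow through west edge
    cx[..., -1] = np.where(uf[:, -1] > 0, c[..., -1], 0.0)
    fx = uf * cx

    cy = np.zeros(c.shape[:-2] + (grid.ny + 1, grid.nx))
    cy[..., 1:-1, :] = np.where(vf[1:-1, :] > 0, c[..., :-1, :], c[..., 1:, :])
    cy[..., 0, :] = np.where(vf[0, :] < 0, c[..., 0, :], 0.0)
    cy[..., -1, :] = np.where(vf[-1, :] > 0, c[..., -1, :], 0.0)
    fy = vf * cy

    new = c - dt / grid.dx * (fx[..., 1:] - fx[..., :-1]) - dt / grid.dy * (
        fy[..., 1:, :] - fy[..., :-1, :]
    )

    if K > 0:
        # centred diffusive fluxes through water-water faces only
        gx = np.zeros_like(cx)
        gx[..., 1:-1] = -K * (c[..., 1:] - c[..., :-1]) / grid.dx
        gx[..., 1:-1] *= mask[:, :-1] & mask[:, 1:]
        gy = np.zeros_like(cy)
        gy[..., 1:-1, :] = -K * (c[..., 1:, :] - c[..., :-1, :]) / grid.dy
        gy[..., 1:-1, :] *= mask[:-1, :] & mask[1:, :]
        new -= dt / grid.dx * (gx[..., 1:] - gx[..., :-1])
        new -= dt / grid.dy * (gy[..., 1:, :] - gy[..., :-1, :])

    new = np.where(mask, new, 0.0)
    # upwind + stable diffusion preserve non-negativity; clip FP dust only
    np.clip(new, 0.0, None, out=new)

    for k, src in enumerate(sources):
        src.validate_on(grid)
        q = src.discharge_on(when) * ML_PER_DAY_TO_M3_PER_S  # m3/s
        if q == 0.0:
            continue
        rate = min(q * dt / grid.cell_volume, 1.0)
        j, i = src.cell
        chan = source_channels.get(src.name, k) if source_channels is not None else k
        # relaxation toward the source concentration, clipped to [0, 1]
        if new.ndim == 2:
            new[j, i] = min(new[j, i] + rate * (src.source_concentration - new[j, i]), 1.0)
        else:
            new[chan, j, i] = min(new[chan, j, i] + rate * (src.source_concentration - new[chan, j, i]), 1.0)
    return new


def run_simulation(
    grid: Grid,
    flow: FlowField | Callable[[date], FlowField],
    sources: Sequence[RiverSource],
    params: TransportParams,
    window: tuple[date, date],
) -> TracerSeries:
    """Run the tracer simulation over a date window, recording daily fields.

    One tracer per source ("unique tracers"); tracers are transported by
    the same linear operator and do not interact.  The simulation
    sub-steps at ``params.dt`` and records the field at the end of each
    day.  The window is inclusive on both ends.
    """
    start, end = window
    if end < start:
        raise ConfigError("empty simulation window")
    if not sources:
        raise ConfigError("at least one river source is required")
    for src in sources:
        src.validate_on(grid)

    n_days = (end - start).days + 1
    steps_per_day = max(1, int(round(86400.0 / params.dt)))
    channels = {src.name: k for k, src in enumerate(sources)}

    state = np.zeros((len(sources), grid.ny, grid.nx))
    conc = np.empty((n_days, len(sources), grid.ny, grid.nx))
    for d in range(n_days):
        today = start + timedelta(days=d)
        f = flow(today) if callable(flow) else flow
        for _ in range(steps_per_day):
            state = step_transport(
                state, f, params, sources, grid=grid, when=today, source_channels=channels
            )
        conc[d] = state

    times = pd.date_range(start=start, periods=n_days, freq="D")
    return TracerSeries(times=times, tracer_names=[s.name for s in sources], conc=conc, grid=grid)
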