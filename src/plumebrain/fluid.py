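"""Interactive 2-D incompressible-flow solver with odorant dye transport.

The scheme follows the classic interactive "stable fluids" pipeline:
per step the velocity field receives body forces, diffuses implicitly,
is projected to (discretely) divergence-free, self-advects by
semi-Lagrangian backtracing, and is projected again; each dye channel
receives source injections, diffuses implicitly, is advected along the
velocity field, and decays first-order (evaporation).  Every sub-step is
unconditionally stable, so the solver tolerates arbitrary time steps.

Discretization notes
--------------------
* Collocated square grid, cell (0, 0) at the lower left; array axis 0 is y.
  ``u[i, j]`` is read as the flow through the face between cells (i, j) and
  (i, j+1) (and ``v`` likewise in y), which makes the backward-difference
  divergence and forward-difference pressure gradient exact adjoints: their
  composition is the compact 5-point Neumann Laplacian, so the projection
  residual — and hence the post-projection divergence — is driven to zero
  by the iterative pressure solve.
* Pressure is solved by red-black SOR with the over-relaxation factor set
  from the grid size; ``solver_iters`` (default 20) trades interactivity
  against projection accuracy.
* Implicit diffusion systems (I - a L) x = b are solved exactly through a
  cached sparse LU factorization.  The Neumann Laplacian L has zero column
  sums, so dye mass is conserved to machine precision by diffusion.
* Semi-Lagrangian advection does not conserve mass under nonzero flow; the
  dye total is renormalized to its pre-advection value after each advection
  (``conserve_dye_mass``, on by default), keeping the mass budget exact up
  to float rounding under arbitrary wind schedules.
* Walls (the outer box and internal obstacle rectangles) close the faces
  they touch: face velocities there are held at zero, diffusion and the
  pressure solve exclude closed faces, and dye is zero-flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "FlowGrid",
    "WindSource",
    "OdorPlumeSource",
    "Obstacle",
    "ConfigurationError",
    "NumericalStateError",
    "step_fluid",
    "sample_concentrations",
    "robot_perturbation_forces",
    "divergence",
]


class ConfigurationError(ValueError):
    """A source, force, or obstacle is inconsistent with the grid."""


class NumericalStateError(RuntimeError):
    """Field values went non-finite; the trial must abort."""


@dataclass(frozen=True)
class Obstacle:
    """Axis-aligned solid rectangle in cell coordinates, inclusive bounds."""

    ix0: int
    iy0: int
    ix1: int
    iy1: int

    def __post_init__(self) -> None:
        if self.ix1 < self.ix0 or self.iy1 < self.iy0:
            raise ConfigurationError("obstacle bounds must satisfy ix0<=ix1, iy0<=iy1")


@dataclass
class WindSource:
    """Convection source: a velocity increment applied to a set of cells
    each step (e.g. a fan or vent).  ``strength`` scales at runtime."""

    cells: list[tuple[int, int]]
    force: tuple[float, float]
    strength: float = 1.0


@dataclass
class OdorPlumeSource:
    """Dye injection at one cell: ``emission_rate`` dye units per second
    into channel ``channel``; adjustable at runtime."""

    cell: tuple[int, int]
    channel: int = 0
    emission_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.emission_rate < 0.0:
            raise ConfigurationError("emission_rate must be >= 0")


class FlowGrid:
    """CFD state: per-cell velocity plus one dye field per odorant channel.

    Parameters
    ----------
    nx, ny : cell counts (default 140 x 140)
    cell_size : meters per cell
    dt : seconds per CFD step (default 0.030)
    viscosity, dye_diffusion : diffusion coefficients (m^2/s equivalent,
        applied in cell units as ``coef * dt / cell_size**2``)
    evaporation_rate : per-second first-order dye decay
    n_channels : number of odorant dye fields (default 3)
    solver_iters : SOR sweeps of the pressure solve (default 20)
    obstacles : internal solid rectangles (outer walls always present)
    """

    def __init__(
        self,
        nx: int = 140,
        ny: int = 140,
        cell_size: float = 0.015,
        dt: float = 0.030,
        viscosity: float = 0.0,
        dye_diffusion: float = 1e-4,
        evaporation_rate: float = 0.0,
        n_channels: int = 3,
        solver_iters: int = 20,
        obstacles: list[Obstacle] | None = None,
        conserve_dye_mass: bool = True,
        pressure_solver: str = "sor",
    ):
        if pressure_solver not in ("sor", "direct"):
            raise ConfigurationError("pressure_solver must be 'sor' or 'direct'")
        if nx < 3 or ny < 3:
            raise ConfigurationError("grid must be at least 3 x 3")
        if cell_size <= 0 or dt <= 0:
            raise ConfigurationError("cell_size and dt must be > 0")
        if viscosity < 0 or dye_diffusion < 0 or evaporation_rate < 0:
            raise ConfigurationError("coefficients must be >= 0")
        if n_channels < 1 or solver_iters < 1:
            raise ConfigurationError("n_channels and solver_iters must be >= 1")
        self.nx, self.ny = int(nx), int(ny)
        self.cell_size = float(cell_size)
        self.dt = float(dt)
        self.viscosity = float(viscosity)
        self.dye_diffusion = float(dye_diffusion)
        self.evaporation_rate = float(evaporation_rate)
        self.n_channels = int(n_channels)
        self.solver_iters = int(solver_iters)
        self.conserve_dye_mass = bool(conserve_dye_mass)
        self.pressure_solver = pressure_solver
        self.obstacles = list(obstacles or [])

        self.u = np.zeros((ny, nx), dtype=float)
        self.v = np.zeros((ny, nx), dtype=float)
        self.dye = np.zeros((n_channels, ny, nx), dtype=float)

        self.solid = np.zeros((ny, nx), dtype=bool)
        for ob in self.obstacles:
            if not (0 <= ob.ix0 and ob.ix1 < nx and 0 <= ob.iy0 and ob.iy1 < ny):
                raise ConfigurationError(f"obstacle {ob} outside grid")
            self.solid[ob.iy0 : ob.iy1 + 1, ob.ix0 : ob.ix1 + 1] = True

        self._build_operators()
        self._diffusion_cache: dict[float, spla.SuperLU] = {}
        self._pressure_lu: spla.SuperLU | None = None
        self._grid_yx = np.indices((self.ny, self.nx), dtype=float)
        # DCT-II diagonalizes the 5-point Neumann Laplacian on an
        # obstacle-free box: spectral solves are exact and O(n log n)
        self._spectral = not self.solid.any()
        kx = 2.0 * np.cos(np.pi * np.arange(self.nx) / self.nx) - 2.0
        ky = 2.0 * np.cos(np.pi * np.arange(self.ny) / self.ny) - 2.0
        self._lap_eigs = ky[:, None] + kx[None, :]

    # -- topology -----------------------------------------------------------
    def _build_operators(self) -> None:
        ny, nx = self.ny, self.nx
        solid = self.solid
        fluid = ~solid
        # open_r[i,j]: the face between (i,j) and (i,j+1) is open
        open_r = np.zeros((ny, nx), dtype=bool)
        open_r[:, :-1] = fluid[:, :-1] & fluid[:, 1:]
        open_u = np.zeros((ny, nx), dtype=bool)
        open_u[:-1, :] = fluid[:-1, :] & fluid[1:, :]
        open_l = np.zeros((ny, nx), dtype=bool)
        open_l[:, 1:] = open_r[:, :-1]
        open_d = np.zeros((ny, nx), dtype=bool)
        open_d[1:, :] = open_u[:-1, :]
        self._open_r, self._open_u = open_r, open_u
        self._open_l, self._open_d = open_l, open_d
        deg = (
            open_r.astype(np.int64)
            + open_l.astype(np.int64)
            + open_u.astype(np.int64)
            + open_d.astype(np.int64)
        )
        self._deg = deg
        self._fluid = fluid
        yy, xx = np.indices((ny, nx))
        self._red = ((yy + xx) % 2 == 0) & fluid & (deg > 0)
        self._black = ((yy + xx) % 2 == 1) & fluid & (deg > 0)
        n = max(nx, ny)
        self._omega = 2.0 / (1.0 + np.sin(np.pi / n))

    def _laplacian(self) -> sp.csc_matrix:
        """Compact Neumann Laplacian over the open-face graph (row i:
        sum over open faces of (x_nb - x_i)); zero rows for solid cells."""
        ny, nx = self.ny, self.nx
        n = ny * nx
        idx = np.arange(n).reshape(ny, nx)
        rows, cols, vals = [], [], []
        for mask, shift in (
            (self._open_r, idx + 1),
            (self._open_l, idx - 1),
            (self._open_u, idx + nx),
            (self._open_d, idx - nx),
        ):
            r = idx[mask]
            c = shift[mask]
            rows.append(r)
            cols.append(c)
            vals.append(np.ones(r.size))
            rows.append(r)
            cols.append(r)
            vals.append(-np.ones(r.size))
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        return sp.csc_matrix((vals, (rows, cols)), shape=(n, n))

    def _pressure_solver_lu(self) -> spla.SuperLU:
        """Direct factorization of the (pinned) Neumann pressure Poisson
        system; the nullspace constant is removed by fixing one cell."""
        if self._pressure_lu is None:
            lap = self._laplacian().tolil()
            pin = int(np.flatnonzero(self._fluid.ravel())[0])
            lap.rows[pin] = [pin]
            lap.data[pin] = [1.0]
            solids = np.flatnonzero(~self._fluid.ravel())
            for s in solids:
                lap.rows[s] = [int(s)]
                lap.data[s] = [1.0]
            self._pressure_lu = spla.splu(lap.tocsc())
            self._pressure_pin = pin
        return self._pressure_lu

    def _diffusion_solver(self, a: float) -> spla.SuperLU:
        lu = self._diffusion_cache.get(a)
        if lu is None:
            n = self.ny * self.nx
            mat = sp.identity(n, format="csc") - a * self._laplacian()
            lu = spla.splu(mat.tocsc())
            self._diffusion_cache[a] = lu
        return lu

    # -- helpers ------------------------------------------------------------
    def zero_closed_faces(self) -> None:
        """Hold face velocities at walls/obstacle faces at zero and kill any
        velocity stored in solid cells."""
        self.u[~self._open_r] = 0.0
        self.v[~self._open_u] = 0.0
        self.u[self.solid] = 0.0
        self.v[self.solid] = 0.0

    def total_dye(self, channel: int | None = None) -> float:
        if channel is None:
            return float(self.dye.sum())
        return float(self.dye[channel].sum())

    def copy(self) -> "FlowGrid":
        g = FlowGrid(
            nx=self.nx,
            ny=self.ny,
            cell_size=self.cell_size,
            dt=self.dt,
            viscosity=self.viscosity,
            dye_diffusion=self.dye_diffusion,
            evaporation_rate=self.evaporation_rate,
            n_channels=self.n_channels,
            solver_iters=self.solver_iters,
            obstacles=self.obstacles,
            conserve_dye_mass=self.conserve_dye_mass,
            pressure_solver=self.pressure_solver,
        )
        g.u = self.u.copy()
        g.v = self.v.copy()
        g.dye = self.dye.copy()
        # factorizations are immutable; share them across copies
        g._diffusion_cache = self._diffusion_cache
        if self._pressure_lu is not None:
            g._pressure_lu = self._pressure_lu
            g._pressure_pin = self._pressure_pin
        return g


# -- discrete operators -----------------------------------------------------

def divergence(grid: FlowGrid) -> np.ndarray:
    """Discrete divergence: net outflow through each cell's open faces
    (backward differences in cell units; closed faces contribute zero)."""
    u = np.where(grid._open_r, grid.u, 0.0)
    v = np.where(grid._open_u, grid.v, 0.0)
    div = u.copy()
    div[:, 1:] -= u[:, :-1]
    div += v
    div[1:, :] -= v[:-1, :]
    div[grid.solid] = 0.0
    return div


def _project(grid: FlowGrid, iters: int | None = None) -> None:
    """Subtract a pressure gradient so the velocity field becomes
    divergence-free (to the accuracy of ``iters`` SOR sweeps)."""
    grid.zero_closed_faces()
    div = divergence(grid)
    nfluid = int(grid._fluid.sum())
    if nfluid:
        div[grid._fluid] -= div[grid._fluid].sum() / nfluid
    if grid.pressure_solver == "direct" and iters is None:
        if grid._spectral:
            dh = scipy.fft.dctn(div, type=2, norm="ortho")
            with np.errstate(divide="ignore", invalid="ignore"):
                ph = dh / grid._lap_eigs
            ph[0, 0] = 0.0
            p = scipy.fft.idctn(ph, type=2, norm="ortho")
        else:
            lu = grid._pressure_solver_lu()
            rhs = div.ravel().copy()
            rhs[grid._pressure_pin] = 0.0
            rhs[~grid._fluid.ravel()] = 0.0
            p = lu.solve(rhs).reshape(div.shape)
    else:
        p = _sor_pressure(grid, div, grid.solver_iters if iters is None else iters)
    # forward-difference pressure gradient on open faces only
    o_r, o_u = grid._open_r, grid._open_u
    gpx = np.zeros_like(p)
    gpx[:, :-1] = np.where(o_r[:, :-1], p[:, 1:] - p[:, :-1], 0.0)
    gpy = np.zeros_like(p)
    gpy[:-1, :] = np.where(o_u[:-1, :], p[1:, :] - p[:-1, :], 0.0)
    grid.u -= gpx
    grid.v -= gpy
    grid.zero_closed_faces()


def _sor_pressure(grid: FlowGrid, div: np.ndarray, n_iters: int) -> np.ndarray:
    p = np.zeros_like(div)
    deg = np.where(grid._deg > 0, grid._deg, 1).astype(float)
    omega = grid._omega
    o_r, o_l, o_u, o_d = grid._open_r, grid._open_l, grid._open_u, grid._open_d
    nb = np.zeros_like(p)
    for _ in range(n_iters):
        for mask in (grid._red, grid._black):
            nb[:] = 0.0
            nb[:, :-1] += np.where(o_r[:, :-1], p[:, 1:], 0.0)
            nb[:, 1:] += np.where(o_l[:, 1:], p[:, :-1], 0.0)
            nb[:-1, :] += np.where(o_u[:-1, :], p[1:, :], 0.0)
            nb[1:, :] += np.where(o_d[1:, :], p[:-1, :], 0.0)
            p_gs = (nb - div) / deg
            p[mask] += omega * (p_gs[mask] - p[mask])
    return p


def _diffuse(grid: FlowGrid, x: np.ndarray, coef: float) -> np.ndarray:
    if coef <= 0.0:
        return x
    a = coef * grid.dt / grid.cell_size**2
    if grid._spectral:
        xh = scipy.fft.dctn(x, type=2, norm="ortho")
        xh /= 1.0 - a * grid._lap_eigs
        return scipy.fft.idctn(xh, type=2, norm="ortho")
    lu = grid._diffusion_solver(a)
    return lu.solve(x.ravel()).reshape(x.shape)


def _backtrace_indices(field_shape, gy, gx):
    ny, nx = field_shape
    gx = np.clip(gx, 0.0, nx - 1.0)
    gy = np.clip(gy, 0.0, ny - 1.0)
    x0 = np.minimum(gx.astype(np.intp), nx - 2) if nx > 1 else np.zeros_like(gx, np.intp)
    y0 = np.minimum(gy.astype(np.intp), ny - 2) if ny > 1 else np.zeros_like(gy, np.intp)
    return y0, x0, gy - y0, gx - x0


def _bilinear(field: np.ndarray, gy: np.ndarray, gx: np.ndarray) -> np.ndarray:
    y0, x0, fy, fx = _backtrace_indices(field.shape, gy, gx)
    f00 = field[y0, x0]
    f01 = field[y0, x0 + 1]
    f10 = field[y0 + 1, x0]
    f11 = field[y0 + 1, x0 + 1]
    return (1 - fy) * ((1 - fx) * f00 + fx * f01) + fy * ((1 - fx) * f10 + fx * f11)


def _advect(grid: FlowGrid, field: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Semi-Lagrangian advection: backtrace cell centers along the flow and
    bilinearly sample the old field (clamped at the walls)."""
    s = grid.dt / grid.cell_size
    yy, xx = grid._grid_yx
    gx = xx - u * s
    gy = yy - v * s
    return _bilinear(field, gy, gx)


# -- the step ---------------------------------------------------------------

def step_fluid(
    grid: FlowGrid,
    winds: list[WindSource] = (),
    sources: list[OdorPlumeSource] = (),
    body_forces: list[tuple[tuple[int, int], tuple[float, float]]] = (),
    obstacles: list[Obstacle] | None = None,
) -> FlowGrid:
    """Advance the grid by one dt, in place (the grid is also returned).

    Velocity: add forces -> implicit diffusion -> project -> self-advect ->
    project.  Dye, per channel: add sources -> implicit diffusion -> advect
    -> evaporate, clamped non-negative.  ``body_forces`` are per-step
    velocity increments at single cells (e.g. the robot's wake).

    ``obstacles``, if given, must equal the obstacle set the grid was built
    with (walls are part of the grid topology).
    """
    if obstacles is not None and list(obstacles) != grid.obstacles:
        raise ConfigurationError("obstacles differ from the grid's; rebuild the FlowGrid")

    for w in winds:
        for (ix, iy) in w.cells:
            if not (0 <= ix < grid.nx and 0 <= iy < grid.ny):
                raise ConfigurationError(f"wind cell ({ix}, {iy}) outside grid")
            grid.u[iy, ix] += w.force[0] * w.strength
            grid.v[iy, ix] += w.force[1] * w.strength
    for (ix, iy), (fx, fy) in body_forces:
        if not (0 <= ix < grid.nx and 0 <= iy < grid.ny):
            raise ConfigurationError(f"body force cell ({ix}, {iy}) outside grid")
        grid.u[iy, ix] += fx
        grid.v[iy, ix] += fy
    grid.zero_closed_faces()

    if grid.viscosity > 0.0:
        grid.u = _diffuse(grid, grid.u, grid.viscosity)
        grid.v = _diffuse(grid, grid.v, grid.viscosity)
    _project(grid)
    u0, v0 = grid.u, grid.v
    s = grid.dt / grid.cell_size
    yy, xx = grid._grid_yx
    y0, x0, fy, fx = _backtrace_indices(u0.shape, yy - v0 * s, xx - u0 * s)
    w00, w01 = (1 - fy) * (1 - fx), (1 - fy) * fx
    w10, w11 = fy * (1 - fx), fy * fx
    grid.u = w00 * u0[y0, x0] + w01 * u0[y0, x0 + 1] + w10 * u0[y0 + 1, x0] + w11 * u0[y0 + 1, x0 + 1]
    grid.v = w00 * v0[y0, x0] + w01 * v0[y0, x0 + 1] + w10 * v0[y0 + 1, x0] + w11 * v0[y0 + 1, x0 + 1]
    _project(grid)

    for s in sources:
        ix, iy = s.cell
        if not (0 <= ix < grid.nx and 0 <= iy < grid.ny):
            raise ConfigurationError(f"plume source cell ({ix}, {iy}) outside grid")
        if s.channel >= grid.n_channels:
            raise ConfigurationError(f"plume channel {s.channel} >= {grid.n_channels}")
        grid.dye[s.channel, iy, ix] += s.emission_rate * grid.dt

    moving = np.any(grid.u != 0.0) or np.any(grid.v != 0.0)
    decay = np.exp(-grid.evaporation_rate * grid.dt) if grid.evaporation_rate > 0.0 else 1.0
    for k in range(grid.n_channels):
        d = _diffuse(grid, grid.dye[k], grid.dye_diffusion)
        if moving:
            total = d.sum()
            d = _advect(grid, d, grid.u, grid.v)
            d[grid.solid] = 0.0
            if grid.conserve_dye_mass and d.sum() > 0.0:
                d *= total / d.sum()
        if decay != 1.0:
            d = d * decay
        np.clip(d, 0.0, None, out=d)
        grid.dye[k] = d

    checksum = grid.u.sum() + grid.v.sum() + grid.dye.sum()
    if not np.isfinite(checksum):
        raise NumericalStateError("non-finite field values after CFD step")
    return grid


# -- sampling and robot coupling --------------------------------------------

def world_to_grid(grid: FlowGrid, position) -> tuple[float, float]:
    """World meters -> fractional cell-center coordinates (gx, gy)."""
    x, y = float(position[0]), float(position[1])
    if not (0.0 <= x <= grid.nx * grid.cell_size and 0.0 <= y <= grid.ny * grid.cell_size):
        raise ConfigurationError(f"position {position} outside the world")
    return x / grid.cell_size - 0.5, y / grid.cell_size - 0.5


def sample_concentrations(
    grid: FlowGrid,
    position,
    normalize_by: np.ndarray | None = None,
) -> np.ndarray:
    """Per-channel dye at a world position, bilinearly interpolated from the
    four surrounding cell centers.  ``normalize_by`` (per-channel maxima,
    e.g. at the source cells) optionally rescales for logging parity."""
    gx, gy = world_to_grid(grid, position)
    gxa, gya = np.array([gx]), np.array([gy])
    out = np.array([_bilinear(grid.dye[k], gya, gxa)[0] for k in range(grid.n_channels)])
    if normalize_by is not None:
        ref = np.where(np.asarray(normalize_by) > 0.0, normalize_by, 1.0)
        out = out / ref
    return out


def leading_edge_cells(grid: FlowGrid, robot_state) -> list[tuple[int, int]]:
    """Grid cells crossed by the robot's leading edge (the front edge of the
    footprint, normal to the heading), supersampled at one sample per cell
    width and deduplicated."""
    x, y = robot_state.position
    th = robot_state.heading
    fwd = np.array([np.cos(th), np.sin(th)])
    left = np.array([-np.sin(th), np.cos(th)])
    half_w = robot_state.width / 2.0
    center = np.array([x, y]) + fwd * (robot_state.length / 2.0)
    n_samples = max(2, int(np.ceil(robot_state.width / grid.cell_size)) + 1)
    ts = np.linspace(-half_w, half_w, n_samples)
    cells: list[tuple[int, int]] = []
    seen = set()
    for t in ts:
        p = center + left * t
        # samples may poke just past a wall when the chassis is flush
        # against it; clamp them onto the grid
        gx = np.clip(p[0] / grid.cell_size - 0.5, 0.0, grid.nx - 1.0)
        gy = np.clip(p[1] / grid.cell_size - 0.5, 0.0, grid.ny - 1.0)
        cell = (int(np.floor(gx + 0.5)), int(np.floor(gy + 0.5)))
        if cell not in seen:
            seen.add(cell)
            cells.append(cell)
    return cells


def robot_perturbation_forces(
    grid: FlowGrid,
    robot_state,
    effect_magnitude: float = 1.0,
) -> list[tuple[tuple[int, int], tuple[float, float]]]:
    """Equal-and-opposite forces along the robot's leading edge.

    For each CFD cell under the leading edge the returned force is minus the
    velocity vector stored at that cell, scaled by ``effect_magnitude`` (the
    robot's configurable effect on the flow field).
    """
    forces = []
    for (ix, iy) in leading_edge_cells(grid, robot_state):
        fx = -effect_magnitude * grid.u[iy, ix]
        fy = -effect_magnitude * grid.v[iy, ix]
        forces.append(((ix, iy), (fx, fy)))
    return forces
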