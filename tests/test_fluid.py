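"""Stable-fluids solver: stability, incompressibility, dye bookkeeping."""

import numpy as np
import pytest

from plumebrain.fluid import (
    ConfigurationError,
    FlowGrid,
    Obstacle,
    OdorPlumeSource,
    WindSource,
    divergence,
    leading_edge_cells,
    robot_perturbation_forces,
    sample_concentrations,
    step_fluid,
)
from plumebrain.world import RobotState


def oracle_divergence(grid: FlowGrid) -> np.ndarray:
    """Independent cell-by-cell finite-difference divergence (backward
    differences over open faces, zero flux through walls)."""
    ny, nx = grid.ny, grid.nx
    div = np.zeros((ny, nx))
    for i in range(ny):
        for j in range(nx):
            if grid.solid[i, j]:
                continue
            right = grid.u[i, j] if (j + 1 < nx and not grid.solid[i, j + 1]) else 0.0
            left = grid.u[i, j - 1] if (j - 1 >= 0 and not grid.solid[i, j - 1]) else 0.0
            up = grid.v[i, j] if (i + 1 < ny and not grid.solid[i + 1, j]) else 0.0
            down = grid.v[i - 1, j] if (i - 1 >= 0 and not grid.solid[i - 1, j]) else 0.0
            div[i, j] = right - left + up - down
    return div


def test_still_air_identity(small_grid):
    """No flow, no sources, no diffusion: the dye field is a fixed point."""
    g = FlowGrid(nx=16, ny=16, cell_size=0.05, dye_diffusion=0.0, evaporation_rate=0.0)
    g.dye[0] = np.random.default_rng(0).random((16, 16))
    before = g.dye.copy()
    step_fluid(g)
    np.testing.assert_array_equal(g.dye, before)


def test_projection_kills_divergence(small_grid, rng):
    """After a step with 200 pressure sweeps, interior divergence is at most
    1e-6 of the velocity scale, checked against a brute-force oracle."""
    g = small_grid
    g.u = rng.normal(0.0, 0.3, size=g.u.shape)
    g.v = rng.normal(0.0, 0.3, size=g.v.shape)
    step_fluid(g)
    vmax = max(np.abs(g.u).max(), np.abs(g.v).max())
    div = oracle_divergence(g)
    assert np.abs(div).max() <= 1e-6 * vmax
    np.testing.assert_allclose(divergence(g), div, atol=1e-14)


def test_default_iterations_reduce_divergence(rng):
    """Even at interactive solver settings a projection removes at least 90%
    of the divergence present before it."""
    from plumebrain.fluid import _project

    g = FlowGrid(nx=16, ny=16, cell_size=0.05, solver_iters=20)
    g.u = rng.normal(0.0, 0.3, size=g.u.shape)
    g.v = rng.normal(0.0, 0.3, size=g.v.shape)
    g.zero_closed_faces()
    before = np.abs(divergence(g)).max()
    _project(g)
    after = np.abs(divergence(g)).max()
    assert after <= 0.1 * before


def test_mass_budget_single_source_still_air():
    """In still air with diffusion on, one step adds exactly emission*dt."""
    g = FlowGrid(nx=20, ny=20, cell_size=0.05, dye_diffusion=5e-4, evaporation_rate=0.0)
    g.dye[0, 10, 10] = 2.0
    m0 = g.total_dye()
    step_fluid(g, sources=[OdorPlumeSource(cell=(5, 5), channel=0, emission_rate=3.0)])
    assert g.total_dye() == pytest.approx(m0 + 3.0 * g.dt, rel=1e-9)


def test_mass_budget_and_nonnegativity_under_wind(rng):
    """With evaporation off, total dye changes only by injected mass even
    under an arbitrary wind schedule; the field never goes negative."""
    g = FlowGrid(nx=16, ny=16, cell_size=0.05, dye_diffusion=2e-4)
    src = OdorPlumeSource(cell=(8, 8), channel=0, emission_rate=2.0)
    injected = 0.0
    for k in range(200):
        wind = WindSource(
            cells=[(int(rng.integers(0, 16)), int(rng.integers(0, 16)))],
            force=(rng.normal(0, 0.2), rng.normal(0, 0.2)),
        )
        step_fluid(g, winds=[wind], sources=[src])
        injected += src.emission_rate * g.dt
        assert g.dye.min() >= 0.0
    assert g.total_dye() == pytest.approx(injected, rel=1e-9)


def test_evaporation_first_order_decay():
    g = FlowGrid(nx=16, ny=16, cell_size=0.05, dye_diffusion=0.0, evaporation_rate=2.0)
    g.dye[1, 4, 4] = 1.0
    step_fluid(g)
    assert g.dye[1, 4, 4] == pytest.approx(np.exp(-2.0 * g.dt))


def test_unconditional_stability_large_dt(rng):
    """Fields remain finite at ten times the default time step."""
    g = FlowGrid(nx=16, ny=16, cell_size=0.05, dt=0.30, viscosity=1e-3, dye_diffusion=1e-3)
    wind = WindSource(cells=[(8, 8)], force=(0.5, 0.2))
    src = OdorPlumeSource(cell=(4, 12), channel=0, emission_rate=5.0)
    for _ in range(100):
        step_fluid(g, winds=[wind], sources=[src])
    assert np.isfinite(g.u).all() and np.isfinite(g.v).all() and np.isfinite(g.dye).all()


def test_determinism_bit_identical(rng):
    def run():
        g = FlowGrid(nx=16, ny=16, cell_size=0.05, dye_diffusion=1e-4)
        wind = WindSource(cells=[(3, 3)], force=(0.1, -0.05))
        src = OdorPlumeSource(cell=(10, 10), channel=2, emission_rate=1.0)
        for _ in range(50):
            step_fluid(g, winds=[wind], sources=[src])
        return g

    a, b = run(), run()
    np.testing.assert_array_equal(a.u, b.u)
    np.testing.assert_array_equal(a.v, b.v)
    np.testing.assert_array_equal(a.dye, b.dye)


def test_source_outside_grid_is_configuration_error(small_grid):
    with pytest.raises(ConfigurationError):
        step_fluid(small_grid, sources=[OdorPlumeSource(cell=(99, 0), channel=0)])
    with pytest.raises(ConfigurationError):
        step_fluid(small_grid, winds=[WindSource(cells=[(0, 99)], force=(0.1, 0))])


def test_obstacles_block_dye_and_flow(rng):
    g = FlowGrid(
        nx=24, ny=24, cell_size=0.05, dye_diffusion=2e-4,
        obstacles=[Obstacle(10, 0, 12, 16)],
    )
    src = OdorPlumeSource(cell=(4, 8), channel=0, emission_rate=3.0)
    wind = WindSource(cells=[(2, 8)], force=(0.2, 0.0))
    for _ in range(100):
        step_fluid(g, winds=[wind], sources=[src])
    assert np.all(g.dye[0][g.solid] == 0.0)
    assert np.all(g.u[g.solid] == 0.0) and np.all(g.v[g.solid] == 0.0)


class TestSampling:
    def test_cell_center_identity(self, small_grid):
        g = small_grid
        g.dye[0, 5, 7] = 3.5
        pos = ((7 + 0.5) * g.cell_size, (5 + 0.5) * g.cell_size)
        assert sample_concentrations(g, pos)[0] == pytest.approx(3.5)

    def test_uniform_field_invariance(self, small_grid, rng):
        g = small_grid
        g.dye[1] = 0.77
        for _ in range(20):
            pos = rng.uniform(0.06, g.nx * g.cell_size - 0.06, size=2)
            assert sample_concentrations(g, pos)[1] == pytest.approx(0.77)

    def test_four_cell_midpoint(self, small_grid):
        """Midpoint of four cells holding (0, 0, 4, 4) interpolates to 2."""
        g = small_grid
        g.dye[0, 5, 5] = 0.0
        g.dye[0, 5, 6] = 0.0
        g.dye[0, 6, 5] = 4.0
        g.dye[0, 6, 6] = 4.0
        pos = ((5 + 1.0) * g.cell_size, (5 + 1.0) * g.cell_size)
        assert sample_concentrations(g, pos)[0] == pytest.approx(2.0)

    def test_out_of_grid_position_errors(self, small_grid):
        with pytest.raises(ConfigurationError):
            sample_concentrations(small_grid, (-0.1, 0.1))

    def test_normalization(self, small_grid):
        g = small_grid
        g.dye[0, 2, 2] = 5.0
        pos = ((2 + 0.5) * g.cell_size, (2 + 0.5) * g.cell_size)
        out = sample_concentrations(g, pos, normalize_by=np.array([10.0, 1.0, 1.0]))
        assert out[0] == pytest.approx(0.5)


class TestRobotPerturbation:
    def _robot(self, g: FlowGrid) -> RobotState:
        w = g.nx * g.cell_size
        return RobotState(position=(w / 2, w / 2), heading=0.0)

    def test_still_air_zero_forces(self, small_grid):
        for _, f in robot_perturbation_forces(small_grid, self._robot(small_grid)):
            assert f == (0.0, 0.0) or (f[0] == 0.0 and f[1] == 0.0)

    def test_equal_and_opposite(self, small_grid):
        g = small_grid
        g.u[:, :] = 0.2
        for (_, _), (fx, fy) in robot_perturbation_forces(g, self._robot(g), effect_magnitude=1.0):
            assert fx == pytest.approx(-0.2)
            assert fy == pytest.approx(0.0)

    def test_sum_matches_brute_force(self, small_grid, rng):
        g = small_grid
        g.u = rng.normal(0, 0.1, g.u.shape)
        g.v = rng.normal(0, 0.1, g.v.shape)
        robot = self._robot(g)
        mag = 1.7
        forces = robot_perturbation_forces(g, robot, effect_magnitude=mag)
        cells = leading_edge_cells(g, robot)
        expected = -mag * np.sum([[g.u[iy, ix], g.v[iy, ix]] for ix, iy in cells], axis=0)
        total = np.sum([f for _, f in forces], axis=0)
        np.testing.assert_allclose(total, expected, rtol=1e-12)

    def test_edge_spans_robot_width(self, small_grid):
        cells = leading_edge_cells(small_grid, self._robot(small_grid))
        # 0.10 m wide robot over 0.05 m cells: leading edge covers 3 columns
        assert len(cells) == 3
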