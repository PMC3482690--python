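"""Robot agent, trial execution, and the CFD/neural scheduler.

The agent is a differential-drive rectangle (default 0.12 m x 0.10 m, the
footprint of a small tracked robot).  Signed 8-bit tread currents set
target linear and angular speeds; actual speeds relax toward the targets
with a motor time constant and decay by a velocity-proportional friction
decrement each step.  The pose is integrated with forward Euler.

A trial couples the robot, the flow grid, and a controller in a closed
loop at the CFD cadence (default 30 ms): sample the odor concentrations at
the sensor, ask the controller for tread currents (a neural controller
internally advances four simulation timesteps per CFD step — one beta
cycle), move the robot, inject the robot's equal-and-opposite wake forces
into the flow, and step the fluid.  The trial ends when the robot first
comes within the proximity radius of the target plume source, or at the
time cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely.affinity
from shapely.geometry import Polygon, box

from .fluid import (
    FlowGrid,
    Obstacle,
    OdorPlumeSource,
    WindSource,
    robot_perturbation_forces,
    sample_concentrations,
    step_fluid,
)
from .olfaction import Odorant

__all__ = [
    "RobotState",
    "Scenario",
    "TrialResult",
    "step_robot",
    "proximity",
    "run_trial",
    "warmed_grid",
    "beta_cycles",
    "TrialAbort",
]


class TrialAbort(RuntimeError):
    """Controller protocol violation or numerical failure during a trial."""


@dataclass
class RobotState:
    """Agent pose and kinematics."""

    position: tuple[float, float]
    heading: float = 0.0
    speed: float = 0.0
    angular_speed: float = 0.0
    current_left: int = 0
    current_right: int = 0
    length: float = 0.12
    width: float = 0.10
    sensor_offset: tuple[float, float] = (0.06, 0.0)
    """Sensor location in body coordinates (x forward); default front-center."""

    def footprint(self) -> Polygon:
        hl, hw = self.length / 2.0, self.width / 2.0
        poly = box(-hl, -hw, hl, hw)
        poly = shapely.affinity.rotate(poly, self.heading, origin=(0, 0), use_radians=True)
        return shapely.affinity.translate(poly, self.position[0], self.position[1])

    def sensor_position(self) -> tuple[float, float]:
        c, s = np.cos(self.heading), np.sin(self.heading)
        ox, oy = self.sensor_offset
        return (self.position[0] + c * ox - s * oy, self.position[1] + s * ox + c * oy)


def step_robot(
    state: RobotState,
    current_left: int,
    current_right: int,
    dt: float,
    friction_mu: float = 0.5,
    k_m: float = 0.004,
    track_separation: float = 0.10,
    motor_tau: float = 0.1,
) -> RobotState:
    """One kinematic step under signed tread currents.

    Target speeds: v* = k_m (I_L + I_R) / 2 and w* = k_m (I_R - I_L) / W.
    Speeds relax toward the targets (first-order, time constant
    ``motor_tau``) then decay by the friction factor (1 - mu dt); the pose
    is integrated with forward Euler.
    """
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    if abs(current_left) > 127 or abs(current_right) > 127:
        raise ValueError("tread currents must fit a signed 8-bit integer")
    v_target = k_m * (current_left + current_right) / 2.0
    w_target = k_m * (current_right - current_left) / track_separation
    alpha = min(1.0, dt / motor_tau) if motor_tau > 0.0 else 1.0
    decay = max(0.0, 1.0 - friction_mu * dt)
    v = (state.speed + alpha * (v_target - state.speed)) * decay
    w = (state.angular_speed + alpha * (w_target - state.angular_speed)) * decay
    x = state.position[0] + v * np.cos(state.heading) * dt
    y = state.position[1] + v * np.sin(state.heading) * dt
    heading = (state.heading + w * dt) % (2.0 * np.pi)
    return replace(
        state,
        position=(x, y),
        heading=heading,
        speed=v,
        angular_speed=w,
        current_left=int(current_left),
        current_right=int(current_right),
    )


def _footprint_corners(state: RobotState) -> np.ndarray:
    hl, hw = state.length / 2.0, state.width / 2.0
    c, s = np.cos(state.heading), np.sin(state.heading)
    local = np.array([[hl, hw], [hl, -hw], [-hl, -hw], [-hl, hw]])
    rot = np.array([[c, -s], [s, c]])
    return local @ rot.T + np.asarray(state.position)


def proximity(state: RobotState, world_w: float, world_h: float, obstacles_m: list[Polygon] = ()) -> float:
    """Minimum distance (m) from the robot footprint to any wall or
    obstacle; 0 on contact or penetration (including leaving the box)."""
    corners = _footprint_corners(state)
    margins = np.concatenate([corners[:, 0], world_w - corners[:, 0], corners[:, 1], world_h - corners[:, 1]])
    d = float(margins.min())
    if d <= 0.0:
        return 0.0
    if not obstacles_m:
        # convex footprint inside the box: the nearest wall point is a corner
        return d
    fp = state.footprint()
    for ob in obstacles_m:
        if fp.intersects(ob):
            return 0.0
        d = min(d, float(fp.distance(ob)))
    return d


@dataclass
class Scenario:
    """One trial's world definition (grid, sources, robot, termination)."""

    nx: int = 140
    ny: int = 140
    cell_size: float = 0.015
    dt: float = 0.030
    viscosity: float = 0.0
    dye_diffusion: float = 1e-4
    evaporation_rate: float = 0.0
    solver_iters: int = 20
    pressure_solver: str = "sor"
    n_channels: int = 3
    sources: list[OdorPlumeSource] = field(default_factory=list)
    winds: list[WindSource] = field(default_factory=list)
    obstacles: list[Obstacle] = field(default_factory=list)
    odorants: list[Odorant] = field(default_factory=list)
    start_position: tuple[float, float] = (1.05, 1.05)
    start_heading: float = 0.0
    robot_length: float = 0.12
    robot_width: float = 0.10
    sensor_offset: tuple[float, float] = (0.06, 0.0)
    friction_mu: float = 0.5
    k_m: float = 0.004
    track_separation: float = 0.10
    motor_tau: float = 0.1
    robot_effect_magnitude: float = 1.0
    target_source: int = 0
    proximity_radius: float = 0.15
    max_duration: float = 30.0
    warmup_steps: int = 0
    neural_steps_per_cfd_step: int = 4
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self) -> None:
        if self.proximity_radius <= 0.0:
            raise ValueError("proximity_radius must be > 0")
        if self.max_duration <= 0.0:
            raise ValueError("max_duration must be > 0")
        if self.sources and not (0 <= self.target_source < len(self.sources)):
            raise ValueError("target_source must index an odor source")

    @property
    def world_size(self) -> tuple[float, float]:
        return (self.nx * self.cell_size, self.ny * self.cell_size)

    @property
    def world_diagonal(self) -> float:
        w, h = self.world_size
        return float(np.hypot(w, h))

    def build_grid(self) -> FlowGrid:
        return FlowGrid(
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
            pressure_solver=self.pressure_solver,
        )

    def initial_robot(self) -> RobotState:
        return RobotState(
            position=self.start_position,
            heading=self.start_heading,
            length=self.robot_length,
            width=self.robot_width,
            sensor_offset=self.sensor_offset,
        )

    def source_position(self, index: int | None = None) -> tuple[float, float]:
        src = self.sources[self.target_source if index is None else index]
        ix, iy = src.cell
        return ((ix + 0.5) * self.cell_size, (iy + 0.5) * self.cell_size)

    def obstacle_polygons(self) -> list[Polygon]:
        h = self.cell_size
        return [box(ob.ix0 * h, ob.iy0 * h, (ob.ix1 + 1) * h, (ob.iy1 + 1) * h) for ob in self.obstacles]


@dataclass
class TrialResult:
    """Outcome and per-CFD-step logs of one closed-loop trial."""

    reached: bool
    time_to_source: float
    final_distance: float
    collision_count: int
    trajectory: np.ndarray
    """Columns: t, x, y, heading, I_L, I_R, proximity."""
    concentrations: np.ndarray
    """Columns: t, c_1..c_K (raw dye units at the sensor)."""
    source_max: np.ndarray
    """Per-channel maximum dye seen at the source cells (normalization ref)."""
    dt: float = 0.030

    def normalized_concentrations(self) -> np.ndarray:
        ref = np.where(self.source_max > 0.0, self.source_max, 1.0)
        out = self.concentrations.copy()
        out[:, 1:] = out[:, 1:] / ref
        return out


def beta_cycles(n_neural_steps: int, steps_per_cycle: int = 4) -> float:
    """Beta oscillation cycles spanned by ``n_neural_steps`` simulation
    timesteps at the default four timesteps per cycle (10,000 timesteps are
    2,500 beta cycles)."""
    if steps_per_cycle < 1:
        raise ValueError("steps_per_cycle must be >= 1")
    return n_neural_steps / steps_per_cycle


def _clamp_current(x) -> int:
    return int(np.clip(int(x), -127, 127))


def warmed_grid(scenario: Scenario) -> FlowGrid:
    """Build the scenario's grid and run its warm-up CFD steps (plume
    establishment before the robot starts moving)."""
    grid = scenario.build_grid()
    for _ in range(scenario.warmup_steps):
        step_fluid(grid, scenario.winds, scenario.sources)
    return grid


def run_trial(
    scenario: Scenario,
    controller,
    seed: int | None = None,
    initial_grid: FlowGrid | None = None,
) -> TrialResult:
    """Execute the closed sensorimotor loop; bit-reproducible under
    (scenario, controller state, seed).

    Per CFD step: sample concentrations at the sensor, get tread currents
    from the controller, advance the robot (collisions clamp the pose and
    zero the speed), inject the robot's perturbation forces, and step the
    fluid.  Terminates at the first step where the robot center is within
    the proximity radius of the target source, or at ``max_duration``.

    ``initial_grid`` (e.g. from :func:`warmed_grid`) replaces the built-in
    warm-up, letting many trials share one deterministic plume spin-up; the
    grid is copied, never mutated.
    """
    if seed is None:
        seed = scenario.seed
    grid = initial_grid.copy() if initial_grid is not None else None
    state = scenario.initial_robot()
    obstacles_m = scenario.obstacle_polygons()
    world_w, world_h = scenario.world_size
    target = np.asarray(scenario.source_position()) if scenario.sources else None
    dt = scenario.dt
    n_steps = int(round(scenario.max_duration / dt))

    try:
        controller.reset(seed)
    except Exception as exc:  # noqa: BLE001 - protocol violation surfaces as abort
        raise TrialAbort(f"controller reset failed: {exc}") from exc

    if grid is None:
        grid = warmed_grid(scenario)

    src_cells = [(s.cell, s.channel) for s in scenario.sources]
    source_max = np.zeros(grid.n_channels)
    traj_rows, conc_rows = [], []
    reached = False
    time_to_source = scenario.max_duration
    collisions = 0
    in_contact = False  # a clamped collision counts as zero proximity

    for step in range(n_steps):
        t = step * dt
        if target is not None:
            dist = float(np.hypot(*(np.asarray(state.position) - target)))
            if dist <= scenario.proximity_radius:
                reached = True
                time_to_source = t
                break
        for (ix, iy), ch in src_cells:
            source_max[ch] = max(source_max[ch], grid.dye[ch, iy, ix])
        sx, sy = state.sensor_position()
        conc = sample_concentrations(
            grid, (min(max(sx, 0.0), world_w), min(max(sy, 0.0), world_h))
        )
        prox = 0.0 if in_contact else proximity(state, world_w, world_h, obstacles_m)
        try:
            i_l, i_r = controller.command(conc, prox, dt)
        except Exception as exc:  # noqa: BLE001
            raise TrialAbort(f"controller command failed: {exc}") from exc
        i_l, i_r = _clamp_current(i_l), _clamp_current(i_r)
        new_state = step_robot(
            state,
            i_l,
            i_r,
            dt,
            friction_mu=scenario.friction_mu,
            k_m=scenario.k_m,
            track_separation=scenario.track_separation,
            motor_tau=scenario.motor_tau,
        )
        if proximity(new_state, world_w, world_h, obstacles_m) <= 0.0:
            # collision: clamp the pose (keep the old position, allow the
            # turn), zero the speed into the wall
            new_state = replace(
                new_state,
                position=state.position,
                speed=0.0,
            )
            collisions += 1
            in_contact = True
        else:
            in_contact = False
        state = new_state
        forces = robot_perturbation_forces(grid, state, scenario.robot_effect_magnitude)
        step_fluid(grid, scenario.winds, scenario.sources, forces)
        traj_rows.append((t, state.position[0], state.position[1], state.heading, i_l, i_r, prox))
        conc_rows.append((t, *conc))

    final_distance = (
        float(np.hypot(*(np.asarray(state.position) - target))) if target is not None else float("nan")
    )
    return TrialResult(
        reached=reached,
        time_to_source=time_to_source,
        final_distance=final_distance,
        collision_count=collisions,
        trajectory=np.array(traj_rows, dtype=float).reshape(-1, 7),
        concentrations=np.array(conc_rows, dtype=float).reshape(-1, 1 + grid.n_channels),
        source_max=source_max,
        dt=dt,
    )
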