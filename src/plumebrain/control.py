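"""Motor-pool mapping and the built-in five-state exploratory behavior.

The 16 motor units split into four directional pools — left-forward,
left-backward, right-forward, right-backward — with forces 1, 2, 4, 8
assigned within each pool (the size principle: units of graded power are
recruited incrementally).  Each tread's net current is the forward pool sum
minus the backward pool sum, an 8-bit signed integer; the backward pools
exist because firing rates cannot be negative.

The scripted exploratory behavior classifies the recent odor signal into
five states — LOW / HIGH absolute concentration, RISING / FALLING relative
to the reading 1 s earlier, and a collision-triggered REVERSING mode — and
maps each state to a tread-current command (surge, slow advance, crosswind
casting, biased random walk, backing out).
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotorPools",
    "motor_units_to_currents",
    "BehaviorState",
    "BehaviorParams",
    "classify_state",
    "BehaviorController",
    "ZeroController",
    "NeuralController",
]

POOL_FORCES = (1, 2, 4, 8)


@dataclass(frozen=True)
class MotorPools:
    """Assignment of 16 motor units to the 4 directional pools.

    Defaults: units 0-3 left-forward, 4-7 left-backward, 8-11 right-forward,
    12-15 right-backward, forces (1, 2, 4, 8) in index order within a pool.
    """

    left_forward: tuple[int, ...] = (0, 1, 2, 3)
    left_backward: tuple[int, ...] = (4, 5, 6, 7)
    right_forward: tuple[int, ...] = (8, 9, 10, 11)
    right_backward: tuple[int, ...] = (12, 13, 14, 15)
    gain: float = 1.0
    pool_gains: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    """Per-pool scaling (LF, LB, RF, RB) applied before the net sum."""

    def __post_init__(self) -> None:
        pools = (self.left_forward, self.left_backward, self.right_forward, self.right_backward)
        all_units = [u for p in pools for u in p]
        if sorted(all_units) != list(range(16)):
            raise ValueError("pools must partition motor units 0..15")
        if any(len(p) != 4 for p in pools):
            raise ValueError("each pool holds exactly 4 units")


def _pool_sum(activity: np.ndarray, pool: tuple[int, ...]) -> int:
    return int(sum(f * int(activity[u]) for f, u in zip(POOL_FORCES, pool)))


def motor_units_to_currents(activity, pools: MotorPools = MotorPools()) -> tuple[int, int]:
    """Net signed tread currents from 16 binary motor-unit activities.

    Per tread: (forward pool force sum) - (backward pool force sum), scaled
    by the pool gain and clamped to the signed 8-bit range.  With gain 1 the
    result lies in [-15, 15].
    """
    a = np.asarray(activity)
    if a.shape != (16,):
        raise ValueError("expected 16 motor activities")
    if not np.all((a == 0) | (a == 1)):
        raise ValueError("motor activities must be binary")
    g_lf, g_lb, g_rf, g_rb = pools.pool_gains
    i_l = g_lf * _pool_sum(a, pools.left_forward) - g_lb * _pool_sum(a, pools.left_backward)
    i_r = g_rf * _pool_sum(a, pools.right_forward) - g_rb * _pool_sum(a, pools.right_backward)
    i_l = int(np.clip(round(pools.gain * i_l), -127, 127))
    i_r = int(np.clip(round(pools.gain * i_r), -127, 127))
    return i_l, i_r


class BehaviorState(enum.Enum):
    LOW = "low"
    HIGH = "high"
    RISING = "rising"
    FALLING = "falling"
    REVERSING = "reversing"


@dataclass
class BehaviorParams:
    """Thresholds and command table for the five-state behavior.

    Concentrations are summed across channels.  Defaults place the LOW/HIGH
    thresholds at 0.05/0.6 of normalized concentration with a 0.02 deadband
    on the 1-s rising/falling comparison.
    """

    theta_low: float = 0.05
    theta_high: float = 0.6
    deadband: float = 0.02
    lookback_s: float = 1.0
    reversing_dwell_s: float = 1.0
    cast_dwell_s: float = 0.5
    surge: tuple[int, int] = (15, 15)
    slow: tuple[int, int] = (4, 4)
    cast_magnitude: int = 12
    reverse: tuple[int, int] = (-10, -10)
    walk_forward: int = 8
    walk_turn_max: int = 7

    def __post_init__(self) -> None:
        if not self.theta_low < self.theta_high:
            raise ValueError("theta_low must be < theta_high")


def classify_state(
    history,
    proximity: float,
    params: BehaviorParams,
    dt: float,
    reversing_timer: float = 0.0,
) -> BehaviorState:
    """Classify the current sensory state from the summed-concentration
    history (most recent last, one entry per CFD step of length ``dt``).

    Priority: REVERSING (zero proximity or an active reversing timer) >
    HIGH > RISING > FALLING > LOW.  With less than 1 s of history the
    rising/falling comparison is unavailable and the state falls back to
    the absolute-concentration rules.
    """
    if proximity <= 0.0 or reversing_timer > 0.0:
        return BehaviorState.REVERSING
    if len(history) == 0:
        return BehaviorState.LOW
    c_now = history[-1]
    if c_now >= params.theta_high:
        return BehaviorState.HIGH
    lag = int(round(params.lookback_s / dt))
    if lag >= 1 and len(history) > lag:
        c_then = history[-1 - lag]
        if c_now - c_then > params.deadband:
            return BehaviorState.RISING
        if c_then - c_now > params.deadband:
            return BehaviorState.FALLING
    return BehaviorState.LOW


class BehaviorController:
    """Drop-in controller implementing the five-state exploration.

    Same interface as the neural controller: ``reset(seed)`` then one
    ``command(concentrations, proximity, dt)`` call per CFD step returning
    signed tread currents.
    """

    def __init__(self, params: BehaviorParams | None = None):
        self.params = params or BehaviorParams()
        self.reset(0)

    def reset(self, seed: int | None) -> None:
        self._rng = np.random.default_rng(seed)
        self._history: deque[float] = deque(maxlen=4096)
        self._reversing_timer = 0.0
        self._cast_timer = 0.0
        self._cast_sign = 1
        self.last_state: BehaviorState | None = None

    def command(self, concentrations, proximity: float, dt: float) -> tuple[int, int]:
        p = self.params
        self._history.append(float(np.sum(concentrations)))
        state = classify_state(self._history, proximity, p, dt, self._reversing_timer)
        self.last_state = state
        if state is BehaviorState.REVERSING:
            if self._reversing_timer <= 0.0:
                self._reversing_timer = p.reversing_dwell_s
            self._reversing_timer -= dt
            if self._reversing_timer <= 0.0:
                # dwell expired: pick a fresh random heading next step
                turn = int(self._rng.integers(-p.walk_turn_max, p.walk_turn_max + 1))
                return (p.walk_forward - turn, p.walk_forward + turn)
            return p.reverse
        self._reversing_timer = 0.0
        if state is BehaviorState.RISING:
            return p.surge
        if state is BehaviorState.HIGH:
            return p.slow
        if state is BehaviorState.FALLING:
            self._cast_timer -= dt
            if self._cast_timer <= 0.0:
                self._cast_timer = p.cast_dwell_s
                self._cast_sign = -self._cast_sign
            m = p.cast_magnitude
            return (m * self._cast_sign, -m * self._cast_sign)
        # LOW: biased random walk, forward plus a seeded random turn
        turn = int(self._rng.integers(-p.walk_turn_max, p.walk_turn_max + 1))
        return (p.walk_forward - turn, p.walk_forward + turn)


class ZeroController:
    """Controller that never moves (null baseline)."""

    def reset(self, seed: int | None) -> None:  # noqa: ARG002 - interface
        return None

    def command(self, concentrations, proximity, dt) -> tuple[int, int]:  # noqa: ARG002
        return (0, 0)


class NeuralController:
    """Closed-loop neural controller: odor concentrations -> motif mixture ->
    sensor array -> circuit -> motor pools -> tread currents.

    Per CFD step the network advances ``substeps`` simulation timesteps
    (default 4 — one beta cycle per CFD update); the tread currents are read
    from the motor activity of the final substep.
    """

    def __init__(
        self,
        network,
        sensor_array,
        odorants,
        background=None,
        pools: MotorPools | None = None,
        substeps: int = 4,
    ):
        from .olfaction import Background

        self.network = network
        self.sensor_array = sensor_array
        self.odorants = list(odorants)
        self.background = background if background is not None else Background()
        self.pools = pools or MotorPools()
        self.substeps = int(substeps)
        self._rng = np.random.default_rng(0)

    def reset(self, seed: int | None) -> None:
        self._rng = np.random.default_rng(seed)
        self.network.reset()

    def command(self, concentrations, proximity, dt) -> tuple[int, int]:  # noqa: ARG002
        from .olfaction import motif_concentrations

        bg_sample = None
        if self.background.odorants:
            bg_sample = self.background.sample(self._rng if self.background.noise_sd > 0 else None)
        m = motif_concentrations(
            concentrations,
            self.odorants,
            self.background,
            bg_sample,
            n_motifs=self.sensor_array.n_motifs,
        )
        activations = self.sensor_array.respond(m)
        motor = self.network.motor
        for _ in range(self.substeps):
            motor = self.network.step(activations)
        return motor_units_to_currents(motor, self.pools)
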