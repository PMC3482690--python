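"""Named scenario presets (the fixture generator).

All inputs to the platform are synthesized: these presets build complete,
valid scenarios deterministically from (name, seed, scale).

* ``three-plume`` — three independent plume sources on distinct odorant
  channels (the red/green/blue arrangement), no obstacles.
* ``figure3`` — two plumes, two wind sources, and one internal boundary,
  with the robot starting near the center.
* ``corridor`` — obstacle-free kinematics test: a single target source
  straight ahead of the robot, still air.
* ``desk-evolution`` — the scaled-down closed-loop evolution arena: a 70x70
  grid, a single upwind target plume advected toward the robot's start
  area.

``scale`` is ``"full"`` (140 x 140 cells) or ``"desk"`` (70 x 70).
"""

from __future__ import annotations

import numpy as np

from .fluid import Obstacle, OdorPlumeSource, WindSource
from .olfaction import Odorant
from .world import Scenario

__all__ = ["PRESETS", "generate_fixture"]

# canonical odorant chemistry: three plume odorants on channels 0..2, each
# exhibiting a handful of the 10 motifs in fixed degrees
_ODORANT_DEGREES = (
    (0.9, 0.6, 0.3, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    (0.0, 0.0, 0.4, 0.8, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0),
    (0.0, 0.0, 0.0, 0.0, 0.0, 0.3, 0.7, 0.9, 0.2, 0.0),
)


def _odorants(n: int) -> list[Odorant]:
    return [Odorant(degrees=np.array(_ODORANT_DEGREES[k]), channel=k) for k in range(n)]


def _dims(scale: str) -> tuple[int, float]:
    if scale == "full":
        return 140, 0.015
    if scale == "desk":
        return 70, 0.010
    raise ValueError(f"unknown scale {scale!r}; choose 'full' or 'desk'")


def _three_plume(seed: int, scale: str) -> Scenario:
    n, h = _dims(scale)
    w = n * h
    cells = [int(n * f) for f in (0.2, 0.5, 0.8)]
    sources = [
        OdorPlumeSource(cell=(cells[0], int(n * 0.8)), channel=0, emission_rate=30.0),
        OdorPlumeSource(cell=(cells[1], int(n * 0.85)), channel=1, emission_rate=30.0),
        OdorPlumeSource(cell=(cells[2], int(n * 0.8)), channel=2, emission_rate=30.0),
    ]
    winds = [
        WindSource(cells=[(c, int(n * 0.9))], force=(0.0, -0.02)) for c in cells
    ]
    return Scenario(
        nx=n,
        ny=n,
        cell_size=h,
        sources=sources,
        winds=winds,
        odorants=_odorants(3),
        start_position=(w / 2, w * 0.2),
        start_heading=np.pi / 2,
        target_source=1,
        proximity_radius=0.12 if scale == "desk" else 0.15,
        max_duration=30.0,
        warmup_steps=60,
        seed=seed,
        name=f"three-plume-{scale}",
    )


def _figure3(seed: int, scale: str) -> Scenario:
    n, h = _dims(scale)
    w = n * h
    sources = [
        OdorPlumeSource(cell=(int(n * 0.15), int(n * 0.75)), channel=0, emission_rate=30.0),
        OdorPlumeSource(cell=(int(n * 0.85), int(n * 0.75)), channel=2, emission_rate=30.0),
    ]
    winds = [
        WindSource(cells=[(int(n * 0.1), int(n * 0.9))], force=(0.015, -0.015)),
        WindSource(cells=[(int(n * 0.9), int(n * 0.9))], force=(-0.015, -0.015)),
    ]
    wall_y = int(n * 0.5)
    obstacles = [Obstacle(ix0=int(n * 0.35), iy0=wall_y, ix1=int(n * 0.65), iy1=wall_y + 1)]
    return Scenario(
        nx=n,
        ny=n,
        cell_size=h,
        sources=sources,
        winds=winds,
        obstacles=obstacles,
        odorants=_odorants(3),
        start_position=(w / 2, w * 0.25),
        start_heading=np.pi / 2,
        target_source=0,
        proximity_radius=0.12 if scale == "desk" else 0.15,
        max_duration=30.0,
        warmup_steps=60,
        seed=seed,
        name=f"figure3-{scale}",
    )


def _corridor(seed: int, scale: str) -> Scenario:
    n, h = _dims(scale)
    w = n * h
    sources = [OdorPlumeSource(cell=(int(n * 0.85), n // 2), channel=0, emission_rate=30.0)]
    return Scenario(
        nx=n,
        ny=n,
        cell_size=h,
        sources=sources,
        winds=[],
        odorants=_odorants(3),
        start_position=(w * 0.15, w / 2),
        start_heading=0.0,
        target_source=0,
        proximity_radius=0.10,
        max_duration=30.0,
        warmup_steps=0,
        seed=seed,
        name=f"corridor-{scale}",
    )


def _desk_evolution(seed: int, scale: str) -> Scenario:
    n, h = _dims("desk")
    w = n * h  # 0.70 m arena
    src = (int(n * 0.72), int(n * 0.60))
    fan = [(int(n * 0.9), int(n * 0.62) + dy) for dy in (-2, 0, 2)]
    sources = [OdorPlumeSource(cell=src, channel=0, emission_rate=40.0)]
    winds = [WindSource(cells=fan, force=(-0.08, -0.04))]
    return Scenario(
        nx=n,
        ny=n,
        cell_size=h,
        dye_diffusion=2e-4,
        pressure_solver="direct",
        n_channels=1,
        sources=sources,
        winds=winds,
        odorants=_odorants(1),
        start_position=(w * 0.30, w * 0.40),
        start_heading=0.0,
        k_m=0.006,
        target_source=0,
        proximity_radius=0.09,
        max_duration=5.0,
        warmup_steps=400,
        seed=seed,
        name="desk-evolution",
    )


PRESETS = {
    "three-plume": _three_plume,
    "figure3": _figure3,
    "corridor": _corridor,
    "desk-evolution": _desk_evolution,
}


def generate_fixture(name: str, seed: int = 0, scale: str = "full") -> Scenario:
    """Build a named preset scenario; deterministic under (name, seed, scale)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](seed, scale)
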