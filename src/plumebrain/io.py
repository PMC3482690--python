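"""Configuration and log file formats: scenario YAML, CSV logs, manifests.

Everything the CLI emits round-trips through the readers here, and every
run writes a manifest (config hash, seeds, package version) sufficient to
reproduce it bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fluid import Obstacle, OdorPlumeSource, WindSource
from .olfaction import Odorant
from .world import Scenario, TrialResult

__all__ = [
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario",
    "write_trajectory_csv",
    "write_concentration_trace",
    "write_trial_json",
    "write_manifest",
]


def scenario_to_dict(s: Scenario) -> dict:
    d = {
        k: v
        for k, v in asdict(s).items()
        if k not in ("sources", "winds", "obstacles", "odorants")
    }
    d["start_position"] = list(s.start_position)
    d["sensor_offset"] = list(s.sensor_offset)
    d["sources"] = [
        {"cell": list(src.cell), "channel": src.channel, "emission_rate": src.emission_rate}
        for src in s.sources
    ]
    d["winds"] = [
        {"cells": [list(c) for c in w.cells], "force": list(w.force), "strength": w.strength}
        for w in s.winds
    ]
    d["obstacles"] = [[ob.ix0, ob.iy0, ob.ix1, ob.iy1] for ob in s.obstacles]
    d["odorants"] = [
        {"degrees": [float(x) for x in od.degrees], "channel": od.channel} for od in s.odorants
    ]
    return d


def scenario_from_dict(d: dict) -> Scenario:
    d = dict(d)
    sources = [
        OdorPlumeSource(cell=tuple(x["cell"]), channel=int(x["channel"]), emission_rate=float(x["emission_rate"]))
        for x in d.pop("sources", [])
    ]
    winds = [
        WindSource(
            cells=[tuple(c) for c in x["cells"]],
            force=tuple(x["force"]),
            strength=float(x.get("strength", 1.0)),
        )
        for x in d.pop("winds", [])
    ]
    obstacles = [Obstacle(*map(int, row)) for row in d.pop("obstacles", [])]
    odorants = [
        Odorant(degrees=np.array(x["degrees"], dtype=float), channel=x["channel"])
        for x in d.pop("odorants", [])
    ]
    d["start_position"] = tuple(d.get("start_position", (0.0, 0.0)))
    d["sensor_offset"] = tuple(d.get("sensor_offset", (0.06, 0.0)))
    return Scenario(sources=sources, winds=winds, obstacles=obstacles, odorants=odorants, **d)


def save_scenario(s: Scenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(s), sort_keys=True))


def load_scenario(path: str | Path) -> Scenario:
    return scenario_from_dict(yaml.safe_load(Path(path).read_text()))


def write_trajectory_csv(result: TrialResult, path: str | Path) -> None:
    cols = ["t", "x", "y", "heading", "I_L", "I_R", "proximity"]
    pd.DataFrame(result.trajectory, columns=cols).to_csv(path, index=False)


def write_concentration_trace(result: TrialResult, path: str | Path) -> None:
    """Concentration log, one row per CFD step (1/30 s at defaults):
    t, raw c_1..c_K, then the same normalized by the per-channel maximum
    concentration found at the source cells."""
    k = result.concentrations.shape[1] - 1
    cols = ["t"] + [f"c{i + 1}" for i in range(k)]
    df = pd.DataFrame(result.concentrations, columns=cols)
    norm = result.normalized_concentrations()
    for i in range(k):
        df[f"c{i + 1}_norm"] = norm[:, 1 + i]
    df.to_csv(path, index=False)


def write_trial_json(result: TrialResult, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "reached": bool(result.reached),
                "time_to_source": result.time_to_source,
                "final_distance": result.final_distance,
                "collision_count": result.collision_count,
                "n_steps": int(result.trajectory.shape[0]),
                "dt": result.dt,
            },
            indent=2,
        )
    )


def write_manifest(path: str | Path, config: dict, seed: int | None, extra: dict | None = None) -> dict:
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "python": platform.python_version(),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
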