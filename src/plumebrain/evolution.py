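"""Genetic-algorithm harness over the circuit's parameter vector.

The genome (schema v1, 40 named bounded parameters) covers the five
synapse classes (weight, PSP duration, depression fraction and recovery
rate, weight spread), the cortical integration parameters (branch mode,
branches-to-fire, gain, initial thresholds, homeostatic target rates),
and the motor mapping gains.  Fitness is behavioral: the time for the
neurally controlled robot to reach a defined proximity of the target
plume source, with unreached trials scored as the time cap plus the
normalized final distance so selection keeps a gradient.

Operators: tournament selection, uniform crossover, per-gene Gaussian
mutation clipped to bounds, and elitism.  All randomness derives from the
master seed; per-individual trial seeds are derived from (master seed,
generation, index) so results are independent of evaluation order, and
each generation's reproduction uses its own derived stream so a run can
resume from a checkpoint bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .brain import NetworkConfig, NetworkParams, SynapseClassParams, SYNAPSE_CLASSES, build_network
from .control import MotorPools, NeuralController
from .olfaction import generate_sensor_array
from .world import Scenario, TrialAbort, run_trial, warmed_grid

__all__ = [
    "ParamSpec",
    "GENOME_SCHEMA",
    "Genome",
    "EvolutionConfig",
    "EvolutionHistory",
    "fitness",
    "next_generation",
    "run_evolution",
]

GENOME_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ParamSpec:
    name: str
    lo: float
    hi: float
    integer: bool = False


def _build_schema() -> list[ParamSpec]:
    specs: list[ParamSpec] = []
    for cls in SYNAPSE_CLASSES:
        if cls == "inter_cortex":
            specs.append(ParamSpec(f"{cls}.weight", -2.0, -0.01))
        else:
            specs.append(ParamSpec(f"{cls}.weight", 0.0, 2.0))
        specs.append(ParamSpec(f"{cls}.psp_duration", 1, 8, integer=True))
        specs.append(ParamSpec(f"{cls}.dep_u", 0.0, 0.8))
        specs.append(ParamSpec(f"{cls}.dep_recovery", 0.01, 0.5))
        specs.append(ParamSpec(f"{cls}.weight_sd", 0.0, 0.3))
    specs += [
        ParamSpec("branch_mode", 0, 2, integer=True),
        ParamSpec("branches_to_fire", 1, 8, integer=True),
        ParamSpec("branch_gain", 0.5, 8.0),
        ParamSpec("branch_threshold0", 0.02, 2.0),
        ParamSpec("soma_threshold0", 0.02, 2.0),
        ParamSpec("inter_threshold", 0.02, 2.0),
        ParamSpec("motor_threshold", 0.02, 4.0),
        ParamSpec("mitral_gain", 0.2, 2.0),
        ParamSpec("branch_target", 0.01, 0.3),
        ParamSpec("soma_target", 0.01, 0.3),
        ParamSpec("motor_gain", 0.5, 3.0),
        ParamSpec("pool_gain_lf", 0.5, 1.5),
        ParamSpec("pool_gain_lb", 0.5, 1.5),
        ParamSpec("pool_gain_rf", 0.5, 1.5),
        ParamSpec("pool_gain_rb", 0.5, 1.5),
    ]
    return specs


GENOME_SCHEMA: list[ParamSpec] = _build_schema()
_SCHEMA_BY_NAME = {s.name: s for s in GENOME_SCHEMA}
_BRANCH_MODES = ("thresholded", "linear", "sigmoidal")


@dataclass
class Genome:
    """Named bounded parameter vector (all values stored as floats).

    ``step`` is the genome's self-adaptive mutation scale (an evolution
    strategy device: inherited through selection and log-normally perturbed
    at reproduction, so the search radius anneals itself); it multiplies
    the base mutation sigma and is not part of the parameter schema.
    """

    values: dict[str, float]
    schema_version: int = GENOME_SCHEMA_VERSION
    step: float = 1.0

    def __post_init__(self) -> None:
        missing = set(_SCHEMA_BY_NAME) - set(self.values)
        extra = set(self.values) - set(_SCHEMA_BY_NAME)
        if missing or extra:
            raise ValueError(f"genome keys mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, v in self.values.items():
            spec = _SCHEMA_BY_NAME[name]
            if not (spec.lo <= v <= spec.hi):
                raise ValueError(f"{name}={v} outside [{spec.lo}, {spec.hi}]")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def _int(self, name: str) -> int:
        spec = _SCHEMA_BY_NAME[name]
        return int(np.clip(round(self.values[name]), spec.lo, spec.hi))

    @classmethod
    def random(cls, rng: np.random.Generator) -> "Genome":
        vals = {s.name: float(rng.uniform(s.lo, s.hi)) for s in GENOME_SCHEMA}
        return cls(vals)

    @classmethod
    def default(cls) -> "Genome":
        """Mid-range genome with sane signs; a reasonable evolution parent."""
        vals = {}
        for s in GENOME_SCHEMA:
            if s.name.endswith(".weight"):
                vals[s.name] = -1.0 if s.name.startswith("inter_cortex") else 1.0
            elif s.name.endswith(".psp_duration"):
                vals[s.name] = 1.0
            elif s.name.endswith(".dep_u") or s.name.endswith(".weight_sd"):
                vals[s.name] = 0.0
            elif s.name.endswith(".dep_recovery"):
                vals[s.name] = 0.1
            elif s.name == "branch_mode":
                vals[s.name] = 0.0
            elif s.name == "branches_to_fire":
                vals[s.name] = 2.0
            elif s.name.startswith("pool_gain"):
                vals[s.name] = 1.0
            else:
                vals[s.name] = float(np.clip(0.5, s.lo, s.hi))
        vals["branch_gain"] = 4.0
        vals["motor_gain"] = 1.0
        vals["mitral_gain"] = 1.0
        vals["branch_target"] = 0.05
        vals["soma_target"] = 0.05
        return cls(vals)

    # -- mapping into the circuit ------------------------------------------
    def network_params(self) -> NetworkParams:
        classes = {}
        for cls in SYNAPSE_CLASSES:
            classes[cls] = SynapseClassParams(
                weight=self.values[f"{cls}.weight"],
                psp_duration=self._int(f"{cls}.psp_duration"),
                dep_u=self.values[f"{cls}.dep_u"],
                dep_recovery=self.values[f"{cls}.dep_recovery"],
                weight_sd=self.values[f"{cls}.weight_sd"],
            )
        return NetworkParams(
            classes=classes,
            branch_mode=_BRANCH_MODES[self._int("branch_mode")],
            branches_to_fire=self._int("branches_to_fire"),
            branch_gain=self.values["branch_gain"],
            branch_threshold0=self.values["branch_threshold0"],
            soma_threshold0=self.values["soma_threshold0"],
            inter_threshold=self.values["inter_threshold"],
            motor_threshold=self.values["motor_threshold"],
            mitral_gain=self.values["mitral_gain"],
            branch_target=self.values["branch_target"],
            soma_target=self.values["soma_target"],
        )

    def motor_pools(self) -> MotorPools:
        return MotorPools(
            gain=self.values["motor_gain"],
            pool_gains=(
                self.values["pool_gain_lf"],
                self.values["pool_gain_lb"],
                self.values["pool_gain_rf"],
                self.values["pool_gain_rb"],
            ),
        )

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"schema_version": self.schema_version, "step": self.step, "values": self.values},
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Genome":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            values={k: float(v) for k, v in d["values"].items()},
            schema_version=d.get("schema_version", 1),
            step=float(d.get("step", 1.0)),
        )


@dataclass
class EvolutionConfig:
    """GA settings.  Desk defaults (16 x 20) scale down the order-100
    populations and generations of a full farm run."""

    population: int = 16
    generations: int = 20
    mutation_prob: float = 1.0
    mutation_sigma: float = 0.1
    step_tau: float = 0.3
    step_min: float = 0.001
    """Self-adaptive mutation: every gene receives Gaussian noise whose scale
    is the base sigma times the genome's step multiplier; the multiplier is
    log-normally perturbed (sd ``step_tau``) at reproduction and inherited
    through selection, so the search radius anneals itself."""
    crossover_prob: float = 0.9
    crossover_kind: str = "centroid"
    """'centroid' recombines each child from the mean of the tournament-
    selected parent pool (intermediate multi-parent recombination, which
    averages away mutation noise); 'blend' draws each gene uniformly
    between two parents; 'uniform' copies each gene from one of them."""
    recombination_parents: int = 6
    tournament_size: int = 3
    elitism: int = 1
    trials_per_individual: int = 1
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not (0 <= self.elitism < self.population):
            raise ValueError("elitism must be < population")


@dataclass
class EvolutionHistory:
    """Per-generation, per-individual fitness records plus best genomes."""

    records: list[dict] = field(default_factory=list)
    best_genomes: list[Genome] = field(default_factory=list)

    def fitness_matrix(self, population: int) -> np.ndarray:
        gens = 1 + max(r["generation"] for r in self.records)
        m = np.full((gens, population), np.nan)
        for r in self.records:
            m[r["generation"], r["individual"]] = r["fitness"]
        return m

    def best_per_generation(self) -> np.ndarray:
        gens = sorted({r["generation"] for r in self.records})
        return np.array([min(r["fitness"] for r in self.records if r["generation"] == g) for g in gens])

    def best_so_far(self) -> np.ndarray:
        return np.minimum.accumulate(self.best_per_generation())


def _trial_seed(master: int, generation: int, index: int, trial: int = 0) -> int:
    ss = np.random.SeedSequence([int(master), int(generation), int(index), int(trial)])
    return int(ss.generate_state(1)[0] % (2**31))


def build_controller(
    genome: Genome,
    scenario: Scenario,
    network_config: NetworkConfig | None = None,
) -> NeuralController:
    """Wire a neural controller for this scenario from a genome.

    The sensor array and network wiring derive from the scenario seed (the
    arena, not the genome, fixes them) so all genomes compete on identical
    wiring.
    """
    cfg = network_config or NetworkConfig()
    array = generate_sensor_array(n_sensors=cfg.n_sensors, seed=scenario.seed)
    net = build_network(genome.network_params(), cfg, seed=scenario.seed)
    from .olfaction import Background

    return NeuralController(
        network=net,
        sensor_array=array,
        odorants=scenario.odorants,
        background=Background(),
        pools=genome.motor_pools(),
        substeps=scenario.neural_steps_per_cfd_step,
    )


def fitness(
    genome: Genome,
    scenario: Scenario,
    seed: int,
    network_config: NetworkConfig | None = None,
    trials: int = 1,
) -> float:
    """Time-to-source fitness (seconds; lower is better).

    Runs the closed loop; unreached trials score ``T_max + final distance /
    world diagonal``; aborted trials score ``T_max + 1``.  Averaged over
    ``trials`` with distinct derived seeds.  The deterministic plume warm-up
    is computed once per scenario and shared across trials.
    """
    grid0 = _warm_grid_cached(scenario)
    scores = []
    for k in range(trials):
        trial_seed = int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2**31))
        try:
            controller = build_controller(genome, scenario, network_config)
            result = run_trial(scenario, controller, seed=trial_seed, initial_grid=grid0)
        except TrialAbort:
            scores.append(scenario.max_duration + 1.0)
            continue
        if result.reached:
            scores.append(result.time_to_source)
        else:
            scores.append(scenario.max_duration + result.final_distance / scenario.world_diagonal)
    return float(np.mean(scores))


_WARM_GRID_CACHE: dict[str, object] = {}


def _warm_grid_cached(scenario: Scenario):
    from .io import scenario_to_dict

    key = json.dumps(scenario_to_dict(scenario), sort_keys=True)
    grid = _WARM_GRID_CACHE.get(key)
    if grid is None:
        grid = warmed_grid(scenario)
        _WARM_GRID_CACHE.clear()  # hold at most one scenario's spin-up
        _WARM_GRID_CACHE[key] = grid
    return grid


def _tournament(fitnesses: np.ndarray, size: int, rng: np.random.Generator) -> int:
    k = min(max(1, size), len(fitnesses))
    contestants = rng.choice(len(fitnesses), size=k, replace=False)
    return int(contestants[np.argmin(fitnesses[contestants])])


def _mutate(
    values: dict[str, float],
    step: float,
    config: EvolutionConfig,
    rng: np.random.Generator,
    sigma_scale: float,
) -> tuple[dict[str, float], float]:
    step = float(np.clip(step * np.exp(config.step_tau * rng.normal()), config.step_min, 1.0))
    sigma = config.mutation_sigma * step * sigma_scale
    out = dict(values)
    for s in GENOME_SCHEMA:
        if rng.random() < config.mutation_prob:
            out[s.name] = float(
                np.clip(out[s.name] + rng.normal(0.0, sigma * (s.hi - s.lo)), s.lo, s.hi)
            )
    return out, step


def next_generation(
    population: list[Genome],
    fitnesses,
    config: EvolutionConfig,
    rng: np.random.Generator,
    sigma_scale: float = 1.0,
) -> list[Genome]:
    """Elitism + tournament selection + uniform crossover + clipped Gaussian
    mutation; output size equals input size; deterministic under ``rng``."""
    f = np.asarray(fitnesses, dtype=float)
    if len(population) != f.shape[0]:
        raise ValueError("population and fitness lengths differ")
    order = np.argsort(f, kind="stable")
    new_pop: list[Genome] = [
        Genome(dict(population[i].values), step=population[i].step) for i in order[: config.elitism]
    ]
    while len(new_pop) < len(population):
        if config.crossover_kind == "centroid" and rng.random() < config.crossover_prob:
            # intermediate multi-parent recombination with mirrored mutation:
            # the +z / -z twins bracket the centroid, so one of them points
            # downhill and selection keeps run-to-run progress steady
            idx = [
                _tournament(f, config.tournament_size, rng)
                for _ in range(max(2, config.recombination_parents))
            ]
            parents = [population[i] for i in idx]
            centroid = {
                s.name: float(np.mean([p.values[s.name] for p in parents])) for s in GENOME_SCHEMA
            }
            step = float(np.exp(np.mean([np.log(p.step) for p in parents])))
            step = float(np.clip(step * np.exp(config.step_tau * rng.normal()), config.step_min, 1.0))
            sigma = config.mutation_sigma * step * sigma_scale
            noise = {
                s.name: (
                    rng.normal(0.0, sigma * (s.hi - s.lo)) if rng.random() < config.mutation_prob else 0.0
                )
                for s in GENOME_SCHEMA
            }
            for sign in (1.0, -1.0):
                if len(new_pop) >= len(population):
                    break
                vals = {
                    s.name: float(np.clip(centroid[s.name] + sign * noise[s.name], s.lo, s.hi))
                    for s in GENOME_SCHEMA
                }
                new_pop.append(Genome(vals, step=step))
            continue
        p1 = population[_tournament(f, config.tournament_size, rng)]
        p2 = population[_tournament(f, config.tournament_size, rng)]
        step = float(np.sqrt(p1.step * p2.step))
        if rng.random() < config.crossover_prob:
            child = {}
            if config.crossover_kind == "blend":
                for s in GENOME_SCHEMA:
                    u = rng.random()
                    child[s.name] = u * p1.values[s.name] + (1.0 - u) * p2.values[s.name]
            else:
                for s in GENOME_SCHEMA:
                    child[s.name] = p1.values[s.name] if rng.random() < 0.5 else p2.values[s.name]
        else:
            child = dict(p1.values)
            step = p1.step
        child, step = _mutate(child, step, config, rng, sigma_scale)
        new_pop.append(Genome(child, step=step))
    return new_pop


def run_evolution(
    config: EvolutionConfig,
    scenario: Scenario,
    network_config: NetworkConfig | None = None,
    fitness_fn=None,
    out_dir: str | Path | None = None,
    resume: bool = False,
    progress: bool = False,
    n_workers: int = 1,
) -> EvolutionHistory:
    """Evolve for ``config.generations``; fully reproducible from the master
    seed and resumable from the last completed generation's checkpoint.

    ``fitness_fn(genome, seed) -> float`` may replace the closed-loop
    evaluation (e.g. an analytic landscape for solver checks).  Individuals
    within a generation are evaluated independently with seeds derived from
    (master seed, generation, index), so evaluation order cannot affect the
    result — and ``n_workers > 1`` evaluates them in parallel processes
    with identical results.
    """
    if fitness_fn is None:
        def fitness_fn(genome, seed):  # noqa: ANN001
            return fitness(genome, scenario, seed, network_config, config.trials_per_individual)

    out_path = Path(out_dir) if out_dir is not None else None
    history = EvolutionHistory()
    start_gen = 0
    init_rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 9000]))
    population = [Genome.random(init_rng) for _ in range(config.population)]

    def _load_genome(entry: dict) -> Genome:
        return Genome(
            values={k: float(v) for k, v in entry["values"].items()},
            step=float(entry.get("step", 1.0)),
        )  # noqa: E501 - checkpoint entries carry {values, step}

    ckpt_file = out_path / "checkpoint.json" if out_path else None
    if resume and ckpt_file is not None and ckpt_file.exists():
        ck = json.loads(ckpt_file.read_text())
        start_gen = ck["next_generation"]
        population = [_load_genome(e) for e in ck["population"]]
        history.records = ck["records"]
        history.best_genomes = [_load_genome(e) for e in ck["best_genomes"]]

    for gen in range(start_gen, config.generations):
        seeds = [_trial_seed(config.master_seed, gen, idx) for idx in range(config.population)]
        if n_workers > 1:
            from joblib import Parallel, delayed

            fits = np.array(
                Parallel(n_jobs=n_workers)(
                    delayed(fitness_fn)(g, s) for g, s in zip(population, seeds)
                )
            )
        else:
            fits = np.array([fitness_fn(g, s) for g, s in zip(population, seeds)])
        for idx in range(config.population):
            history.records.append(
                {"generation": gen, "individual": idx, "fitness": float(fits[idx]), "seed": seeds[idx]}
            )
        best_idx = int(np.argmin(fits))
        history.best_genomes.append(Genome(dict(population[best_idx].values)))
        if progress:
            print(f"generation {gen}: best {fits[best_idx]:.3f} median {np.median(fits):.3f}")
        if out_path is not None:
            out_path.mkdir(parents=True, exist_ok=True)
            history.best_genomes[-1].to_json(out_path / f"best_gen{gen:04d}.json")
        repro_rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 1000 + gen]))
        population = next_generation(population, fits, config, repro_rng)
        if out_path is not None:
            ckpt_file.write_text(
                json.dumps(
                    {
                        "next_generation": gen + 1,
                        "population": [{"values": g.values, "step": g.step} for g in population],
                        "records": history.records,
                        "best_genomes": [
                            {"values": g.values, "step": g.step} for g in history.best_genomes
                        ],
                    }
                )
            )
    if out_path is not None:
        import pandas as pd

        pd.DataFrame(history.records).to_csv(out_path / "fitness_history.csv", index=False)
    return history
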