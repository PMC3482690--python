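# plumebrain

A closed-loop olfactorimotor simulation platform: an interactive
two-dimensional plume world (stable-fluids CFD with multi-channel odorant
dye), a differential-drive robot whose motion both samples and perturbs
the flow, a motif-based olfactory sensor array, a five-stage neural
circuit with branch-thresholded dendrites, short-term synaptic depression
and homeostatic excitability, a size-principle motor-pool mapping, and a
genetic-algorithm harness that evolves the circuit's parameters against
time-to-source fitness.

It is aimed at people studying odor source localization — how plume
physics, sensor chemistry, and neural sensorimotor circuitry interact
when the agent's own movement disturbs the signal it is chasing — and at
anyone who needs a reproducible, scriptable chemotaxis testbed.

## The models in brief

**Plume world.**  A grid of cells (default 140x140, 30 ms steps) carries a
velocity field and one dye field per odorant.  Each step: add forces
(fans, the robot's wake), implicit diffusion, pressure projection,
semi-Lagrangian self-advection, projection again; dye channels receive
source injections, diffuse, advect, and evaporate.  Every sub-step is
unconditionally stable.  The robot couples back into the flow through
equal-and-opposite forces at the cells under its leading edge.

**Sensors.**  Odorants are vectors of degrees d over 10 abstract motifs;
sensors bind motifs with half-activation concentrations K.  A
single-motif sensor responds as A = C·d/(C·d + K), reaching A = 0.5 at
C50 = K/d; mixtures combine receptor drives linearly, S = Σ m/K,
A = S/(1+S).  First-order kinetics dA/dt = r_f(Ā−A) − r_β·A are available;
instantaneous activation is the default.

**Circuit.**  1,024 sensors → 256 mitral relays (clusters of 4) →
feedforward interneurons and a delayed mitral copy → 4,096 pyramidal
neurons, each with 8 independent thresholded branches receiving 16
excitatory and 4 inhibitory inputs (655,360 synapses) → 16 motor units
(256 random cortical afferents each).  One stage per timestep: a step
stimulus reaches the motor layer on the fifth timestep.  All five synapse
classes carry box-car PSPs and first-order depression with recovery;
branch and soma thresholds self-adjust toward target firing rates.

**Motor mapping.**  Motor units form four pools (left/right x
forward/backward) with forces 1, 2, 4, 8; each tread's net current is the
forward minus backward pool sum, a signed 8-bit value — the size
principle, with backward pools encoding negative currents.

**Evolution.**  A 40-parameter bounded genome (synaptic weights, PSP
durations, depression and recovery rates per class, homeostatic targets,
integration and motor gains) is tuned by tournament selection, multi-parent
centroid recombination with mirrored mutation, a self-adaptive mutation
step, and elitism, against the time for the robot to reach a defined
proximity of the target plume source (unreached trials score the cap plus
normalized final distance).

## Worked example

Generate the desk-scale arena (a 0.70 m box, one odorant plume advected by
a fan across the robot's start position), lengthen the trial, and run the
built-in five-state exploratory behavior (surge on rising concentration,
cast on falling, reverse on collision):

```python
from dataclasses import replace
from plumebrain.fixtures import generate_fixture
from plumebrain.io import save_scenario

sc = generate_fixture("desk-evolution", seed=0)
save_scenario(replace(sc, max_duration=20.0), "desk.yaml")
```

```sh
$ plumebrain simulate --scenario desk.yaml --controller behavior --seed 3 --out demo
reached source: time_to_source=8.82s final_distance=0.090m collisions=0

$ plumebrain simulate --scenario desk.yaml --controller zero --seed 3 --out demo0
did not reach source: time_to_source=20.00s final_distance=0.329m collisions=0
```

The behavior-driven robot surges up the concentration gradient and enters
the 0.09 m proximity radius of the source after 8.82 s; the motionless
baseline times out at the 20 s cap, 0.329 m away.  `demo/` holds the
trajectory log (`t, x, y, heading, I_L, I_R, proximity`, one row per 30 ms
step), the concentration trace (raw and normalized to the source maximum,
one row per 1/30 s), a trial summary, and a manifest with the config hash
and seed that reproduce the run bit-exactly.

A neural controller is a drop-in replacement: build it from a genome with
`--controller neural --genome best.json`, or evolve one:

```sh
plumebrain evolve --scale desk --seed 1 --out evorun
```

which logs per-generation fitness (`evorun/fitness_history.csv`), the best
genome per generation, and a resumable checkpoint.  `plumebrain serve`
exposes any controller on the ASCII SENSE/MOTOR socket protocol
(`SENSE c1 c2 c3` in, `MOTOR l r` back, a few tens of bytes per step), so
a brain can run as a separate process — or a different program entirely.

## Layout

| Module | Contents |
| --- | --- |
| `plumebrain.fluid` | stable-fluids solver, wind/odor sources, obstacles, sampling, robot wake forces |
| `plumebrain.world` | robot kinematics, proximity, scenario, trial loop, beta-cycle arithmetic |
| `plumebrain.olfaction` | odorants, sensors, mixtures, kinetics, array generation, background |
| `plumebrain.brain` | layered circuit, synapse classes, depression, homeostasis, latency probe |
| `plumebrain.control` | motor pools, five-state behavior, neural controller |
| `plumebrain.evolution` | genome schema, fitness, GA operators, evolution runner |
| `plumebrain.protocol` | SENSE/MOTOR codec, TCP brain server and world-side client |
| `plumebrain.fixtures` / `io` / `cli` | scenario presets, YAML/CSV/JSON round-trips, manifests, `plumebrain` CLI |

See `docs/methods.md` for the full model description, parameter tables,
numerical choices, and known limitations.
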