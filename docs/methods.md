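# Methods

`plumebrain` simulates a closed olfactorimotor loop: a two-dimensional
interactive plume world, a differential-drive robot whose movement both
samples and perturbs the flow, a motif-based chemistry layer turning dye
concentrations into sensor activations, a layered neural circuit turning
those activations into motor-unit firing, a size-principle motor mapping
turning firing into tread currents, and a genetic-algorithm harness that
tunes the circuit's parameters against time-to-source fitness.  This note
records the models, the parameters that matter, the numerical choices, and
the limits of what the synthetic experiments show.

## Flow and plume model (`fluid`)

The solver follows the interactive stable-fluids pipeline: per 30 ms step
the velocity field receives body forces (fans, vents, and the robot's
wake), diffuses implicitly, is projected to be discretely divergence-free,
self-advects semi-Lagrangianly, and is projected again; each odorant dye
channel receives source injections, diffuses implicitly, advects along the
flow, and decays first-order (evaporation, `exp(-rate*dt)`).  Every
sub-step is unconditionally stable, so the solver tolerates time steps far
beyond the default without blowing up; accuracy, not stability, is what
degrades.

Numerical choices worth knowing:

* **Operator pairing.** Divergence is a backward difference over cell
  faces and the pressure gradient the matching forward difference, so
  their composition is the compact 5-point Neumann Laplacian.  The
  projection residual therefore *is* the post-projection divergence, and
  driving the solve down drives the divergence down with it — to machine
  precision with an exact solve, or contracting by roughly a third per
  sweep of the red-black SOR solver on a 16x16 grid (the over-relaxation
  factor is set from the grid size).  `solver_iters` (default 20) is the
  interactivity/accuracy dial.
* **Pressure solvers.** `pressure_solver="sor"` (default) is the iterative
  path; `"direct"` solves the Poisson system exactly — spectrally via
  DCT-II on obstacle-free boxes (the transform diagonalizes the Neumann
  Laplacian), or through a cached sparse LU factorization with one pinned
  cell when internal walls break the separable structure.
* **Implicit diffusion** systems `(I - aL)x = b` are solved exactly (DCT
  or cached sparse LU), not iteratively.  The Neumann Laplacian has zero
  column sums, so diffusion conserves dye mass to machine precision — an
  invariant the test suite checks at 1e-9.
* **Advective mass conservation.**  Semi-Lagrangian advection does not
  conserve mass under nonzero flow; after each dye advection the field is
  renormalized to its pre-advection total (`conserve_dye_mass`, on by
  default).  With evaporation off, total dye then equals exactly the
  injected source mass under arbitrary wind schedules.
* **Walls.**  The outer box and obstacle rectangles close the faces they
  touch: face velocities are held at zero there, the diffusion and
  pressure operators exclude closed faces (zero-flux), and dye inside
  solids is zeroed.  Collisions of backtraced characteristics with walls
  are handled by clamping.
* **Units.**  Dye concentration is an arbitrary unit (logs offer
  per-channel normalization by the maximum seen at the source cells);
  velocities are m/s; the default grid is 140x140 cells at 15 mm/cell.

The robot's wake is injected as equal-and-opposite forces: each CFD cell
under the chassis' leading edge (the front edge of the footprint,
supersampled at one sample per cell width and deduplicated) receives minus
its current velocity vector, scaled by a configurable effect magnitude.
Whether the robot should also displace dye directly is left out: only
momentum is injected.

## Robot and trial loop (`world`)

The agent is a 0.12 m x 0.10 m rectangle (the footprint of a small tracked
robot).  The model is kinematic, not dynamic: signed 8-bit tread currents
set targets `v* = k_m (I_L + I_R)/2` and `w* = k_m (I_R - I_L)/W`
(`k_m` = 0.004 m/s per current unit, track separation `W` = 0.10 m, both
configurable, chosen so a full +/-15 command gives ~0.06 m/s); speeds relax
toward the targets with a 0.1 s motor time constant and decay by the
friction factor `(1 - mu dt)`; the pose integrates with forward Euler.
Mass and inertia are not modeled — the friction decrement and motor time
constant stand in for them.

Proximity is the minimum distance from the footprint to any wall or
obstacle (shapely handles the obstacle geometry; the wall case reduces to
corner margins).  Collisions clamp the pose to its pre-step position, zero
the linear speed (a differential drive cannot slide along a wall, so the
full speed — the component into the wall plus nothing else meaningful —
is removed), allow the turn to proceed, and report zero proximity on the
following step so a reversing behavior can trigger.

One trial couples everything at the CFD cadence: sample the K dye
concentrations at the sensor (front-center of the chassis, bilinear
interpolation), hand them to the controller, which advances four neural
timesteps — one beta cycle per 30 ms CFD update, making a neural timestep
7.5 ms, in the 5-10 ms EPSP range — and returns tread currents; step the
robot; inject its wake forces; step the fluid.  The trial ends when the
robot center first enters the proximity radius of the target source or at
the time cap.  Everything is bit-reproducible from (scenario, controller,
seed), and the socket coupling (below) produces the same trials as the
in-process one.

A scenario's plume spin-up (`warmup_steps` CFD steps before the robot
moves) is deterministic, so `warmed_grid` computes it once and trials copy
the result.

## Protocol (`protocol`)

The world and the brain exchange ASCII lines over TCP: `SENSE c1 c2 c3\n`
(6-decimal floats, one per odorant channel, <= 40 bytes) one way and
`MOTOR l r\n` (signed 8-bit net tread currents) back, one exchange per CFD
step.  A `SEED n` line resets the served controller.  The brain side is
served (`plumebrain serve`); the world side connects as a client.  The
same controller object can instead be passed in-process; the couplings are
interchangeable.

## Odorant and sensor chemistry (`olfaction`)

Odorants are abstract vectors of degrees (0 to 1) over 10 molecular
motifs; sensors bind motifs, not odorants.  Sensor *i* has, for each motif
it responds to, a half-activation concentration `K[i,a]` (affinity is the
inverse).  Odorant concentration times motif degree gives motif
concentration; motif concentrations add across plume odorants and a
background (a set of odorants constant in space and time up to clamped
zero-mean Gaussian noise, applied at the sensor rather than transported as
dye).

Response forms:

* one shared motif: `A = C d / (C d + K)` — exactly 0.5 at `C = K/d`;
* the printed single-odorant multi-motif form `A = C / (C + sum K/d)` is
  provided verbatim (`steady_state_activation`), with a caveat: as printed
  it makes a sensor *less* sensitive the more shared motifs an odorant
  carries, which sits oddly with receptors that "act jointly".  It is kept
  for single-odorant evaluation and tests, not silently corrected.
* mixtures (`mixture_activation`, what the closed loop uses): receptor
  drives combine linearly, `S = sum_a m_a / K[a]`, and the sensor
  saturates as `A = S/(1+S)`.  This is the unique occupancy form that
  reduces to the single-motif law and is monotone in every motif.

Kinetic mode integrates `dA/dt = r_f (A_eq - A) - r_b A` by explicit
Euler (sub-stepping with a warning if `dt (r_f + r_b) > 1`); its fixed
point is `r_f A_eq / (r_f + r_b)`.  The default is instantaneous
steady-state activation — the regime where sensor kinetics are fast
against plume fluctuations.

Arrays of 1,024 (or 256) sensors are generated by assigning each sensor 3
distinct motifs uniformly at random with K drawn log-uniformly from
[0.05, 5.0] normalized concentration units, deterministic under a seed.

## Neural circuit (`brain`)

Units are rate/activation units per timestep — additive PSPs, thresholded
branches, stage-based propagation; no membrane-potential integration.
Stages: sensors -> 256 mitral relays (each the mean of a disjoint cluster
of 4 sensors, graded) -> {binary feedforward interneurons; a one-step
delayed mitral copy} -> 4,096 pyramidal neurons x 8 dendritic branches
(16 excitatory + 4 inhibitory synapses per branch; 160 afferents and so
655,360 cortical synapses at full scale) -> 16 binary motor units pooling
256 random cortical neurons each.  One stage per timestep makes the
sensor-to-motor latency exactly five timesteps; the delayed mitral copy is
what lets direct excitation and disynaptic feedforward inhibition reach a
branch in the same stage (a test-only flag removes that stage and the
latency drops to four, confirming the accounting).

Branches integrate in one of three modes: independent thresholded units
(ties activate; the soma fires when the count of firing branches reaches a
threshold number, default 2, evolvable), linear (branch sums forwarded
unthresholded), or sigmoidal (logistic with evolvable gain).  Thresholded
is the default and the mode used in the closed loop.

Five synapse classes (sensor->mitral, mitral->interneuron, mitral->cortex,
interneuron->cortex — the one inhibitory class — and cortex->motor) each
carry an additive weight, an optional log-normal-free weight spread, a PSP
duration D (a box-car: one activation contributes for D timesteps), and
first-order depression: at presynaptic activity `a` the effective output
is `a R` (resource read before depletion), then `R <- R(1 - U a)`, and
every timestep `R <- R + r_rec (1 - R)`.  Under sustained unit activity
`R* = r_rec / (r_rec + U - U r_rec)`.  Depletion depends only on
presynaptic activity and class parameters, so all synapses of a class
sharing an axon have identical resource dynamics and R is stored per
presynaptic axon — bit-identical to per-synapse storage at a fraction of
the memory.

Cortical branch thresholds and soma thresholds adjust homeostatically: a
slow exponential moving average of activity (time constant 200 timesteps)
is compared to a target rate (branch and soma targets are genome
parameters; adjustment rate 1e-3 and the averaging constant are fixed),
and the threshold moves up under excess activity and down under silence,
clipped to [1e-4, 10].  In thresholded mode the soma threshold *is* the
branches-to-fire count, homeostatically adapting from its genome starting
value.  A freeze flag reproduces calibration-style operation; the closed
loop runs with homeostasis on.  Activity-dependent rewiring and
dendrodendritic bulb circuitry are out of scope by design.

## Motor mapping and built-in behavior (`control`)

The 16 motor units divide into four pools — left/right x forward/backward,
4 units each — with forces 1, 2, 4, 8 within a pool (the size principle:
graded units recruited incrementally).  Each tread's net current is
(forward sum − backward sum), scaled and clamped to the signed 8-bit
range; with unit gain it spans exactly [−15, 15], and every value in that
range is representable because the backward pools encode the negative
half.  Pool assignment is by index blocks and configurable.

The scripted exploratory behavior classifies the summed concentration
signal into five states with priority REVERSING (zero proximity or an
active reversing timer) > HIGH (>= 0.6) > RISING / FALLING (change over
the reading 1 s earlier beyond a 0.02 deadband) > LOW, and maps them to
commands: surge (15, 15), slow advance (4, 4), crosswind casting
(alternating +/-12 with a 0.5 s dwell), a seeded biased random walk, and
1 s of backing out.  The thresholds and command table are package choices
(the state set is the contract; surge/cast magnitudes are tuned so all
five states are reachable in the default scenarios) and every constant is
configurable.

## Evolution (`evolution`)

The genome (schema v1) is 40 named bounded parameters: per synapse class
weight, PSP duration, depression fraction U, recovery rate, and weight
spread (25), the cortical integration parameters (mode, branches-to-fire,
gain, initial thresholds, homeostatic targets, mitral gain, interneuron
and motor thresholds — 10), and the motor mapping gains (overall plus four
per-pool — 5).  Integer-valued genes (PSP durations, branches-to-fire,
mode) are carried as floats and rounded at network build.  The schema is
versioned so stored genomes survive revisions.

Fitness is behavioral: build the controller from the genome (sensor array
and network wiring derive from the *scenario* seed, so all genomes compete
on identical wiring), run the closed loop, and score time-to-source in
seconds; unreached trials score the cap plus the final distance normalized
by the world diagonal (keeping a selection gradient when nothing reaches),
aborted trials the cap plus one.  Per-individual seeds derive from
(master seed, generation, index), so evaluation order cannot affect
results and generations parallelize trivially; each generation's
reproduction uses its own derived stream, making checkpointed runs resume
bit-identically.

Operators: tournament selection (size 3), intermediate multi-parent
recombination — each child pair is the centroid of six tournament-selected
parents plus mirrored Gaussian noise (+z and −z twins) — with a log-normal
self-adaptive step multiplier per genome (sd 0.3, floor 1e-3) scaling a
base sigma of 0.1 of each gene's range, clipped to bounds, and elitism 1.
Plain uniform and two-parent blend crossover remain available by config.
The centroid/mirrored/self-adaptive suite was adopted because a
plain uniform-crossover GA at desk scale (16 individuals) cannot converge
on even a convex landscape at a useful rate: intermediate recombination
averages away mutation noise, mirrored twins cut run-to-run variance, and
the inherited step anneals the search radius without a schedule.  On a
40-dimensional quadratic bowl the suite improves the best fitness by over
100x in 50 generations at desk scale, the regression the test suite runs.

Desk defaults are 16 individuals x 20 generations on the 70x70 arena with
a 512-neuron cortex and 256 sensors; the order-100-by-100 scale of a full
evolution remains available as configuration.

## Scenario presets and scale (`fixtures`, `harness`)

Presets: `three-plume` (three sources on distinct channels), `figure3`
(two plumes, two fans, one internal boundary), `corridor` (kinematics
test), and `desk-evolution` — a 0.70 m arena, one plume advected by a
three-cell fan (velocity increment (−0.08, −0.04) m/s per step) across the
robot's start area, 400 warm-up steps (12 s) to establish the plume,
single dye channel, exact spectral projection, a 0.09 m proximity radius,
a 5 s cap, and `k_m` = 0.006 so the crossing is feasible within the cap.
These sizes were chosen so one full desk evolution (320 trials) completes
in minutes on a single core while leaving a real selection gradient:
typical generation-0 genomes fail to reach the source and are ranked by
final distance.

Every CLI run writes a manifest (SHA-256 of the resolved configuration,
seeds, package version) sufficient to reproduce it; all emitted YAML/CSV/
JSON round-trips through the package's own readers.

## What the synthetic experiments do and do not show

The desk-scale evolution demonstrates that the full loop — plume physics,
chemistry, circuit, motor mapping, selection — is wired correctly and that
selection finds genomes measurably better than the generation-0 median
under elitism-monotone best-so-far trajectories.  It does not reproduce
overnight order-100x100 evolutions, and single desk runs rarely evolve
robust source-finding within 20 generations; claims about the *quality* of
evolved chemotaxis strategies are outside what these tests establish.
The plume world is two-dimensional, has no buoyancy or temperature
effects, and its turbulence is whatever the stable-fluids scheme (with its
substantial numerical diffusion) produces — qualitatively plume-like,
quantitatively uncalibrated.  The sensor model is motif-abstract and noise
enters only through the background term; real sensor drift, hysteresis,
and slow reversibility are not modeled.

## Known limitations

* Collision response is clamp-and-stop, not sliding contact.
* The robot perturbs momentum only; its body does not block or displace
  dye.
* Obstacle-aware advection clamps backtraces rather than reflecting them;
  dye adjacent to a wall loses a little sharpness (mass is restored by the
  conservation rescale).
* Motor units respond instantaneously; no integration across timesteps.
* The number of feedforward interneurons (256, fan-in 16 at full scale) is
  a package choice; the architecture leaves it open.
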