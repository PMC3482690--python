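"""Layered olfactorimotor neural circuit.

Activity flows sensors -> mitral -> {feedforward interneurons, delayed
mitral copy} -> cortical pyramids -> motor units, one stage per simulation
timestep, so a step change at the sensors first reaches the motor layer on
the fifth timestep (inclusive).  The delayed mitral copy makes direct
excitation and disynaptic feedforward inhibition arrive at cortex in the
same stage.

Layer models
------------
* 1,024 sensors (graded, computed upstream by the olfaction module) feed 256
  mitral relay units in disjoint clusters of four; a mitral unit's activation
  is the mean of its cluster, scaled.
* Feedforward interneurons (256, fan-in 16 from mitral) are binary
  thresholded units whose only targets are cortical dendrites (the one
  inhibitory synapse class).
* The cortex is an array of 4,096 pyramidal neurons, each with 8 identical
  dendritic branches receiving 16 excitatory (mitral) and 4 inhibitory
  (interneuron) synapses — 160 afferents per neuron, 655,360 synapses at
  full scale.  Branches integrate in one of three modes: independent
  thresholded units (the soma fires when a threshold number of branches
  fire), linear (unthresholded branch sums forwarded to the soma), or
  sigmoidal.
* 16 binary motor units each pool 256 random cortical neurons.

Synapses come in exactly five classes (sensor->mitral, mitral->interneuron,
mitral->cortex, interneuron->cortex, cortex->motor), each an additive weight
with an evolvable PSP duration (a box-car of D timesteps) plus first-order
depression: on presynaptic activity a the resource depletes R <- R(1 - U a)
and every timestep recovers R <- R + r_rec (1 - R).  All synapses of one
class sharing a presynaptic axon have identical resource dynamics, so R is
stored per presynaptic axon.

Cortical branch and soma thresholds adjust homeostatically toward target
average firing rates (slow exponential activity average, fixed adjustment
rate and averaging time constant; the targets themselves are genome
parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SynapseClassParams",
    "SYNAPSE_CLASSES",
    "NetworkConfig",
    "NetworkParams",
    "Network",
    "build_network",
    "branch_activation",
    "apply_depression",
    "update_homeostasis",
    "measure_latency",
    "NO_PROPAGATION",
]

SYNAPSE_CLASSES = (
    "sensor_mitral",
    "mitral_inter",
    "mitral_cortex",
    "inter_cortex",
    "cortex_motor",
)

BRANCH_MODES = ("thresholded", "linear", "sigmoidal")

NO_PROPAGATION = -1


@dataclass(frozen=True)
class SynapseClassParams:
    """One synapse class: additive weight, PSP duration, depression."""

    weight: float
    psp_duration: int = 1
    dep_u: float = 0.0
    dep_recovery: float = 0.1
    weight_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.psp_duration < 1:
            raise ValueError("psp_duration must be >= 1 timestep")
        if not (0.0 <= self.dep_u <= 1.0):
            raise ValueError("depression fraction U must be in [0, 1]")
        if not (0.0 <= self.dep_recovery <= 1.0):
            raise ValueError("recovery rate must be in [0, 1] per timestep")


def default_synapse_classes() -> dict[str, SynapseClassParams]:
    return {
        "sensor_mitral": SynapseClassParams(weight=1.0),
        "mitral_inter": SynapseClassParams(weight=1.0),
        "mitral_cortex": SynapseClassParams(weight=1.0),
        "inter_cortex": SynapseClassParams(weight=-1.0),
        "cortex_motor": SynapseClassParams(weight=1.0),
    }


@dataclass(frozen=True)
class NetworkConfig:
    """Structural counts and wiring flags (not evolved)."""

    n_sensors: int = 1024
    sensors_per_mitral: int = 4
    n_inter: int = 256
    inter_fanin: int = 16
    n_cortex: int = 4096
    branches: int = 8
    exc_per_branch: int = 16
    inh_per_branch: int = 4
    n_motor: int = 16
    motor_fanin: int = 256
    align_inhibition: bool = True
    """Insert the one-step mitral delay so direct excitation and disynaptic
    inhibition reach cortex together (5-stage pipeline).  Disabling removes
    that stage (4-step latency); used to verify stage accounting."""

    def __post_init__(self) -> None:
        if self.n_sensors % self.sensors_per_mitral != 0:
            raise ValueError("sensor count must be divisible by cluster size")

    @property
    def n_mitral(self) -> int:
        return self.n_sensors // self.sensors_per_mitral

    @property
    def n_cortex_synapses(self) -> int:
        return self.n_cortex * self.branches * (self.exc_per_branch + self.inh_per_branch)

    @property
    def inputs_per_cortex_neuron(self) -> int:
        return self.branches * (self.exc_per_branch + self.inh_per_branch)


DESK_CONFIG = NetworkConfig(n_sensors=256, n_inter=64, inter_fanin=8, n_cortex=512, motor_fanin=64)


@dataclass(frozen=True)
class NetworkParams:
    """Tunable (genome-visible) parameters of the circuit."""

    classes: dict[str, SynapseClassParams] = field(default_factory=default_synapse_classes)
    branch_mode: str = "thresholded"
    branches_to_fire: int = 2
    branch_gain: float = 4.0
    branch_threshold0: float = 0.5
    soma_threshold0: float = 0.5
    inter_threshold: float = 0.5
    motor_threshold: float = 0.5
    mitral_gain: float = 1.0
    branch_target: float = 0.05
    soma_target: float = 0.05
    homeostasis_eta: float = 1e-3
    homeostasis_tau: float = 200.0
    theta_min: float = 1e-4
    theta_max: float = 10.0
    homeostasis_frozen: bool = False

    def __post_init__(self) -> None:
        if set(self.classes) != set(SYNAPSE_CLASSES):
            raise ValueError(f"classes must be exactly {SYNAPSE_CLASSES}")
        if self.classes["inter_cortex"].weight >= 0.0:
            raise ValueError("inter_cortex is the inhibitory class: weight < 0")
        for name in SYNAPSE_CLASSES:
            if name != "inter_cortex" and self.classes[name].weight < 0.0:
                raise ValueError(f"{name} weight must be >= 0")
        if self.branch_mode not in BRANCH_MODES:
            raise ValueError(f"branch_mode must be one of {BRANCH_MODES}")
        if self.branches_to_fire < 1:
            raise ValueError("branches_to_fire must be >= 1")


def branch_activation(psp_sum, mode: str, theta: float, gain: float = 4.0):
    """Branch transfer function for one weighted PSP sum.

    thresholded: 1 if sum >= theta else 0 (ties activate); linear: identity;
    sigmoidal: logistic(gain * (sum - theta)).
    """
    x = np.asarray(psp_sum, dtype=float)
    if mode == "thresholded":
        return (x >= theta).astype(float)
    if mode == "linear":
        return x
    if mode == "sigmoidal":
        return 1.0 / (1.0 + np.exp(-gain * (x - theta)))
    raise ValueError(f"unknown branch mode {mode!r}")


try:  # low-overhead CSR matvec (falls back to the operator on API change)
    from scipy.sparse import _sparsetools as _spt

    def _csr_matvec(w, x):
        y = np.zeros(w.shape[0])
        _spt.csr_matvec(w.shape[0], w.shape[1], w.indptr, w.indices, w.data, x, y)
        return y
except ImportError:  # pragma: no cover
    def _csr_matvec(w, x):
        return w @ x


def apply_depression(
    resource: np.ndarray,
    activity: np.ndarray,
    dep_u: float,
    dep_recovery: float,
) -> tuple[np.ndarray, np.ndarray]:
    """First-order synaptic depression for one timestep.

    Returns ``(effective, resource')``: the effective presynaptic output
    ``activity * resource`` (resource read at activation time), after which
    the resource depletes by ``R <- R (1 - U a)`` and recovers first-order
    ``R <- R + r_rec (1 - R)``.  Under sustained unit activity the resource
    settles at ``R* = r_rec / (r_rec + U - U r_rec)``.
    """
    a = np.asarray(activity, dtype=float)
    eff = a * resource
    r = resource * (1.0 - dep_u * a)
    if dep_recovery > 0.0:
        r = r + dep_recovery * (1.0 - r)
    return eff, np.clip(r, 0.0, 1.0)


def update_homeostasis(
    avg: np.ndarray,
    theta: np.ndarray,
    activity: np.ndarray,
    target: float,
    eta: float = 1e-3,
    tau: float = 200.0,
    theta_min: float = 1e-4,
    theta_max: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One step of local homeostatic excitability adjustment.

    The activity average is a slow exponential moving average
    (``avg += (a - avg)/tau``); the threshold moves up when the unit runs
    above its target rate and down when below, clipped to bounds.  With
    ``eta = 0`` thresholds are frozen regardless of activity.
    """
    avg = avg + (np.asarray(activity, dtype=float) - avg) * (1.0 / tau)
    theta = np.clip(theta + eta * (avg - target), theta_min, theta_max)
    return avg, theta


class _ClassState:
    """Per-class synaptic state: PSP box-car trace + depression resource.

    The trace holds, per presynaptic axon, the sum of that axon's effective
    outputs (activation x resource at activation time) over the last D
    timesteps — i.e. the box-car PSP a postsynaptic reader sees one step
    later.
    """

    def __init__(self, n_pre: int, params: SynapseClassParams):
        self.params = params
        self.ring = np.zeros((params.psp_duration, n_pre), dtype=float)
        self.trace = np.zeros(n_pre, dtype=float)
        self.resource = np.ones(n_pre, dtype=float)
        self._ptr = 0

    def push(self, activation: np.ndarray) -> None:
        p = self.params
        if p.dep_u > 0.0 or p.dep_recovery > 0.0:
            eff, self.resource = apply_depression(self.resource, activation, p.dep_u, p.dep_recovery)
        else:
            eff = activation * self.resource
        self.trace += eff - self.ring[self._ptr]
        self.ring[self._ptr] = eff
        self._ptr = (self._ptr + 1) % self.ring.shape[0]

    def reset(self) -> None:
        self.ring[:] = 0.0
        self.trace[:] = 0.0
        self.resource[:] = 1.0
        self._ptr = 0


class Network:
    """Built circuit: wiring tables, synaptic state, pipeline buffers.

    Use :func:`build_network`; step with :meth:`step`, which advances one
    simulation timestep and returns the 16 binary motor activities.
    """

    def __init__(self, config: NetworkConfig, params: NetworkParams, seed: int | None):
        self.config = config
        self.params = params
        self.seed = seed
        rng = np.random.default_rng(seed)
        c, p = config, params

        self.exc_idx = rng.integers(0, c.n_mitral, size=(c.n_cortex, c.branches, c.exc_per_branch))
        self.inh_idx = rng.integers(0, c.n_inter, size=(c.n_cortex, c.branches, c.inh_per_branch))
        self.inter_idx = rng.integers(0, c.n_mitral, size=(c.n_inter, c.inter_fanin))
        self.motor_idx = rng.integers(0, c.n_cortex, size=(c.n_motor, c.motor_fanin))

        def _weights(shape, cls: SynapseClassParams):
            w = np.full(shape, cls.weight, dtype=float)
            if cls.weight_sd > 0.0:
                w *= 1.0 + cls.weight_sd * rng.standard_normal(shape)
                if cls.weight >= 0.0:
                    np.clip(w, 0.0, None, out=w)
                else:
                    np.clip(w, None, 0.0, out=w)
            return w

        self.w_exc = _weights(self.exc_idx.shape, p.classes["mitral_cortex"])
        self.w_inh = _weights(self.inh_idx.shape, p.classes["inter_cortex"])
        self.w_motor = _weights(self.motor_idx.shape, p.classes["cortex_motor"])

        # CSR views of the wiring for fast afferent sums (duplicate synapses
        # onto one target sum, exactly as the index tables would)
        import scipy.sparse as sp

        def _csr(idx, w, n_pre):
            n_post = idx.shape[0] * (idx.shape[1] if idx.ndim > 2 else 1)
            flat_idx = idx.reshape(n_post, -1)
            flat_w = w.reshape(n_post, -1)
            rows = np.repeat(np.arange(n_post), flat_idx.shape[1])
            return sp.csr_matrix(
                (flat_w.ravel(), (rows, flat_idx.ravel())), shape=(n_post, n_pre)
            )

        self._W_exc = _csr(self.exc_idx, self.w_exc, c.n_mitral)
        self._W_inh = _csr(self.inh_idx, self.w_inh, c.n_inter)
        self._W_motor = _csr(self.motor_idx, self.w_motor, c.n_cortex)
        w_mi = np.full(self.inter_idx.shape, p.classes["mitral_inter"].weight)
        self._W_inter = _csr(self.inter_idx[:, None, :], w_mi[:, None, :], c.n_mitral)

        # synaptic state per class, keyed by presynaptic layer size
        self.state = {
            "sensor_mitral": _ClassState(c.n_sensors, p.classes["sensor_mitral"]),
            "mitral_inter": _ClassState(c.n_mitral, p.classes["mitral_inter"]),
            "mitral_cortex": _ClassState(c.n_mitral, p.classes["mitral_cortex"]),
            "inter_cortex": _ClassState(c.n_inter, p.classes["inter_cortex"]),
            "cortex_motor": _ClassState(c.n_cortex, p.classes["cortex_motor"]),
        }

        self._mitral_delay = np.zeros(c.n_mitral, dtype=float)

        # homeostatic thresholds and activity averages (cortex only); in
        # thresholded mode the soma threshold is the branches-to-fire count
        # and adapts from that starting point
        self.branch_theta = np.full((c.n_cortex, c.branches), p.branch_threshold0, dtype=float)
        soma0 = float(p.branches_to_fire) if p.branch_mode == "thresholded" else p.soma_threshold0
        self.soma_theta = np.full(c.n_cortex, soma0, dtype=float)
        self._branch_avg = np.full((c.n_cortex, c.branches), p.branch_target, dtype=float)
        self._soma_avg = np.full(c.n_cortex, p.soma_target, dtype=float)

        self.mitral = np.zeros(c.n_mitral, dtype=float)
        self.inter = np.zeros(c.n_inter, dtype=float)
        self.cortex = np.zeros(c.n_cortex, dtype=float)
        self.motor = np.zeros(c.n_motor, dtype=float)
        self.t = 0

    # -- counts -------------------------------------------------------------
    @property
    def n_cortex_synapses(self) -> int:
        return int(self.w_exc.size + self.w_inh.size)

    def reset(self) -> None:
        for s in self.state.values():
            s.reset()
        self._mitral_delay[:] = 0.0
        self.mitral[:] = 0.0
        self.inter[:] = 0.0
        self.cortex[:] = 0.0
        self.motor[:] = 0.0
        self.t = 0

    # -- dynamics -----------------------------------------------------------
    def step(self, sensor_activations) -> np.ndarray:
        """Advance one timestep; returns the 16 binary motor activities."""
        c, p = self.config, self.params
        s_in = np.asarray(sensor_activations, dtype=float)
        if s_in.shape != (c.n_sensors,):
            raise ValueError(f"expected {c.n_sensors} sensor activations")
        if not np.all(np.isfinite(s_in)):
            raise ValueError("non-finite sensor input")

        st = self.state

        # each layer reads the previous stage's trace (activity up to t-1)
        motor_drive = _csr_matvec(self._W_motor, st["cortex_motor"].trace)
        new_motor = (motor_drive >= p.motor_threshold).astype(float)

        branch_sum = _csr_matvec(self._W_exc, st["mitral_cortex"].trace)
        branch_sum += _csr_matvec(self._W_inh, st["inter_cortex"].trace)
        branch_sum = branch_sum.reshape(c.n_cortex, c.branches)
        branch_out = branch_activation(branch_sum, p.branch_mode, self.branch_theta, p.branch_gain)
        new_cortex = (branch_out.sum(axis=1) >= self.soma_theta).astype(float)

        inter_drive = _csr_matvec(self._W_inter, st["mitral_inter"].trace)
        new_inter = (inter_drive >= p.inter_threshold).astype(float)

        sm_trace = st["sensor_mitral"].trace
        cluster_mean = sm_trace.reshape(c.n_mitral, c.sensors_per_mitral).mean(axis=1)
        new_mitral = np.clip(cluster_mean * p.classes["sensor_mitral"].weight * p.mitral_gain, 0.0, 1.0)

        # push this step's activations into the class traces
        st["sensor_mitral"].push(s_in)
        st["mitral_inter"].push(new_mitral)
        if c.align_inhibition:
            st["mitral_cortex"].push(self._mitral_delay)
            self._mitral_delay = new_mitral
        else:
            st["mitral_cortex"].push(new_mitral)
        st["inter_cortex"].push(new_inter)
        st["cortex_motor"].push(new_cortex)

        if not p.homeostasis_frozen:
            self._update_homeostasis(branch_out, new_cortex)

        self.mitral, self.inter, self.cortex, self.motor = new_mitral, new_inter, new_cortex, new_motor
        self.t += 1
        return new_motor

    def _update_homeostasis(self, branch_act: np.ndarray, soma_act: np.ndarray) -> None:
        p = self.params
        self._branch_avg, self.branch_theta = update_homeostasis(
            self._branch_avg, self.branch_theta, branch_act, p.branch_target,
            p.homeostasis_eta, p.homeostasis_tau, p.theta_min, p.theta_max,
        )
        self._soma_avg, self.soma_theta = update_homeostasis(
            self._soma_avg, self.soma_theta, soma_act, p.soma_target,
            p.homeostasis_eta, p.homeostasis_tau, p.theta_min, p.theta_max,
        )


def build_network(
    params: NetworkParams | None = None,
    config: NetworkConfig | None = None,
    seed: int | None = 0,
) -> Network:
    """Build the wired circuit; deterministic under ``seed``."""
    return Network(config or NetworkConfig(), params or NetworkParams(), seed)


def permissive_params(**overrides) -> NetworkParams:
    """Parameters with low thresholds, no depression, frozen homeostasis —
    a calibrated fixture in which any sustained input propagates."""
    classes = {
        name: SynapseClassParams(weight=(-1.0 if name == "inter_cortex" else 1.0))
        for name in SYNAPSE_CLASSES
    }
    base = NetworkParams(
        classes=classes,
        branches_to_fire=1,
        branch_threshold0=1e-3,
        soma_threshold0=1e-3,
        inter_threshold=1e-3,
        motor_threshold=1e-3,
        homeostasis_frozen=True,
    )
    return replace(base, **overrides) if overrides else base


def measure_latency(net: Network, stimulus, max_steps: int = 64) -> int:
    """Inclusive timestep count from stimulus onset to first motor activity.

    The network is reset and driven with the constant ``stimulus`` from t=0;
    returns 5 for the default 5-stage pipeline.  If no motor unit fires
    within ``max_steps`` returns :data:`NO_PROPAGATION`.
    """
    net.reset()
    for t in range(max_steps):
        motor = net.step(stimulus)
        if np.any(motor > 0.0):
            return t + 1
    return NO_PROPAGATION
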