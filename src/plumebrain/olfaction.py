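"""Motif-based odorant and sensor chemistry.

Odorants are abstract: each is a vector of "motif" degrees in [0, 1] over a
small alphabet of M molecular motifs (default 10).  Sensors bind motifs, not
odorants: sensor *i* has, for each motif alpha it responds to, a
half-activation motif concentration ``K[i, alpha]`` (its affinity is
``1 / K``).  The concentration of a motif in the air is the odorant
concentration times the odorant's degree for that motif, summed over all
odorants present (plume channels plus a spatially constant stochastic
background).

Steady-state activation follows first-order receptor occupancy:

* single shared motif:  ``A = C d / (C d + K)``  — activation is 0.5 at the
  odorant concentration ``C50 = K / d``;
* one odorant carrying several shared motifs (printed single-odorant form):
  ``A = C / (C + sum_alpha K_alpha / d_alpha)``;
* general mixtures: motif concentrations add across odorants and the sensor
  saturates as ``A = S / (1 + S)`` with ``S = sum_alpha m_alpha / K_alpha``.

A first-order kinetic mode ``dA/dt = r_f (A_eq - A) - r_b A`` is available;
the default is instantaneous (steady-state) activation, the regime in which
sensor kinetics are fast compared to plume fluctuations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Odorant",
    "Sensor",
    "SensorArray",
    "Background",
    "motif_concentrations",
    "steady_state_activation",
    "mixture_activation",
    "kinetic_update",
    "generate_sensor_array",
]

DEFAULT_N_MOTIFS = 10


@dataclass(frozen=True)
class Odorant:
    """An odorant: motif degrees in [0, 1] plus the dye channel it rides on.

    ``channel`` is the index of the CFD dye field carrying this odorant, or
    ``None`` for background odorants (not transported by the flow).
    """

    degrees: np.ndarray
    channel: int | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.degrees, dtype=float)
        if d.ndim != 1:
            raise ValueError("degrees must be a 1-D vector")
        if np.any(d < 0.0) or np.any(d > 1.0):
            raise ValueError("motif degrees must lie in [0, 1]")
        if not np.any(d > 0.0):
            raise ValueError("an odorant must exhibit at least one motif")
        object.__setattr__(self, "degrees", d)

    @property
    def n_motifs(self) -> int:
        return self.degrees.shape[0]


@dataclass
class Sensor:
    """One sensor: half-activation concentrations K per motif it binds.

    ``half_conc`` maps motif index -> K (motif concentration giving 50%
    activation in isolation).  ``rate_on`` / ``rate_off`` (1/s) are the
    kinetic activation/deactivation rates used only in kinetic mode.
    """

    half_conc: dict[int, float]
    rate_on: float = 50.0
    rate_off: float = 10.0
    activation: float = 0.0

    def __post_init__(self) -> None:
        if not self.half_conc:
            raise ValueError("a sensor needs at least one motif affinity")
        for alpha, k in self.half_conc.items():
            if k <= 0.0:
                raise ValueError(f"K for motif {alpha} must be > 0, got {k}")
        if self.rate_on < 0.0 or self.rate_off < 0.0:
            raise ValueError("kinetic rates must be >= 0")

    @property
    def motifs(self) -> list[int]:
        return sorted(self.half_conc)


@dataclass
class Background:
    """Background odor: constant in space/time up to zero-mean noise.

    Each background odorant has a mean concentration; per sample a Gaussian
    perturbation with standard deviation ``noise_sd`` is added and the result
    clamped at zero.  Applied at the sensor as extra motif concentration, not
    as a dye channel.
    """

    odorants: list[Odorant] = field(default_factory=list)
    mean_concentrations: list[float] = field(default_factory=list)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if len(self.odorants) != len(self.mean_concentrations):
            raise ValueError("one mean concentration per background odorant")
        if any(m < 0.0 for m in self.mean_concentrations):
            raise ValueError("background mean concentrations must be >= 0")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be >= 0")

    def sample(self, rng: np.random.Generator | None = None) -> list[float]:
        """Draw one clamped-Gaussian concentration per background odorant."""
        means = np.asarray(self.mean_concentrations, dtype=float)
        if self.noise_sd > 0.0:
            if rng is None:
                raise ValueError("noise_sd > 0 requires an rng")
            means = means + rng.normal(0.0, self.noise_sd, size=means.shape)
        return np.maximum(means, 0.0).tolist()


def motif_concentrations(
    odor_concentrations,
    odorants: list[Odorant],
    background: Background | None = None,
    background_sample=None,
    n_motifs: int = DEFAULT_N_MOTIFS,
) -> np.ndarray:
    """Total motif concentration vector from plume channels plus background.

    ``odor_concentrations[j]`` is the dye concentration of channel j at the
    sensor; each plume odorant contributes ``C[channel] * degrees``.
    ``background_sample`` (from :meth:`Background.sample`) supplies the
    background odorant concentrations; if omitted the background means are
    used.
    """
    conc = np.asarray(odor_concentrations, dtype=float)
    if np.any(conc < 0.0):
        raise ValueError("odor concentrations must be >= 0")
    m = np.zeros(n_motifs, dtype=float)
    for od in odorants:
        if od.channel is None or od.channel >= conc.shape[0]:
            raise ValueError(f"odorant channel {od.channel} has no concentration")
        if od.n_motifs != n_motifs:
            raise ValueError("odorant motif count mismatch")
        m += conc[od.channel] * od.degrees
    if background is not None and background.odorants:
        sample = background_sample
        if sample is None:
            sample = background.mean_concentrations
        for od, c in zip(background.odorants, sample):
            if od.n_motifs != n_motifs:
                raise ValueError("background odorant motif count mismatch")
            m += max(float(c), 0.0) * od.degrees
    return m


def steady_state_activation(sensor: Sensor, odorant: Odorant, concentration: float) -> float:
    """Steady-state activation of one sensor by one odorant in isolation.

    Implements the printed single-odorant forms: for a single shared motif
    ``A = C d / (C d + K)``; for several shared motifs
    ``A = C / (C + sum K/d)``, the sum running over motifs the odorant and
    sensor share.  No shared motif gives 0.  Note the multi-motif form as
    printed makes a sensor *less* sensitive the more shared motifs the
    odorant carries (the sum of K/d grows); mixtures should normally go
    through :func:`mixture_activation`, which combines receptor occupancies
    linearly instead.
    """
    if concentration < 0.0:
        raise ValueError("concentration must be >= 0")
    shared = [a for a in sensor.half_conc if odorant.degrees[a] > 0.0]
    if not shared:
        return 0.0
    if len(shared) == 1:
        a = shared[0]
        cd = concentration * odorant.degrees[a]
        return cd / (cd + sensor.half_conc[a])
    denom = sum(sensor.half_conc[a] / odorant.degrees[a] for a in shared)
    return concentration / (concentration + denom)


def mixture_activation(sensor: Sensor, motif_conc: np.ndarray) -> float:
    """Activation from a motif concentration vector (any number of odorants).

    Receptor drives combine linearly, S = sum_alpha m_alpha / K_alpha over
    the sensor's motifs, and the sensor saturates as A = S / (1 + S).
    Reduces exactly to the single-motif steady-state form.
    """
    s = 0.0
    for alpha, k in sensor.half_conc.items():
        m = float(motif_conc[alpha])
        if m < 0.0:
            raise ValueError("motif concentrations must be >= 0")
        s += m / k
    return s / (1.0 + s)


def kinetic_update(sensor: Sensor, target: float, dt: float) -> float:
    """One explicit-Euler step of dA/dt = r_f (target - A) - r_b A.

    The discrete fixed point is ``A* = r_f target / (r_f + r_b)``.  If the
    Euler step would be unstable (``dt (r_f + r_b) > 1``) the update is
    sub-stepped and a warning issued.  Returns (and stores) the new
    activation, clamped to [0, 1].
    """
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    total = sensor.rate_on + sensor.rate_off
    n_sub = 1
    if total > 0.0 and dt * total > 1.0:
        n_sub = int(np.ceil(dt * total))
        warnings.warn(
            f"kinetic_update: dt*(r_f+r_b)={dt * total:.3g} > 1; sub-stepping x{n_sub}",
            RuntimeWarning,
            stacklevel=2,
        )
    h = dt / n_sub
    a = sensor.activation
    for _ in range(n_sub):
        a += h * (sensor.rate_on * (target - a) - sensor.rate_off * a)
    a = min(max(a, 0.0), 1.0)
    sensor.activation = a
    return a


@dataclass
class SensorArray:
    """A seeded random array of motif sensors (default 1,024; also 256).

    Vectorized view: ``motif_idx[i]`` lists the motifs sensor i binds and
    ``half_conc_matrix[i, alpha]`` holds K (inf where unbound), so a whole
    array responds to one motif vector with a few numpy ops.
    """

    sensors: list[Sensor]
    n_motifs: int = DEFAULT_N_MOTIFS
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.sensors)
        if n == 0:
            raise ValueError("empty sensor array")
        inv_k = np.zeros((n, self.n_motifs), dtype=float)
        for i, s in enumerate(self.sensors):
            for alpha, k in s.half_conc.items():
                if alpha >= self.n_motifs:
                    raise ValueError("sensor motif index out of range")
                inv_k[i, alpha] = 1.0 / k
        self._inv_k = inv_k

    def __len__(self) -> int:
        return len(self.sensors)

    def respond(self, motif_conc: np.ndarray) -> np.ndarray:
        """Steady-state activations of every sensor for one motif vector."""
        m = np.asarray(motif_conc, dtype=float)
        s = self._inv_k @ m
        return s / (1.0 + s)

    def to_dict(self) -> dict:
        return {
            "n_motifs": self.n_motifs,
            "seed": self.seed,
            "sensors": [
                {
                    "half_conc": {str(a): k for a, k in s.half_conc.items()},
                    "rate_on": s.rate_on,
                    "rate_off": s.rate_off,
                }
                for s in self.sensors
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorArray":
        sensors = [
            Sensor(
                half_conc={int(a): float(k) for a, k in s["half_conc"].items()},
                rate_on=float(s.get("rate_on", 50.0)),
                rate_off=float(s.get("rate_off", 10.0)),
            )
            for s in d["sensors"]
        ]
        return cls(sensors=sensors, n_motifs=int(d["n_motifs"]), seed=d.get("seed"))


def generate_sensor_array(
    n_sensors: int = 1024,
    n_motifs: int = DEFAULT_N_MOTIFS,
    motifs_per_sensor: int = 3,
    k_range: tuple[float, float] = (0.05, 5.0),
    seed: int | None = None,
) -> SensorArray:
    """Draw a sensor array: each sensor binds ``motifs_per_sensor`` distinct
    motifs chosen uniformly at random, with K drawn log-uniformly from
    ``k_range``.  Deterministic under ``seed``.
    """
    if not (1 <= motifs_per_sensor <= n_motifs):
        raise ValueError("motifs_per_sensor must be in [1, n_motifs]")
    lo, hi = k_range
    if not (0.0 < lo <= hi):
        raise ValueError("k_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    sensors = []
    for _ in range(n_sensors):
        motifs = rng.choice(n_motifs, size=motifs_per_sensor, replace=False)
        ks = np.exp(rng.uniform(np.log(lo), np.log(hi), size=motifs_per_sensor))
        sensors.append(Sensor(half_conc={int(a): float(k) for a, k in zip(motifs, ks)}))
    return SensorArray(sensors=sensors, n_motifs=n_motifs, seed=seed)
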