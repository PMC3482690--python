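"""Motif chemistry: half-activation, mixtures, kinetics, array generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plumebrain.olfaction import (
    Background,
    Odorant,
    Sensor,
    generate_sensor_array,
    kinetic_update,
    mixture_activation,
    motif_concentrations,
    steady_state_activation,
)


def odorant(*degrees: float) -> Odorant:
    d = np.zeros(10)
    d[: len(degrees)] = degrees
    return Odorant(degrees=d, channel=0)


class TestSteadyState:
    def test_half_activation_at_c50(self):
        """A single-motif sensor driven at C = K/d sits exactly at 0.5."""
        sensor = Sensor(half_conc={0: 0.8})
        od = odorant(0.4)
        c50 = 0.8 / 0.4
        assert steady_state_activation(sensor, od, c50) == pytest.approx(0.5)

    def test_zero_concentration(self):
        assert steady_state_activation(Sensor(half_conc={0: 1.0}), odorant(0.5), 0.0) == 0.0

    def test_no_shared_motif(self):
        sensor = Sensor(half_conc={7: 1.0})
        assert steady_state_activation(sensor, odorant(1.0), 5.0) == 0.0

    def test_two_shared_motifs_printed_form(self):
        """Multi-motif single-odorant form: A = C / (C + sum K/d)."""
        sensor = Sensor(half_conc={0: 1.0, 1: 1.5})
        od = odorant(1.0, 0.5)  # K/d terms: 1.0 and 3.0
        assert steady_state_activation(sensor, od, 4.0) == pytest.approx(0.5)

    @given(
        k=st.floats(0.05, 5.0),
        d=st.floats(0.05, 1.0),
        c1=st.floats(0.0, 50.0),
        c2=st.floats(0.0, 50.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_and_saturating(self, k, d, c1, c2):
        sensor = Sensor(half_conc={0: k})
        od = odorant(d)
        lo, hi = sorted((c1, c2))
        a_lo = steady_state_activation(sensor, od, lo)
        a_hi = steady_state_activation(sensor, od, hi)
        assert 0.0 <= a_lo <= a_hi < 1.0


class TestMixture:
    def test_zero_mixture(self):
        assert mixture_activation(Sensor(half_conc={0: 1.0}), np.zeros(10)) == 0.0

    def test_reduces_to_half_activation(self):
        sensor = Sensor(half_conc={3: 0.7})
        m = np.zeros(10)
        m[3] = 0.7
        assert mixture_activation(sensor, m) == pytest.approx(0.5)

    def test_hand_sum(self):
        """m/K contributions 0.25 + 0.25 give S = 0.5 and A = 1/3."""
        sensor = Sensor(half_conc={0: 4.0, 1: 4.0})
        m = np.zeros(10)
        m[0] = m[1] = 1.0
        assert mixture_activation(sensor, m) == pytest.approx(1.0 / 3.0)

    @given(st.lists(st.floats(0.0, 10.0), min_size=10, max_size=10), st.integers(0, 9))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_each_motif(self, m, idx):
        sensor = Sensor(half_conc={idx: 0.5, (idx + 1) % 10: 2.0})
        m = np.array(m)
        a0 = mixture_activation(sensor, m)
        m2 = m.copy()
        m2[idx] += 1.0
        assert mixture_activation(sensor, m2) >= a0
        assert a0 < 1.0


class TestMotifConcentrations:
    def test_direct_product(self):
        m = motif_concentrations([2.0], [odorant(0.5)])
        assert m[0] == pytest.approx(1.0)
        assert np.all(m[1:] == 0.0)

    def test_zero_case(self):
        assert np.all(motif_concentrations([0.0], [odorant(1.0)]) == 0.0)

    def test_shared_motif_sums(self):
        od_a = Odorant(degrees=np.eye(10)[3] * 0.4, channel=0)
        od_b = Odorant(degrees=np.eye(10)[3] * 0.6, channel=1)
        m = motif_concentrations([1.0, 1.0], [od_a, od_b])
        assert m[3] == pytest.approx(1.0)

    def test_background_contributes_constant_offset(self):
        bg = Background(odorants=[odorant(1.0)], mean_concentrations=[0.3], noise_sd=0.0)
        m = motif_concentrations([0.0], [odorant(1.0)], background=bg)
        assert m[0] == pytest.approx(0.3)

    def test_background_noise_clamped_and_seeded(self):
        bg = Background(odorants=[odorant(1.0)], mean_concentrations=[0.01], noise_sd=1.0)
        rng = np.random.default_rng(7)
        samples = [bg.sample(rng)[0] for _ in range(50)]
        assert min(samples) >= 0.0
        rng2 = np.random.default_rng(7)
        assert samples == [bg.sample(rng2)[0] for _ in range(50)]


class TestKinetics:
    def test_fixed_point_is_stationary(self):
        s = Sensor(half_conc={0: 1.0}, rate_on=5.0, rate_off=2.0)
        target = 0.8
        a_star = 5.0 * target / 7.0
        s.activation = a_star
        assert kinetic_update(s, target, dt=0.01) == pytest.approx(a_star)

    def test_pure_decay(self):
        s = Sensor(half_conc={0: 1.0}, rate_on=5.0, rate_off=2.0, activation=0.6)
        prev = s.activation
        for _ in range(100):
            a = kinetic_update(s, 0.0, dt=0.01)
            assert a <= prev
            prev = a
        assert prev < 1e-2

    def test_converges_to_closed_form(self):
        """Discrete trajectory approaches A* = r_f A_eq / (r_f + r_b) within
        1e-6 and tracks the continuous exponential solution."""
        r_f, r_b, dt, target = 5.0, 2.0, 0.01, 0.9
        s = Sensor(half_conc={0: 1.0}, rate_on=r_f, rate_off=r_b, activation=0.0)
        a_star = r_f * target / (r_f + r_b)
        n = int(20.0 / (dt * (r_f + r_b)))
        for i in range(1, n + 1):
            a = kinetic_update(s, target, dt)
            exact = a_star * (1.0 - np.exp(-(r_f + r_b) * i * dt))
            assert a == pytest.approx(exact, abs=0.01)
        assert abs(a - a_star) < 1e-6

    def test_unstable_dt_substeps_with_warning(self):
        s = Sensor(half_conc={0: 1.0}, rate_on=100.0, rate_off=50.0, activation=0.0)
        with pytest.warns(RuntimeWarning):
            a = kinetic_update(s, 1.0, dt=0.1)
        assert 0.0 <= a <= 1.0

    def test_fast_kinetics_match_instantaneous(self):
        """With rates fast compared to 1/dt the kinetic sensor reproduces the
        steady state adopted by default."""
        s = Sensor(half_conc={0: 1.0}, rate_on=1000.0, rate_off=0.0, activation=0.0)
        target = 0.42
        for _ in range(5):
            with pytest.warns(RuntimeWarning):
                a = kinetic_update(s, target, dt=0.03)
        assert a == pytest.approx(target, rel=1e-3)


class TestArrayGeneration:
    def test_counts_and_motif_range(self):
        arr = generate_sensor_array(n_sensors=1024, seed=3)
        assert len(arr) == 1024
        assert all(0 <= a < 10 for s in arr.sensors for a in s.half_conc)
        assert all(len(s.half_conc) == 3 for s in arr.sensors)

    def test_seed_determinism(self):
        a = generate_sensor_array(n_sensors=64, seed=11)
        b = generate_sensor_array(n_sensors=64, seed=11)
        assert [s.half_conc for s in a.sensors] == [s.half_conc for s in b.sensors]

    def test_motif_usage_uniform(self):
        """Motif usage over a large array stays within 3 sd of the binomial
        expectation for uniform random assignment."""
        n, m, per = 10_000, 10, 3
        arr = generate_sensor_array(n_sensors=n, n_motifs=m, motifs_per_sensor=per, seed=5)
        counts = np.zeros(m)
        for s in arr.sensors:
            for a in s.half_conc:
                counts[a] += 1
        p = per / m
        sd = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) <= 3 * sd)

    def test_vectorized_response_matches_scalar(self, rng):
        arr = generate_sensor_array(n_sensors=32, seed=9)
        m = rng.uniform(0, 2, size=10)
        vec = arr.respond(m)
        scalar = [mixture_activation(s, m) for s in arr.sensors]
        np.testing.assert_allclose(vec, scalar, rtol=1e-12)

    def test_roundtrip_serialization(self):
        arr = generate_sensor_array(n_sensors=8, seed=2)
        from plumebrain.olfaction import SensorArray

        clone = SensorArray.from_dict(arr.to_dict())
        assert [s.half_conc for s in clone.sensors] == [s.half_conc for s in arr.sensors]

    def test_invalid_ranges_error(self):
        with pytest.raises(ValueError):
            generate_sensor_array(motifs_per_sensor=11)
        with pytest.raises(ValueError):
            generate_sensor_array(k_range=(-1.0, 2.0))
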