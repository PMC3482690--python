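"""Circuit structure, pipeline latency, depression, and homeostasis."""

from dataclasses import replace

import numpy as np
import pytest

from plumebrain.brain import (
    NO_PROPAGATION,
    NetworkConfig,
    SynapseClassParams,
    apply_depression,
    branch_activation,
    build_network,
    measure_latency,
    permissive_params,
    update_homeostasis,
)


class TestBuild:
    def test_full_scale_counts(self):
        net = build_network(seed=0)
        c = net.config
        assert c.n_cortex == 4096 and c.branches == 8
        assert c.inputs_per_cortex_neuron == 160
        assert net.n_cortex_synapses == 655_360
        assert c.n_mitral == 256
        assert c.n_motor == 16 and c.motor_fanin == 256
        assert net.motor_idx.shape == (16, 256)

    def test_scaled_config_counting_oracle(self):
        cfg = NetworkConfig(
            n_sensors=64, n_cortex=64, branches=2, exc_per_branch=4, inh_per_branch=1,
            n_inter=16, inter_fanin=4, n_motor=4, motor_fanin=8,
        )
        net = build_network(config=cfg, seed=0)
        # direct count from the wiring tables
        per_neuron = net.exc_idx.shape[1] * net.exc_idx.shape[2] + net.inh_idx.shape[1] * net.inh_idx.shape[2]
        assert per_neuron == 2 * (4 + 1) == cfg.inputs_per_cortex_neuron
        assert net.n_cortex_synapses == 64 * 10

    def test_wiring_deterministic_under_seed(self):
        a = build_network(seed=42)
        b = build_network(seed=42)
        np.testing.assert_array_equal(a.exc_idx, b.exc_idx)
        np.testing.assert_array_equal(a.inh_idx, b.inh_idx)
        np.testing.assert_array_equal(a.motor_idx, b.motor_idx)

    def test_sensor_clusters_partition(self):
        """Each sensor feeds exactly one mitral unit (disjoint clusters of 4)."""
        cfg = NetworkConfig()
        assert cfg.n_sensors == 1024 and cfg.sensors_per_mitral == 4
        assert cfg.n_mitral * cfg.sensors_per_mitral == cfg.n_sensors

    def test_inhibitory_class_sign_enforced(self):
        params = permissive_params()
        classes = dict(params.classes)
        classes["inter_cortex"] = SynapseClassParams(weight=-1.0)
        classes["mitral_cortex"] = SynapseClassParams(weight=-0.5)
        with pytest.raises(ValueError):
            replace(params, classes=classes)


class TestPipeline:
    def test_zero_input_silent(self, permissive_tiny_net):
        net = permissive_tiny_net
        for _ in range(10):
            assert np.all(net.step(np.zeros(4)) == 0.0)

    def test_five_step_latency(self, permissive_tiny_net):
        assert measure_latency(permissive_tiny_net, np.ones(4)) == 5

    def test_latency_without_alignment_stage(self, tiny_config):
        """Removing the mitral-delay stage shortens the pipeline to 4 steps,
        confirming the stage accounting."""
        params = permissive_params()
        classes = dict(params.classes)
        classes["inter_cortex"] = SynapseClassParams(weight=-0.25)
        net = build_network(
            replace(params, classes=classes),
            replace(tiny_config, align_inhibition=False),
            seed=0,
        )
        assert measure_latency(net, np.ones(4)) == 4

    def test_no_propagation_sentinel(self, permissive_tiny_net):
        assert measure_latency(permissive_tiny_net, np.zeros(4)) == NO_PROPAGATION

    def test_hand_simulated_trajectory(self, permissive_tiny_net):
        """One-unit-per-layer chain against a hand-computed firing table:
        mitral follows input after 1 step, the interneuron after 2, cortex
        after 3 (excitation 1.0 minus aligned inhibition 0.25), motor after 4."""
        net = permissive_tiny_net
        rows = []
        for _ in range(8):
            net.step(np.ones(4))
            rows.append((float(net.mitral[0]), float(net.inter[0]), float(net.cortex[0]), float(net.motor[0])))
        expected = [
            (0.0, 0.0, 0.0, 0.0),
            (1.0, 0.0, 0.0, 0.0),
            (1.0, 1.0, 0.0, 0.0),
            (1.0, 1.0, 1.0, 0.0),
            (1.0, 1.0, 1.0, 1.0),
            (1.0, 1.0, 1.0, 1.0),
            (1.0, 1.0, 1.0, 1.0),
            (1.0, 1.0, 1.0, 1.0),
        ]
        assert rows == expected

    def test_memory_bounded_without_plasticity(self, tiny_config):
        """With depression off and homeostasis frozen the network output is a
        pure function of the recent input window."""
        params = permissive_params()
        classes = dict(params.classes)
        classes["inter_cortex"] = SynapseClassParams(weight=-0.25)
        params = replace(params, classes=classes)
        rng = np.random.default_rng(0)
        window = [rng.random(4) for _ in range(10)]

        def tail_states(prefix):
            net = build_network(params, tiny_config, seed=0)
            for x in prefix:
                net.step(x)
            return [tuple(net.step(x)) for x in window]

        prefix_a = [rng.random(4) for _ in range(7)]
        prefix_b = [np.zeros(4) for _ in range(19)]
        assert tail_states(prefix_a)[-4:] == tail_states(prefix_b)[-4:]

    def test_non_finite_input_rejected(self, permissive_tiny_net):
        with pytest.raises(ValueError):
            permissive_tiny_net.step(np.array([np.nan, 0, 0, 0]))


class TestBranchActivation:
    def test_threshold_tie_activates(self):
        assert branch_activation(0.5, "thresholded", theta=0.5) == 1.0
        assert branch_activation(0.4999, "thresholded", theta=0.5) == 0.0

    def test_linear_identity(self):
        assert branch_activation(0.37, "linear", theta=0.5) == pytest.approx(0.37)

    def test_sigmoid_midpoint(self):
        assert branch_activation(0.5, "sigmoidal", theta=0.5, gain=4.0) == pytest.approx(0.5)

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError):
            branch_activation(0.1, "quadratic", theta=0.5)


class TestDepression:
    def test_no_depression_limit(self):
        r = np.ones(3)
        for _ in range(20):
            eff, r = apply_depression(r, np.ones(3), dep_u=0.0, dep_recovery=0.1)
            np.testing.assert_array_equal(eff, 1.0)
        np.testing.assert_array_equal(r, 1.0)

    def test_pure_recovery_geometric(self):
        r = np.array([0.2])
        rec = 0.25
        for k in range(1, 30):
            _, r = apply_depression(r, np.zeros(1), dep_u=0.5, dep_recovery=rec)
            assert 1.0 - r[0] == pytest.approx(0.8 * (1 - rec) ** k, rel=1e-12)

    def test_sustained_activation_fixed_point(self):
        """R* = r_rec / (r_rec + U - U r_rec) under every-step activation."""
        u, rec = 0.3, 0.07
        r = np.ones(1)
        for _ in range(3000):
            _, r = apply_depression(r, np.ones(1), dep_u=u, dep_recovery=rec)
        r_star = rec / (rec + u - u * rec)
        assert r[0] == pytest.approx(r_star, abs=1e-9)

    def test_resource_bounded_under_arbitrary_activity(self, rng):
        r = rng.random(16)
        for _ in range(500):
            a = (rng.random(16) < 0.5).astype(float) * rng.random(16)
            _, r = apply_depression(r, a, dep_u=rng.random(), dep_recovery=rng.random())
            assert np.all((r >= 0.0) & (r <= 1.0))

    def test_effective_weight_read_before_depletion(self):
        r = np.ones(1)
        eff, r = apply_depression(r, np.ones(1), dep_u=0.5, dep_recovery=0.0)
        assert eff[0] == 1.0
        assert r[0] == pytest.approx(0.5)


class TestHomeostasis:
    def test_equilibrium_threshold_unchanged(self):
        avg, theta = np.array([0.2]), np.array([0.6])
        a2, t2 = update_homeostasis(avg, theta, np.array([0.2]), target=0.2)
        assert t2[0] == pytest.approx(0.6)

    def test_disabled_adaptation(self):
        avg, theta = np.array([0.0]), np.array([0.6])
        for _ in range(100):
            avg, theta = update_homeostasis(avg, theta, np.array([1.0]), target=0.1, eta=0.0)
        assert theta[0] == 0.6

    def test_single_unit_converges_to_target_rate(self):
        """A thresholded unit with uniform random drive self-adjusts until its
        long-run firing rate sits within 10% of the target."""
        rng = np.random.default_rng(0)
        target = 0.2
        avg, theta = np.array([target]), np.array([0.5])
        fired = []
        for t in range(40_000):
            drive = rng.random(1)
            act = (drive >= theta).astype(float)
            avg, theta = update_homeostasis(avg, theta, act, target=target)
            fired.append(act[0])
        rate = np.mean(fired[-10_000:])
        assert abs(rate - target) <= 0.1 * target

    def test_supra_threshold_drive_raises_threshold(self):
        avg, theta = np.array([0.0]), np.array([0.5])
        thetas = []
        for _ in range(2000):
            avg, theta = update_homeostasis(avg, theta, np.array([1.0]), target=0.05)
            thetas.append(theta[0])
        assert all(b >= a for a, b in zip(thetas[100:], thetas[101:]))

    def test_network_rates_track_targets(self):
        """Scaled-down cortex under stationary stochastic input: long-run
        soma rates land within 20% of the evolved target on average."""
        cfg = NetworkConfig(
            n_sensors=64, n_inter=16, inter_fanin=4, n_cortex=64,
            branches=4, exc_per_branch=8, inh_per_branch=2, n_motor=4, motor_fanin=16,
        )
        params = replace(
            permissive_params(homeostasis_frozen=False),
            branch_target=0.15,
            soma_target=0.15,
            branch_threshold0=0.5,
            homeostasis_eta=5e-3,
        )
        net = build_network(params, cfg, seed=0)
        rng = np.random.default_rng(3)
        counts = np.zeros(cfg.n_cortex)
        n_tail = 4000
        for t in range(12_000):
            out = net.step(rng.random(64))
            if t >= 12_000 - n_tail:
                counts += net.cortex
        mean_rate = counts.mean() / n_tail
        assert abs(mean_rate - params.soma_target) <= 0.2 * params.soma_target
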