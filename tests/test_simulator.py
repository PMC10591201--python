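"""Biophysical simulator: neuron dynamics, forced spiking, failure, latency,
noise calibration."""

import numpy as np
import pytest

from cocomap import (
    ExperimentConfig,
    LatencyModel,
    NeuronParams,
    build_network,
    calibrate_background_noise,
    generate_stimulation_matrix,
    izhikevich_step,
    run_mapping_experiment,
    run_simulation,
    sample_neuron_params,
    schedule_trials,
)
from cocomap.network import GroundTruthNetwork
from cocomap.simulator import CalibrationError

RS = dict(a=0.02, b=0.2, c=-65.0, d=8.0)  # regular-spiking parameter set


def scalar_params(**kw):
    return NeuronParams(
        a=np.array([kw["a"]]),
        b=np.array([kw["b"]]),
        c=np.array([kw["c"]]),
        d=np.array([kw["d"]]),
    )


def reference_izhikevich(a, b, c, d, I, v0, u0, n_steps, dt):
    """Independent scalar re-implementation used as an oracle: plain Python
    floats, no shared code with the package's vectorised update."""
    v, u = v0, u0
    spikes = []
    for t in range(n_steps):
        v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
        u_new = u + dt * a * (b * v - u)
        if v_new >= 30.0:
            spikes.append(t)
            v_new, u_new = c, u_new + d
        v, u = v_new, u_new
    return spikes


class TestIzhikevichStep:
    def test_reset_rule_after_cutoff(self):
        p = scalar_params(**RS)
        v, u, spiked = izhikevich_step(np.array([29.0]), np.array([-10.0]), p, 500.0, 0.5)
        assert spiked[0]
        assert v[0] == RS["c"]
        assert u[0] == pytest.approx(-10.0 + 0.5 * RS["a"] * (RS["b"] * 29.0 + 10.0) + RS["d"])

    def test_resting_fixed_point_is_stationary(self):
        # v = -70, u = -14 solves 0.04 v^2 + 4.8 v + 140 = 0 with u = b v
        p = scalar_params(**RS)
        v, u = np.array([-70.0]), np.array([-14.0])
        for _ in range(100):
            v, u, spiked = izhikevich_step(v, u, p, 0.0, 0.5)
            assert not spiked[0]
        assert v[0] == pytest.approx(-70.0, abs=1e-9)
        assert u[0] == pytest.approx(-14.0, abs=1e-9)

    def test_spike_train_matches_scalar_reference_exactly(self):
        n_steps = 2000  # 1 s at 0.5 ms
        expected = reference_izhikevich(**RS, I=10.0, v0=-70.0, u0=-14.0, n_steps=n_steps, dt=0.5)
        p = scalar_params(**RS)
        v, u = np.array([-70.0]), np.array([-14.0])
        got = []
        for t in range(n_steps):
            v, u, spiked = izhikevich_step(v, u, p, 10.0, 0.5)
            if spiked[0]:
                got.append(t)
        assert got == expected
        assert len(got) > 0  # the oracle actually fires at this drive

    def test_parameter_families_by_cell_type(self, rng):
        exc = np.array([True] * 50 + [False] * 50)
        p = sample_neuron_params(exc, rng)
        assert np.all(p.a[:50] == 0.02) and np.all(p.b[:50] == 0.2)
        assert np.all((p.c[:50] >= -65.0) & (p.c[:50] <= -50.0))
        assert np.all(p.d[50:] == 2.0) and np.all(p.c[50:] == -65.0)
        assert np.all((p.a[50:] >= 0.02) & (p.a[50:] <= 0.1))


def two_neuron_network(weight: float) -> GroundTruthNetwork:
    w = np.zeros((2, 2))
    w[1, 0] = weight  # 0 -> 1
    return GroundTruthNetwork(
        weights=w,
        is_excitatory=np.array([weight >= 0, True]),
        observed=np.array([0, 1]),
        connect_prob=0.5,
    )


def fixed_rs_params(n):
    return NeuronParams(
        a=np.full(n, RS["a"]), b=np.full(n, RS["b"]),
        c=np.full(n, RS["c"]), d=np.full(n, RS["d"]),
    )


class TestMappingExperiment:
    @staticmethod
    def _hand_trace(n_steps, kick_step, kick, dt=0.5):
        """Independent Euler stepping of one regular-spiking cell receiving a
        single current kick at ``kick_step``."""
        v, u = -65.0, -13.0  # v0 = -65, u0 = b*v0
        out = []
        for t in range(n_steps):
            I = kick if t == kick_step else 0.0
            v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
            u_new = u + dt * RS["a"] * (RS["b"] * v - u)
            v, u = v_new, u_new
            out.append(v)
        return np.array(out)

    def test_psp_onset_at_configured_latency(self, rng):
        """With zero noise and a single connection j -> i, the postsynaptic
        trace equals a hand-stepped Euler trace receiving the weight as a
        current kick exactly round(latency/dt) steps after the trial."""
        net = two_neuron_network(5.0)
        M = generate_stimulation_matrix(1, 2, 0.5, rng)
        M.entries[:] = [[1, 0]]
        sched = schedule_trials(1, 0.5, 50.0, 0.0)
        for mean_ms, delay_steps in [(1.0, 2), (2.5, 5)]:
            rec = run_mapping_experiment(
                net, M, sched, 0.0, np.random.default_rng(0),
                params=fixed_rs_params(2),
                latency=LatencyModel(mean=mean_ms, sd=0.0),
            )
            ts = sched.trial_steps[0]
            expected = self._hand_trace(rec.n_steps, ts + delay_steps, 5.0)
            assert np.allclose(rec.voltages[1], expected, atol=1e-4)
            # and the kick at any other step would not match
            wrong = self._hand_trace(rec.n_steps, ts + delay_steps + 1, 5.0)
            assert not np.allclose(rec.voltages[1], wrong, atol=1e-4)

    def test_forced_spike_guarantee_and_logging(self, rng):
        cfg = ExperimentConfig(total_cells=40, n_obs=20, n_trials=8, warmup=50.0)
        net = build_network(cfg, rng)
        params = sample_neuron_params(net.is_excitatory, rng)
        M = generate_stimulation_matrix(8, 20, 0.3, rng)
        sched = schedule_trials(8, 0.5, 50.0, 50.0)
        rec = run_mapping_experiment(net, M, sched, 0.5, rng, params=params)
        for t, step in enumerate(sched.trial_steps):
            stim = net.observed[M.entries[t] == 1]
            for cell in stim:
                assert step in rec.spike_steps[cell]

    def test_trial_spike_set_is_row_union_off_target(self, rng):
        cfg = ExperimentConfig(total_cells=30, n_obs=10, n_trials=6, warmup=50.0)
        net = build_network(cfg, rng)
        params = sample_neuron_params(net.is_excitatory, rng)
        M = generate_stimulation_matrix(6, 10, 0.3, rng)
        sched = schedule_trials(6, 0.5, 50.0, 50.0)
        rec = run_mapping_experiment(
            net, M, sched, 0.0, rng, params=params, off_target_prob=1.0
        )
        for t, step in enumerate(sched.trial_steps):
            spikers = {c for c in range(30) if step in rec.spike_steps[c]}
            expected = set(net.observed[M.entries[t] == 1].tolist())
            extra = rec.off_target_log[t]
            assert extra is not None and extra not in expected
            assert spikers == expected | {extra}

    def test_total_failure_blocks_all_transmission(self, rng):
        net = two_neuron_network(8.0)
        M = generate_stimulation_matrix(3, 2, 0.5, rng)
        M.entries[:] = [[1, 0], [1, 0], [1, 0]]
        sched = schedule_trials(3, 0.5, 50.0, 0.0)
        rec = run_mapping_experiment(
            net, M, sched, 0.0, np.random.default_rng(0),
            params=fixed_rs_params(2), syn_fail_prob=1.0,
        )
        # postsynaptic cell relaxes from init untouched: compare to a run with no connection
        rec0 = run_mapping_experiment(
            two_neuron_network(0.0), M, sched, 0.0, np.random.default_rng(0),
            params=fixed_rs_params(2), syn_fail_prob=0.0,
        )
        assert np.array_equal(rec.voltages[1], rec0.voltages[1])
        assert rec.failed_events == rec.transmission_events > 0

    def test_failure_fraction_matches_binomial(self, rng):
        cfg = ExperimentConfig(total_cells=60, n_obs=30, sparsity=0.3, n_trials=40, warmup=50.0)
        net = build_network(cfg, rng)
        params = sample_neuron_params(net.is_excitatory, rng)
        M = generate_stimulation_matrix(40, 30, 0.3, rng)
        sched = schedule_trials(40, 0.5, 50.0, 50.0)
        p = 0.4
        rec = run_mapping_experiment(net, M, sched, 0.0, rng, params=params, syn_fail_prob=p)
        n = rec.transmission_events
        se = np.sqrt(p * (1 - p) / n)
        assert abs(rec.failed_events / n - p) < 3 * se

    def test_probability_arguments_validated(self, rng):
        net = two_neuron_network(1.0)
        M = generate_stimulation_matrix(1, 2, 0.5, rng)
        sched = schedule_trials(1, 0.5, 50.0, 0.0)
        with pytest.raises(ValueError):
            run_mapping_experiment(net, M, sched, 0.0, rng, syn_fail_prob=1.5)
        with pytest.raises(ValueError):
            run_mapping_experiment(net, M, sched, 0.0, rng, off_target_prob=-0.1)

    def test_raster_seed_determinism(self, rng):
        cfg = ExperimentConfig(total_cells=50, n_obs=20, n_trials=5, warmup=50.0)
        net = build_network(cfg, np.random.default_rng(4))
        params = sample_neuron_params(net.is_excitatory, np.random.default_rng(5))
        M = generate_stimulation_matrix(5, 20, 0.2, np.random.default_rng(6))
        sched = schedule_trials(5, 0.5, 50.0, 50.0)
        recs = [
            run_mapping_experiment(
                net, M, sched, 1.5, np.random.default_rng(7), params=params,
                syn_fail_prob=0.2, off_target_prob=0.3,
            )
            for _ in range(2)
        ]
        assert np.array_equal(recs[0].voltages, recs[1].voltages)
        for s0, s1 in zip(recs[0].spike_steps, recs[1].spike_steps):
            assert np.array_equal(s0, s1)
        assert recs[0].off_target_log == recs[1].off_target_log


class TestBackgroundNoise:
    def test_no_noise_no_spikes(self, rng):
        cfg = ExperimentConfig(total_cells=100, n_obs=10)
        net = build_network(cfg, rng)
        params = sample_neuron_params(net.is_excitatory, rng)
        rec = run_simulation(net, params, 4000, 0.0, rng, record_voltages=False)
        assert rec.total_spikes() == 0

    def test_rate_monotone_in_sigma(self, rng):
        cfg = ExperimentConfig(total_cells=200, n_obs=10)
        net = build_network(cfg, rng)
        params = sample_neuron_params(net.is_excitatory, rng)
        rates = [
            run_simulation(net, params, 10000, s, np.random.default_rng(9),
                           record_voltages=False).mean_firing_rate()
            for s in (1.0, 2.5, 4.0)
        ]
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0

    def test_rate_increases_with_connection_probability(self):
        """Denser recurrent networks amplify stimulation-driven activity:
        the network-mean rate over a mapping run grows with density."""
        from cocomap import run_experiment

        rates = []
        for p in (0.02, 0.1, 0.2):
            cfg = ExperimentConfig(sparsity=p, n_trials=20)
            rates.append(run_experiment(cfg, seed=5, noise_sigma=2.03).mean_firing_rate)
        assert rates[0] < rates[1] < rates[2]

    def test_calibration_reaches_target_rate(self, rng):
        cfg = ExperimentConfig(total_cells=300, n_obs=10)
        net = build_network(cfg, rng)
        params = sample_neuron_params(net.is_excitatory, rng)
        cal = calibrate_background_noise(
            net, params, rng, target_rate=1.0, sim_seconds=5.0, tolerance=0.2
        )
        assert abs(cal.achieved_rate - 1.0) <= 0.2
        assert len(cal.trace) >= 1

    def test_unreachable_target_raises(self, rng):
        cfg = ExperimentConfig(total_cells=50, n_obs=10)
        net = build_network(cfg, rng)
        params = sample_neuron_params(net.is_excitatory, rng)
        with pytest.raises(CalibrationError):
            calibrate_background_noise(
                net, params, rng, target_rate=50.0, sim_seconds=2.0,
                sigma_hi=0.05, tolerance=0.1,
            )


def test_recording_bundle_roundtrip(tmp_path, rng):
    from cocomap.simulator import load_recording, save_recording

    cfg = ExperimentConfig(total_cells=30, n_obs=10, n_trials=4, warmup=50.0)
    net = build_network(cfg, rng)
    params = sample_neuron_params(net.is_excitatory, rng)
    M = generate_stimulation_matrix(4, 10, 0.3, rng)
    sched = schedule_trials(4, 0.5, 50.0, 50.0)
    rec = run_mapping_experiment(net, M, sched, 1.0, rng, params=params)
    save_recording(rec, tmp_path / "bundle")
    loaded = load_recording(tmp_path / "bundle")
    assert np.array_equal(loaded.voltages, rec.voltages)
    assert np.array_equal(loaded.M.entries, rec.M.entries)
    assert loaded.schedule.trial_steps.tolist() == rec.schedule.trial_steps.tolist()
    for a, b in zip(loaded.spike_steps, rec.spike_steps):
        assert np.array_equal(a, b)
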