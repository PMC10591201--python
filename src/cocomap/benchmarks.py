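"""Headline benchmark experiments of the mapping method.

Each function runs the full pipeline from scratch at a documented study
configuration and reports the summary quantity (mean recall over seeds, or
the calibrated spontaneous rate).  Background-noise calibration runs once
per configuration on the first seed's network and the calibrated sigma is
reused for the remaining seeds of that configuration (the rate-vs-sigma
curve depends on the configuration, not the individual network draw).

The base reconstruction flow is: unconstrained L1 decode of every observed
neuron, classification of presynaptic cell types from the result, and a
sign-constrained re-solve (mode ``inferred_sign_constrained``); the
synaptic-failure benchmark reports the plain unconstrained decode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ExperimentConfig
from .network import build_network
from .neurons import sample_neuron_params
from .pipeline import run_experiment
from .simulator import calibrate_background_noise, run_simulation

__all__ = [
    "BenchmarkResult",
    "mean_recall_benchmark",
    "base_mapping_recall",
    "partial_observability_recall",
    "synaptic_failure_recall",
    "calibrated_spontaneous_rate",
]


@dataclass
class BenchmarkResult:
    value: float  # on the reporting scale (percent or Hz)
    n: int  # problem size (trials, or simulated seconds for rates)
    per_seed: list[float]
    noise_sigma: float


def _child_seeds(seed: int, label: int, count: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), int(label)])
    return [int(s) for s in ss.generate_state(count) % (2**31)]


def _calibrated_network(config: ExperimentConfig, seed: int, **kwargs):
    """Build the configuration's network and calibrate its background noise."""
    rng_net = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    network = build_network(config, rng_net)
    params = sample_neuron_params(network.is_excitatory, rng_net)
    cal = calibrate_background_noise(
        network,
        params,
        np.random.default_rng(np.random.SeedSequence([seed, 1])),
        target_rate=config.target_rate,
        dt=config.dt,
        **kwargs,
    )
    return network, params, cal.sigma


def _calibrate_for(config: ExperimentConfig, seed: int, **kwargs) -> float:
    return _calibrated_network(config, seed, **kwargs)[2]


def mean_recall_benchmark(
    config: ExperimentConfig,
    seed: int,
    label: int,
    n_seeds: int = 5,
    mode: str = "inferred_sign_constrained",
) -> BenchmarkResult:
    """Mean recall (percent) over ``n_seeds`` independent experiments."""
    seeds = _child_seeds(seed, label, n_seeds)
    sigma = _calibrate_for(config, seeds[0])
    recalls = []
    for s in seeds:
        res = run_experiment(config, s, mode=mode, noise_sigma=sigma)
        recalls.append(res.recall)
    return BenchmarkResult(
        value=100.0 * float(np.mean(recalls)),
        n=config.n_trials,
        per_seed=[100.0 * r for r in recalls],
        noise_sigma=sigma,
    )


def base_mapping_recall(seed: int, n_seeds: int = 5) -> BenchmarkResult:
    """Base configuration: 1,000 cells, 200 observed, density 0.1, T = 100
    trials — half the 200 trials one-cell-per-trial mapping would need."""
    return mean_recall_benchmark(ExperimentConfig(), seed, label=1, n_seeds=n_seeds)


def partial_observability_recall(seed: int, n_seeds: int = 5) -> BenchmarkResult:
    """Only 10% of the network observable: 2,000 cells, 200 observed, T = 100."""
    config = ExperimentConfig(total_cells=2000)
    return mean_recall_benchmark(config, seed, label=2, n_seeds=n_seeds)


def synaptic_failure_recall(seed: int, n_seeds: int = 5) -> BenchmarkResult:
    """Unreliable transmission: every (spike, connection) event fails with
    probability 0.5; T = 1,000 trials, unconstrained decode."""
    config = ExperimentConfig(syn_fail_prob=0.5, n_trials=1000)
    return mean_recall_benchmark(
        config, seed, label=4, n_seeds=n_seeds, mode="unconstrained"
    )


def calibrated_spontaneous_rate(seed: int, eval_seconds: float = 120.0) -> BenchmarkResult:
    """Calibrate the background current on the base network, then measure the
    network-mean spontaneous rate (Hz) on an independent stimulation-free run
    of ``eval_seconds`` of that same network with the calibrated variance."""
    config = ExperimentConfig()
    seeds = _child_seeds(seed, 3, 2)
    network, params, sigma = _calibrated_network(config, seeds[0])
    n_steps = int(round(eval_seconds * 1000.0 / config.dt))
    rec = run_simulation(
        network,
        params,
        n_steps,
        sigma,
        np.random.default_rng(np.random.SeedSequence([seeds[1], 2])),
        dt=config.dt,
        record_voltages=False,
    )
    rate = rec.mean_firing_rate()
    return BenchmarkResult(
        value=float(rate), n=int(eval_seconds), per_seed=[float(rate)], noise_sigma=sigma
    )
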