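import numpy as np
import pytest

from cocomap import (
    ExperimentConfig,
    LatencyModel,
    StimulationMatrix,
    TrialSchedule,
)
from cocomap.simulator import ExperimentRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A scaled-down experiment that runs in well under a second."""
    return ExperimentConfig(
        total_cells=80,
        n_obs=30,
        sparsity=0.1,
        n_trials=12,
        warmup=50.0,
    )


def make_recording(
    voltages: np.ndarray,
    trial_steps: np.ndarray,
    M_entries: np.ndarray,
    dt: float = 0.5,
    interval: float = 50.0,
    latency_mean: float = 1.0,
    latency_sd: float = 0.0,
    spike_steps=None,
    observed=None,
    n_cells=None,
) -> ExperimentRecording:
    """Assemble a synthetic recording from hand-built voltage traces."""
    n_obs = voltages.shape[0]
    n_cells = n_cells or n_obs
    observed = np.arange(n_obs) if observed is None else np.asarray(observed)
    spike_steps = spike_steps or [np.array([], dtype=np.int64) for _ in range(n_cells)]
    schedule = TrialSchedule(
        trial_steps=np.asarray(trial_steps), dt=dt, interval=interval, warmup=0.0
    )
    M = StimulationMatrix(entries=np.asarray(M_entries, dtype=np.uint8), fraction_stim=0.1)
    return ExperimentRecording(
        voltages=np.asarray(voltages, dtype=np.float32),
        spike_steps=spike_steps,
        schedule=schedule,
        M=M,
        observed=observed,
        off_target_log=[None] * len(trial_steps),
        noise_sigma=0.0,
        dt=dt,
        latency=LatencyModel(mean=latency_mean, sd=latency_sd),
        n_cells=n_cells,
    )
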