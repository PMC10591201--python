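"""Biophysical simulation of a full stimulation experiment.

Steps the recurrent Izhikevich network at dt = 0.5 ms under per-step
Gaussian background current, forced presynaptic spiking on scheduled trials,
per-event synaptic failure, optional off-target stimulation, and frozen
per-connection propagation latency.  Membrane voltages of observed cells and
spike times of all cells are recorded.

Synaptic transmission is a delta-current: a presynaptic spike of cell j at
step t adds weight w_ij to the input current of cell i at step t + delay_ij
(independently zeroed with probability syn_fail_prob per event).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .network import GroundTruthNetwork
from .neurons import LatencyModel, NeuronParams, izhikevich_step, sample_neuron_params
from .stimulation import StimulationMatrix, TrialSchedule

__all__ = [
    "ExperimentRecording",
    "CalibrationResult",
    "CalibrationError",
    "run_simulation",
    "calibrate_background_noise",
    "run_mapping_experiment",
    "save_recording",
    "load_recording",
]


class CalibrationError(RuntimeError):
    def __init__(self, message: str, achieved_rate: float):
        super().__init__(message)
        self.achieved_rate = achieved_rate


@dataclass
class ExperimentRecording:
    """Everything one simulated run produced."""

    voltages: np.ndarray  # (n_obs, n_steps) float32, mV
    spike_steps: list[np.ndarray]  # per cell (all cells), sorted step indices
    schedule: TrialSchedule | None
    M: StimulationMatrix | None
    observed: np.ndarray
    off_target_log: list[int | None]  # per trial, forced off-target cell or None
    noise_sigma: float
    dt: float
    latency: LatencyModel
    n_cells: int
    transmission_events: int = 0
    failed_events: int = 0
    config_snapshot: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.voltages.shape[1]

    def total_spikes(self) -> int:
        return int(sum(len(s) for s in self.spike_steps))

    def mean_firing_rate(self) -> float:
        """Network-mean spontaneous/evoked rate in Hz over the whole run."""
        seconds = self.n_steps * self.dt / 1000.0
        return self.total_spikes() / (self.n_cells * seconds)


def _edge_structure(net: GroundTruthNetwork):
    """CSC factorisation of the weight matrix for per-presynaptic delivery."""
    W = sparse.csc_array(net.weights)
    return W.indptr, W.indices.astype(np.int64), W.data


def run_simulation(
    network: GroundTruthNetwork,
    params: NeuronParams,
    n_steps: int,
    noise_sigma: float,
    rng: np.random.Generator,
    dt: float = 0.5,
    schedule: TrialSchedule | None = None,
    M: StimulationMatrix | None = None,
    syn_fail_prob: float = 0.0,
    off_target_prob: float = 0.0,
    latency: LatencyModel | None = None,
    record_voltages: bool = True,
) -> ExperimentRecording:
    """Integrate the network for ``n_steps`` steps of ``dt`` ms.

    If a schedule and stimulation matrix are given, row t of M is consumed at
    schedule.trial_steps[t]: the cells with 1-entries (observed-subset
    indexing) are forced to spike, plus possibly one logged off-target cell.
    """
    if not 0.0 <= syn_fail_prob <= 1.0:
        raise ValueError("syn_fail_prob must lie in [0, 1]")
    if not 0.0 <= off_target_prob <= 1.0:
        raise ValueError("off_target_prob must lie in [0, 1]")
    if (schedule is None) != (M is None):
        raise ValueError("schedule and M must be given together")
    latency = latency or LatencyModel()

    n = network.n_cells
    observed = np.asarray(network.observed)
    indptr, indices, data = _edge_structure(network)
    delays = latency.draw_delays(len(data), dt, rng)
    max_delay = int(delays.max()) if len(delays) else 1

    trial_of_step: dict[int, int] = {}
    if schedule is not None:
        if M.n_trials < schedule.n_trials:
            raise ValueError("schedule has more trials than rows of M")
        if schedule.n_trials and schedule.trial_steps[-1] >= n_steps:
            raise ValueError("schedule does not fit in n_steps")
        trial_of_step = {int(s): t for t, s in enumerate(schedule.trial_steps)}

    v, u = params.resting_state()
    L = max_delay + 1
    buffer = np.zeros((L, n))
    voltages = (
        np.zeros((len(observed), n_steps), dtype=np.float32) if record_voltages else
        np.zeros((0, n_steps), dtype=np.float32)
    )
    spike_lists: list[list[int]] = [[] for _ in range(n)]
    off_target_log: list[int | None] = [None] * (schedule.n_trials if schedule else 0)
    transmission_events = 0
    failed_events = 0
    cutoff = params.spike_cutoff

    for t in range(n_steps):
        slot = t % L
        I = buffer[slot] + noise_sigma * rng.standard_normal(n)
        buffer[slot] = 0.0

        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + I
        v_new = v + dt * dv
        u_new = u + dt * params.a * (params.b * v - u)

        trial = trial_of_step.get(t)
        if trial is not None:
            stim_cells = observed[M.entries[trial] == 1]
            v_new[stim_cells] = cutoff  # force spikes regardless of state
            if off_target_prob > 0.0 and rng.random() < off_target_prob:
                candidates = np.setdiff1d(np.arange(n), stim_cells, assume_unique=False)
                extra = int(rng.choice(candidates))
                v_new[extra] = cutoff
                off_target_log[trial] = extra

        if not np.all(np.isfinite(v_new)):
            bad = int(np.flatnonzero(~np.isfinite(v_new))[0])
            raise FloatingPointError(
                f"non-finite membrane state in neuron {bad} at step {t}"
            )

        spiked = v_new >= cutoff
        if record_voltages:
            voltages[:, t] = np.minimum(v_new, cutoff)[observed]

        v = np.where(spiked, params.c, v_new)
        u = np.where(spiked, u_new + params.d, u_new)

        if spiked.any():
            for j in np.flatnonzero(spiked):
                spike_lists[j].append(t)
                lo, hi = indptr[j], indptr[j + 1]
                rows = indices[lo:hi]
                w = data[lo:hi]
                dl = delays[lo:hi]
                transmission_events += len(rows)
                if syn_fail_prob > 0.0 and len(rows):
                    keep = rng.random(len(rows)) >= syn_fail_prob
                    failed_events += int(len(rows) - keep.sum())
                    rows, w, dl = rows[keep], w[keep], dl[keep]
                arrive = t + dl
                ok = arrive < n_steps
                np.add.at(buffer, (arrive[ok] % L, rows[ok]), w[ok])

    return ExperimentRecording(
        voltages=voltages,
        spike_steps=[np.asarray(s, dtype=np.int64) for s in spike_lists],
        schedule=schedule,
        M=M,
        observed=observed,
        off_target_log=off_target_log,
        noise_sigma=noise_sigma,
        dt=dt,
        latency=latency,
        n_cells=n,
        transmission_events=transmission_events,
        failed_events=failed_events,
    )


@dataclass
class CalibrationResult:
    sigma: float
    achieved_rate: float  # Hz
    trace: list[tuple[float, float]]  # (sigma, rate) evaluations


def calibrate_background_noise(
    network: GroundTruthNetwork,
    params: NeuronParams,
    rng: np.random.Generator,
    target_rate: float = 0.2,
    sim_seconds: float = 30.0,
    tolerance: float = 0.05,
    dt: float = 0.5,
    max_iter: int = 20,
    sigma_hi: float = 20.0,
) -> CalibrationResult:
    """Bisect the per-step Gaussian current s.d. until a stimulation-free run
    of ``sim_seconds`` gives a network-mean firing rate within
    ``tolerance * target_rate`` of the target.

    The spontaneous rate is monotone non-decreasing in sigma, so bisection on
    the rate error is sound; the upper bracket is doubled (up to 4x) if it
    does not yet reach the target.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    ss = np.random.SeedSequence(rng.integers(2**31))
    n_steps = int(round(sim_seconds * 1000.0 / dt))

    def rate_at(sigma: float) -> float:
        child = np.random.default_rng(ss.spawn(1)[0])
        rec = run_simulation(
            network, params, n_steps, sigma, child, dt=dt, record_voltages=False
        )
        return rec.mean_firing_rate()

    trace: list[tuple[float, float]] = []
    lo, lo_rate = 0.0, 0.0  # no drive, no spikes from rest
    hi = sigma_hi
    hi_rate = rate_at(hi)
    trace.append((hi, hi_rate))
    expansions = 0
    while hi_rate < target_rate and expansions < 2:
        hi *= 2.0
        hi_rate = rate_at(hi)
        trace.append((hi, hi_rate))
        expansions += 1
    if hi_rate < target_rate:
        raise CalibrationError(
            f"target rate {target_rate} Hz unreachable below sigma={hi}", hi_rate
        )

    sigma, rate = hi, hi_rate
    for _ in range(max_iter):
        if abs(rate - target_rate) <= tolerance * target_rate:
            return CalibrationResult(sigma=sigma, achieved_rate=rate, trace=trace)
        if rate > target_rate:
            hi, hi_rate = sigma, rate
        else:
            lo, lo_rate = sigma, rate
        sigma = 0.5 * (lo + hi)
        rate = rate_at(sigma)
        trace.append((sigma, rate))
    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations "
        f"(best rate {rate:.4g} Hz at sigma={sigma:.4g})",
        rate,
    )


def run_mapping_experiment(
    network: GroundTruthNetwork,
    M: StimulationMatrix,
    schedule: TrialSchedule,
    noise_sigma: float,
    rng: np.random.Generator,
    params: NeuronParams | None = None,
    syn_fail_prob: float = 0.0,
    off_target_prob: float = 0.0,
    latency: LatencyModel | None = None,
    dt: float = 0.5,
    tail_steps: int | None = None,
) -> ExperimentRecording:
    """Run a full stimulation experiment and record observed voltages.

    Neuron parameters are sampled from the model's biophysical range unless
    given.  The simulation extends one inter-trial interval past the last
    trial so the final trial's response window is complete.
    """
    if M.n_obs != network.n_obs:
        raise ValueError("stimulation matrix width must equal number of observed cells")
    if params is None:
        params = sample_neuron_params(network.is_excitatory, rng)
    if tail_steps is None:
        tail_steps = schedule.interval_steps
    n_steps = int(schedule.trial_steps[-1]) + tail_steps if schedule.n_trials else tail_steps
    return run_simulation(
        network,
        params,
        n_steps,
        noise_sigma,
        rng,
        dt=dt,
        schedule=schedule,
        M=M,
        syn_fail_prob=syn_fail_prob,
        off_target_prob=off_target_prob,
        latency=latency or LatencyModel(),
    )


# -- recording bundle I/O --------------------------------------------------


def save_recording(rec: ExperimentRecording, directory: str | Path) -> None:
    """Write a run bundle: voltages (HDF5), spikes/logs (JSON), M (CSV),
    schedule (JSON) and, if attached, the config snapshot."""
    import h5py

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with h5py.File(d / "voltages.h5", "w") as f:
        f.create_dataset("voltages", data=rec.voltages, compression="gzip")
        f.attrs["dt"] = rec.dt
        f.attrs["noise_sigma"] = rec.noise_sigma
    payload = {
        "spike_steps": [s.tolist() for s in rec.spike_steps],
        "observed": rec.observed.tolist(),
        "off_target_log": rec.off_target_log,
        "noise_sigma": rec.noise_sigma,
        "dt": rec.dt,
        "n_cells": rec.n_cells,
        "latency": {"mean": rec.latency.mean, "sd": rec.latency.sd},
        "transmission_events": rec.transmission_events,
        "failed_events": rec.failed_events,
    }
    (d / "events.json").write_text(json.dumps(payload))
    if rec.M is not None:
        rec.M.to_csv(d / "stimulation_matrix.csv")
        rec.schedule.to_json(d / "schedule.json")
    if rec.config_snapshot:
        (d / "config.json").write_text(json.dumps(rec.config_snapshot, indent=2))


def load_recording(directory: str | Path) -> ExperimentRecording:
    import h5py

    d = Path(directory)
    with h5py.File(d / "voltages.h5", "r") as f:
        voltages = f["voltages"][:]
    payload = json.loads((d / "events.json").read_text())
    M = schedule = None
    if (d / "stimulation_matrix.csv").exists():
        M = StimulationMatrix.from_csv(d / "stimulation_matrix.csv")
        sched = json.loads((d / "schedule.json").read_text())
        schedule = TrialSchedule(
            trial_steps=np.asarray(sched["trial_steps"]),
            dt=sched["dt"],
            interval=sched["interval"],
            warmup=sched["warmup"],
        )
    return ExperimentRecording(
        voltages=voltages,
        spike_steps=[np.asarray(s, dtype=np.int64) for s in payload["spike_steps"]],
        schedule=schedule,
        M=M,
        observed=np.asarray(payload["observed"]),
        off_target_log=payload["off_target_log"],
        noise_sigma=payload["noise_sigma"],
        dt=payload["dt"],
        latency=LatencyModel(**payload["latency"]),
        n_cells=payload["n_cells"],
        transmission_events=payload["transmission_events"],
        failed_events=payload["failed_events"],
    )
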