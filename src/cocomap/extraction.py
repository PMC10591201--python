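"""Turn recorded voltage traces into per-trial measurement vectors y.

For fixed (deterministic) latency the response is the one-step voltage
increment at PSP arrival.  For random latency, responses are summed over a
window of three latency standard deviations past the mean, after removing
each cell's estimated passive voltage decay, so that a PSP is captured
wherever in the window its delay lands.

Trials in which the measured cell itself was force-spiked are excluded from
that cell's own measurement vector by default: the suprathreshold reset
dominates the trace and would only add noise to the decode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulator import ExperimentRecording

__all__ = [
    "MeasurementSet",
    "extract_point_responses",
    "estimate_voltage_decay",
    "extract_windowed_responses",
    "extract_responses",
]


@dataclass
class MeasurementSet:
    """Per observed neuron: trial responses y (mV) and exclusion mask."""

    y: np.ndarray  # (n_obs, T)
    excluded: np.ndarray  # (n_obs, T) bool; True = trial not used for that cell
    window_steps: int  # steps summed per trial (1 for point extraction)

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_trials(self) -> int:
        return self.y.shape[1]

    def to_csv(self, y_path, mask_path) -> None:
        pd.DataFrame(self.y.T).to_csv(y_path, index=False)
        pd.DataFrame(self.excluded.T.astype(int)).to_csv(mask_path, index=False)


def _self_trial_mask(rec: ExperimentRecording, retain_self_trials: bool) -> np.ndarray:
    """excluded[n, t] = True where observed cell n was in trial t's pattern."""
    T = rec.schedule.n_trials
    n_obs = len(rec.observed)
    if retain_self_trials:
        return np.zeros((n_obs, T), dtype=bool)
    return rec.M.entries[:T].T.astype(bool)


def extract_point_responses(
    rec: ExperimentRecording,
    measure_offset_steps: int | None = None,
    retain_self_trials: bool = False,
) -> MeasurementSet:
    """y[n, t] = v_n(trial_step + offset) - v_n(trial_step + offset - 1).

    The default offset is round(latency_mean / dt): the single step on which
    every PSP arrives when the latency jitter is zero.  Requires latency
    sd = 0 (use extract_windowed_responses otherwise).
    """
    if rec.schedule is None:
        raise ValueError("recording has no trial schedule")
    if rec.latency.sd != 0:
        raise ValueError("point extraction requires latency sd = 0")
    if measure_offset_steps is None:
        measure_offset_steps = max(1, round(rec.latency.mean / rec.dt))
    steps = rec.schedule.trial_steps + measure_offset_steps
    if steps[-1] >= rec.n_steps:
        raise ValueError("measurement window exceeds end of recorded trace")
    y = (rec.voltages[:, steps] - rec.voltages[:, steps - 1]).astype(float)
    return MeasurementSet(
        y=y,
        excluded=_self_trial_mask(rec, retain_self_trials),
        window_steps=1,
    )


def estimate_voltage_decay(
    rec: ExperimentRecording,
    windows: list[tuple[int, int]],
    v_floor: float = 1e-6,
) -> np.ndarray:
    """Per-cell passive decay ratio: mean of v(s+1)/v(s) over window steps.

    Steps adjoining a spike of the cell (the reset breaks the ratio) and
    steps with |v(s)| below ``v_floor`` are excluded.  A cell with no valid
    steps gets ratio 1.0, with a warning.
    """
    if not windows:
        raise ValueError("windows must be non-empty")
    n_obs = rec.voltages.shape[0]
    decay = np.ones(n_obs)
    step_idx = np.concatenate(
        [np.arange(a, min(b, rec.n_steps - 1)) for a, b in windows]
    )
    v = rec.voltages.astype(float)
    n_warn = 0
    for i in range(n_obs):
        cell = int(rec.observed[i])
        spikes = rec.spike_steps[cell]
        bad = np.zeros(rec.n_steps, dtype=bool)
        bad[spikes] = True
        bad[np.clip(spikes - 1, 0, None)] = True  # ratio into the spike step
        s = step_idx[~bad[step_idx] & ~bad[np.minimum(step_idx + 1, rec.n_steps - 1)]]
        s = s[np.abs(v[i, s]) >= v_floor]
        if len(s) == 0:
            n_warn += 1
            continue
        decay[i] = np.mean(v[i, s + 1] / v[i, s])
    if n_warn:
        warnings.warn(f"{n_warn} cells had no valid decay steps; ratio set to 1.0")
    return decay


def extract_windowed_responses(
    rec: ExperimentRecording,
    latency_mean: float | None = None,
    latency_sd: float | None = None,
    decay: np.ndarray | float | None = None,
    retain_self_trials: bool = False,
) -> MeasurementSet:
    """Decay-normalised windowed summation for random-latency recordings.

    The per-trial window spans W = ceil((latency_mean + 3 latency_sd) / dt)
    steps after the trial step, truncated (with a warning) so it cannot touch
    the next trial.  The response is

        y[n, t] = sum_{s = ts}^{ts + W - 1} [ v_n(s+1) - decay_n * v_n(s) ],

    which telescopes to the net voltage displacement when decay = 1, so a PSP
    contributes the same amount wherever in the window its delay lands.
    If ``decay`` is None it is estimated from the post-stimulation intervals
    of this recording.
    """
    if rec.schedule is None:
        raise ValueError("recording has no trial schedule")
    if latency_mean is None:
        latency_mean = rec.latency.mean
    if latency_sd is None:
        latency_sd = rec.latency.sd
    W = int(np.ceil((latency_mean + 3.0 * latency_sd) / rec.dt))
    W = max(W, 1)
    limit = rec.schedule.interval_steps - 1
    if W > limit:
        warnings.warn(
            f"response window of {W} steps overlaps the next trial; truncated to {limit}"
        )
        W = limit
    ts = rec.schedule.trial_steps
    if ts[-1] + W >= rec.n_steps:
        raise ValueError("measurement window exceeds end of recorded trace")
    if decay is None:
        decay = estimate_voltage_decay(rec, [(int(t), int(t) + W) for t in ts])
    decay = np.broadcast_to(np.asarray(decay, dtype=float), (rec.voltages.shape[0],))

    v = rec.voltages.astype(float)
    # increments v(s+1) - decay * v(s) for s in [ts, ts+W)
    offsets = np.arange(W)
    idx = ts[None, :] + offsets[:, None]  # (W, T)
    y = (v[:, idx + 1] - decay[:, None, None] * v[:, idx]).sum(axis=1)
    return MeasurementSet(
        y=y,
        excluded=_self_trial_mask(rec, retain_self_trials),
        window_steps=W,
    )


def extract_responses(rec: ExperimentRecording, retain_self_trials: bool = False) -> MeasurementSet:
    """Dispatch on latency jitter: point extraction when sd = 0, windowed otherwise."""
    if rec.latency.sd == 0:
        return extract_point_responses(rec, retain_self_trials=retain_self_trials)
    return extract_windowed_responses(rec, retain_self_trials=retain_self_trials)
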