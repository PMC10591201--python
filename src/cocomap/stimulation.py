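"""Stimulation protocol: the binary design matrix M and the trial schedule.

Each row of M is one stimulation pattern; entry (t, n) = 1 means observed
neuron n is force-spiked on trial t.  Trials run every ``interval`` ms
(default 50), consuming rows of M in order, without replacement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "StimulationMatrix",
    "TrialSchedule",
    "generate_stimulation_matrix",
    "schedule_trials",
]


@dataclass
class StimulationMatrix:
    entries: np.ndarray  # (T, N) uint8, values in {0, 1}
    fraction_stim: float

    @property
    def n_trials(self) -> int:
        return self.entries.shape[0]

    @property
    def n_obs(self) -> int:
        return self.entries.shape[1]

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.entries, fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, path: str | Path, fraction_stim: float = float("nan")) -> "StimulationMatrix":
        entries = np.loadtxt(path, dtype=np.uint8, delimiter=",", ndmin=2)
        return cls(entries=entries, fraction_stim=fraction_stim)


@dataclass
class TrialSchedule:
    """Simulation step index of every trial; row t of M runs at trial_steps[t]."""

    trial_steps: np.ndarray  # strictly increasing, one per row of M
    dt: float  # ms
    interval: float  # ms
    warmup: float  # ms

    @property
    def n_trials(self) -> int:
        return len(self.trial_steps)

    @property
    def interval_steps(self) -> int:
        return int(round(self.interval / self.dt))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "trial_steps": self.trial_steps.tolist(),
                    "dt": self.dt,
                    "interval": self.interval,
                    "warmup": self.warmup,
                },
                indent=2,
            )
        )


def generate_stimulation_matrix(
    n_trials: int,
    n_obs: int,
    fraction_stim: float,
    rng: np.random.Generator,
    exact_row_count: bool = False,
) -> StimulationMatrix:
    """Binary random i.i.d. Bernoulli(fraction_stim) stimulation matrix.

    With ``exact_row_count`` every row instead stimulates exactly
    round(fraction_stim * n_obs) cells at random positions, removing the
    binomial fluctuation in pattern size.
    """
    if n_trials < 1 or n_obs < 1:
        raise ValueError("n_trials and n_obs must be at least 1")
    if not 0.0 < fraction_stim <= 1.0:
        raise ValueError("fraction_stim must lie in (0, 1]")
    if exact_row_count:
        k = int(round(fraction_stim * n_obs))
        entries = np.zeros((n_trials, n_obs), dtype=np.uint8)
        for t in range(n_trials):
            entries[t, rng.choice(n_obs, size=k, replace=False)] = 1
    else:
        entries = (rng.random((n_trials, n_obs)) < fraction_stim).astype(np.uint8)
    return StimulationMatrix(entries=entries, fraction_stim=fraction_stim)


def schedule_trials(
    n_trials: int, dt: float, interval: float = 50.0, warmup: float = 0.0
) -> TrialSchedule:
    """Place trial t at step (warmup + (t + 1) * interval) / dt.

    The first trial happens one full inter-trial interval after the warm-up,
    so every trial has an identical pre-trial settling window.
    """
    for name, value in (("interval", interval), ("warmup", warmup)):
        if abs(value / dt - round(value / dt)) > 1e-9:
            raise ValueError(f"{name} must be an integer multiple of dt")
    base = int(round(warmup / dt))
    step = int(round(interval / dt))
    steps = base + step * np.arange(1, n_trials + 1)
    return TrialSchedule(trial_steps=steps, dt=dt, interval=interval, warmup=warmup)
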