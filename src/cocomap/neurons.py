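"""Izhikevich point-neuron model and per-connection latency.

The membrane model is the two-variable quadratic integrate model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

with a spike registered when v reaches 30 mV, followed by the reset
v <- c, u <- u + d.  Parameters are randomised per cell over the standard
biophysical range: excitatory cells span regular-spiking to chattering
behaviour ((a,b) = (0.02, 0.2), c = -65 + 15 r^2, d = 8 - 6 r^2), inhibitory
cells span fast-spiking to low-threshold ((a,b) = (0.02 + 0.08 r,
0.25 - 0.05 r), (c,d) = (-65, 2)), with r ~ Uniform(0,1) per cell.
Integration is single forward-Euler at dt = 0.5 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPIKE_CUTOFF",
    "NeuronParams",
    "sample_neuron_params",
    "izhikevich_step",
    "LatencyModel",
]

SPIKE_CUTOFF = 30.0  # mV


@dataclass
class NeuronParams:
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    spike_cutoff: float = SPIKE_CUTOFF

    @property
    def n(self) -> int:
        return len(self.a)

    def resting_state(self) -> tuple[np.ndarray, np.ndarray]:
        """Common initial condition: v = -65 mV, u = b v."""
        v = np.full(self.n, -65.0)
        return v, self.b * v


def sample_neuron_params(is_excitatory: np.ndarray, rng: np.random.Generator) -> NeuronParams:
    n = len(is_excitatory)
    r = rng.random(n)
    exc = np.asarray(is_excitatory, dtype=bool)
    a = np.where(exc, 0.02, 0.02 + 0.08 * r)
    b = np.where(exc, 0.2, 0.25 - 0.05 * r)
    c = np.where(exc, -65.0 + 15.0 * r**2, -65.0)
    d = np.where(exc, 8.0 - 6.0 * r**2, 2.0)
    return NeuronParams(a=a, b=b, c=c, d=d)


def izhikevich_step(
    v: np.ndarray,
    u: np.ndarray,
    params: NeuronParams,
    input_current: np.ndarray | float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One forward-Euler step; returns (v, u, spiked) with resets applied.

    ``spiked`` marks cells whose voltage reached the cutoff during the step;
    their returned state is the post-reset (c, u + d).
    """
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + input_current
    v_new = v + dt * dv
    u_new = u + dt * params.a * (params.b * v - u)
    spiked = v_new >= params.spike_cutoff
    v_out = np.where(spiked, params.c, v_new)
    u_out = np.where(spiked, u_new + params.d, u_new)
    return v_out, u_out, spiked


@dataclass
class LatencyModel:
    """Per-connection propagation delay: Normal(mean, sd) ms, rounded to the
    nearest time step, clipped at one step, frozen for the whole run."""

    mean: float = 1.0  # ms
    sd: float = 0.0  # ms

    def draw_delays(self, size: int, dt: float, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            delays = np.full(size, round(self.mean / dt))
        else:
            delays = np.rint(rng.normal(self.mean, self.sd, size) / dt)
        return np.maximum(delays, 1).astype(np.int64)
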