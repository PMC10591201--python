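"""Experiment configuration.

A single flat configuration object drives the whole pipeline: network
construction, stimulation protocol, biophysical simulation, response
extraction and decoding.  Config files (YAML or JSON) use the canonical
experiment-parameter names (``TotalCells``, ``N_obsCell``, ``sparsity``,
``fractionStim``, ``offTargetProb``, ``synFailProb``, ``latency_mean``,
``latency_sd``, ``WSbeta``, ``lambda``) so that a run's config snapshot is
directly comparable with published parameter tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["ExperimentConfig", "PARAM_NAME_MAP"]

#: map from the canonical config-file key to the attribute name
PARAM_NAME_MAP: dict[str, str] = {
    "TotalCells": "total_cells",
    "N_obsCell": "n_obs",
    "sparsity": "sparsity",
    "fractionStim": "fraction_stim",
    "offTargetProb": "off_target_prob",
    "synFailProb": "syn_fail_prob",
    "latency_mean": "latency_mean",
    "latency_sd": "latency_sd",
    "WSbeta": "ws_beta",
    "lambda": "lam",
    # extra keys, not part of the canonical table but accepted in files
    "topology": "topology",
    "n_trials": "n_trials",
    "dt": "dt",
    "trial_interval": "trial_interval",
    "warmup": "warmup",
    "target_rate": "target_rate",
    "excitatory_fraction": "excitatory_fraction",
    "w_exc_max": "w_exc_max",
    "w_inh_max": "w_inh_max",
    "exact_row_count": "exact_row_count",
    "retain_self_trials": "retain_self_trials",
}

_ATTR_TO_KEY = {v: k for k, v in PARAM_NAME_MAP.items()}


@dataclass
class ExperimentConfig:
    """Parameters of one simulated mapping experiment.

    Defaults are the base operating point of the study design: a 1,000-cell
    recurrent network with 200 observed cells, 10% connection probability,
    10% of observed cells stimulated per trial, no synaptic failure or
    off-target stimulation, 1 ms fixed propagation latency and lambda=0.25.
    """

    total_cells: int = 1000
    n_obs: int = 200
    sparsity: float = 0.1
    fraction_stim: float = 0.1
    off_target_prob: float = 0.0
    syn_fail_prob: float = 0.0
    latency_mean: float = 1.0  # ms
    latency_sd: float = 0.0  # ms
    ws_beta: float = 1.0
    lam: float = 0.25

    topology: str = "uniform"  # "uniform" | "watts_strogatz"
    n_trials: int = 100
    dt: float = 0.5  # ms
    trial_interval: float = 50.0  # ms
    warmup: float = 500.0  # ms before the first trial
    target_rate: float = 0.2  # Hz, spontaneous-rate calibration target
    excitatory_fraction: float = 0.8
    # Maximum synaptic weight magnitudes (injected-current increments per
    # presynaptic spike); magnitudes are Uniform(0, max].  See docs/methods.md
    # for how these scales were anchored.
    w_exc_max: float = 8.0
    w_inh_max: float = 16.0
    exact_row_count: bool = False
    retain_self_trials: bool = False

    def __post_init__(self) -> None:
        if self.total_cells <= 0:
            raise ValueError("total_cells must be positive")
        if not 0 <= self.sparsity <= 1:
            raise ValueError("sparsity must lie in [0, 1]")
        if self.topology not in ("uniform", "watts_strogatz"):
            raise ValueError(f"unknown topology {self.topology!r}")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        """Flat dict keyed by the canonical parameter names."""
        out = {}
        for f in dataclasses.fields(self):
            out[_ATTR_TO_KEY.get(f.name, f.name)] = getattr(self, f.name)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = {}
        for key, value in d.items():
            attr = PARAM_NAME_MAP.get(key, key)
            if attr not in {f.name for f in dataclasses.fields(cls)}:
                raise KeyError(f"unknown configuration key {key!r}")
            kwargs[attr] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))

    def replace(self, **kwargs) -> "ExperimentConfig":
        return dataclasses.replace(self, **kwargs)
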