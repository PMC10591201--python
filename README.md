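# cocomap

Compressed connectivity mapping of simulated spiking networks.

Mapping synaptic connectivity by stimulating one candidate presynaptic
neuron per trial needs at least as many trials as there are neurons.  When
connectivity is sparse — as in cortex, where roughly 10% of ordered pairs
are connected — compressive sensing lets an experiment stimulate *random
subsets* of neurons in parallel and recover each recorded neuron's incoming
weights from far fewer trials.  `cocomap` is a simulation testbed for that
experimental design: it builds a recurrent excitatory/inhibitory network of
Izhikevich neurons with known ground-truth weights, simulates patterned
stimulation with realistic nuisances (background noise calibrated to a
0.2 Hz spontaneous rate, partial observability, synaptic failure,
propagation latency, off-target stimulation, small-world topology), decodes
the weights by sparse recovery, and scores the reconstruction against the
ground truth.

## Model

Each observed neuron n obeys the linear measurement model

    y_n = M x_n + e_n ,

where M ∈ {0,1}^(T×N) marks which of the N observed cells were force-spiked
on each of T trials, x_n is the unknown presynaptic weight vector, and e_n
collects background-activity and membrane noise (both emerge from the
biophysical simulation rather than being injected).  Weights are estimated
per neuron by the penalised form

    min_x  λ‖x‖₁ + ½‖y − Mx‖₂²            (λ = 0.25 by default)

or by basis pursuit (min ‖x‖₁ s.t. ‖y − Mx‖₂ ≤ ε), optionally with
cell-type sign constraints x(E) ≥ 0, x(I) ≤ 0.  The standard flow solves
unconstrained, classifies each presynaptic cell from the sign of its summed
outgoing estimates, and re-solves with the inferred constraints.  Estimates
above 1% of the strongest recovered weight are declared connections, and
the map is scored by recall = TP/(TP+FN) and precision = TP/(TP+FP) over
ordered observed pairs.

See `docs/methods.md` for the full model description, parameter defaults
and numerical choices.

## Worked example

Write a small configuration (keys use the canonical experiment-parameter
names) and run one end-to-end experiment:

```
$ cat demo.yaml
TotalCells: 300
N_obsCell: 60
sparsity: 0.1
fractionStim: 0.15
n_trials: 40

$ cocomap run --config demo.yaml --seed 7 --out demo_run
{
  "seed": 7,
  "mode": "unconstrained",
  "recall": 0.8802228412256268,
  "precision": 0.1961514587212911,
  "mean_firing_rate_hz": 0.792156862745098,
  "noise_sigma": 1.875
}
```

The run calibrated the background current to σ ≈ 1.88 (0.2 Hz spontaneous
rate), simulated 40 stimulation trials of ~9 cells each, and recovered 88%
of the true connections among the 60 observed cells — using 40 trials where
one-cell-per-trial mapping would need 60.  Precision is low at this trial
count because the under-determined solve fits part of the background noise;
it improves with more trials or with the sign-constrained flow
(`--mode inferred`).  The output directory holds the estimated and true
weight matrices, the thresholded adjacency, inferred cell types and
diagnostics.

Parameter sweeps and re-scoring exported matrices:

```
cocomap sweep --param synFailProb --grid 0,0.25,0.5 --seeds 5 \
        --config demo.yaml --out sweep_out
cocomap eval --estimate demo_run/estimated_weights.csv \
        --truth demo_run/true_weights.csv
```

The same functionality is available as a library:

```python
from cocomap import ExperimentConfig, run_experiment
res = run_experiment(ExperimentConfig(), seed=1, mode="inferred_sign_constrained")
print(res.recall, res.precision)
```

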