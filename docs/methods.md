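# Methods

`cocomap` simulates patterned multi-cell stimulation experiments on a
recurrent spiking network and reconstructs each observed neuron's incoming
synaptic weights from the stimulation patterns and the evoked membrane
responses, using L1-regularised sparse recovery.  This note documents the
model, its parameters and defaults, the numerical choices, and what the
synthetic experiments do and do not establish about real recordings.

## Measurement model

For each observed (putative postsynaptic) neuron n, the experiment produces

    y_n = M x_n + e_n,        e_n = e_sf + e_v,

where M is the T x N binary stimulation matrix (row t marks which of the N
observed cells were force-spiked on trial t), x_n is the unknown vector of
presynaptic weights onto n, and the error term combines spontaneous/evoked
background firing (e_sf) and membrane noise (e_v).  Neither error component
is injected into y directly: both arise mechanistically inside the
biophysical simulation, and the decoder never sees them separately.

Weights are estimated per neuron by

    min_x  lambda ||x||_1 + 1/2 ||y - M x||_2^2          (penalised form)

or  min_x ||x||_1  s.t.  ||y - M x||_2 <= epsilon        (basis pursuit),

optionally with cell-type sign constraints x(E) >= 0, x(I) <= 0.  Entries
above 1% of the strongest recovered weight (global maximum by default) are
declared connections.  The base reconstruction flow runs the unconstrained
solve, classifies each presynaptic cell as excitatory or inhibitory by the
sign of its summed outgoing estimated weights (zero sums tie to excitatory,
the majority class), and re-solves with the inferred sign constraints, so
every presynaptic column of the final estimate is sign-pure.

## Network model

- 1,000 Izhikevich neurons by default, 80% excitatory / 20% inhibitory.
  Parameters randomised per cell over the standard biophysical range:
  excitatory (a,b) = (0.02, 0.2), c = -65 + 15 r^2, d = 8 - 6 r^2
  (regular-spiking to chattering); inhibitory (a,b) = (0.02 + 0.08 r,
  0.25 - 0.05 r), (c,d) = (-65, 2) (fast-spiking to low-threshold);
  r ~ U(0,1) per cell.
- Connectivity: every ordered pair connected independently with probability
  `sparsity` (default 0.1), or a directed Watts–Strogatz construction
  (ring lattice of out-degree k = nearest even integer to
  sparsity*(n-1); each edge's target endpoint rewired with probability
  `WSbeta`, resampling to avoid self-loops and duplicates).  No autapses.
- Weights: sign fixed by the presynaptic type, magnitude U(0, w_max] with
  w_exc_max = 8 and w_inh_max = 16 current units (2:1
  inhibitory/excitatory strength).  On the scale choice, see "Operating
  regime" below.
- Observed subset: uniform sample without replacement (default 200 cells).

## Simulation

Forward Euler at dt = 0.5 ms:

    v += dt (0.04 v^2 + 5 v + 140 - u + I),   u += dt a (b v_old - u),

spike at v >= 30 mV, reset (c, u + d).  The input current I sums (i) a
zero-mean Gaussian term drawn independently per neuron and step with s.d.
`noise_sigma`, and (ii) delta-current synaptic inputs: a presynaptic spike
of cell j at step t adds w_ij to cell i's input at step t + delay_ij.
Delays are Normal(latency_mean, latency_sd) in ms, rounded to steps,
clipped at one step, and frozen per connection for the whole run.  Each
transmission event is independently zeroed with probability `synFailProb`.

Trials run every 50 ms after a 500 ms warm-up, consuming rows of M in
order.  Stimulated cells are forced to spike by setting v to the cutoff
(the stimulation threshold is treated as known).  With probability
`offTargetProb` per trial one additional cell, drawn uniformly outside the
stimulated set (observed or not), is also forced to spike; this is logged
but never reflected in M, emulating off-target photostimulation.

Background-noise calibration bisects `noise_sigma` until a stimulation-free
run yields a network-mean spontaneous rate of 0.2 Hz.  The search uses 30 s
evaluation runs, a [0, 20] starting bracket (doubled if needed), at most 20
iterations, and a 5% relative tolerance — tighter than the 10% band used to
assess the resulting rate, so that calibration error cannot consume the
assessment band.  The rate-vs-sigma curve is extremely steep near 0.2 Hz
(rare-event crossings of a 12–20 mV effective barrier), so the calibrated
sigma is pinned near 2.0 current-units for the base network.

## Response extraction

With deterministic latency, the response is the one-step voltage increment
at PSP arrival: y[n,t] = v_n(ts + o) - v_n(ts + o - 1) with offset
o = round(latency_mean/dt) (the printed description "the following time
step" coincides with this when the latency is one step; the offset is
configurable).  With latency jitter, responses are summed over a window of
ceil((latency_mean + 3 latency_sd)/dt) steps with per-cell decay
normalisation: y = sum_s [v(s+1) - rho_n v(s)], where rho_n is the mean of
raw v(t+1)/v(t) ratios over post-stimulation intervals, excluding steps
adjoining a spike and steps with |v| < 1e-6 mV.  With rho = 1 the sum
telescopes to the net displacement, so a PSP contributes identically
wherever in the window its delay lands.

Trials in which the measured neuron itself was force-spiked are excluded
from that neuron's own system by default (the suprathreshold reset masks
the subthreshold response); `retain_self_trials` keeps them, in which case
the reset response loads onto the discarded diagonal.

## Solvers

The penalised problem is solved by coordinate descent (scikit-learn's
Lasso, duality-gap tolerance 1e-8, no intercept; lambda maps to
alpha = lambda/T under the 1/T scaling of that implementation).  The
sign-constrained problem reduces exactly to a positive lasso: with
s in {+1,-1} per presynaptic cell, z = s*x >= 0 makes ||x||_1 linear, so
solving the positive lasso on M diag(s) and mapping back attains the
constrained optimum.  Basis pursuit with epsilon = 0 is the standard linear
program (HiGHS); for epsilon > 0 the solution is found by root-finding on
lambda along the lasso Pareto frontier, where the residual norm is monotone
in lambda; infeasible epsilon (below the least-squares residual floor) is
reported as a decode failure.  The unsquared-loss variant
lambda ||x||_1 + 1/2 ||y - Mx||_2 is available via fixed-point iteration on
the effective penalty lambda' = lambda ||r||_2.

lambda defaults to 0.25 applied to raw responses in mV, with no rescaling
of M or y, so a single lambda serves all conditions.

## Evaluation

Recall = TP/(TP+FN) and precision = TP/(TP+FP) over ordered observed pairs
(pre != post); the decoder cannot see unobserved cells, so they are outside
the evaluation universe.  Zero-denominator metrics are reported as missing
(NaN), never as 0 or 1.  Per-postsynaptic-cell metrics restrict the counts
to each row.

## Operating regime and the weight scale

The weight magnitudes are the one quantity the model family does not pin
down, and they control everything through a single ratio: PSP amplitude
versus measurement noise.  Two constraints bracket the choice:

1. The 0.2 Hz calibration fixes the per-step Gaussian voltage noise near
   1 mV (stationary fluctuations ~1.4 mV): quieter noise cannot produce the
   target spontaneous rate in this neuron model.
2. Stimulating ~20 cells per trial delivers coincident EPSP volleys
   (Binomial fan-in, mean ~2 EPSPs per target).  Once single EPSPs reach
   ~10 mV, a few percent of cells fire on every trial and the cascade
   ignites self-sustained 50–80 Hz network activity whose background PSPs
   then dominate the measurement noise; reconstruction degrades and seed
   variance grows.  The ignition boundary moves down as the network grows
   (at fixed sparsity the cascade branching ratio scales with cell count),
   so the scale must keep the *largest* study network quiescent, not just
   the base one: U(0,10] excitatory weights are quiescent at 1,000 cells
   but intermittently re-enter the evoked regime at 2,000.  The defaults
   therefore sit at the largest scale reliably quiescent across the study
   sizes: w_exc_max = 8 (4 mV peak EPSP), w_inh_max = 16.  Very large
   dense networks (4,000 cells at 10%+ density) can still approach the
   boundary; the run's mean firing rate, reported with every result, is
   the regime diagnostic.

Consequences worth knowing: at T = 100 trials the per-coefficient noise is
roughly 0.3–0.5 mV, so with uniform weight magnitudes the smallest-weight
tail of true connections (below ~10–15% of the maximum) is not reliably
recovered, capping recall near the low-to-mid-80s percent; recall climbs
above 90% by T = 200 and reaches ~97% in overdetermined designs (T = 1,000),
even with 50% synaptic failure.  Precision at lambda = 0.25 is
noise-limited (the underdetermined T=100 solve fits part of the noise), and
the cell-type constraint step recovers a substantial part of it.  Note that
sign constraints trade a little *unsigned* recall for that precision:
the unconstrained decode earns recall credit for true connections detected
with the wrong sign, which the constraints zero out, so under heavy
synaptic failure constrained recall can sit a few points below
unconstrained while precision roughly doubles and F1 rises sharply.

## What the generator does and does not emulate

Emulated: recurrent dynamics with memory across trials, heterogeneous cell
parameters, partial observability (unobserved cells contribute real
background PSPs), per-event synaptic failure, frozen per-connection
latency, off-target stimulation, and small-world topology.

Not emulated: voltage-indicator kinetics and shot noise (responses are read
from the model voltage directly), nonlinear synaptic integration such as
shunting inhibition (inputs are delta currents, additive by construction),
laser-power misestimation (forced spikes always succeed), distance-dependent
or heavy-tailed connectivity, and state-dependent (up/down) background
statistics.  Passing tests therefore demonstrate correct recovery under
additive, linear mixing with realistic network noise — the regime the
method itself assumes — not robustness to indicator physics or nonlinear
dendritic integration.

## Numerical choices and degenerate inputs

- Integration is single-step forward Euler (no sub-stepping), matching the
  0.5 ms update of the adopted model; voltages are recorded as the cutoff
  value on spike steps, then the reset state.
- Delays round half-to-even via `np.rint` and clip at one step; a zero-
  jitter latency model gives every connection round(latency_mean/dt) steps.
- Cell-type counts round half-up; `select_observed_subset` rejects empty
  subsets; Watts–Strogatz construction rejects densities with ring degree
  below 2, naming the minimum.
- All-zero estimated weight matrices threshold to an empty adjacency
  (no division by the zero maximum).
- Every random draw flows from an explicit `numpy` Generator; identical
  seeds reproduce networks, stimulation patterns, traces and
  reconstructions bit for bit.  Sweeps derive per-row seeds from
  `SeedSequence([seed0, grid_index, seed_index])`, so any execution order
  yields identical tables.

## Benchmarks

`scripts/acceptance.py` recomputes four headline quantities end to end
(see the README for how to run it): base-configuration recall at T = 100
(5 seeds), recall with 10% observability (2,000-cell network, 5 seeds),
the calibrated spontaneous rate measured on an independent 120 s run, and
recall under 50% synaptic failure with T = 1,000 (5 seeds).  Calibration
runs once per configuration and its sigma is reused across that
configuration's seeds.  On one CPU the script takes roughly 10 minutes;
the problem sizes are the full study sizes (no scaling down).
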