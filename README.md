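# bgloops

Firing-rate simulation of dopamine-modulated basal-ganglia selection loops,
and of a three-loop embodied agent that explores a button-and-light board
under intrinsic motivation.

## What this is for

The basal ganglia are widely modeled as a selection device: parallel
channels of a cortex → striatum → SNr/GPi → thalamus → cortex loop compete,
and suppressing one channel of the tonically active output nucleus releases
("gates") the matching thalamo-cortical channel.  Striatal dopamine sets the
gain of this competition.  This package implements that hypothesis as a
leaky-integrator rate model

    tau_g du_j/dt = -u_j + b_j + (eps_g + lam_g d) * sum_i w_ji y_i,
    y_j = [tanh(alpha_g (u_j - theta_g))]^+

with the multiplicative dopamine term `(eps + lam*d)` attached to the D1
striatum, and uses it to study how one mechanism produces several of
dopamine's putative functions:

* **operating regimes** — as tonic dopamine rises, a loop moves from weak
  selection through enhanced (argmax-correct, switchable) discrimination to
  maintenance and multiple-channel activation;
* **vigor** — two noise-driven loops (gaze and arm action) complete more
  joint actions as tonic dopamine rises;
* **intrinsically motivated learning** — a three-loop agent (manipulation,
  attention, goal; striatal sensitivities `lam` = 1.5, 2.5, 1.0) explores a
  board with three buttons and three transparent boxes.  Novelty
  (hippocampal habituation, 1.0 → 0.1 in ~2 min) raises tonic dopamine;
  light flashes caused by pressing buttons fire phasic bursts that gate a
  Hebbian rule `dw = eta g y (w_max - w) [d - zeta]^+`, building forward
  and inverse models between the loops and a prefrontal predictor that
  cancels bursts for self-caused outcomes; a visible reward then recalls
  the learned (attend-button, press) pair.

Everything is pure Python on numpy/pandas; runs are deterministic given a
seed.

## A worked example

```
python examples/single_loop_regimes.py
```

runs the canonical six-interval, three-channel input schedule at four tonic
dopamine levels (+N % means `d = 1 + N/100`) and prints the regime label of
every 60 s interval:

```
DA +  15%: ['weak', 'weak', 'weak', 'weak', 'enhanced', 'weak']
DA +  20%: ['weak', 'enhanced', 'enhanced', 'weak', 'enhanced', 'enhanced']
DA +  30%: ['weak', 'enhanced', 'maintenance', 'maintenance', 'enhanced', 'maintenance']
DA +  50%: ['multiple', 'multiple', 'maintenance', 'maintenance', 'weak', 'maintenance']
```

At +15 % only the strong, sparse interval-5 vector is selected.  At +20 %
the loop tracks the input argmax and switches when the input changes.  At
+30 % a previously selected channel persists long after its input has been
demoted (maintenance), and at +50 % the near-tied strong pair of interval 1
drives two inner-layer channels above threshold simultaneously — only
lateral inhibition keeps the external layer single-valued.

Other examples: `examples/habituation.py` (novelty decay 1.0 → 0.1 and its
dopamine re-amplification), `examples/vigor.py` (completed-action counts at
baseline/+20 %/+40 %), `examples/board_task.py` (a shortened board-task run
with the learned-association report).

A thin CLI wraps the same protocols:
`bgloops sweep|vigor|simulate-loop|board-task|report --help`.

## Layout

```
src/bgloops/core.py        leaky-integrator networks, noise, integration
src/bgloops/loops.py       the prototypical loop, presets, selection readout
src/bgloops/neuromod.py    dopamine circuit and hippocampal habituation
src/bgloops/plasticity.py  dopamine-gated Hebbian rule, agent wiring
src/bgloops/board.py       abstract mechatronic board environment
src/bgloops/protocols.py   input schedules, DA sweep, vigor experiment
src/bgloops/agent.py       three-loop agent, board task, behavior modes
src/bgloops/config.py      YAML run configuration with validation
src/bgloops/io.py          CSV/JSON/HDF5 run serialization
src/bgloops/cli.py         command-line entry points
docs/methods.md            model description, calibration, limitations
```
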