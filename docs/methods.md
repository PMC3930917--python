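# Model and methods

## The selection loop

The package simulates striato-cortical selection loops as firing-rate
networks of leaky-integrator units.  A unit `j` in group `g` obeys

    tau_g du_j/dt = -u_j + b_j + (eps_g + lam_g * d) * sum_i w_ji y_i
    y_j = [tanh(alpha_g (u_j - theta_g))]^+

where `d` is the instantaneous dopamine level.  The multiplicative gain
`eps + lam*d` is the only site of dopamine action in a loop and is attached
to the D1 striatum (and, in the agent, the hippocampal field); all other
groups keep `eps = 1, lam = 0`.  Activations are bounded in `[0, 1)`;
potentials may go negative (the positive-part transfer clips them).

One loop wires a two-layer cortex, D1 striatum, STN, SNr/GPi and thalamus:
the direct pathway (cortex → striatum → SNr, channel-parallel, net
disinhibitory) competes with the hyperdirect pathway (cortex → STN → SNr,
diffuse excitatory).  The SNr tonically inhibits the thalamus; suppressing
one SNr channel releases the matching thalamo-cortical channel, which
re-excites the cortex — a positive feedback that converts graded input
differences into discrete selections.  The external cortical layer is a
thresholded copy of the inner layer (threshold `theta_2`) with optional
lateral inhibition; a channel counts as *selected* while its external unit
is above zero.

Raising tonic dopamine tilts the striatum/STN competition toward the
striatum and moves the loop through three regimes: *weak selection* (only
strong, sparse inputs are selected), *enhanced discrimination*
(argmax-correct selection that follows input changes), and *maintenance*
(a selected channel survives demotion of its input; at still higher
dopamine several inner-layer channels can exceed threshold at once, and
only lateral inhibition keeps the external layer single-valued).

## Integration and noise

Fixed-step forward Euler at `dt = 0.01 s` (the fastest stated process, a
0.5 s foveation, spans 50 steps; `dt` must stay below the smallest group
time constant, and the integrator refuses unstable steps).  Thalamic noise
is a per-unit uniform draw, centred and scaled by the per-loop noise
magnitude, smoothed by a first-order filter.  The decay counts of the noise
table are read as milliseconds, giving smoothing time constants of 1 s
(attention) and 2 s (arm): with slower noise the loops could not try all
three actions on one cue within a single exploration bout, nor produce
selection dwell times commensurate with the 2 s completion criterion.  The
magnitude-to-drive conversion (`noise_gain`) is a calibrated constant.  The
smoothed trace is a random walk whose excursions occasionally overcome SNr
inhibition — the model's source of spontaneous exploration.  All draws come
from named, seeded streams: identical seeds give bit-identical
trajectories.

## Parameters

The per-loop essentials (channel counts, striatal `lam`, the two cortical
thresholds, lateral inhibition, thalamic noise magnitude and decay) are
fixed model constants:

| parameter | attention | arm action | goal |
|---|---|---|---|
| channels | 6 | 3 | 6 |
| striatal lam | 2.5 | 1.5 | 1.0 |
| theta layer 1 | 0.4 | 0.6 | 0.1 |
| theta layer 2 | 0.8 | 0.8 | 0.6 |
| lateral inhibition | 2 | 0.2 | 0 |
| thalamic noise | 20 | 30 | 0 |
| noise decay | 1000 | 2000 | 0 |

The ordering of `lam` (attention > arm > goal) implements the differential
dopamine sensitivity of the striatal territories: the attention loop locks
on first as dopamine rises, the motor loop wakes into enhanced
discrimination at the same level, and the goal loop requires the most
dopamine to activate at all.

Every remaining weight, slope, basal level and time constant is a
calibrated default (the loops' complete parameter set is not part of the
published essentials).  Calibration was done once, against the printed
behavioral constraints — sub-selectivity of the test input at baseline
dopamine, the appearance of each regime in its stated dopamine band, and
the vigor counts — and then frozen in `bgloops.loops.LoopSpec`; every run
reads the same defaults.  The single-loop test configuration (`"single"`)
and the embodied presets carry their own calibrated unlisted values;
Table-level essentials are never altered.

## Dopamine circuit

One unit stands in for the joint VTA/SNc population.  Its baseline `d0 = 1`
(dopamine conditions "+N %" mean `d = d0 (1 + N/100)`) is maintained
against a tonically active inhibitory interneuron and tonic inhibition from
the ventral loop's output nucleus.  Four controllers steer it:

* **Superior colliculus.**  A luminance change (light flash) injects a
  decaying transient of calibrated amplitude 0.8 and decay 0.7 s: a phasic
  burst peaking near `d = 1.8`–2.0 depending on the tonic level.
* **Prefrontal predictor.**  A Hebbian-trained inhibitory projection from
  the inner prefrontal layer onto the SC pathway; it subtracts from the
  burst amplitude before onset, so a fully predicted outcome produces no
  burst.
* **Hippocampus → NAcc → SNr.**  The novelty response of the fixated cue
  excites the ventral striatum, which suppresses the ventral SNr and
  disinhibits the dopamine unit: fixating a novel cue raises tonic
  dopamine by up to ~25 % within seconds, and the rise fades as the cue
  habituates.
* **Amygdala.**  A visible reward inhibits the tonic interneuron,
  sustaining an elevated tonic level while the reward is perceived.

The hippocampal field holds one unit per spatial cue.  Its response decays
exponentially from 1.0 toward a floor of 0.1 while the cue is fixated, with
`tau_hab = 120 / ln(180) ≈ 23.1 s`, chosen so the response sits within 5 %
of the floor after 120 s of exposure.  The emitted signal is scaled by the
field's own dopamine gain (`eps = 0.1, lam = 0.9`), so bursts strongly
re-amplify habituated responses — the coupling that sustains a pressing
bout across its repetitions.  There is no spontaneous recovery within a run
(`recovery_tau` exposes it, default off).

## Plasticity

The dopamine-gated Hebbian rule

    dw_ji = eta * g_j * y_i * (w_max - w_ji) * [d - zeta]^+ * dt

trains five connections of the agent: two forward models
(PMC_ext → PFC_inner, FEF_ext → PFC_inner), two inverse models
(PFC_ext → PMC_inner, PFC_ext → FEF_inner) and the predictor
(PFC_inner → DA interneuron).  Weights are non-negative, non-decreasing and
soft-bounded by `w_max`; the increment is scaled by `dt` so learning speed
is independent of the integration step.

The cortico-cortical threshold coefficient is 0.2.  It must sit above
*every* tonic excursion: the agent's novelty- and reward-driven tonic
dopamine reaches ≈ 1.25 (the `tonic_ceiling`), so the absolute gate is
`1.25 + 0.2 = 1.45`.  Burst peaks (≈ 1.8–2.0 when unpredicted) clear it;
tonic excursions never do.  The predictor coefficient 0.00008 is ambiguous
between a threshold and a rate; both readings are implemented
(`predictor_coeff_role`), defaulting to the rate reading with the same
burst-level gate, paired with a large weight ceiling calibrated so that
roughly five to ten flash repetitions suppress the burst.  `eta_ctx` is
calibrated so the same handful of bursts saturates an association.

The two forward models combine *conjunctively* (the goal layer receives the
geometric mean of the action-driven and gaze-driven forward drives): an
outcome is anticipated only when both the action and its target match.
With an additive combination, a saturated press→outcome weight alone would
activate the outcome channel, so the predictor would generalize across
buttons and block learning of the remaining associations.

## Board environment

The board abstracts the robot-and-device setup to its causal skeleton: six
cues (three buttons, three transparent boxes, button *i* wired to box *i*),
three arm actions (press, grab, wipe — the latter two are dummies), 0.5 s
foveation, action durations drawn uniformly in [2, 3] s per initiation
(replacing posture-dependent variability), 1 s flashes emitted exactly by
completed presses on buttons, and a relocatable visible reward.  Changing
either selection mid-action aborts it.  A box closes again when its flash
ends (configurable), so unpredicted presses keep producing flashes.  For
counting, an action is *completed* when both loops jointly hold one
(action, gaze) pair for 2 s; repetitions re-count.  The physical press uses
the drawn 2–3 s duration; both notions are logged.

## The task loop

In the embodied task the six visible cues provide a small constant
bottom-up salience to the attention loop, and the manipulable objects a
matching affordance drive to the motor loop (`w_cue_salience`,
`w_action_salience`); the vigor test, by contrast, runs the loops with no
external input at all, as specified.  During free exploration the attention
loop wanders under thalamic noise and this salience.
Fixating a novel cue raises tonic dopamine, which locks attention on the
cue (maintenance) and wakes the motor loop (enhanced discrimination): the
agent tries its actions on the fixated cue.  A press on a button flashes
the matched box; the flash captures gaze toward the box, drives the box's
goal channel, and fires a dopamine burst.  Inside the burst window the
Hebbian rule binds the flashed box's goal channel to the (press, button)
pair and grows the predictor; after several repetitions the burst is
cancelled, dopamine stays low, and exploration resumes.  In the reward
phase, seeing the reward through a box wall drives the amygdala and the
box's goal channel; the matured inverse models bias attention to the
matched button and the motor loop to press — the learned, goal-directed
route to opening the box.

## Numerical choices and degenerate inputs

* `dt` must satisfy `dt < min(tau)`; violations raise immediately, as do
  NaN or overflowing potentials.
* `tanh` saturates to 1.0 in floating point; the transfer clips to the
  largest double below 1 to keep the open bound exact.
* Exactly tied channel inputs are not broken at the dynamics level:
  symmetric inputs may produce symmetric (multi-channel) states, and only
  configured noise breaks them.  The ventral loop has no lateral
  inhibition, so multi-goal states are reported, not resolved.
* An all-zero input schedule is legal and classifies as weak at every
  dopamine level.

## What the generated inputs do and do not emulate

The canonical test schedule is generated, not printed: six 60 s
piecewise-constant intervals on three channels whose values are placed at
calibrated distances from the loop's engagement thresholds (a near-tied
strong pair, cold-started moderate winners, a dense interval, one strong
sparse vector), with seeded jitter on the sub-threshold entries.  It
reproduces the *structure* of the single-loop experiment — which regimes
appear at which dopamine bands — not any specific published trace.
Similarly, the board task reproduces the causal chain of the embodied
experiment, not robot kinematics or vision.  Engagement transients in this
parameterization are faster than in the published traces (selection
ignites within seconds rather than tens of seconds); the dopamine ordering
of onset latencies is preserved, the absolute latency scale is not.

## Known limitations

* The indirect pathway (D2 striatum, GPe) and the re-entrant
  thalamo-cortical circuitry are omitted by design; behavior below baseline
  dopamine (depletion) is outside the model's validated range.
* The vigor counts depend on the noise-conversion convention.  With the
  frozen calibration the means are ≈ 2.9 (baseline), ≈ 27.8 (+20 %) and
  ≈ 53 (+40 %) completed actions per 6-minute run against the published
  0.6 / 28.2 / 91.8: the ordering and the more-than-tenfold
  baseline-to-+40 % separation are robust, the +20 % mean is essentially
  exact, but the baseline mean reads high and the +40 % mean low.  The
  dopamine-gain ratio between conditions (bounded by the fixed striatal
  `lam`) limits how strongly noise-driven ignition and survival can differ
  across conditions in this parameterization.
* On the board task, individual associations are typically learned within
  3–9 minutes of their first press, but full three-button coverage within
  12 minutes depends on the exploration path and is reached only in a
  minority of seeds; goal-directed recall of the correct button after a
  reward relocation is likewise path-dependent rather than near-certain.
* Cortico-striatal plasticity is absent: all learning is cortico-cortical
  or prefronto-dopaminergic.
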