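"""Experiment protocols: single-loop DA sweep, vigor test, input schedules.

Three protocols probe the dopamine-dependent operating regimes of the
selection loop:

* ``single_loop_sweep`` runs one loop over a fixed six-interval input
  schedule at several tonic dopamine levels and classifies each interval as
  weak / enhanced / maintenance / multiple;
* ``generate_input_schedule`` builds the canonical three-channel schedule —
  piecewise-constant saliencies whose interval structure (a near-tied strong
  pair, cold-started moderate winners, a dense interval, one strong sparse
  vector) places each dopamine level in a distinct regime;
* ``vigor_experiment`` runs the noise-driven attention + arm-action loop
  pair with no external input and counts completed actions (joint 2 s
  maintenance of both selections), the model's analogue of response vigor.

Dopamine conditions are expressed as percent offsets of the tonic baseline:
``d = d0 * (1 + pct / 100)`` with ``d0 = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import TimeSeries
from .loops import (InputSchedule, Loop, active_channel, build_loop,
                    inject_input, loop_spec, read_selection)

__all__ = [
    "D_BASELINE",
    "da_level",
    "generate_input_schedule",
    "IntervalClassification",
    "RegimeReport",
    "single_loop_sweep",
    "VigorResult",
    "vigor_experiment",
    "count_joint_completions",
]

D_BASELINE = 1.0

#: Canonical six-interval input pattern (rows: 60 s intervals, cols: channels).
#: Interval 1: near-tied strong pair (multiple activation at very high DA);
#: intervals 2/3: cold-started moderate winner then a demoting switch
#: (enhanced discrimination vs maintenance); interval 4: dense (suppressed
#: by the hyperdirect pathway); interval 5: strong sparse (the one vector
#: selectable at low DA); interval 6: moderate winner again.
_CANONICAL = np.array(
    [
        [0.880, 0.879, 0.20],
        [0.28, 0.40, 0.818],
        [0.818, 0.40, 0.30],
        [0.84, 0.72, 0.70],
        [0.08, 0.86, 0.04],
        [0.30, 0.40, 0.818],
    ]
)
#: Entries below this are open to seeded jitter; larger values sit at
#: calibrated distances from the loop's engagement thresholds.
_JITTER_BELOW = 0.5
_BASELINE_CAP = 0.885  # strongest allowed component: sub-selective at d0


def da_level(percent: float) -> float:
    """Tonic DA level for a percent offset: ``d0 * (1 + percent/100)``."""
    return D_BASELINE * (1.0 + percent / 100.0)


def generate_input_schedule(
    seed: int = 0,
    interval: float = 60.0,
    max_value: Optional[float] = None,
    jitter: float = 0.02,
) -> InputSchedule:
    """Deterministic canonical schedule with seeded sub-threshold jitter.

    The construction guarantees: six 60 s intervals on three channels;
    sub-selectivity at baseline DA (no component above ``_BASELINE_CAP``);
    one interval with a near-tied strong pair (both > 0.7, gap < 0.05);
    varying sparseness and mean across intervals.  ``max_value=0`` yields
    the degenerate all-zero schedule.
    """
    if max_value is not None and max_value == 0:
        return InputSchedule(np.zeros_like(_CANONICAL), interval=interval)
    rng = np.random.default_rng(seed)
    vals = _CANONICAL.copy()
    mask = vals < _JITTER_BELOW
    vals[mask] = np.clip(
        vals[mask] + rng.uniform(-jitter, jitter, mask.sum()), 0.0, _JITTER_BELOW
    )
    sched = InputSchedule(vals, interval=interval)
    _check_schedule(sched)
    return sched


def _check_schedule(sched: InputSchedule) -> None:
    v = sched.values
    if v.shape != (6, 3):
        raise ValueError("canonical schedule must be 6 intervals x 3 channels")
    if v.max() > _BASELINE_CAP:
        raise ValueError("schedule is not sub-selective at baseline DA")
    tied = np.sort(v, axis=1)[:, ::-1]
    has_tied = np.any((tied[:, 0] > 0.7) & (tied[:, 1] > 0.7)
                      & (tied[:, 0] - tied[:, 1] < 0.05))
    if not has_tied:
        raise ValueError("schedule lacks a near-tied strong interval")


@dataclass(frozen=True)
class IntervalClassification:
    """Regime label of one (DA level, interval) cell."""

    da_percent: float
    interval: int
    label: str                     # weak | enhanced | maintenance | multiple
    winner: Optional[int]          # selected channel (outer layer), if any
    argmax_input: int
    onset: Optional[float]         # first onset inside the interval (absolute s)
    inner_multiplicity: int


@dataclass
class RegimeReport:
    cells: List[IntervalClassification]
    selections: Dict[float, list]  # per DA percent: selection intervals

    def labels(self, da_percent: float) -> List[str]:
        return [c.label for c in self.cells if c.da_percent == da_percent]

    def n_selected_intervals(self, da_percent: float) -> int:
        return sum(
            1 for c in self.cells
            if c.da_percent == da_percent and c.onset is not None
        )


MAINTENANCE_HOLD = 10.0   # seconds a demoted winner must persist
INNER_THRESHOLD = 0.8     # external-layer transfer threshold on inner units


def single_loop_sweep(
    loop_or_preset="single",
    schedule: Optional[InputSchedule] = None,
    da_percents: Sequence[float] = (15.0, 20.0, 30.0, 50.0),
    dt: float = 0.01,
    stride: int = 50,
) -> RegimeReport:
    """Run the identical schedule at each DA level and classify intervals.

    Labels per interval: ``multiple`` if >= 2 inner-layer channels are
    simultaneously above the external threshold; ``maintenance`` if a
    previously selected winner persists >= 10 s past an input change that
    demoted it; ``enhanced`` if the interval's input argmax becomes selected
    within the interval; ``weak`` otherwise.
    """
    if schedule is None:
        schedule = generate_input_schedule()
    if schedule.n_intervals < 1:
        raise ValueError("schedule must have at least one interval")
    cells: List[IntervalClassification] = []
    selections: Dict[float, list] = {}
    for pct in da_percents:
        if isinstance(loop_or_preset, Loop):
            loop = build_loop(loop_or_preset.spec)
        else:
            loop = build_loop(loop_or_preset)
        if schedule.n_channels != loop.n_channels:
            raise ValueError("schedule dimensionality does not match the loop")
        inject_input(loop, schedule)
        ts = loop.run(schedule.duration, da=da_level(pct), dt=dt, stride=stride)
        rep = read_selection(ts, "cx_outer")
        selections[pct] = rep.intervals
        yi = ts.y_of("cx_inner")
        T = schedule.interval
        for k in range(schedule.n_intervals):
            lo, hi = k * T, (k + 1) * T
            in_win = (ts.t >= lo) & (ts.t < hi)
            multi = int((yi[in_win] > INNER_THRESHOLD).sum(axis=1).max()) if in_win.any() else 0
            arg = int(np.argmax(schedule.values[k]))
            onsets = [iv for iv in rep.intervals if lo <= iv.onset < hi]
            onset = min((iv.onset for iv in onsets), default=None)
            winner = None
            for iv in onsets:
                if iv.channel == arg:
                    winner = arg
                    break
            if winner is None and onsets:
                winner = onsets[0].channel
            # maintenance: a channel selected before this interval persists
            # >= 10 s into it although the input change demoted it
            maint = False
            if k > 0:
                prev_arg_vals = schedule.values[k - 1]
                for iv in rep.intervals:
                    if iv.onset < lo and iv.offset >= lo + MAINTENANCE_HOLD:
                        demoted = (
                            schedule.values[k][iv.channel]
                            < prev_arg_vals[iv.channel] - 1e-9
                            or int(np.argmax(schedule.values[k])) != iv.channel
                        )
                        if demoted:
                            maint = True
            if multi >= 2:
                label = "multiple"
            elif maint:
                label = "maintenance"
            elif onset is not None and winner == arg:
                label = "enhanced"
            else:
                label = "weak"
            cells.append(
                IntervalClassification(
                    da_percent=pct, interval=k, label=label, winner=winner,
                    argmax_input=arg, onset=onset, inner_multiplicity=multi,
                )
            )
    return RegimeReport(cells=cells, selections=selections)


# -- vigor ----------------------------------------------------------------

COMPLETION_HOLD = 2.0   # joint selection maintenance that counts an action


@dataclass
class VigorResult:
    """Completed-action counts per DA condition over repeated runs."""

    da_percents: Tuple[float, ...]
    counts: Dict[float, List[int]]                      # per rep
    histograms: Dict[float, np.ndarray]                 # (action, target) bins

    def mean(self, pct: float) -> float:
        return float(np.mean(self.counts[pct]))

    def sem(self, pct: float) -> float:
        c = self.counts[pct]
        return float(np.std(c, ddof=1) / np.sqrt(len(c))) if len(c) > 1 else 0.0


def count_joint_completions(
    t: np.ndarray,
    y_action: np.ndarray,
    y_gaze: np.ndarray,
    hold: float = COMPLETION_HOLD,
    grace: float = 0.3,
) -> Tuple[int, np.ndarray]:
    """Count completed actions: every ``hold`` seconds of joint selection of
    one (action, gaze) pair counts one action (repetitions included).

    A maintenance bout survives silent dips shorter than ``grace`` seconds —
    rate units sitting near the external threshold cross it briefly without
    the selected channel changing; switching to a *different* pair always
    resets the clock.  Returns the count and the (action, target) histogram.
    """
    n_act, n_gaze = y_action.shape[1], y_gaze.shape[1]
    hist = np.zeros((n_act, n_gaze))
    current: Optional[Tuple[int, int]] = None
    t_start = 0.0
    none_since: Optional[float] = None
    count = 0
    for i in range(len(t)):
        a = active_channel(y_action[i])
        g = active_channel(y_gaze[i])
        pair = (a, g) if a is not None and g is not None else None
        if pair is None:
            if current is not None:
                if none_since is None:
                    none_since = t[i]
                elif t[i] - none_since > grace:
                    current, none_since = None, None
            continue
        none_since = None
        if pair != current:
            current, t_start = pair, t[i]
        elif t[i] - t_start >= hold:
            count += 1
            hist[pair] += 1
            t_start = t[i]
    return count, hist


def vigor_experiment(
    da_percents: Sequence[float] = (0.0, 20.0, 40.0),
    duration: float = 360.0,
    reps: int = 10,
    seed: int = 0,
    dt: float = 0.01,
    noise_on: bool = True,
) -> VigorResult:
    """Noise-driven vigor test on the attention + arm-action loop pair.

    Both loops receive no external input; smoothed thalamic noise triggers
    occasional selections whose frequency and persistence grow with tonic
    DA.  An action completes when the two loops jointly hold one
    (action, gaze) selection for 2 s; repetitions recount.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    counts: Dict[float, List[int]] = {pct: [] for pct in da_percents}
    hists: Dict[float, np.ndarray] = {pct: np.zeros((3, 6)) for pct in da_percents}
    for rep, child in enumerate(ss.spawn(reps)):
        rep_seeds = child.generate_state(2)
        for pct in da_percents:
            arm = build_loop(loop_spec("arm_action") if noise_on
                             else loop_spec("arm_action", noise_strength=0.0))
            att = build_loop(loop_spec("attention") if noise_on
                             else loop_spec("attention", noise_strength=0.0))
            d = da_level(pct)
            ts_arm = arm.run(duration, da=d, dt=dt, seed=int(rep_seeds[0]), stride=10)
            ts_att = att.run(duration, da=d, dt=dt, seed=int(rep_seeds[1]), stride=10)
            n, h = count_joint_completions(
                ts_arm.t, ts_arm.y_of("cx_outer"), ts_att.y_of("cx_outer")
            )
            counts[pct].append(n)
            hists[pct] += h
    return VigorResult(tuple(da_percents), counts, hists)
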