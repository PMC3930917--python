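"""Construction of the prototypical striato-cortical selection loop.

One loop contains a two-layer cortex (inner layer inside the loop, external
layer as gated output), D1 striatum, STN, SNr/GPi and thalamus, wired as

    cx_inner -> striatum_d1   parallel, excitatory   (direct pathway)
    cx_inner -> stn           parallel, excitatory   (hyperdirect pathway)
    striatum_d1 -> snr        parallel, inhibitory
    stn -> snr                diffuse, excitatory
    snr -> thalamus           parallel, inhibitory
    thalamus -> cx_inner      parallel, excitatory
    cx_inner -> cx_outer      parallel, excitatory
    cx_outer -> cx_outer      lateral inhibition (when configured)

Only the striatum carries a dopamine gain (``eps + lam * d``); raising ``d``
tilts the direct-vs-hyperdirect competition toward the direct pathway and
moves the loop through weak-selection, enhanced-discrimination and
maintenance regimes.

Three presets reproduce the motor ("arm_action"), attention and goal
("ventral") loops, which differ in channel count, striatal dopamine
sensitivity ``lam``, cortical thresholds, lateral inhibition and thalamic
noise.  All remaining weights and time constants are shared calibrated
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Network, NoiseSource, Projection, TimeSeries, UnitGroup

__all__ = [
    "LoopSpec",
    "Loop",
    "PRESETS",
    "loop_spec",
    "build_loop",
    "InputSchedule",
    "inject_input",
    "SelectionInterval",
    "SelectionReport",
    "read_selection",
    "active_channel",
]

GROUPS = ("cx_inner", "cx_outer", "striatum_d1", "stn", "snr", "thalamus")


@dataclass(frozen=True)
class LoopSpec:
    """Compact per-loop parameter set.

    The first block holds the parameters that distinguish the three loops;
    the second block holds shared calibrated defaults (weights, time
    constants, slopes) that any preset may override.
    """

    name: str
    n_channels: int
    lam_striatum: float
    theta_layer1: float
    theta_layer2: float
    lateral_inhibition: float
    noise_strength: float
    noise_decay: float
    # shared calibrated defaults
    noise_gain: float = 1.6
    noise_decay_unit: float = 0.001   # decay counts are in milliseconds
    eps_striatum: float = 0.1
    w_cx_str: float = 0.2658
    w_cx_stn: float = 0.505
    w_str_snr: float = 2.867
    w_stn_snr: float = 0.4737
    w_snr_th: float = 1.057
    w_th_cx: float = 1.2696
    w_cx_io: float = 1.0
    snr_basal: float = 0.8471
    th_basal: float = 0.6702
    tau_cx_inner: float = 1.0
    tau_cx_outer: float = 0.05
    tau_str: float = 0.05
    tau_stn: float = 0.05
    tau_snr: float = 0.05
    tau_th: float = 0.05
    alpha_cx: float = 2.5
    alpha_str: float = 1.0
    alpha_stn: float = 2.0
    alpha_snr: float = 2.0
    alpha_th: float = 2.0

    def __post_init__(self) -> None:
        if self.n_channels <= 0:
            raise ValueError("n_channels must be positive")
        if self.lam_striatum < 0:
            raise ValueError("lam_striatum must be >= 0")


#: Essential per-loop parameters of the three striato-cortical loops
#: (channel count, striatal lambda, layer thresholds, lateral inhibition,
#: thalamic noise) plus the calibrated striatal input weight of each loop.
PRESETS: Dict[str, dict] = {
    "attention": dict(
        n_channels=6,
        lam_striatum=2.5,
        theta_layer1=0.4,
        theta_layer2=0.8,
        lateral_inhibition=2.0,
        noise_strength=20.0,
        noise_decay=1000.0,
        w_cx_str=0.25,
        w_stn_snr=1.1,
        noise_gain=0.8,
    ),
    "arm_action": dict(
        n_channels=3,
        lam_striatum=1.5,
        theta_layer1=0.6,
        theta_layer2=0.8,
        lateral_inhibition=0.2,
        noise_strength=30.0,
        noise_decay=2000.0,
        th_basal=0.90,
        w_th_cx=1.30,
        w_stn_snr=0.55,
        noise_gain=0.8,
    ),
    "goal": dict(
        n_channels=6,
        lam_striatum=1.0,
        theta_layer1=0.1,
        theta_layer2=0.6,
        lateral_inhibition=0.0,
        noise_strength=0.0,
        noise_decay=0.0,
        tau_cx_inner=0.2,
        w_cx_str=0.18,
        w_th_cx=0.25,
    ),
    # the single-loop test configuration: arm-action thresholds, no noise
    "single": dict(
        n_channels=3,
        lam_striatum=1.5,
        theta_layer1=0.6,
        theta_layer2=0.8,
        lateral_inhibition=0.2,
        noise_strength=0.0,
        noise_decay=0.0,
    ),
}


def loop_spec(preset: str, **overrides) -> LoopSpec:
    """Build a :class:`LoopSpec` from a named preset, optionally overridden."""
    if preset not in PRESETS:
        raise KeyError(
            f"unknown loop preset {preset!r}; available: {sorted(PRESETS)}"
        )
    params = dict(PRESETS[preset])
    params.update(overrides)
    return LoopSpec(name=preset, **params)


class Loop:
    """A built loop: a :class:`~bgloops.core.Network` plus its spec.

    ``run`` integrates the loop under a dopamine level (constant or callable
    of time) and an optional external input schedule applied to the inner
    cortical layer.
    """

    def __init__(self, spec: LoopSpec, network: Network) -> None:
        self.spec = spec
        self.network = network
        self.input_fn = None  # set by inject_input

    @property
    def n_channels(self) -> int:
        return self.spec.n_channels

    def run(
        self,
        duration: float,
        da: float | callable = 1.0,
        dt: float = 0.01,
        seed: Optional[int] = None,
        stride: int = 10,
    ) -> TimeSeries:
        inputs = None
        if self.input_fn is not None:
            inputs = {"cx_inner": self.input_fn}
        return self.network.run(
            duration, dt=dt, da=da, inputs=inputs, seed=seed, stride=stride
        )


def build_loop(spec: LoopSpec | str) -> Loop:
    """Construct the prototypical loop from a spec or preset name.

    With zero external input at baseline dopamine the SNr settles on a
    positive tonic activation that keeps the thalamus (hence the cortex)
    silent; selection requires striatal suppression of an SNr channel.
    """
    if isinstance(spec, str):
        spec = loop_spec(spec)
    n = spec.n_channels
    noise = None
    if spec.noise_strength > 0:
        # Table-1 noise magnitudes are unitless; noise_gain is the calibrated
        # conversion to drive amplitude, and the decay counts are read as
        # milliseconds (the loops switch selections within tens of seconds,
        # which requires a noise correlation time of a couple of seconds)
        noise = NoiseSource(strength=spec.noise_strength * spec.noise_gain,
                            decay=spec.noise_decay * spec.noise_decay_unit)
    groups = [
        UnitGroup("cx_inner", n, tau=spec.tau_cx_inner, alpha=spec.alpha_cx,
                  theta=spec.theta_layer1),
        UnitGroup("cx_outer", n, tau=spec.tau_cx_outer, alpha=spec.alpha_cx,
                  theta=spec.theta_layer2),
        UnitGroup("striatum_d1", n, tau=spec.tau_str, alpha=spec.alpha_str,
                  epsilon=spec.eps_striatum, lam=spec.lam_striatum),
        UnitGroup("stn", n, tau=spec.tau_stn, alpha=spec.alpha_stn),
        UnitGroup("snr", n, tau=spec.tau_snr, alpha=spec.alpha_snr,
                  basal=spec.snr_basal),
        UnitGroup("thalamus", n, tau=spec.tau_th, alpha=spec.alpha_th,
                  basal=spec.th_basal, noise=noise),
    ]
    projections = [
        Projection("cx_inner", "striatum_d1", "parallel", "excitatory", spec.w_cx_str),
        Projection("cx_inner", "stn", "parallel", "excitatory", spec.w_cx_stn),
        Projection("striatum_d1", "snr", "parallel", "inhibitory", spec.w_str_snr),
        Projection("stn", "snr", "diffuse", "excitatory", spec.w_stn_snr),
        Projection("snr", "thalamus", "parallel", "inhibitory", spec.w_snr_th),
        Projection("thalamus", "cx_inner", "parallel", "excitatory", spec.w_th_cx),
        Projection("cx_inner", "cx_outer", "parallel", "excitatory", spec.w_cx_io),
    ]
    if spec.lateral_inhibition > 0:
        projections.append(
            Projection("cx_outer", "cx_outer", "lateral_inhibition", "inhibitory",
                       spec.lateral_inhibition)
        )
    return Loop(spec, Network(groups, projections))


# -- input schedules ------------------------------------------------------


@dataclass(frozen=True)
class InputSchedule:
    """Piecewise-constant per-channel drive: interval i covers
    ``[i * interval, (i+1) * interval)`` seconds and applies row i of
    ``values`` (shape n_intervals x n_channels)."""

    values: np.ndarray
    interval: float = 60.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (n_intervals x n_channels)")
        object.__setattr__(self, "values", v)

    @property
    def n_intervals(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_intervals * self.interval

    def __call__(self, t: float) -> np.ndarray:
        i = min(int(t // self.interval), self.n_intervals - 1)
        return self.values[i]

    def interval_of(self, t: float) -> int:
        return min(int(t // self.interval), self.n_intervals - 1)


def inject_input(loop: Loop, schedule) -> Loop:
    """Attach an external drive schedule to the loop's inner cortex.

    ``schedule`` may be ``None`` (no-op), an :class:`InputSchedule`, or any
    callable of time returning an ``n_channels`` vector.
    """
    if schedule is None:
        return loop
    if isinstance(schedule, InputSchedule):
        if schedule.n_channels != loop.n_channels:
            raise ValueError(
                f"schedule has {schedule.n_channels} channels, loop has "
                f"{loop.n_channels}"
            )
    loop.input_fn = schedule
    return loop


# -- selection readout ----------------------------------------------------


@dataclass(frozen=True)
class SelectionInterval:
    channel: int
    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class SelectionReport:
    """Per-channel activation intervals of a gated cortical layer."""

    intervals: List[SelectionInterval]
    duration: float

    def channels(self) -> List[int]:
        return sorted({iv.channel for iv in self.intervals})

    def active_at(self, t: float) -> List[int]:
        return [iv.channel for iv in self.intervals if iv.onset <= t < iv.offset]

    def first_onset(self) -> Optional[float]:
        return min((iv.onset for iv in self.intervals), default=None)


def active_channel(y_row: np.ndarray):
    """The selected channel of a gated layer: the most active strictly
    positive unit, or None if the layer is silent."""
    if not np.any(y_row > 0):
        return None
    return int(np.argmax(y_row))


def read_selection(
    ts: TimeSeries, group: str = "cx_outer", threshold: float = 0.0
) -> SelectionReport:
    """Extract selection intervals: a channel is selected while its
    activation in ``group`` exceeds ``threshold`` (strictly)."""
    y = ts.y_of(group)
    t = ts.t
    intervals: List[SelectionInterval] = []
    active = y > threshold
    for c in range(y.shape[1]):
        col = active[:, c]
        if not col.any():
            continue
        edges = np.flatnonzero(np.diff(col.astype(int)))
        starts = list(np.flatnonzero(col[1:] & ~col[:-1]) + 1)
        if col[0]:
            starts.insert(0, 0)
        for s in starts:
            e = s
            while e < len(col) and col[e]:
                e += 1
            off = t[e] if e < len(col) else t[-1]
            intervals.append(SelectionInterval(c, float(t[s]), float(off)))
    intervals.sort(key=lambda iv: (iv.onset, iv.channel))
    return SelectionReport(intervals=intervals, duration=float(t[-1]) if len(t) else 0.0)
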