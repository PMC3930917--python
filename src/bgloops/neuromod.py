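"""Dopamine control circuitry and hippocampal novelty habituation.

A single dopaminergic unit stands in for the joint activity of VTA and SNc.
Its output ``d`` has a tonic baseline ``d0`` maintained by a tonically
active inhibitory interneuron, and is steered by four controllers:

* superior colliculus (SC): luminance-change events inject a fast excitatory
  transient — the phasic burst that gates Hebbian learning;
* prefrontal predictor: a learned inhibitory drive that cancels the SC
  signal before burst onset once an outcome has become self-predicted;
* ventral-loop output nucleus (SNr): its tonic inhibition of the DA unit is
  lifted when the hippocampus excites the NAcc (novelty -> tonic DA rise);
* amygdala: a perceived reward inhibits the tonic interneuron, disinhibiting
  the DA unit into a sustained tonic elevation.

The hippocampal layer is a field of spatial-cue units whose response to a
fixated cue decays exponentially from 1.0 to a floor of 0.1 in about two
minutes of exposure (novelty habituation).  The field itself is dopamine
sensitive, so high DA re-amplifies habituated responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import da_gain

__all__ = ["DopamineSystem", "HabituationField", "novelty_drive"]


@dataclass
class DopamineSystem:
    """Single DA unit with burst machinery and tonic controllers.

    With all inputs at zero, ``d`` settles exactly at ``d_baseline``: the
    basal drive of the DA unit is derived in ``__post_init__`` from the
    interneuron's resting activity and the expected resting inhibition from
    the ventral output nucleus (``snr_rest``).
    """

    d_baseline: float = 1.0
    tau_da: float = 0.05
    tau_burst: float = 0.4          # decay of the SC-driven transient
    burst_amplitude: float = 0.8    # peak d excess of an unpredicted burst
    tau_interneuron: float = 0.5
    interneuron_basal: float = 1.0
    w_amg: float = 0.22             # amygdala inhibition of the interneuron
    w_interneuron: float = 1.0
    w_snr_ventral: float = 0.15     # per-unit tonic inhibition from ventral SNr
    snr_rest: float = 0.0           # resting ventral SNr sum (wired by the agent)
    tau_tonic: float = 2.0          # smoothing of tonic (SNr/Amg) influences

    def __post_init__(self) -> None:
        self._basal = (
            self.d_baseline
            + self.w_interneuron * self.interneuron_basal
            + self.w_snr_ventral * self.snr_rest
        )
        self.reset()

    def reset(self) -> None:
        self._burst = 0.0
        self._u_int = self.interneuron_basal
        self._tonic = 0.0           # smoothed SNr-disinhibition state
        self.d = self.d_baseline

    def update_da(
        self,
        sc_event: bool = False,
        amg_level: float = 0.0,
        snr_ventral_level: Optional[float] = None,
        pfc_prediction: float = 0.0,
        dt: float = 0.01,
    ) -> float:
        """Advance the DA circuit one step and return the new ``d``.

        ``sc_event`` marks a luminance-change onset; ``pfc_prediction`` is
        the learned inhibitory drive onto the SC pathway (it subtracts from
        the burst amplitude before onset, so a saturated predictor yields no
        burst at all).  ``snr_ventral_level`` is the summed activation of
        the ventral output nucleus; values below ``snr_rest`` disinhibit the
        DA unit (novelty-driven tonic rise).  ``amg_level`` inhibits the
        tonic interneuron (reward-driven tonic rise).
        """
        if sc_event:
            self._burst += max(self.burst_amplitude - max(pfc_prediction, 0.0), 0.0)
        self._burst -= dt * self._burst / self.tau_burst
        # tonically active interneuron, inhibited by the amygdala
        self._u_int += (dt / self.tau_interneuron) * (
            -self._u_int + self.interneuron_basal - self.w_amg * max(amg_level, 0.0)
        )
        y_int = max(self._u_int, 0.0)
        snr = self.snr_rest if snr_ventral_level is None else snr_ventral_level
        self._tonic += (dt / self.tau_tonic) * (
            -self._tonic + self.w_snr_ventral * (self.snr_rest - snr)
        )
        # fast DA unit: basal drive + burst - interneuron - ventral SNr rest
        target = (
            self._basal
            + self._burst
            + self._tonic
            - self.w_interneuron * y_int
            - self.w_snr_ventral * self.snr_rest
        )
        self.d += (dt / self.tau_da) * (-self.d + target)
        self.d = max(self.d, 0.0)
        return self.d


@dataclass
class HabituationField:
    """Hippocampal novelty responses, one unit per spatial cue location.

    ``response(i)`` starts at 1.0 for a never-seen cue and decays toward
    ``floor`` with time constant ``tau_hab`` while cue ``i`` is fixated
    (exposure-driven habituation).  The default ``tau_hab`` puts the
    response within 5% of the floor after 120 s of exposure.  The emitted
    (dopamine-scaled) response is ``response * (epsilon + lam * d)``, so the
    field re-amplifies under high DA.  ``recovery_tau`` (None disables)
    allows spontaneous recovery of unexposed cues.
    """

    n_units: int = 6
    floor: float = 0.1
    tau_hab: float = 120.0 / np.log(180.0)   # response(120 s) = floor * 1.05
    epsilon: float = 0.5
    lam: float = 0.5
    recovery_tau: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.floor < 1:
            raise ValueError("floor must lie in [0, 1)")
        self.response = np.ones(self.n_units)

    def habituate(self, fixated_cue: Optional[int], dt: float, d: float = 1.0) -> float:
        """Expose the fixated cue for ``dt`` seconds; return its emitted
        (DA-scaled) response.  Non-fixated cues are unchanged unless
        spontaneous recovery is enabled."""
        if fixated_cue is not None and not 0 <= fixated_cue < self.n_units:
            raise IndexError(f"unknown cue location {fixated_cue}")
        if self.recovery_tau is not None:
            idle = np.ones(self.n_units, dtype=bool)
            if fixated_cue is not None:
                idle[fixated_cue] = False
            self.response[idle] += dt * (1.0 - self.response[idle]) / self.recovery_tau
        if fixated_cue is None:
            return 0.0
        r = self.response[fixated_cue]
        r += dt * (self.floor - r) / self.tau_hab
        self.response[fixated_cue] = r
        return float(r * da_gain(self.epsilon, self.lam, d))

    def gain(self, d: float) -> float:
        return da_gain(self.epsilon, self.lam, d)


def novelty_drive(field: HabituationField, fixated_cue: Optional[int]) -> np.ndarray:
    """Per-channel NAcc input: the raw habituation response on the fixated
    cue's channel, zero elsewhere (zero vector if nothing is fixated)."""
    v = np.zeros(field.n_units)
    if fixated_cue is not None:
        if not 0 <= fixated_cue < field.n_units:
            raise IndexError(f"unknown cue location {fixated_cue}")
        v[fixated_cue] = field.response[fixated_cue]
    return v
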