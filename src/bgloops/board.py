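"""Abstract mechatronic-board environment.

A discrete-time stand-in for the robot-and-board setup: six spatial cues
(indices 0-2 are buttons, 3-5 transparent boxes), with button ``i`` wired to
box/light ``i``.  The agent interacts through two selection channels — a
gaze target (0-5) and an arm action (0: press, 1: grab, 2: wipe).  An action
is always performed on the currently fixated cue; it completes only if both
selections are held for the action's full drawn duration (uniform in
[2, 3] s), and a completed *press on a button* opens the matched box and
emits a 1 s light flash (the luminance event that drives phasic dopamine).
Grab and wipe are dummy actions; presses on boxes do nothing.  A visible
reward may be placed in a box; it is seen (driving the amygdala) whenever
the agent fixates that box.

Changing either selection mid-action aborts it without consequence.
Foveation takes 0.5 s: after a gaze change the new cue counts as fixated
only once the foveation completes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "ACTIONS", "PRESS", "GRAB", "WIPE",
    "N_CUES", "BUTTONS", "BOXES",
    "Observation", "OngoingAction", "BoardState", "Board",
    "enumerate_combinations",
]

ACTIONS = ("press", "grab", "wipe")
PRESS, GRAB, WIPE = 0, 1, 2
N_CUES = 6
BUTTONS = (0, 1, 2)
BOXES = (3, 4, 5)

FLASH_DURATION = 1.0
FOVEATION_TIME = 0.5
ACTION_DURATION_RANGE = (2.0, 3.0)


@dataclass
class OngoingAction:
    action: int
    target: int
    start: float
    duration: float


@dataclass
class Observation:
    """What the agent perceives in one step."""

    fixated_cue: Optional[int]
    luminance_change: bool        # flash onset this step
    flash_location: Optional[int]  # box index while a flash is lit
    reward_visible: bool


@dataclass
class BoardState:
    reward_location: Optional[int] = None
    open_boxes: set = field(default_factory=set)
    current_fixation: Optional[int] = None
    gaze_target: Optional[int] = None
    foveation_elapsed: float = 0.0
    ongoing_action: Optional[OngoingAction] = None
    flash_box: Optional[int] = None
    flash_remaining: float = 0.0


@dataclass
class BoardEvent:
    t: float
    event: str
    target: Optional[int]


class Board:
    """Steppable board with an event log.

    ``rng`` draws the per-initiation action durations; ``boxes_stay_open``
    and ``flash_retrigger`` expose the unspecified corner cases (defaults:
    boxes close when their flash ends, and a press during an ongoing flash
    re-triggers it).
    """

    def __init__(
        self,
        rng: Optional[np.random.Generator] = None,
        boxes_stay_open: bool = False,
        flash_retrigger: bool = True,
    ) -> None:
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.boxes_stay_open = boxes_stay_open
        self.flash_retrigger = flash_retrigger
        self.state = BoardState()
        self.t = 0.0
        self.events: List[BoardEvent] = []
        self.completed_actions: List[Tuple[float, int, int]] = []

    # -- experimenter interface ------------------------------------------

    def place_reward(self, box: Optional[int]) -> None:
        """Put the visible reward in ``box`` (3-5), or remove it (None)."""
        if box is not None and box not in BOXES:
            raise ValueError(f"reward location must be a box index {BOXES} or None")
        self.state.reward_location = box
        self.events.append(BoardEvent(self.t, "reward_placed" if box is not None
                                      else "reward_removed", box))

    # -- agent interface --------------------------------------------------

    def step(self, gaze: Optional[int], action: Optional[int], dt: float) -> Observation:
        """Advance ``dt`` seconds under the agent's current selections."""
        if gaze is not None and not 0 <= gaze < N_CUES:
            raise ValueError(f"gaze channel {gaze} out of range")
        if action is not None and action not in (PRESS, GRAB, WIPE):
            raise ValueError(f"action channel {action} out of range")
        st = self.state
        self.t += dt
        flash_onset = False

        # gaze / foveation
        if gaze != st.gaze_target:
            st.gaze_target = gaze
            st.foveation_elapsed = 0.0
            st.current_fixation = None
        elif gaze is not None and st.current_fixation is None:
            st.foveation_elapsed += dt
            if st.foveation_elapsed >= FOVEATION_TIME:
                st.current_fixation = gaze
                self.events.append(BoardEvent(self.t, "fixation", gaze))

        # action initiation / maintenance / abort
        ong = st.ongoing_action
        if ong is not None:
            if action != ong.action or st.gaze_target != ong.target:
                self.events.append(BoardEvent(self.t, "action_aborted", ong.target))
                st.ongoing_action = None
                ong = None
        if ong is None and action is not None and st.current_fixation is not None:
            dur = float(self.rng.uniform(*ACTION_DURATION_RANGE))
            st.ongoing_action = OngoingAction(action, st.current_fixation, self.t, dur)
            ong = st.ongoing_action
        if ong is not None and self.t - ong.start >= ong.duration:
            self.completed_actions.append((self.t, ong.action, ong.target))
            self.events.append(
                BoardEvent(self.t, f"completed_{ACTIONS[ong.action]}", ong.target))
            if ong.action == PRESS and ong.target in BUTTONS:
                box = ong.target + 3
                if st.flash_box is None or self.flash_retrigger:
                    st.flash_box = box
                    st.flash_remaining = FLASH_DURATION
                    st.open_boxes.add(box)
                    flash_onset = True
                    self.events.append(BoardEvent(self.t, "flash", box))
            st.ongoing_action = None

        # flash countdown; box closes when its flash ends unless configured
        if st.flash_box is not None:
            st.flash_remaining -= dt
            if st.flash_remaining <= 0:
                if not self.boxes_stay_open:
                    st.open_boxes.discard(st.flash_box)
                st.flash_box = None
                st.flash_remaining = 0.0

        reward_visible = (
            st.reward_location is not None
            and st.current_fixation == st.reward_location
        )
        return Observation(
            fixated_cue=st.current_fixation,
            luminance_change=flash_onset,
            flash_location=st.flash_box,
            reward_visible=reward_visible,
        )


def enumerate_combinations(n_actions: int = len(ACTIONS), n_cues: int = N_CUES) -> int:
    """Count distinct (action, target-cue) pairs available on the board."""
    if n_actions < 0 or n_cues < 0:
        raise ValueError("counts must be non-negative")
    return n_actions * n_cues
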