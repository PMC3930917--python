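"""Three-loop embodied agent for the mechatronic-board task.

The agent couples three striato-cortical loops — manipulation (PMC/putamen,
3 action channels), attention (FEF/caudate, 6 gaze channels) and goal
(PFC/NAcc, 6 outcome channels) — with the dopamine circuit, the hippocampal
habituation field and the board environment:

* the attention loop's selected external channel sets the gaze target, the
  manipulation loop's the arm action; both loops are driven by thalamic
  noise (random exploration) plus learned top-down bias from the goal loop
  (inverse models);
* the hippocampus responds to the fixated cue with a novelty-scaled signal
  that excites the NAcc directly and the inner PFC layer; NAcc activity
  suppresses the ventral output nucleus, disinhibiting the dopamine unit
  (novelty -> tonic DA rise -> motor loop wakes up, attention locks on);
* a light flash excites the superior colliculus: a phasic dopamine burst
  that gates Hebbian learning, plus a bottom-up gaze-capture drive toward
  the flash location and a strong salience input to the goal channel of the
  flashed box;
* a visible reward drives the amygdala (sustained tonic DA) and the goal
  channel of its box, so the matured inverse models recall the press action
  and the matched button.

Learning is gated above ``d0 + zeta_ctx``, a level only bursts reach; the
prefrontal predictor cancels bursts for outcomes the agent has learned to
cause, ending each button's exploration bout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .board import Board, BOXES, BUTTONS, N_CUES, PRESS
from .core import TimeSeries
from .loops import Loop, build_loop, loop_spec
from .neuromod import DopamineSystem, HabituationField, novelty_drive
from .plasticity import PlasticMatrix, hebbian_update, wire_agent_plasticity
from .loops import active_channel

__all__ = ["AgentConfig", "Agent", "AgentEvent", "BoardTaskLog"]


@dataclass
class AgentConfig:
    """Coupling weights and learning coefficients of the three-loop agent.

    All couplings outside the Hebbian-trained matrices are fixed; the
    calibrated defaults place the novelty-driven tonic dopamine excursion
    below the learning gate and burst peaks above it.
    """

    d_baseline: float = 1.0
    # hippocampus -> ventral loop
    w_hip_nacc: float = 0.6         # direct novelty drive onto the NAcc
    w_novelty_pfc: float = 0.12      # novelty drive onto inner PFC
    # constant bottom-up salience of the visible board cues on the
    # attention loop (present only in the embodied task; the vigor test has
    # no external input by design)
    w_cue_salience: float = 0.30
    # matching affordance salience of the manipulable objects on the
    # manipulation loop (embodied task only)
    w_action_salience: float = 0.25
    # superior-colliculus flash pathways
    w_flash_pfc: float = 0.55       # flash-location salience onto inner PFC
    w_capture_fef: float = 0.4      # bottom-up gaze capture toward the flash
    # reward pathway
    w_reward_pfc: float = 0.45      # visible-reward drive onto inner PFC
    # forward-model drive: the two forward models combine conjunctively
    # (geometric mean), so anticipating an outcome requires both the action
    # and its target; either alone predicts nothing
    w_fwd_gain: float = 0.75
    # dopamine circuit
    w_snr_ventral: float = 0.35
    tau_tonic: float = 1.0
    burst_amplitude: float = 0.8
    tau_burst: float = 0.7
    # plasticity
    eta_ctx: float = 12.0
    w_max_ctx: float = 1.0
    zeta_ctx: float = 0.2
    # highest tonic dopamine the control circuitry can produce (novelty or
    # reward driven); the learning threshold zeta_ctx is measured above it,
    # so only phasic bursts open the Hebbian gate
    tonic_ceiling: float = 1.25
    # typical novelty-driven tonic level during an exploration bout; used
    # to judge whether a press's expected burst peak still clears the gate
    bout_tonic: float = 1.15
    eta_pred: float = 0.00008
    w_max_pred: float = 18000.0
    predictor_coeff_role: str = "rate"
    # hippocampal field
    hip_epsilon: float = 0.1
    hip_lam: float = 0.9


@dataclass
class AgentEvent:
    t: float
    event: str
    detail: dict


@dataclass
class BoardTaskLog:
    """Everything a board-task run records."""

    t: np.ndarray
    d: np.ndarray
    gaze: np.ndarray           # -1 = none
    action: np.ndarray         # -1 = none
    goal: np.ndarray           # -1 = none (strongest active PFC_ext channel)
    events: List[AgentEvent]
    board_events: list
    weights: Dict[str, np.ndarray]
    burst_peaks: List[Tuple[float, int, float]]   # (t, button, peak d)
    associations: dict = field(default_factory=dict)


class Agent:
    """Steppable three-loop agent bound to a board environment."""

    def __init__(
        self,
        config: Optional[AgentConfig] = None,
        seed: int = 0,
        board: Optional[Board] = None,
        learning: bool = True,
        sc_enabled: bool = True,
    ) -> None:
        self.config = config or AgentConfig()
        cfg = self.config
        ss = np.random.SeedSequence(seed)
        s_man, s_att, s_board = ss.spawn(3)
        self.loops: Dict[str, Loop] = {
            "manipulation": build_loop(loop_spec("arm_action")),
            "attention": build_loop(loop_spec("attention")),
            "goal": build_loop(loop_spec("goal")),
        }
        self.loops["manipulation"].network.reset(int(s_man.generate_state(1)[0]))
        self.loops["attention"].network.reset(int(s_att.generate_state(1)[0]))
        self.loops["goal"].network.reset(0)
        self.board = board if board is not None else Board(
            np.random.default_rng(s_board)
        )
        self.hip = HabituationField(
            n_units=N_CUES, epsilon=cfg.hip_epsilon, lam=cfg.hip_lam
        )
        goal_spec = self.loops["goal"].spec
        snr_rest_unit = float(
            np.tanh(goal_spec.alpha_snr * goal_spec.snr_basal)
        )
        self.da = DopamineSystem(
            d_baseline=cfg.d_baseline,
            burst_amplitude=cfg.burst_amplitude,
            tau_burst=cfg.tau_burst,
            tau_tonic=cfg.tau_tonic,
            w_snr_ventral=cfg.w_snr_ventral,
            snr_rest=snr_rest_unit * goal_spec.n_channels,
        )
        self.plastic = wire_agent_plasticity(
            self,
            eta_ctx=cfg.eta_ctx,
            w_max_ctx=cfg.w_max_ctx,
            zeta_ctx=cfg.zeta_ctx + (cfg.tonic_ceiling - cfg.d_baseline),
            eta_pred=cfg.eta_pred,
            w_max_pred=cfg.w_max_pred,
            d_baseline=cfg.d_baseline,
            predictor_coeff_role=cfg.predictor_coeff_role,
        )
        self.learning = learning
        self.sc_enabled = sc_enabled
        self.t = 0.0
        self.d = cfg.d_baseline
        #: optional extra per-loop cortical drive (used by probes and tests)
        self.extra_inputs: Dict[str, np.ndarray] = {}
        self.events: List[AgentEvent] = []
        #: per-button learning bookkeeping, updated at each flash
        self.association_state: Dict[int, dict] = {}
        self._burst_open = False
        self._burst_peak = 0.0
        self._burst_button: Optional[int] = None

    # -- readouts ---------------------------------------------------------

    def _y(self, loop: str, group: str) -> np.ndarray:
        lp = self.loops[loop]
        return lp.network.state.y[lp.network.index[group]]

    @property
    def gaze(self) -> Optional[int]:
        return active_channel(self._y("attention", "cx_outer"))

    @property
    def action(self) -> Optional[int]:
        return active_channel(self._y("manipulation", "cx_outer"))

    @property
    def goal(self) -> Optional[int]:
        return active_channel(self._y("goal", "cx_outer"))

    def goal_channels(self) -> List[int]:
        """All active goal channels (the ventral loop has no lateral
        inhibition, so multi-goal states are reported, not resolved)."""
        y = self._y("goal", "cx_outer")
        return list(np.flatnonzero(y > 0))

    # -- stepping ---------------------------------------------------------

    def step(self, dt: float = 0.01) -> None:
        cfg = self.config
        # 1. environment under current selections
        obs = self.board.step(self.gaze, self.action, dt)

        # 2. hippocampal exposure to the fixated cue
        self.hip.habituate(obs.fixated_cue, dt, self.d)
        hip_gain = self.hip.gain(self.d)
        novelty = novelty_drive(self.hip, obs.fixated_cue)

        # 3. assemble external inputs
        goal_in = cfg.w_novelty_pfc * hip_gain * novelty
        nacc_in = cfg.w_hip_nacc * hip_gain * novelty
        att_in = np.full(self.loops["attention"].n_channels,
                         cfg.w_cue_salience, dtype=float)
        if obs.flash_location is not None:
            # a flash is a transient luminance event: always salient,
            # re-amplified by dopamine like any hippocampal response
            goal_in[obs.flash_location] += cfg.w_flash_pfc * hip_gain
            att_in[obs.flash_location] += cfg.w_capture_fef
        if obs.reward_visible:
            goal_in[self.board.state.reward_location] += cfg.w_reward_pfc
        y_pmc_ext = self._y("manipulation", "cx_outer")
        y_fef_ext = self._y("attention", "cx_outer")
        y_pfc_ext = self._y("goal", "cx_outer")
        fwd_act = self.plastic["pmc_to_pfc"].drive(y_pmc_ext)
        fwd_gaze = self.plastic["fef_to_pfc"].drive(y_fef_ext)
        goal_in += cfg.w_fwd_gain * np.sqrt(
            np.clip(fwd_act, 0, None) * np.clip(fwd_gaze, 0, None))
        man_in = (np.full(self.loops["manipulation"].n_channels,
                          cfg.w_action_salience, dtype=float)
                  + self.plastic["pfc_to_pmc"].drive(y_pfc_ext))
        att_in += self.plastic["pfc_to_fef"].drive(y_pfc_ext)
        if "manipulation" in self.extra_inputs:
            man_in = man_in + self.extra_inputs["manipulation"]
        if "attention" in self.extra_inputs:
            att_in = att_in + self.extra_inputs["attention"]
        if "goal" in self.extra_inputs:
            goal_in = goal_in + self.extra_inputs["goal"]

        # 4. dopamine
        y_pfc_inner = self._y("goal", "cx_inner")
        prediction = float(self.plastic["predictor"].drive(y_pfc_inner)[0])
        snr_v = float(self._y("goal", "snr").sum())
        sc_event = bool(obs.luminance_change) and self.sc_enabled
        self.d = self.da.update_da(
            sc_event=sc_event,
            amg_level=1.0 if obs.reward_visible else 0.0,
            snr_ventral_level=snr_v,
            pfc_prediction=prediction,
            dt=dt,
        )
        if sc_event:
            self.events.append(AgentEvent(self.t, "sc_event", {
                "box": obs.flash_location, "prediction": prediction}))
            btn = obs.flash_location - 3 if obs.flash_location is not None else None
            if btn is not None:
                rec = self.association_state.setdefault(
                    btn, {"bursts": 0, "presses": 0, "learned_t": None})
                rec["presses"] += 1
                amp_eff = max(self.config.burst_amplitude - prediction, 0.0)
                if self.d + amp_eff > self.plastic["pmc_to_pfc"].zeta:
                    rec["bursts"] += 1     # expected peak clears the gate
                if rec["learned_t"] is None and self.association_learned(btn):
                    rec["learned_t"] = self.t
            self._burst_open = True
            self._burst_peak = self.d
            self._burst_button = (
                obs.flash_location - 3 if obs.flash_location is not None else None
            )
        if self._burst_open:
            self._burst_peak = max(self._burst_peak, self.d)
            if self.d < self.da.d_baseline + 0.05:
                self.events.append(AgentEvent(self.t, "burst", {
                    "button": self._burst_button, "peak": self._burst_peak}))
                self._burst_open = False

        # 5. advance the loops under the shared dopamine level
        self.loops["manipulation"].network.step(
            dt, d=self.d, external={"cx_inner": man_in})
        self.loops["attention"].network.step(
            dt, d=self.d, external={"cx_inner": att_in})
        self.loops["goal"].network.step(
            dt, d=self.d,
            external={"cx_inner": goal_in, "striatum_d1": nacc_in})

        # 6. burst-gated Hebbian learning
        if self.learning and self.association_state and int(self.t / dt) % 100 == 0:
            for btn, rec in self.association_state.items():
                if rec["learned_t"] is None and self.association_learned(btn):
                    rec["learned_t"] = self.t
        if self.learning:
            y_pfc_inner = self._y("goal", "cx_inner")
            pairs = [
                ("pmc_to_pfc", y_pmc_ext, y_pfc_inner),
                ("fef_to_pfc", y_fef_ext, y_pfc_inner),
                ("pfc_to_pmc", y_pfc_ext, self._y("manipulation", "cx_inner")),
                ("pfc_to_fef", y_pfc_ext, self._y("attention", "cx_inner")),
                ("predictor", y_pfc_inner, np.ones(1)),
            ]
            for name, pre, post in pairs:
                hebbian_update(self.plastic[name], pre, post, self.d, dt)
        self.t += dt

    # -- protocols --------------------------------------------------------

    def run(
        self,
        duration: float,
        dt: float = 0.01,
        stride: int = 25,
        reward_schedule: Optional[List[Tuple[float, Optional[int]]]] = None,
    ) -> BoardTaskLog:
        """Free-run the agent, applying timed reward placements."""
        schedule = sorted(reward_schedule or [], key=lambda x: x[0])
        si = 0
        n_steps = int(round(duration / dt))
        ts_t, ts_d, ts_g, ts_a, ts_goal = [], [], [], [], []
        for k in range(n_steps):
            while si < len(schedule) and self.t >= schedule[si][0] - 1e-9:
                self.board.place_reward(schedule[si][1])
                self.events.append(AgentEvent(self.t, "reward_moved",
                                              {"box": schedule[si][1]}))
                si += 1
            self.step(dt)
            if k % stride == 0:
                ts_t.append(self.t)
                ts_d.append(self.d)
                ts_g.append(-1 if self.gaze is None else self.gaze)
                ts_a.append(-1 if self.action is None else self.action)
                ts_goal.append(-1 if self.goal is None else self.goal)
        return BoardTaskLog(
            t=np.asarray(ts_t),
            d=np.asarray(ts_d),
            gaze=np.asarray(ts_g),
            action=np.asarray(ts_a),
            goal=np.asarray(ts_goal),
            events=list(self.events),
            board_events=list(self.board.events),
            weights={k: m.w.copy() for k, m in self.plastic.items()},
            burst_peaks=[
                (e.t, e.detail["button"], e.detail["peak"])
                for e in self.events if e.event == "burst"
            ],
        )

    # -- learned-association probes --------------------------------------

    def predicted_flash(self, button: int, pre_level: float = 0.9) -> float:
        """Predicted inhibitory drive onto the SC pathway when pressing
        ``button`` while fixating it, computed from the forward models: the
        anticipated inner-PFC activation feeds the learned predictor."""
        from .core import transfer
        spec = self.loops["goal"].spec
        fwd = self.config.w_fwd_gain * np.sqrt(
            np.clip(pre_level * self.plastic["pmc_to_pfc"].w[PRESS], 0, None)
            * np.clip(pre_level * self.plastic["fef_to_pfc"].w[button], 0, None)
        )
        y_hat = transfer(fwd, spec.alpha_cx, spec.theta_layer1)
        return float((np.asarray(y_hat) @ self.plastic["predictor"].w)[0])

    def recall_probe(self, box: int, threshold: float = 0.3):
        """(gaze, action) recalled by activating the goal channel of ``box``
        through the inverse models; None entries mean no association yet."""
        if box not in BOXES:
            raise ValueError(f"{box} is not a box index")
        g_row = self.plastic["pfc_to_fef"].w[box]
        a_row = self.plastic["pfc_to_pmc"].w[box]
        gaze = int(np.argmax(g_row)) if g_row.max() > threshold else None
        action = int(np.argmax(a_row)) if a_row.max() > threshold else None
        return gaze, action

    def association_learned(self, button: int) -> bool:
        """True when pressing ``button`` no longer yields a full burst and
        the box's goal channel recalls (attend button, press)."""
        amp_eff = max(
            self.config.burst_amplitude - self.predicted_flash(button), 0.0)
        suppressed = (
            self.config.bout_tonic + amp_eff < self.plastic["pmc_to_pfc"].zeta
        )
        gaze, action = self.recall_probe(button + 3)
        return suppressed and gaze == button and action == PRESS

    def association_report(self) -> dict:
        """Per-button summary: press/burst counts, predictor closure and
        inverse-model recall."""
        report = {}
        for b in BUTTONS:
            rec = self.association_state.get(
                b, {"bursts": 0, "presses": 0, "learned_t": None})
            gaze, action = self.recall_probe(b + 3)
            report[b] = {
                "presses": rec["presses"],
                "bursts": rec["bursts"],
                "learned_t": rec["learned_t"],
                "predicted": self.config.bout_tonic
                + max(self.config.burst_amplitude - self.predicted_flash(b), 0.0)
                < self.plastic["pmc_to_pfc"].zeta,
                "recall_gaze": gaze,
                "recall_action": action,
                "recall_correct": gaze == b and action == PRESS,
            }
        return report


DEFAULT_REWARD_SCHEDULE = [(1260.0, 3), (1440.0, 4), (1620.0, 5)]


def board_task(
    agent: Optional[Agent] = None,
    duration: float = 1800.0,
    reward_schedule: Optional[List[Tuple[float, Optional[int]]]] = None,
    seed: int = 0,
    dt: float = 0.01,
    stride: int = 25,
) -> BoardTaskLog:
    """Run the full board task: free exploration, then reward placements.

    Phase 1 (default 0-21 min) is reward-free exploration driven by novelty;
    phase 2 places the visible reward in each box in turn (defaults: box 0
    at 21 min, box 1 at 24 min, box 2 at 27 min).  Returns the run log with
    the learned-association report attached.
    """
    if agent is None:
        agent = Agent(seed=seed)
    if reward_schedule is None:
        reward_schedule = list(DEFAULT_REWARD_SCHEDULE)
    log = agent.run(duration, dt=dt, stride=stride,
                    reward_schedule=reward_schedule)
    log.associations = agent.association_report()
    return log


def classify_behavior_mode(log: BoardTaskLog, t0: float, t1: float) -> str:
    """Label a window of a run log as rest / visual_exploration /
    motor_exploration / goal_directed.

    rest: no selections in either loop.  visual_exploration: gaze moves with
    no completed actions.  motor_exploration: stable gaze with repeated
    action initiations.  goal_directed: the prefrontal layer is active and
    biasing the other loops.
    """
    if t1 - t0 < 10.0:
        raise ValueError("classification window must span at least 10 s")
    win = (log.t >= t0) & (log.t < t1)
    if not win.any():
        raise ValueError("window outside the logged range")
    gaze = log.gaze[win]
    action = log.action[win]
    goal = log.goal[win]
    completed = [
        e for e in log.board_events
        if e.event.startswith("completed") and t0 <= e.t < t1
    ]
    if (goal >= 0).mean() > 0.4:
        return "goal_directed"
    gaze_active = gaze[gaze >= 0]
    act_active = action[action >= 0]
    if len(gaze_active) == 0 and len(act_active) == 0:
        return "rest"
    gaze_switches = int((np.diff(gaze_active) != 0).sum()) if len(gaze_active) else 0
    act_runs = int((np.diff(act_active) != 0).sum()) + (1 if len(act_active) else 0)
    stable_gaze = (
        len(gaze_active) > 0
        and gaze_switches == 0
        and (gaze >= 0).mean() > 0.5
    )
    if stable_gaze and (act_runs >= 2 or len(completed) >= 2):
        return "motor_exploration"
    if len(completed) == 0 or not stable_gaze:
        return "visual_exploration"
    return "motor_exploration"
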