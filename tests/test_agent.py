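"""Tests for the three-loop agent: dopamine control, learning, behavior."""

import numpy as np
import pytest

from bgloops.agent import Agent, AgentConfig, BoardTaskLog, classify_behavior_mode
from bgloops.board import PRESS

DT = 0.01


class ScriptedAgent(Agent):
    """Agent whose attention/manipulation loops are driven onto fixed
    channels by strong external drive (probe harness)."""

    def __init__(self, gaze_ch=0, action_ch=PRESS, **kw):
        super().__init__(**kw)
        att = np.zeros(6)
        att[gaze_ch] = 1.2
        man = np.zeros(3)
        man[action_ch] = 1.2
        self.extra_inputs = {"attention": att, "manipulation": man}


def run_for(agent, seconds):
    for _ in range(int(round(seconds / DT))):
        agent.step(DT)
    return agent


class TestNoveltyTonicLoop:
    def test_fixating_novel_cue_raises_tonic_da_within_5s(self):
        ag = ScriptedAgent(gaze_ch=2, action_ch=1, learning=False)
        ag.extra_inputs.pop("manipulation")
        run_for(ag, 5.0)
        assert ag.d > 1.02

    def test_da_returns_near_baseline_after_habituation(self):
        ag = ScriptedAgent(gaze_ch=2, action_ch=1, learning=False)
        ag.extra_inputs.pop("manipulation")
        run_for(ag, 300.0)
        # cue fully habituated: tonic excursion nearly gone
        assert ag.hip.response[2] < 0.12
        assert abs(ag.d - 1.0) < 0.1

    def test_tonic_novelty_excursion_stays_below_learning_gate(self):
        ag = ScriptedAgent(gaze_ch=1, action_ch=1, learning=False)
        ag.extra_inputs.pop("manipulation")
        peak = 0.0
        for _ in range(int(20 / DT)):
            ag.step(DT)
            peak = max(peak, ag.d)
        gate = ag.plastic["pmc_to_pfc"].zeta
        assert peak < gate
        assert peak <= ag.config.tonic_ceiling + 0.02


class TestBurstLearning:
    @pytest.fixture(scope="class")
    @staticmethod
    def pressed():
        ag = ScriptedAgent(gaze_ch=0, action_ch=PRESS, seed=3)
        return run_for(ag, 90.0)

    def test_presses_trigger_sc_events_and_learning_gate_opens(self, pressed):
        sc = [e for e in pressed.events if e.event == "sc_event"]
        assert len(sc) >= 10
        # cortico-cortical weights changed, which requires d above the gate
        assert any(m.w.max() > 0 for m in pressed.plastic.values())

    def test_burst_excursions_above_gate_only_after_sc_events(self, pressed):
        """Burst/tonic separability: dopamine above the learning gate is
        attributable to flashes (scripted run touches one button only)."""
        gate = 1.0 + pressed.config.zeta_ctx
        sc_times = [e.t for e in pressed.events if e.event == "sc_event"]
        assert sc_times, "no flashes in scripted run"
        # bursts only occur on the pressed button's box
        assert all(e.detail["box"] == 3 for e in pressed.events
                   if e.event == "sc_event")

    def test_forward_and_inverse_models_bind_box_goal_to_button_and_press(
        self, pressed
    ):
        inv_gaze = pressed.plastic["pfc_to_fef"].w
        inv_act = pressed.plastic["pfc_to_pmc"].w
        box_ch = 3
        assert inv_gaze[box_ch].argmax() == 0       # attend button 0
        assert inv_act[box_ch].argmax() == PRESS
        assert inv_gaze[box_ch].max() > 0.3
        fwd = pressed.plastic["fef_to_pfc"].w
        assert fwd[0].max() > 0.2                   # button gaze predicts goal

    def test_prediction_builds_over_repetitions(self, pressed):
        sc = [e for e in pressed.events if e.event == "sc_event"]
        preds = [e.detail["prediction"] for e in sc]
        assert preds[0] == pytest.approx(0.0, abs=1e-6)
        assert max(preds) > 0.4                  # substantial anticipation
        assert np.mean(preds[-5:]) > 0.2         # persists once learned

    def test_recall_probe_reports_the_learned_pair(self, pressed):
        gaze, action = pressed.recall_probe(3)
        assert (gaze, action) == (0, PRESS)

    def test_association_report_marks_learned_button(self, pressed):
        rep = pressed.association_report()
        assert rep[0]["presses"] >= 10
        assert 1 <= rep[0]["bursts"] <= rep[0]["presses"]
        assert rep[0]["recall_correct"]
        assert not rep[1]["recall_correct"]
        assert not rep[2]["recall_correct"]


class TestDisabledPathways:
    def test_sc_disabled_no_bursts_no_learning(self):
        ag = ScriptedAgent(gaze_ch=0, action_ch=PRESS, seed=3, sc_enabled=False)
        run_for(ag, 60.0)
        assert not [e for e in ag.events if e.event == "sc_event"]
        assert all(np.all(m.w == 0) for m in ag.plastic.values())

    def test_learning_flag_freezes_all_matrices(self):
        ag = ScriptedAgent(gaze_ch=0, action_ch=PRESS, seed=3, learning=False)
        run_for(ag, 60.0)
        assert [e for e in ag.events if e.event == "sc_event"]
        assert all(np.all(m.w == 0) for m in ag.plastic.values())


class TestAmygdalaDrive:
    def test_visible_reward_raises_da_and_decays_after_removal(self):
        ag = ScriptedAgent(gaze_ch=3, action_ch=1, learning=False)
        ag.extra_inputs.pop("manipulation")
        ag.board.place_reward(3)
        run_for(ag, 120.0)      # habituation also runs out meanwhile
        d_reward = ag.d
        assert d_reward > 1.05
        ag.board.place_reward(None)
        run_for(ag, 20.0)
        assert ag.d < d_reward - 0.5 * (d_reward - 1.0)


def synthetic_log(gaze, action, goal, dt=0.5, board_events=()):
    n = len(gaze)
    t = np.arange(n) * dt
    return BoardTaskLog(
        t=t, d=np.ones(n), gaze=np.asarray(gaze), action=np.asarray(action),
        goal=np.asarray(goal), events=[], board_events=list(board_events),
        weights={}, burst_peaks=[],
    )


class TestBehaviorModes:
    def test_rest_when_nothing_selected(self):
        log = synthetic_log([-1] * 40, [-1] * 40, [-1] * 40)
        assert classify_behavior_mode(log, 0, 20) == "rest"

    def test_visual_exploration_gaze_moves_no_actions(self):
        gaze = [0] * 10 + [4] * 10 + [2] * 20
        log = synthetic_log(gaze, [-1] * 40, [-1] * 40)
        assert classify_behavior_mode(log, 0, 20) == "visual_exploration"

    def test_motor_exploration_fixed_gaze_many_actions(self):
        gaze = [3] * 40
        action = ([0] * 8 + [1] * 8 + [2] * 8 + [0] * 8 + [1] * 8)
        log = synthetic_log(gaze, action, [-1] * 40)
        assert classify_behavior_mode(log, 0, 20) == "motor_exploration"

    def test_goal_directed_when_prefrontal_layer_is_active(self):
        log = synthetic_log([1] * 40, [0] * 40, [4] * 40)
        assert classify_behavior_mode(log, 0, 20) == "goal_directed"

    def test_window_too_short_rejected(self):
        log = synthetic_log([-1] * 40, [-1] * 40, [-1] * 40)
        with pytest.raises(ValueError):
            classify_behavior_mode(log, 0, 5)


class TestDifferentialSensitivity:
    def test_da_clamped_agent_never_learns(self):
        """With dopamine pinned at baseline, flashes occur but the Hebbian
        gate never opens: the degenerate control for exploration efficiency."""
        ag = ScriptedAgent(gaze_ch=0, action_ch=PRESS, seed=3)
        ag.da.update_da = lambda **kw: 1.0      # clamp the dopamine circuit
        run_for(ag, 60.0)
        assert [e for e in ag.events if e.event == "sc_event"]
        assert all(np.all(m.w == 0) for m in ag.plastic.values())

    def test_ventral_loop_activates_only_at_burst_level_dopamine(self):
        """The goal loop stays below selection under novelty-scale drive at
        tonic dopamine and selects under flash-scale drive at burst DA."""
        from bgloops.loops import build_loop

        cfg = AgentConfig()
        novelty_drive_level = cfg.w_novelty_pfc * 1.1   # novel cue, mild DA
        flash_drive_level = cfg.w_flash_pfc * 1.6       # flash during burst
        for drive, d, should_select in (
            (novelty_drive_level, 1.15, False),
            (flash_drive_level, 1.8, True),
        ):
            loop = build_loop("goal")
            vec = np.zeros(6)
            vec[2] = drive
            for _ in range(300):
                loop.network.step(0.01, d=d, external={"cx_inner": vec})
            y_ext = loop.network.state.y[loop.network.index["cx_outer"]]
            assert (y_ext.max() > 0) == should_select
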