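"""A shortened mechatronic-board run: exploration and association learning.

The agent freely explores six cues (three buttons, three transparent
boxes).  Fixating a novel cue raises tonic dopamine, waking the motor loop;
a completed press on a button flashes the matched box and fires a phasic
burst that gates Hebbian learning.  After several repetitions the flash
becomes self-predicted (no more bursts) and exploration moves on.  The
report below shows, per button: presses, burst-bearing presses, whether
the flash is predicted, and whether activating the box's goal channel
recalls (attend the button, press).
"""

from bgloops.agent import Agent, board_task, classify_behavior_mode

agent = Agent(seed=3)
log = board_task(agent, duration=600.0, reward_schedule=[])
print("button  presses  bursts  predicted  recall         learned at")
for b, rec in log.associations.items():
    recall = f"gaze={rec['recall_gaze']} action={rec['recall_action']}"
    t = "-" if rec["learned_t"] is None else f"{rec['learned_t']:.0f} s"
    print(f"   {b}      {rec['presses']:3d}     {rec['bursts']:3d}      "
          f"{str(rec['predicted']):5s}   {recall:20s} {t}")
n_flash = sum(1 for e in log.board_events if e.event == "flash")
print(f"\nflashes: {n_flash}, dopamine peak: {log.d.max():.2f} "
      f"(baseline 1.0, learning gate {agent.plastic['pmc_to_pfc'].zeta:.2f})")
for t0 in (0.0, 300.0):
    mode = classify_behavior_mode(log, t0, t0 + 60.0)
    print(f"behavior in [{t0:.0f}, {t0+60:.0f}] s: {mode}")
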