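"""Hippocampal novelty habituation under sustained exposure.

A spatial cue's novelty response starts at 1.0 and decays to a floor of 0.1
in about two minutes of fixation; high dopamine re-amplifies the emitted
(scaled) response without resetting the underlying habituation.
"""

from bgloops.neuromod import HabituationField

field = HabituationField()
dt = 0.01
print("exposure (s) -> response")
elapsed = 0.0
marks = [0, 30, 60, 90, 120, 180]
for mark in marks:
    while elapsed < mark:
        field.habituate(0, dt)
        elapsed += dt
    print(f"  {mark:>4d}        {field.response[0]:.3f}")
print(f"\nemitted response at baseline DA : {field.response[0] * field.gain(1.0):.3f}")
print(f"emitted response during a burst : {field.response[0] * field.gain(1.8):.3f}")
print("The floor is 0.1; a burst transiently re-amplifies a familiar cue.")
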