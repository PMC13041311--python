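"""Allometric dose arithmetic: from the human label dose to the rat study doses.

The maximum labelled human dose (2 g every 8 h) is converted to mg/kg/day for
a 70-kg patient, scaled to the rat by the FDA body-surface-area factor 6.2,
and escalated to the maximum tolerated (3x) and lethal (4x) rat doses.
"""

import cefetox as cx

human = 3 * 2000 / 70
rat = cx.hed_to_rat_dose(human)
ladder = cx.escalation_plan(round(rat), [1, 3, 4])

print(f"human maximum daily dose : {human:.1f} mg/kg/day (rounds to {round(human)})")
print(f"rat-equivalent (x6.2)    : {rat:.1f} mg/kg/day (rounds to {round(rat)})")
print(f"escalation ladder        : {ladder} mg/kg/day")
print(f"round trip               : {cx.rat_to_hed_dose(rat):.2f} mg/kg/day")
print()
print("531 mg/kg/day is the allometric starting dose; 1,593 mg/kg is the")
print("maximum tolerated single dose in AKI rats; 2,124 mg/kg was lethal.")
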