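"""Score both instruments from raw item responses.

The CLDQ-NASH total is the mean of six domain means (range 1-7, higher =
better); the EQ-5D-5L index starts at 1.00 and subtracts the US societal
tariff decrement for each dimension/level, down to -0.573 for the worst
state.
"""

import cldqmap as cm

# one respondent: mostly mild problems
cldq_items = [6, 5, 6, 6, 5,          # abdominal
              5, 6, 5, 5, 6, 5, 6,    # activity/energy
              6, 6, 5, 6, 5, 6, 6, 5, # emotional
              5, 5, 4, 5, 5, 6, 5,    # fatigue
              6, 6, 5, 6,             # systemic
              6, 5, 6, 6, 5]          # worry
eq5d_state = [1, 1, 2, 2, 1]  # slight problems with activities and pain

cldq = cm.score_cldq(cldq_items)
index = cm.score_eq5d(eq5d_state)

print("CLDQ-NASH domain scores (1-7, higher = better):")
for dom, score in cldq.domain_scores.items():
    print(f"  {dom:10s} {score:.3f}")
print(f"  total      {cldq.total:.3f}")
print(f"\nEQ-5D-5L state {tuple(eq5d_state)} -> index {index:.3f}")
print(f"extremes: best {cm.score_eq5d([1]*5):.3f}, worst {cm.score_eq5d([5]*5):.3f}")
# the index is 1 minus the tariff decrements of the two level-2 responses
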