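"""Build a training session and a test block; evaluate the learning criterion.

Shows the fixed trial compositions (48 training trials at 12/12/6/6/6/6,
three test days of 8 probes at 2/2/1/1/1/1), the two-consecutive-sessions
>= 75% criterion, and the one-sided exact binomial tail that justifies it.
"""

from collections import Counter

from numfish import build_test_block, build_training_session, criterion_binomial_p, criterion_reached
from numfish.protocol import Phase

plan = build_training_session((3, 6), rewarded_rule="larger", rng=0)
print(f"training session: {len(plan.trials)} trials")
for cond, n in Counter(t.condition.label() for t in plan.trials).most_common():
    print(f"  {cond:>16}: {n}")

block = build_test_block((2, 3), rng=0)
probes = [t for day in block for t in day.trials if t.phase is Phase.PROBE]
print(f"test block: {len(block)} days, {len(probes)} probe trials total")

accs = [0.70, 0.76, 0.80]
reached, idx = criterion_reached(accs)
print(f"accuracies {accs} -> criterion reached: {reached} at session {idx}")
p = criterion_binomial_p(36, 48)
print(
    f"P(X >= 36 | 48 trials, chance) = {p:.2e}: two criterion sessions at 75% "
    "are far beyond chance."
)
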