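"""Trace the weight dynamics of the winning updating rules on 8-trial
fixtures whose behavior can be checked by eye.

The weighted-rate rule shifts part of a fixed "weight" resource to the
target color after every trial (with forgetting); the rate on a trial is
the baseline rate scaled by the weight of that trial's target color, so
repeats run faster than switches, and consecutive repeats accumulate.
"""

import numpy as np

import poprime as pp
from poprime.paradigm import session_to_arrays
from poprime.rules import get_rule_spec, run_rules
from poprime.synth import generate_fixture_suite

fixtures = generate_fixture_suite(seed=0)

colors = [s.target_color for s in fixtures["color"].stimuli]
arrays = session_to_arrays(fixtures["color"])
_, scale, _ = run_rules(
    arrays, [(get_rule_spec("color", "weighted_rate"), {"alpha": 0.8, "delta": 0.2})]
)
print("trial:        ", list(range(1, 9)))
print("target color: ", colors)
print("rate scale:   ", np.round(scale, 3))
# trials 2-3 repeat the color: the scale climbs above 1 and accumulates;
# trial 5 repeats after a run of the other color, so its scale is much lower.

targets = [s.target_position for s in fixtures["position"].stimuli]
arrays = session_to_arrays(fixtures["position"])
_, scale, _ = run_rules(
    arrays,
    [(get_rule_spec("position", "weighted_rate_di"),
      {"alpha": 0.9, "delta_t": 0.3, "delta_d": 0.2})],
)
print("\ntarget position:", targets)
print("rate scale:     ", np.round(scale, 3))
# trials 4 and 7 both move the target onto a previous distractor position
# (TD); the trial-7 weight is lower because distractors kept occupying that
# position in the interim — distractor inhibition accumulates.
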