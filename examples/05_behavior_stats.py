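"""Behavioral statistics: adjusted logit, response speed, permutation tests.

Simulates behavior for a small cohort and contrasts valid / invalid /
neutral temporal-cue trials with the sign-flip permutation test on
logit-transformed accuracy and on 1/RT response speed.
"""

import numpy as np

import alpharhythm as ar
from alpharhythm.simulate import validity_class

n_participants = 12
pc = {"valid": [], "invalid": [], "neutral": []}
speed = {"valid": [], "invalid": [], "neutral": []}
for pid in range(n_participants):
    schedule = ar.make_trial_schedule(160, seed=pid)
    beh = ar.simulate_behavior(schedule, ar.GeneratorParams(seed=pid))
    merged = schedule.merge(beh, on="trial_id")
    cls = validity_class(merged)
    for c in pc:
        cell = merged[(cls == c).to_numpy()]
        pc[c].append(cell["correct"].mean())
        speed[c].append(ar.response_speed(cell["rt"].to_numpy()).mean())

for c in pc:
    print(f"{c:8s} accuracy = {np.mean(pc[c]):.3f}  speed = {np.mean(speed[c]):.3f} 1/s")

t, p = ar.perm_ttest_paired(
    ar.logit_adj(np.array(pc["valid"])), ar.logit_adj(np.array(pc["invalid"])),
    n_perm=10000, seed=0,
)
print(f"valid vs invalid (logit accuracy): t = {t:.2f}, p = {p:.4f}")
t, p = ar.perm_ttest_paired(
    np.array(pc["invalid"]), np.array(pc["neutral"]), n_perm=10000, seed=1
)
print(f"invalid vs neutral (accuracy):     t = {t:.2f}, p = {p:.4f}")
# Valid cues beat invalid ones decisively (planted 0.93 vs 0.79), while
# invalid and neutral (0.79 vs 0.80) are statistically indistinguishable.
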