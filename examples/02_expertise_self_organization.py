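"""Self-organised decision order when group members differ in ability.

Agents share thresholds but differ in personal drift rate (how quickly they
extract evidence from the stimulus).  High-drift "experts" reach their
thresholds sooner, so the group self-organises: experts decide early and
seed accurate social information that the less able members then follow.
"""

import numpy as np
from scipy.stats import spearmanr

from collective_cognition import get_scenario, simulate_group

N_TRIALS = 4000

sc = get_scenario("ddm-expertise")
tr = simulate_group(sc.agents, dt=sc.dt, t_max=sc.t_max,
                    n_trials=N_TRIALS, seed=3)

drifts = [a.delta_p for a in sc.agents]
mean_rt = np.nanmean(tr.decision_time, axis=0)
acc = (tr.choice == 1).mean(axis=0)

print(f"{'agent':>5} {'drift':>6} {'mean RT':>8} {'accuracy':>9}")
for i, (d, rt, a) in enumerate(zip(drifts, mean_rt, acc), start=1):
    print(f"{i:>5} {d:>6.3f} {rt:>8.3f} {a:>9.3f}")
rho = spearmanr(drifts, mean_rt).statistic
print(f"\nSpearman(drift, mean RT) = {rho:+.2f}: the most able agents "
      "decide first, and their early accurate choices raise everyone's "
      "accuracy through the majority signal.")
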