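"""Collective intelligence versus maladaptive herding in social learners.

Five reinforcement learners choose repeatedly between two options whose
Gaussian payoffs (means 15 and 20, SD 3) swap halfway through 100 trials.
Everyone updates values with rate alpha=0.3 and chooses by softmax with
beta=0.18; the three strategies differ only in how much they copy the
previous choices of others (social weight sigma, conformity exponent theta).
The statistic reported is the share of final-quarter choices on the
post-reversal best option: weak conformity tracks the change best, strong
conformity herds on the stale option.
"""

from collective_cognition import get_scenario, simulate_rl_group

N_REPLICATES = 500

print(f"post-reversal adaptation over {N_REPLICATES} replicate groups")
print(f"{'strategy':<24} {'sigma':>5} {'theta':>5} {'adaptation':>11}")
for name in ("rl-asocial", "rl-weak-conformist", "rl-strong-conformist"):
    sc = get_scenario(name)
    tr = simulate_rl_group(sc.agents, sc.env, seed=sc.seed,
                           n_replicates=N_REPLICATES)
    share = (tr.choice[:, 75:, :] == 0).mean()
    a = sc.agents[0]
    print(f"{name:<24} {a.sigma:>5.1f} {a.theta:>5.1f} {share:>11.3f}")
print("\nWeak conformity beats both pure individual learning (information "
      "pooling) and strong conformity (maladaptive herding after the "
      "payoff reversal).")
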