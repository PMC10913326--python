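"""Information cascades in a socially coupled evidence-accumulating group.

Five identical agents accumulate noisy evidence for the correct option A;
once an agent hits a threshold its choice becomes visible and tilts the
drift of the still-undecided members toward the current majority.  We
compare decision accuracy by decision order with and without social
coupling: with coupling, later deciders inherit the accumulated majority
signal and are markedly more accurate than first movers; without coupling
the gradient disappears.
"""


from collective_cognition import AgentDDMParams, get_scenario, simulate_group

N_TRIALS = 4000

sc = get_scenario("ddm-homogeneous")
coupled = simulate_group(sc.agents, dt=sc.dt, t_max=sc.t_max,
                         n_trials=N_TRIALS, seed=1)
uncoupled = simulate_group(
    [AgentDDMParams(delta_p=a.delta_p, s=0.0, threshold_upper=a.threshold_upper,
                    threshold_lower=a.threshold_lower) for a in sc.agents],
    dt=sc.dt, t_max=sc.t_max, n_trials=N_TRIALS, seed=2)

print(f"accuracy by decision rank ({N_TRIALS} trials, 5 agents):")
print(f"{'rank':>4} {'coupled (s=0.45)':>18} {'uncoupled (s=0)':>16}")
for rank in range(1, 6):
    acc_c = (coupled.choice == 1)[coupled.decision_rank == rank].mean()
    acc_u = (uncoupled.choice == 1)[uncoupled.decision_rank == rank].mean()
    print(f"{rank:>4} {acc_c:>18.3f} {acc_u:>16.3f}")
print("\nWith social coupling, accuracy rises with decision order — the "
      "cascade pools early private evidence; without it, order is "
      "uninformative.")
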