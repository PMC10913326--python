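"""Pilot parameter-recovery run establishing estimator-precision tolerances.

Runs the RL and DDM recovery harnesses once at the study scale used by the
test-suite and the acceptance script, with a dedicated pilot seed, and
freezes per-parameter tolerances (double the pilot median absolute error,
with a small absolute floor) into ``tests/data/recovery_pilot.json``.  The
test-suite asserts that fresh recovery runs stay within these tolerances;
regenerating the file requires rerunning this script:

    python scripts/run_recovery_pilot.py
"""

from __future__ import annotations

import json
import math
import time
from pathlib import Path

from collective_cognition import (
    AgentDDMParams,
    Environment,
    RLAgentParams,
    recover_ddm,
    recover_rl,
    recovery_summary,
)

PILOT_SEED = 7777
FLOOR = {"alpha": 0.02, "beta": 0.01, "sigma": 0.02, "theta": 0.25,
         "delta_p": 0.02, "s": 0.02}

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "tests" / "data" / "recovery_pilot.json"


def main() -> None:
    t0 = time.time()
    rl_true = RLAgentParams(alpha=0.3, beta=0.18, sigma=0.3, theta=1.5)
    env = Environment(means=(15.0, 20.0), sd=3.0, n_trials=100)
    rl_rep = recover_rl(rl_true, env, n_agents=5, n_groups=12,
                        seed=PILOT_SEED, n_starts=3)
    rl_mae = recovery_summary(rl_rep)
    print(f"RL pilot ({time.time() - t0:.0f}s):", rl_mae)

    t0 = time.time()
    ddm_true = AgentDDMParams(delta_p=0.3, s=0.2, threshold_upper=1.0,
                              threshold_lower=-1.0)
    ddm_rep = recover_ddm(ddm_true, n_agents=5, n_trials=100, n_datasets=6,
                          sim_dt=0.002, t_max=20.0, seed=PILOT_SEED,
                          n_starts=2)
    ddm_mae = recovery_summary(ddm_rep)
    print(f"DDM pilot ({time.time() - t0:.0f}s):", ddm_mae)

    payload = {
        "pilot_seed": PILOT_SEED,
        "rl": {
            "true": {"alpha": 0.3, "beta": 0.18, "sigma": 0.3, "theta": 1.5},
            "n_groups": 12, "n_agents": 5, "n_trials": 100,
            "median_abs_error": {k: round(v, 5) for k, v in rl_mae.items()},
            "tolerance": {k: round(max(2 * v, FLOOR[k]), 5)
                          for k, v in rl_mae.items()},
        },
        "ddm": {
            "true": {"delta_p": 0.3, "s": 0.2},
            "n_datasets": 6, "n_agents": 5, "n_trials": 100,
            "median_abs_error": {k: round(v, 5) for k, v in ddm_mae.items()},
            "tolerance": {k: round(max(2 * v, FLOOR[k]), 5)
                          for k, v in ddm_mae.items()},
        },
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
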