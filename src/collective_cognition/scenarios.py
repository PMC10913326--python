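"""Named study scenarios, config I/O and trace summaries.

The package ships six frozen scenarios, three per model family, mirroring
the illustrative group settings the models were designed for:

DDM (5 agents, two options, option A correct):

* ``ddm-homogeneous``   -- identical agents with social coupling; decisions
  cascade and later deciders are more accurate than early ones.
* ``ddm-expertise``     -- agents differ in personal drift (ability); able
  agents decide earlier and seed accurate social information.
* ``ddm-thresholds``    -- agents differ in decision threshold
  (speed-accuracy trade-off); hasty low-threshold agents decide early at
  chance-like accuracy and drag down later deciders.

RL (5 agents, Gaussian payoffs with means 15/20 and SD 3 that swap halfway
through 100 trials; alpha = 0.3, beta = 0.18 for everyone):

* ``rl-asocial``           -- sigma = 0.
* ``rl-weak-conformist``   -- sigma = 0.3, theta = 1.5; tracks the reversal.
* ``rl-strong-conformist`` -- sigma = 0.7, theta = 5; herds on the stale option.

The RL parameter values are the published illustrative settings; the DDM
values are package choices (no canonical values exist) documented here and
in the methods note, picked so the qualitative contrasts above are clearly
expressed.  Regenerating any scenario with the same seed is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ddm import AgentDDMParams, simulate_group
from .rl import Environment, RLAgentParams, simulate_rl_group

__all__ = [
    "Scenario",
    "ddm_scenarios",
    "rl_scenarios",
    "all_scenarios",
    "get_scenario",
    "load_config",
    "save_config",
    "summarize",
    "write_trace",
]


@dataclass
class Scenario:
    """A frozen, runnable simulation setting."""

    name: str
    family: str  # "ddm" | "rl"
    agents: list
    seed: int = 0
    dt: float = 0.002            # ddm only
    t_max: float = 20.0          # ddm only
    n_trials: int = 1000         # ddm: trials per run
    env: Environment | None = None  # rl only
    n_replicates: int = 500      # rl: replicate groups per run

    def run(self, seed: int | None = None, n_trials: int | None = None,
            n_replicates: int | None = None) -> pd.DataFrame:
        """Simulate the scenario and return its long-format trace table."""
        seed = self.seed if seed is None else seed
        if self.family == "ddm":
            trace = simulate_group(
                self.agents, dt=self.dt, t_max=self.t_max,
                n_trials=n_trials or self.n_trials, seed=seed)
        elif self.family == "rl":
            trace = simulate_rl_group(
                self.agents, self.env, seed=seed,
                n_replicates=n_replicates or self.n_replicates)
        else:
            raise ValueError(f"unknown model family {self.family!r}")
        return trace.to_frame()

    def to_config(self) -> dict:
        cfg: dict = {"name": self.name, "family": self.family,
                     "seed": self.seed,
                     "agents": [asdict(a) for a in self.agents]}
        if self.family == "ddm":
            cfg.update(dt=self.dt, t_max=self.t_max, n_trials=self.n_trials)
        else:
            env = asdict(self.env)
            env["means"] = list(env["means"])
            cfg.update(environment=env, n_replicates=self.n_replicates)
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "Scenario":
        fam = cfg["family"]
        if fam == "ddm":
            agents = [AgentDDMParams(**a) for a in cfg["agents"]]
            return cls(name=cfg.get("name", "custom"), family="ddm",
                       agents=agents, seed=int(cfg.get("seed", 0)),
                       dt=float(cfg.get("dt", 0.002)),
                       t_max=float(cfg.get("t_max", 20.0)),
                       n_trials=int(cfg.get("n_trials", 1000)))
        if fam == "rl":
            agents = [RLAgentParams(**a) for a in cfg["agents"]]
            e = dict(cfg["environment"])
            e["means"] = tuple(e["means"])
            return cls(name=cfg.get("name", "custom"), family="rl",
                       agents=agents, seed=int(cfg.get("seed", 0)),
                       env=Environment(**e),
                       n_replicates=int(cfg.get("n_replicates", 500)))
        raise ValueError(f"unknown model family {fam!r}")


def load_config(path) -> Scenario:
    """Load a scenario from a YAML config file."""
    with open(path) as fh:
        return Scenario.from_config(yaml.safe_load(fh))


def save_config(scenario: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_config(), fh, sort_keys=False)


def ddm_scenarios() -> dict[str, Scenario]:
    """The three group evidence-accumulation scenarios (values documented above)."""
    mk = lambda dps, ths, s: [
        AgentDDMParams(delta_p=d, s=s, q=1.0, threshold_upper=t,
                       threshold_lower=-t, start=0.0, noise_sd=1.0)
        for d, t in zip(dps, ths)]
    return {
        "ddm-homogeneous": Scenario(
            name="ddm-homogeneous", family="ddm", seed=101,
            agents=mk([0.15] * 5, [1.15] * 5, 0.45)),
        "ddm-expertise": Scenario(
            name="ddm-expertise", family="ddm", seed=102,
            agents=mk([0.0, 0.125, 0.25, 0.375, 0.5], [1.5] * 5, 0.2)),
        "ddm-thresholds": Scenario(
            name="ddm-thresholds", family="ddm", seed=103,
            agents=mk([0.15] * 5, [0.3, 0.725, 1.15, 1.575, 2.0], 0.45)),
    }


def rl_scenarios() -> dict[str, Scenario]:
    """The three social-learning scenarios (published illustrative settings)."""
    env = Environment(means=(15.0, 20.0), sd=3.0, n_trials=100)
    mk = lambda sg, th: [RLAgentParams(alpha=0.3, beta=0.18, sigma=sg,
                                       theta=th, q0=0.0) for _ in range(5)]
    return {
        "rl-asocial": Scenario(
            name="rl-asocial", family="rl", seed=201,
            agents=mk(0.0, 1.0), env=env),
        "rl-weak-conformist": Scenario(
            name="rl-weak-conformist", family="rl", seed=202,
            agents=mk(0.3, 1.5), env=env),
        "rl-strong-conformist": Scenario(
            name="rl-strong-conformist", family="rl", seed=203,
            agents=mk(0.7, 5.0), env=env),
    }


def all_scenarios() -> dict[str, Scenario]:
    return {**ddm_scenarios(), **rl_scenarios()}


def get_scenario(name: str) -> Scenario:
    try:
        return all_scenarios()[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; available: "
                       f"{sorted(all_scenarios())}") from None


def write_trace(df: pd.DataFrame, path) -> None:
    """Write a trace CSV deterministically (byte-stable for equal inputs)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

_SUMMARY_COLS = ["metric", "k1", "k2", "value"]


def _tidy(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=_SUMMARY_COLS)


def summarize_ddm(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic summary of a group-DDM trace table.

    Metrics: ``accuracy_by_rank`` (share of A choices per decision rank),
    ``rt_quantile`` (per agent, 10/50/90%), ``mean_rt`` per agent,
    ``censored_rate`` per agent and ``group_agreement`` (mean share of the
    modal choice among deciders per trial).  Invariant to row order.
    """
    req = {"trial", "agent", "choice", "rt", "rank"}
    if not req <= set(df.columns):
        raise ValueError(f"ddm trace must have columns {sorted(req)}")
    if df.empty:
        return _tidy([])
    df = df.sort_values(["trial", "agent"]).reset_index(drop=True)
    rows = []
    dec = df[df.choice != "NA"]
    for rank, g in dec.groupby("rank"):
        rows.append(("accuracy_by_rank", int(rank), None,
                     float((g.choice == "A").mean())))
    for agent, g in df.groupby("agent"):
        obs = g[g.choice != "NA"]
        for q in (0.1, 0.5, 0.9):
            rows.append(("rt_quantile", int(agent), q,
                         float(obs.rt.quantile(q)) if len(obs) else float("nan")))
        rows.append(("mean_rt", int(agent), None,
                     float(obs.rt.mean()) if len(obs) else float("nan")))
        rows.append(("accuracy", int(agent), None,
                     float((g.choice == "A").mean())))
        rows.append(("censored_rate", int(agent), None,
                     float((g.choice == "NA").mean())))
    agree = []
    for _, g in dec.groupby("trial"):
        counts = g.choice.value_counts()
        agree.append(counts.max() / counts.sum())
    rows.append(("group_agreement", None, None,
                 float(np.mean(agree)) if agree else float("nan")))
    return _tidy(rows)


def summarize_rl(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic summary of a social-RL trace table.

    Metrics: ``choice_prop`` (share choosing each option per trial, pooled
    over replicates), ``group_agreement`` per trial (mean modal-choice
    share), and ``mean_payoff`` per trial.  Invariant to row order.
    """
    req = {"trial", "agent", "choice", "payoff"}
    if not req <= set(df.columns):
        raise ValueError(f"rl trace must have columns {sorted(req)}")
    if df.empty:
        return _tidy([])
    df = df.copy()
    if "replicate" not in df.columns:
        df["replicate"] = 1
    df = df.sort_values(["replicate", "trial", "agent"]).reset_index(drop=True)
    rows = []
    for trial, g in df.groupby("trial"):
        for opt in sorted(df.choice.unique()):
            rows.append(("choice_prop", int(trial), opt,
                         float((g.choice == opt).mean())))
        shares = g.groupby("replicate").choice.agg(
            lambda c: c.value_counts().max() / len(c))
        rows.append(("group_agreement", int(trial), None, float(shares.mean())))
        rows.append(("mean_payoff", int(trial), None, float(g.payoff.mean())))
    return _tidy(rows)


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Dispatch to the DDM or RL summary based on the trace's columns."""
    if "rank" in df.columns:
        return summarize_ddm(df)
    if "payoff" in df.columns:
        return summarize_rl(df)
    raise ValueError("not a recognised trace table (no 'rank' or 'payoff' column)")
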