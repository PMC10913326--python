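"""Social drift-diffusion model (DDM) for groups of interacting decision makers.

Each agent accumulates noisy evidence ``L`` for one of two options (A at the
upper boundary, B at the lower boundary).  The drift rate decomposes into a
personal component ``delta_p`` and a social component that responds to the
signed majority ``M = n_A - n_B`` of group members who have already decided:

    delta(t) = delta_p + s * sign(M) * |M|**q

With ``q = 1`` this is the linear majority rule; ``q < 1`` saturates (each
additional observed choice adds less), ``q > 1`` amplifies large majorities.
Decisions become visible to the still-undecided agents from the step after
they occur, which couples the agents' first-passage problems and produces
information cascades and self-organised decision ordering.

The module provides exact single-step primitives, a vectorised multi-trial
group simulator, and a closed-form constant-drift first-passage oracle used
throughout the test-suite and the numeric likelihood machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgentDDMParams",
    "MajorityState",
    "GroupDDMTrace",
    "majority_size",
    "social_drift",
    "effective_drift",
    "step_evidence",
    "simulate_group_trial",
    "simulate_group",
    "fpt_constant_drift",
]


@dataclass(frozen=True)
class AgentDDMParams:
    """Evidence-accumulation parameters for one agent.

    Parameters
    ----------
    delta_p : float
        Personal drift rate (evidence units per unit time).  Positive values
        drift toward the upper (A) boundary.
    s : float
        Social-drift scale (evidence units per unit time per unit majority).
    q : float
        Power exponent of the social drift; must be > 0.  ``q = 1`` is the
        linear majority rule.
    threshold_upper, threshold_lower : float
        Decision boundaries; ``threshold_lower < start < threshold_upper``.
    start : float
        Initial evidence state.
    noise_sd : float
        Diffusion standard deviation per unit time; must be > 0 in
        simulation (0 is allowed only in the deterministic step primitive).
    """

    delta_p: float
    s: float = 0.0
    q: float = 1.0
    threshold_upper: float = 1.0
    threshold_lower: float = -1.0
    start: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.threshold_lower < self.start < self.threshold_upper:
            raise ValueError(
                "require threshold_lower < start < threshold_upper, got "
                f"{self.threshold_lower} / {self.start} / {self.threshold_upper}"
            )
        if self.q <= 0:
            raise ValueError(f"q must be > 0, got {self.q}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class MajorityState:
    """Counts of already-decided agents and the signed majority they imply."""

    n_A: int
    n_B: int

    def __post_init__(self) -> None:
        if self.n_A < 0 or self.n_B < 0:
            raise ValueError("decision counts must be nonnegative")

    @property
    def M(self) -> int:
        return self.n_A - self.n_B


def majority_size(n_A: int, n_B: int) -> int:
    """Signed majority size ``M = n_A - n_B``; counts must be nonnegative."""
    if n_A < 0 or n_B < 0:
        raise ValueError("decision counts must be nonnegative")
    return n_A - n_B


def social_drift(M, s: float, q: float):
    """Social drift contribution ``s * sign(M) * |M|**q``.

    The sign-preserving power keeps the social drift an odd function of the
    majority, so options A and B are treated symmetrically for any q > 0.
    Accepts scalars or arrays for ``M``.
    """
    if q <= 0:
        raise ValueError(f"q must be > 0, got {q}")
    M = np.asarray(M, dtype=float)
    out = s * np.sign(M) * np.abs(M) ** q
    return float(out) if out.ndim == 0 else out


def effective_drift(params: AgentDDMParams, state: MajorityState) -> float:
    """Total drift: personal drift plus majority-dependent social drift."""
    return params.delta_p + social_drift(state.M, params.s, params.q)


def step_evidence(L, delta, dt: float, noise_sd: float, rng: np.random.Generator):
    """One Euler step of the evidence process: ``L + delta*dt + sqrt(dt)*e``.

    ``e`` is Gaussian with mean 0 and standard deviation ``noise_sd``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    L = np.asarray(L, dtype=float)
    noise = noise_sd * rng.standard_normal(L.shape)
    out = L + np.asarray(delta, dtype=float) * dt + math.sqrt(dt) * noise
    return float(out) if out.ndim == 0 else out


@dataclass
class GroupDDMTrace:
    """Result of simulating a group for one or more trials.

    Arrays are shaped ``(n_trials, n_agents)``.  ``choice`` is +1 for A
    (upper boundary), -1 for B (lower boundary) and 0 for censored agents
    that never decided within the horizon.  ``decision_rank`` is 1-based
    among deciders within a trial (0 for censored); simultaneous crossings
    share a step-end time and are ranked by agent index.  ``n_A_seen`` /
    ``n_B_seen`` are the decided-counts visible to the agent at the start of
    the step in which it decided (-1 for censored).
    """

    choice: np.ndarray
    decision_time: np.ndarray
    decision_rank: np.ndarray
    n_A_seen: np.ndarray
    n_B_seen: np.ndarray
    dt: float
    t_max: float
    seed: int | None
    agents: list[AgentDDMParams] = field(default_factory=list)
    paths: np.ndarray | None = None  # (n_steps+1, n_trials, n_agents) if recorded

    @property
    def n_trials(self) -> int:
        return self.choice.shape[0]

    @property
    def n_agents(self) -> int:
        return self.choice.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per agent x trial (documented CSV schema)."""
        n_t, n_a = self.choice.shape
        trial = np.repeat(np.arange(1, n_t + 1), n_a)
        agent = np.tile(np.arange(1, n_a + 1), n_t)
        code = self.choice.ravel()
        choice = np.where(code == 1, "A", np.where(code == -1, "B", "NA"))
        return pd.DataFrame(
            {
                "trial": trial,
                "agent": agent,
                "choice": choice,
                "rt": self.decision_time.ravel(),
                "rank": self.decision_rank.ravel(),
                "n_A_at_decision": self.n_A_seen.ravel(),
                "n_B_at_decision": self.n_B_seen.ravel(),
                "seed": -1 if self.seed is None else self.seed,
            }
        )

    def paths_frame(self) -> pd.DataFrame:
        """Long-format evidence paths (trial, agent, t, L); requires record_paths."""
        if self.paths is None:
            raise ValueError("evidence paths were not recorded")
        n_steps1, n_t, n_a = self.paths.shape
        t = np.arange(n_steps1) * self.dt
        idx = pd.MultiIndex.from_product(
            [t, np.arange(1, n_t + 1), np.arange(1, n_a + 1)],
            names=["t", "trial", "agent"],
        )
        df = pd.DataFrame({"L": self.paths.ravel()}, index=idx).reset_index()
        return df[["trial", "agent", "t", "L"]]

    def validate(self) -> None:
        """Check internal bookkeeping invariants; raises AssertionError."""
        n_t, n_a = self.choice.shape
        for i in range(n_t):
            decided = self.choice[i] != 0
            ranks = np.sort(self.decision_rank[i][decided])
            assert np.array_equal(ranks, np.arange(1, decided.sum() + 1))
            order = np.argsort(self.decision_rank[i][decided])
            times = self.decision_time[i][decided][order]
            assert np.all(np.diff(times) >= -1e-12)
            steps = self.decision_time[i][decided] / self.dt
            assert np.allclose(steps, np.round(steps), atol=1e-6)


def _param_arrays(agents: Sequence[AgentDDMParams]):
    g = lambda name: np.array([getattr(a, name) for a in agents], dtype=float)
    return (g("delta_p"), g("s"), g("q"), g("threshold_upper"),
            g("threshold_lower"), g("start"), g("noise_sd"))


def simulate_group(
    agents: Sequence[AgentDDMParams],
    dt: float = 0.001,
    t_max: float = 20.0,
    n_trials: int = 1,
    seed: int | np.random.Generator | None = None,
    record_paths: bool = False,
) -> GroupDDMTrace:
    """Simulate ``n_trials`` independent trials of a socially coupled group.

    Within a step every still-undecided agent advances with the effective
    drift computed from the majority state at the START of the step; agents
    whose evidence reaches a boundary are recorded at the step-end time and
    their decision feeds the majority from the NEXT step on.  Agents that
    never decide by ``t_max`` are censored (choice ``0``, time NaN).

    Reproducible: a fixed ``(seed, agents, dt, t_max, n_trials)`` yields a
    bit-identical trace.
    """
    if len(agents) < 1:
        raise ValueError("need at least one agent")
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be > 0")
    delta_p, s, q, up, lo, start, sd = _param_arrays(agents)
    n_a = len(agents)
    n_steps = int(round(t_max / dt))
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    else:
        rng, seed_out = np.random.default_rng(seed), seed

    if record_paths and n_trials > 64:
        raise ValueError("record_paths is limited to <= 64 trials")

    # full-size outputs, indexed by original trial id
    choice = np.zeros((n_trials, n_a), dtype=np.int8)
    dec_time = np.full((n_trials, n_a), np.nan)
    dec_rank = np.zeros((n_trials, n_a), dtype=np.int32)
    nA_seen = np.full((n_trials, n_a), -1, dtype=np.int32)
    nB_seen = np.full((n_trials, n_a), -1, dtype=np.int32)

    # compact working arrays for trials still containing undecided agents
    idx = np.arange(n_trials)
    L = np.tile(start, (n_trials, 1))
    dec = np.zeros((n_trials, n_a), dtype=np.int8)
    nA = np.zeros(n_trials, dtype=np.int64)
    nB = np.zeros(n_trials, dtype=np.int64)
    ndec = np.zeros(n_trials, dtype=np.int64)

    paths = None
    if record_paths:
        paths = np.empty((n_steps + 1, n_trials, n_a))
        paths[0] = L

    sqrt_dt = math.sqrt(dt)
    for k in range(n_steps):
        if idx.size == 0:
            break
        t_end = (k + 1) * dt
        M = nA - nB
        soc = s * np.sign(M)[:, None] * np.abs(M)[:, None].astype(float) ** q
        drift = delta_p + soc
        undec = dec == 0
        noise = rng.standard_normal(L.shape)
        L = np.where(undec, L + drift * dt + sqrt_dt * sd * noise, L)
        hit_up = undec & (L >= up)
        hit_lo = undec & (L <= lo) & ~hit_up
        new = hit_up | hit_lo
        if new.any():
            nA0, nB0 = nA.copy(), nB.copy()
            # 1-based rank: deciders so far + within-step order by agent index
            rank_mat = ndec[:, None] + np.cumsum(new, axis=1)
            tr, ag = np.nonzero(new)
            orig = idx[tr]
            choice[orig, ag] = np.where(hit_up[tr, ag], 1, -1)
            dec_time[orig, ag] = t_end
            dec_rank[orig, ag] = rank_mat[tr, ag]
            nA_seen[orig, ag] = nA0[tr]
            nB_seen[orig, ag] = nB0[tr]
            dec[hit_up] = 1
            dec[hit_lo] = -1
            nA += hit_up.sum(axis=1)
            nB += hit_lo.sum(axis=1)
            ndec += new.sum(axis=1)
            if not record_paths:
                keep = ndec < n_a
                if keep.sum() < 0.75 * idx.size:
                    idx, L, dec = idx[keep], L[keep], dec[keep]
                    nA, nB, ndec = nA[keep], nB[keep], ndec[keep]
        if record_paths:
            paths[k + 1] = L
            if (ndec == n_a).all():
                paths = paths[: k + 2]
                break

    return GroupDDMTrace(
        choice=choice, decision_time=dec_time, decision_rank=dec_rank,
        n_A_seen=nA_seen, n_B_seen=nB_seen, dt=dt, t_max=t_max,
        seed=seed_out, agents=list(agents), paths=paths,
    )


def simulate_group_trial(
    agents: Sequence[AgentDDMParams],
    dt: float = 0.001,
    t_max: float = 20.0,
    seed: int | np.random.Generator | None = None,
    record_paths: bool = False,
) -> GroupDDMTrace:
    """Single-trial convenience wrapper around :func:`simulate_group`."""
    return simulate_group(agents, dt=dt, t_max=t_max, n_trials=1, seed=seed,
                          record_paths=record_paths)


def fpt_constant_drift(
    delta: float,
    start: float,
    lower: float,
    upper: float,
    noise_sd: float = 1.0,
) -> tuple[float, float]:
    """Closed-form two-boundary Wiener first-passage quantities.

    Returns ``(p_upper, mean_fpt)`` for a Brownian motion with constant drift
    ``delta`` and diffusion SD ``noise_sd`` started at ``start`` strictly
    between absorbing boundaries ``lower`` and ``upper``:

    * ``p_upper = (1 - exp(-2*delta*z/sd^2)) / (1 - exp(-2*delta*a/sd^2))``
      with ``z = start - lower``, ``a = upper - lower``; ``z/a`` at zero drift.
    * unconditional mean absorption time: ``(a*p_upper - z)/delta`` by Wald's
      identity, or ``z*(a - z)/sd^2`` at zero drift.
    """
    if not lower < start < upper:
        raise ValueError("start must lie strictly between the boundaries")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    z = start - lower
    a = upper - lower
    s2 = noise_sd**2
    # treat |delta| below this as 0 to avoid catastrophic cancellation
    if abs(delta) < 1e-12:
        return z / a, z * (a - z) / s2
    p_upper = math.expm1(-2.0 * delta * z / s2) / math.expm1(-2.0 * delta * a / s2)
    mean_t = (a * p_upper - z) / delta
    return p_upper, mean_t
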