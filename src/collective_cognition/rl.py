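"""Social reinforcement learning in groups: value updating plus conformist copying.

Agents repeatedly choose between options, receive noisy payoffs and update
latent values by the Rescorla-Wagner delta rule

    Q[i] <- Q[i] + alpha * (payoff - Q[i])        (chosen option only)

A softmax with inverse temperature ``beta`` maps values to asocial choice
probabilities.  Social agents mix those with a frequency-dependent copying
term built from the counts ``n[i]`` of other group members choosing each
option on the previous trial:

    P[i]   = (1 - sigma) * softmax_i + sigma * P_S[i]
    P_S[i] = n[i]**theta / sum_m n[m]**theta

``sigma`` weighs social against personal information; ``theta`` is the
conformity exponent (theta > 1 over-weights majorities -- conformity;
0 < theta < 1 under-weights them -- anticonformity).  Environments are
Gaussian bandits whose option means are permuted after a changepoint,
emulating a mid-experiment payoff reversal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RLAgentParams",
    "Environment",
    "RLGroupTrace",
    "NoSocialInformation",
    "update_q",
    "softmax_choice_prob",
    "conformist_prob",
    "combined_choice_prob",
    "simulate_rl_group",
]


class NoSocialInformation(Exception):
    """Raised when all option counts are zero, so no copying target exists."""


@dataclass(frozen=True)
class RLAgentParams:
    """Learning parameters of one agent.

    alpha: updating rate in [0, 1]; beta: softmax inverse temperature >= 0;
    sigma: social-learning weight in [0, 1]; theta: conformity exponent > 0;
    q0: initial latent value per option (payoff units).
    """

    alpha: float
    beta: float
    sigma: float = 0.0
    theta: float = 1.0
    q0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must be in [0, 1], got {self.sigma}")
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")


@dataclass(frozen=True)
class Environment:
    """Gaussian two-armed (or k-armed) bandit with a payoff reversal.

    ``means`` are the pre-reversal option means (points); after trial
    ``changepoint`` the means are reversed (for two options this swaps
    them), so an initially inferior option becomes the best.
    """

    means: tuple[float, ...] = (15.0, 20.0)
    sd: float = 3.0
    n_trials: int = 100
    changepoint: int | None = None  # defaults to n_trials // 2

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        cp = self.n_trials // 2 if self.changepoint is None else self.changepoint
        if not 1 <= cp <= self.n_trials:
            raise ValueError("changepoint must lie in [1, n_trials]")
        object.__setattr__(self, "changepoint", cp)

    @property
    def n_options(self) -> int:
        return len(self.means)

    def means_at(self, trial: int) -> tuple[float, ...]:
        """Option means in force on 1-based ``trial`` (reversed after changepoint)."""
        if trial <= self.changepoint:
            return self.means
        return tuple(reversed(self.means))


def update_q(q: float, payoff: float, alpha: float) -> float:
    """Delta-rule update of the chosen option's value."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return q + alpha * (payoff - q)


def softmax_choice_prob(q_values, beta: float) -> np.ndarray:
    """Softmax ``exp(beta*Q_i) / sum_m exp(beta*Q_m)``, overflow-safe."""
    q = np.asarray(q_values, dtype=float)
    b = np.asarray(beta, dtype=float)
    if np.any(b < 0):
        raise ValueError(f"beta must be >= 0, got {beta}")
    if not np.all(np.isfinite(q)):
        raise ValueError("Q values must be finite")
    x = b * q
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


def conformist_prob(counts, theta: float) -> np.ndarray:
    """Frequency-dependent copying probabilities ``n_i**theta / sum n_m**theta``.

    Uses the convention ``0**theta = 0``.  Raises
    :class:`NoSocialInformation` when every count is zero (no observable
    choices to copy), so callers can fall back to the asocial rule instead
    of dividing by zero.
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    n = np.asarray(counts, dtype=float)
    if np.any(n < 0):
        raise ValueError("counts must be nonnegative")
    if not n.any():
        raise NoSocialInformation("all option counts are zero")
    w = np.where(n > 0, n**theta, 0.0)
    return w / w.sum(axis=-1, keepdims=True)


def combined_choice_prob(q_values, beta: float, counts, sigma: float,
                         theta: float) -> np.ndarray:
    """Mixture ``(1-sigma)*softmax + sigma*conformist``; falls back to the
    asocial softmax when no social information is available."""
    if not 0.0 <= sigma <= 1.0:
        raise ValueError(f"sigma must be in [0, 1], got {sigma}")
    p_a = softmax_choice_prob(q_values, beta)
    if sigma == 0.0:
        return p_a
    try:
        p_s = conformist_prob(counts, theta)
    except NoSocialInformation:
        return p_a
    return (1.0 - sigma) * p_a + sigma * p_s


@dataclass
class RLGroupTrace:
    """Arrays from a group simulation, shaped ``(n_replicates, n_trials, n_agents)``
    (option-indexed arrays carry a trailing option axis).

    ``choice`` holds 0-based option indices.  ``q_before`` are latent values
    before the trial's choice; probability arrays are the asocial softmax,
    the copying term (NaN when no social information) and their mixture.
    ``counts_prev`` are the other-agent choice counts from the previous
    trial that the agent observed.
    """

    choice: np.ndarray
    payoff: np.ndarray
    q_before: np.ndarray
    p_asocial: np.ndarray
    p_social: np.ndarray
    p_combined: np.ndarray
    counts_prev: np.ndarray
    env: Environment
    agents: list[RLAgentParams]
    seed: int | None

    @property
    def n_replicates(self) -> int:
        return self.choice.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per replicate x trial x agent."""
        n_r, n_t, n_a = self.choice.shape
        rep, tri, agent = np.meshgrid(
            np.arange(1, n_r + 1), np.arange(1, n_t + 1), np.arange(1, n_a + 1),
            indexing="ij",
        )
        labels = np.array([chr(ord("A") + i) for i in range(self.env.n_options)])
        df = pd.DataFrame(
            {
                "replicate": rep.ravel(),
                "trial": tri.ravel(),
                "agent": agent.ravel(),
                "choice": labels[self.choice.ravel()],
                "payoff": self.payoff.ravel(),
                "Q_A": self.q_before[..., 0].ravel(),
                "Q_B": self.q_before[..., 1].ravel(),
                "p_asocial_A": self.p_asocial[..., 0].ravel(),
                "p_social_A": self.p_social[..., 0].ravel(),
                "p_combined_A": self.p_combined[..., 0].ravel(),
                "n_A_prev": self.counts_prev[..., 0].ravel(),
                "n_B_prev": self.counts_prev[..., 1].ravel(),
                "seed": -1 if self.seed is None else self.seed,
            }
        )
        return df


def simulate_rl_group(
    agents: Sequence[RLAgentParams],
    env: Environment,
    seed: int | np.random.Generator | None = None,
    n_replicates: int = 1,
    include_self: bool = False,
) -> RLGroupTrace:
    """Simulate repeated choices of a socially learning group.

    On every trial each agent draws a choice from its combined probability,
    where the copying term uses the counts of the OTHER agents' choices on
    the previous trial (``include_self=True`` switches to all-member
    counts).  Trial 1 has no social information and is asocial.  Payoffs are
    Gaussian with the environment's means (reversed after the changepoint).
    Vectorised over replicate groups; reproducible given ``seed``.
    """
    if len(agents) < 1:
        raise ValueError("need at least one agent")
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    else:
        rng, seed_out = np.random.default_rng(seed), seed
    n_a, n_o, n_t = len(agents), env.n_options, env.n_trials
    alpha = np.array([a.alpha for a in agents])
    beta = np.array([a.beta for a in agents])
    sigma = np.array([a.sigma for a in agents])
    theta = np.array([a.theta for a in agents])
    q0 = np.array([a.q0 for a in agents])

    R = n_replicates
    Q = np.tile(q0[None, :, None], (R, 1, n_o)).astype(float)
    choice = np.zeros((R, n_t, n_a), dtype=np.int64)
    payoff = np.zeros((R, n_t, n_a))
    q_before = np.zeros((R, n_t, n_a, n_o))
    p_asoc = np.zeros((R, n_t, n_a, n_o))
    p_soc = np.full((R, n_t, n_a, n_o), np.nan)
    p_comb = np.zeros((R, n_t, n_a, n_o))
    counts_prev = np.zeros((R, n_t, n_a, n_o), dtype=np.int64)

    prev_choice = None  # (R, n_a) option indices from trial t-1
    eye = np.eye(n_o, dtype=np.int64)
    for t in range(1, n_t + 1):
        q_before[:, t - 1] = Q
        pa = softmax_choice_prob(Q, beta[None, :, None])
        p = pa.copy()
        if prev_choice is not None:
            onehot = eye[prev_choice]                      # (R, n_a, n_o)
            total = onehot.sum(axis=1, keepdims=True)      # (R, 1, n_o)
            counts = total - onehot if not include_self else np.broadcast_to(
                total, onehot.shape)
            counts_prev[:, t - 1] = counts
            nz = counts.sum(axis=-1) > 0                   # (R, n_a)
            w = np.where(counts > 0, counts.astype(float) ** theta[None, :, None], 0.0)
            with np.errstate(invalid="ignore"):
                ps = w / w.sum(axis=-1, keepdims=True)
            ps = np.where(nz[..., None], ps, np.nan)
            p_soc[:, t - 1] = ps
            mix = (1 - sigma[None, :, None]) * pa + sigma[None, :, None] * ps
            p = np.where(nz[..., None], mix, pa)
        p_asoc[:, t - 1] = pa
        p_comb[:, t - 1] = p
        u = rng.random((R, n_a))
        c = (u[..., None] > np.cumsum(p, axis=-1)).sum(axis=-1)
        c = np.minimum(c, n_o - 1)
        choice[:, t - 1] = c
        means_t = np.array(env.means_at(t))
        pay = means_t[c] + env.sd * rng.standard_normal((R, n_a))
        payoff[:, t - 1] = pay
        rr, aa = np.meshgrid(np.arange(R), np.arange(n_a), indexing="ij")
        Q[rr, aa, c] += alpha[None, :] * (pay - Q[rr, aa, c])
        prev_choice = c

    return RLGroupTrace(
        choice=choice, payoff=payoff, q_before=q_before, p_asocial=p_asoc,
        p_social=p_soc, p_combined=p_comb, counts_prev=counts_prev,
        env=env, agents=list(agents), seed=seed_out,
    )
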