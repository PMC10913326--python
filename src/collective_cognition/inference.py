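"""Likelihood evaluation, maximum-likelihood fitting and parameter recovery.

Two model families are supported:

* the social RL model -- the likelihood reconstructs each agent's latent
  values from its recorded choices and payoffs with the delta rule and
  scores every realized choice under the mixture of softmax and conformist
  copying probabilities;
* the social DDM -- each agent's drift schedule within a trial is fixed by
  the observed decision times of the other group members (treated as
  exogenous covariates, the standard conditional factorization), and the
  agent's own (boundary, decision time) is scored under the numeric
  first-passage density of that piecewise-constant-drift process.

Fitting is plain bounded MLE with multi-start jitter; ``noise_sd`` is held
fixed during DDM fitting because the Wiener likelihood is invariant to a
joint rescaling of drift, thresholds and diffusion.  Standard errors come
from the numeric Hessian of the negative log-likelihood on the unconstrained
(transformed) scale, delta-method mapped back to the natural scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .ddm import AgentDDMParams
from .fpt import SpectralFPT, ddm_fpt_grid  # noqa: F401  (re-exported)
from .rl import RLAgentParams, softmax_choice_prob

__all__ = [
    "TrialTableError",
    "rl_loglik",
    "rl_fit",
    "RLFitResult",
    "social_ddm_loglik",
    "ddm_fit",
    "DDMFitResult",
    "ddm_fpt_grid",
    "recover_rl",
    "recover_ddm",
    "aic",
]

_DENSITY_FLOOR = 1e-300


class TrialTableError(ValueError):
    """Raised when a trial table is internally inconsistent."""


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion ``2k - 2*loglik``."""
    return 2.0 * n_params - 2.0 * loglik


# --------------------------------------------------------------------------
# social RL likelihood and fitting
# --------------------------------------------------------------------------

def _rl_arrays(trials: pd.DataFrame):
    """Pivot a long trial table into (choices, payoffs, counts) per replicate."""
    req = {"trial", "agent", "choice", "payoff", "n_A_prev", "n_B_prev"}
    missing = req - set(trials.columns)
    if missing:
        raise TrialTableError(f"trial table missing columns: {sorted(missing)}")
    df = trials.copy()
    if "replicate" not in df.columns:
        df["replicate"] = 1
    out = []
    for rep, g in df.groupby("replicate", sort=True):
        piv = lambda col: g.pivot_table(index="trial", columns="agent",
                                        values=col, aggfunc="first",
                                        observed=True).sort_index()
        ch = g.pivot(index="trial", columns="agent", values="choice").sort_index()
        if ch.isna().any().any():
            raise TrialTableError(f"replicate {rep}: missing agent rows")
        codes = ch.map(lambda c: {"A": 0, "B": 1}.get(c, -1)).to_numpy()
        if (codes < 0).any():
            raise TrialTableError(f"replicate {rep}: choices must be 'A' or 'B'")
        pay = piv("payoff").to_numpy(dtype=float)
        nA = piv("n_A_prev").to_numpy(dtype=float)
        nB = piv("n_B_prev").to_numpy(dtype=float)
        out.append((rep, codes, pay, np.stack([nA, nB], axis=-1)))
    return out


def validate_rl_table(trials: pd.DataFrame, include_self: bool = False) -> None:
    """Check that recorded social counts match the recorded choices.

    For each trial t >= 2 and agent a, ``n_i_prev`` must equal the number of
    (other) agents that chose option i on trial t-1.  Raises
    :class:`TrialTableError` listing the first offending rows.
    """
    for rep, codes, _, counts in _rl_arrays(trials):
        n_t, n_a = codes.shape
        bad = []
        for t in range(1, n_t):
            prev = codes[t - 1]
            tot = np.array([(prev == 0).sum(), (prev == 1).sum()], dtype=float)
            for a in range(n_a):
                expect = tot.copy()
                if not include_self:
                    expect[prev[a]] -= 1
                if not np.allclose(counts[t, a], expect):
                    bad.append((rep, t + 1, a + 1, tuple(counts[t, a]),
                                tuple(expect)))
        if bad:
            raise TrialTableError(
                "social counts inconsistent with recorded choices; first "
                f"offenders (replicate, trial, agent, found, expected): {bad[:5]}")


def _as_rl_param_arrays(params, n_agents: int):
    if isinstance(params, RLAgentParams):
        params = [params] * n_agents
    if len(params) != n_agents:
        raise ValueError(f"need {n_agents} parameter sets, got {len(params)}")
    g = lambda name: np.array([getattr(p, name) for p in params])
    return g("alpha"), g("beta"), g("sigma"), g("theta"), g("q0")


def rl_loglik(trials: pd.DataFrame, params, validate: bool = False) -> float:
    """Log-likelihood of a social-RL trial table.

    ``params`` is a single :class:`RLAgentParams` shared by all agents or a
    sequence with one entry per agent (agents ordered by their id).  The
    recorded ``n_A_prev``/``n_B_prev`` counts are used as the copying input,
    so the likelihood conditions on the observed social environment.
    Deterministic and invariant to row order.
    """
    if validate:
        validate_rl_table(trials)
    total = 0.0
    for _, codes, pay, counts in _rl_arrays(trials):
        n_t, n_a = codes.shape
        alpha, beta, sigma, theta, q0 = _as_rl_param_arrays(params, n_a)
        Q = np.tile(q0[:, None], (1, 2)).astype(float)
        ar = np.arange(n_a)
        for t in range(n_t):
            pa = softmax_choice_prob(Q, beta[:, None])
            c = counts[t]
            nz = c.sum(axis=-1) > 0
            with np.errstate(invalid="ignore", over="ignore"):
                w = np.where(c > 0, c ** theta[:, None], 0.0)
                ps = w / w.sum(axis=-1, keepdims=True)
            ps = np.nan_to_num(ps, nan=0.0, posinf=1.0)
            p = np.where(nz[:, None],
                         (1 - sigma[:, None]) * pa + sigma[:, None]
                         * np.where(nz[:, None], ps, 0.0),
                         pa)
            chosen = p[ar, codes[t]]
            total += float(np.log(np.maximum(chosen, _DENSITY_FLOOR)).sum())
            Q[ar, codes[t]] += alpha * (pay[t] - Q[ar, codes[t]])
    return total


def _logit(p):  # natural -> unconstrained
    return math.log(p) - math.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + math.exp(-x))


def _num_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


@dataclass
class RLFitResult:
    """MLE of social-RL parameters shared across agents."""

    estimates: dict[str, float]
    std_errors: dict[str, float]
    loglik: float
    aic: float
    n_obs: int
    social: bool
    converged: bool
    multistart_spread: float
    flags: list[str] = field(default_factory=list)


_RL_START = {"alpha": 0.5, "beta": 0.1, "sigma": 0.3, "theta": 1.0}


def rl_fit(
    trials: pd.DataFrame,
    social: bool = True,
    q0: float = 0.0,
    n_starts: int = 5,
    seed: int = 0,
    min_trials: int = 20,
    validate: bool = True,
) -> RLFitResult:
    """Maximum-likelihood fit of (alpha, beta[, sigma, theta]) shared by all agents.

    Parameters are optimized on an unconstrained scale (logit for alpha and
    sigma, log for beta and theta) with ``n_starts`` jittered restarts.  At
    least ``min_trials`` trials per agent are required -- with fewer, the
    four-parameter social model is poorly identified.  A fitted sigma near
    zero (below 0.05) makes theta drop out of the likelihood; the result is
    then flagged ``theta_unidentifiable`` rather than silently reported.
    """
    if validate:
        validate_rl_table(trials)
    n_trials = trials.groupby(
        [c for c in ("replicate", "agent") if c in trials.columns]).size().min()
    if n_trials < min_trials:
        raise ValueError(
            f"need at least {min_trials} trials per agent, got {n_trials}")
    names = ["alpha", "beta", "sigma", "theta"] if social else ["alpha", "beta"]

    def unpack(x) -> RLAgentParams:
        alpha, beta = _expit(x[0]), math.exp(x[1])
        if social:
            return RLAgentParams(alpha=alpha, beta=beta, sigma=_expit(x[2]),
                                 theta=math.exp(x[3]), q0=q0)
        return RLAgentParams(alpha=alpha, beta=beta, sigma=0.0, theta=1.0, q0=q0)

    def nll(x):
        try:
            return -rl_loglik(trials, unpack(x))
        except (ValueError, OverflowError):
            return 1e12

    x0 = np.array([_logit(_RL_START["alpha"]), math.log(_RL_START["beta"])]
                  + ([_logit(_RL_START["sigma"]), 0.0] if social else []))
    # transformed-scale box keeps theta (and friends) in a numerically sane
    # range; theta in [e^-3, e^3] covers strong anticonformity to conformity
    xbounds = [(-8.0, 8.0), (-8.0, 4.0)] + ([(-8.0, 8.0), (-3.0, 3.0)]
                                            if social else [])
    rng = np.random.default_rng(seed)
    starts = [x0] + [np.clip(x0 + rng.normal(0, 1.0, size=len(x0)),
                             [b[0] for b in xbounds], [b[1] for b in xbounds])
                     for _ in range(n_starts - 1)]
    results = [minimize(nll, s, method="L-BFGS-B", bounds=xbounds)
               for s in starts]
    ok = [r for r in results if np.isfinite(r.fun)]
    best = min(ok, key=lambda r: r.fun)
    spread = float(max(abs(r.fun - best.fun) for r in ok))

    est_params = unpack(best.x)
    estimates = {n: getattr(est_params, n) for n in names}

    # delta-method SEs from the numeric Hessian on the transformed scale
    se = {n: float("nan") for n in names}
    flags: list[str] = []
    try:
        H = _num_hessian(nll, best.x)
        cov = np.linalg.inv(H)
        grads = []
        for i, n in enumerate(names):
            v = estimates[n]
            grads.append(v * (1 - v) if n in ("alpha", "sigma") else v)
        var = np.diag(cov)
        if np.any(var < 0):
            flags.append("hessian_not_pd")
        se = {n: float(abs(g) * math.sqrt(max(v, 0.0)))
              for n, g, v in zip(names, grads, var)}
    except np.linalg.LinAlgError:
        flags.append("hessian_singular")
    if social and estimates["sigma"] < 0.05:
        flags.append("theta_unidentifiable")
    n_obs = len(trials)
    ll = -best.fun
    return RLFitResult(
        estimates=estimates, std_errors=se, loglik=ll,
        aic=aic(ll, len(names)), n_obs=n_obs, social=social,
        converged=bool(best.success), multistart_spread=spread, flags=flags,
    )


# --------------------------------------------------------------------------
# social DDM likelihood and fitting
# --------------------------------------------------------------------------

def _ddm_trial_arrays(trials: pd.DataFrame):
    """Pivot a DDM trial table into per-trial (choice codes, rts)."""
    req = {"trial", "agent", "choice", "rt"}
    missing = req - set(trials.columns)
    if missing:
        raise TrialTableError(f"trial table missing columns: {sorted(missing)}")
    ch = trials.pivot(index="trial", columns="agent", values="choice").sort_index()
    rt = trials.pivot(index="trial", columns="agent", values="rt").sort_index()
    codes = ch.map(lambda c: {"A": 1, "B": -1}.get(c, 0)).to_numpy()
    return codes, rt.to_numpy(dtype=float)


def _drift_schedule(delta_p: float, s: float, q: float, events) -> list:
    """Piecewise drift [(t, delta), ...] from the other agents' decisions.

    ``events`` is a sequence of (time, +-1) pairs sorted by time; the drift
    changes at each observed decision via the sign-preserving majority power.
    """
    sched = [(0.0, delta_p)]
    M = 0
    by_time: dict[float, int] = {}
    for t_e, c in events:
        by_time[t_e] = by_time.get(t_e, 0) + int(c)
    for t_e in sorted(by_time):
        M += by_time[t_e]
        sched.append((t_e, delta_p + s * math.copysign(abs(M) ** q, M)
                      if M != 0 else delta_p))
    return sched


def _rt_quantum(rts: np.ndarray) -> float | None:
    """Lattice spacing of observed decision times (simulator step size)."""
    vals = rts[np.isfinite(rts)]
    vals = vals[vals > 0]
    if vals.size == 0:
        return None
    ints = np.unique(np.round(vals * 1e6).astype(np.int64))
    g = int(np.gcd.reduce(ints))
    q = g / 1e6
    return q if 1e-5 <= q <= 1.0 else None


def social_ddm_loglik(
    trials: pd.DataFrame,
    params: AgentDDMParams | Sequence[AgentDDMParams],
    t_max: float = 20.0,
    n_bins: int = 80,
) -> float:
    """Log-likelihood of a group DDM trial table.

    Each agent's drift schedule is rebuilt from the other agents' observed
    decision events (others' times treated as exogenous covariates); the
    observed (boundary, rt) is scored under the numeric first-passage
    density, and censored agents contribute the surviving mass at ``t_max``.
    The evaluator's sub-step is snapped to the lattice of the observed
    decision times so densities are evaluated exactly at them.
    """
    codes, rts = _ddm_trial_arrays(trials)
    n_t, n_a = codes.shape
    if isinstance(params, AgentDDMParams):
        params = [params] * n_a
    if len(params) != n_a:
        raise ValueError(f"need {n_a} parameter sets, got {len(params)}")
    observed = ~np.isnan(rts)
    if np.nanmax(rts, initial=0.0) > t_max + 1e-9:
        raise ValueError("observed rt outside the trial horizon t_max")
    quantum = _rt_quantum(rts)

    solvers: dict[tuple, SpectralFPT] = {}
    def solver_for(p: AgentDDMParams) -> SpectralFPT:
        key = (p.start, p.threshold_lower, p.threshold_upper, p.noise_sd)
        if key not in solvers:
            solvers[key] = SpectralFPT(p.start, p.threshold_lower,
                                       p.threshold_upper, p.noise_sd,
                                       n_bins=n_bins, time_quantum=quantum)
        return solvers[key]

    total = 0.0
    for i in range(n_t):
        for a in range(n_a):
            p = params[a]
            horizon = rts[i, a] if observed[i, a] else t_max
            events = [(rts[i, b], codes[i, b]) for b in range(n_a)
                      if b != a and observed[i, b] and rts[i, b] < horizon]
            events.sort()
            sched = _drift_schedule(p.delta_p, p.s, p.q, events)
            sol = solver_for(p)
            if observed[i, a]:
                bnd = "upper" if codes[i, a] == 1 else "lower"
                dens = sol.density(sched, rts[i, a], bnd)
                total += math.log(max(dens, _DENSITY_FLOOR))
            else:
                total += math.log(max(sol.survival(sched, t_max), _DENSITY_FLOOR))
    return total


@dataclass
class DDMFitResult:
    """MLE of the shared (delta_p, s) of a social DDM group."""

    estimates: dict[str, float]
    std_errors: dict[str, float]
    loglik: float
    aic: float
    n_obs: int
    converged: bool
    multistart_spread: float
    flags: list[str] = field(default_factory=list)


def ddm_fit(
    trials: pd.DataFrame,
    template: AgentDDMParams | Sequence[AgentDDMParams],
    t_max: float = 20.0,
    n_bins: int = 80,
    bounds: tuple = ((-2.5, 2.5), (0.0, 1.5)),
    n_starts: int = 3,
    seed: int = 0,
    compute_se: bool = True,
) -> DDMFitResult:
    """Fit shared ``delta_p`` and ``s`` by MLE, geometry held fixed.

    ``template`` provides the known starting point, thresholds, noise scale
    and social exponent ``q`` per agent (a single instance is shared by all
    agents); only the personal drift and the social-drift scale are free.
    ``noise_sd`` stays fixed (scale invariance of the Wiener process).
    """
    codes, _ = _ddm_trial_arrays(trials)
    n_a = codes.shape[1]
    if isinstance(template, AgentDDMParams):
        template = [template] * n_a

    def with_params(dp: float, s: float):
        return [AgentDDMParams(delta_p=dp, s=s, q=t.q,
                               threshold_upper=t.threshold_upper,
                               threshold_lower=t.threshold_lower,
                               start=t.start, noise_sd=t.noise_sd)
                for t in template]

    def nll(x):
        dp = float(np.clip(x[0], *bounds[0]))
        s = float(np.clip(x[1], *bounds[1]))
        try:
            return -social_ddm_loglik(trials, with_params(dp, s),
                                      t_max=t_max, n_bins=n_bins)
        except (ValueError, OverflowError):
            return 1e12

    rng = np.random.default_rng(seed)
    x0 = np.array([0.2, 0.2])
    starts = [x0] + [np.array([rng.uniform(-1, 1), rng.uniform(0, 0.8)])
                     for _ in range(n_starts - 1)]
    results = [minimize(nll, st, method="Nelder-Mead",
                        options={"xatol": 1e-3, "fatol": 1e-3, "maxiter": 200})
               for st in starts]
    best = min(results, key=lambda r: r.fun)
    spread = float(max(abs(r.fun - best.fun) for r in results))
    dp_hat = float(np.clip(best.x[0], *bounds[0]))
    s_hat = float(np.clip(best.x[1], *bounds[1]))

    se = {"delta_p": float("nan"), "s": float("nan")}
    flags: list[str] = []
    if compute_se:
        try:
            H = _num_hessian(nll, np.array([dp_hat, s_hat]), eps=5e-3)
            cov = np.linalg.inv(H)
            var = np.diag(cov)
            if np.any(var < 0):
                flags.append("hessian_not_pd")
            se = {"delta_p": math.sqrt(max(var[0], 0.0)),
                  "s": math.sqrt(max(var[1], 0.0))}
        except np.linalg.LinAlgError:
            flags.append("hessian_singular")
    ll = -best.fun
    return DDMFitResult(
        estimates={"delta_p": dp_hat, "s": s_hat}, std_errors=se,
        loglik=ll, aic=aic(ll, 2), n_obs=len(trials),
        converged=bool(best.success), multistart_spread=spread, flags=flags,
    )


# --------------------------------------------------------------------------
# parameter-recovery harness
# --------------------------------------------------------------------------

def recover_rl(
    true_params: RLAgentParams,
    env,
    n_agents: int = 5,
    n_groups: int = 20,
    seed: int = 0,
    n_starts: int = 3,
    social: bool = True,
) -> pd.DataFrame:
    """Simulate ``n_groups`` replicate groups at known parameters and refit each.

    Returns a tidy frame (replicate, param, true, estimate, abs_error,
    converged) consumable by tests and reports.
    """
    from .rl import simulate_rl_group

    rows = []
    ss = np.random.SeedSequence(seed)
    sim_seed, fit_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    agents = [true_params] * n_agents
    trace = simulate_rl_group(agents, env, seed=sim_seed, n_replicates=n_groups)
    df = trace.to_frame()
    names = ["alpha", "beta", "sigma", "theta"] if social else ["alpha", "beta"]
    for g in range(1, n_groups + 1):
        sub = df[df.replicate == g]
        fit = rl_fit(sub, social=social, q0=true_params.q0,
                     n_starts=n_starts, seed=fit_seed + g, validate=False)
        for nme in names:
            rows.append({
                "replicate": g, "param": nme,
                "true": getattr(true_params, nme),
                "estimate": fit.estimates[nme],
                "abs_error": abs(fit.estimates[nme] - getattr(true_params, nme)),
                "converged": fit.converged,
            })
    return pd.DataFrame(rows)


def recover_ddm(
    true_params: AgentDDMParams,
    n_agents: int = 5,
    n_trials: int = 100,
    n_datasets: int = 10,
    sim_dt: float = 0.002,
    t_max: float = 20.0,
    n_bins: int = 80,
    seed: int = 0,
    n_starts: int = 2,
) -> pd.DataFrame:
    """Recovery study for the shared (delta_p, s) of a social DDM group."""
    from .ddm import simulate_group

    rows = []
    ss = np.random.SeedSequence(seed)
    for k, child in enumerate(ss.spawn(n_datasets), start=1):
        sim_seed, fit_seed = [int(x % (2**31)) for x in child.generate_state(2)]
        trace = simulate_group([true_params] * n_agents, dt=sim_dt,
                               t_max=t_max, n_trials=n_trials, seed=sim_seed)
        fit = ddm_fit(trace.to_frame(), true_params, t_max=t_max,
                      n_bins=n_bins, seed=fit_seed, n_starts=n_starts,
                      compute_se=False)
        for nme in ("delta_p", "s"):
            rows.append({
                "replicate": k, "param": nme,
                "true": getattr(true_params, nme),
                "estimate": fit.estimates[nme],
                "abs_error": abs(fit.estimates[nme] - getattr(true_params, nme)),
                "converged": fit.converged,
            })
    return pd.DataFrame(rows)


def recovery_summary(report: pd.DataFrame) -> dict[str, float]:
    """Median absolute recovery error per parameter."""
    return report.groupby("param")["abs_error"].median().to_dict()
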