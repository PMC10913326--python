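"""Numeric first-passage-time machinery for the (social) drift-diffusion model.

The evidence interval ``(lower, upper)`` is discretized into ``n_bins`` equal
cells whose node points include the two boundaries exactly.  Probability
mass on the interior nodes evolves by a tridiagonal random-walk kernel whose
single-step mean and variance match the diffusion increments ``delta*dt`` and
``noise_sd**2 * dt``; mass stepping past an end node is absorbed at that
boundary.  Because drift enters only through the (piecewise-constant) jump
probabilities, the same discretization serves

* :func:`ddm_fpt_grid` -- forward propagation returning the full
  first-passage density over (time, boundary), used as a numeric oracle and
  for plotting; and
* :class:`SpectralFPT` -- an eigendecomposition of the symmetrized kernel
  that applies exact matrix powers per constant-drift segment, used by the
  social-DDM likelihood where only the density at each observed decision
  time (or the survival mass for censored agents) is needed.

Both views are the same Markov chain, so they agree to rounding error; the
test-suite checks this explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh_tridiagonal

__all__ = ["GridStabilityError", "FPTGridResult", "ddm_fpt_grid", "SpectralFPT"]


class GridStabilityError(ValueError):
    """Raised when per-step transition probabilities leave [0, 1]."""


def _as_schedule(delta_schedule) -> tuple[np.ndarray, np.ndarray]:
    """Normalise a drift schedule to (start_times, deltas); times[0] == 0."""
    if np.isscalar(delta_schedule):
        return np.array([0.0]), np.array([float(delta_schedule)])
    sched = np.asarray(delta_schedule, dtype=float)
    if sched.ndim == 1 and sched.size == 2:
        sched = sched[None, :]
    if sched.ndim != 2 or sched.shape[1] != 2:
        raise ValueError("delta_schedule must be a scalar or a sequence of "
                         "(start_time, delta) pairs")
    t, d = sched[:, 0], sched[:, 1]
    if t[0] != 0.0:
        raise ValueError("first schedule segment must start at time 0")
    if np.any(np.diff(t) < 0):
        raise ValueError("schedule start times must be nondecreasing")
    return t, d


@dataclass
class FPTGridResult:
    """First-passage density of the discretized diffusion.

    ``times`` are output-step end times; ``f_upper``/``f_lower`` are absorbed
    probability per unit time in each output step, so
    ``mass = f * dt``.  ``p_upper``/``p_lower`` are total absorbed masses
    within the horizon and ``survival`` the mass still in play at ``t_max``;
    the three sum to 1 up to float rounding.
    """

    times: np.ndarray
    f_upper: np.ndarray
    f_lower: np.ndarray
    p_upper: float
    p_lower: float
    survival: float
    dt: float
    n_bins: int

    @property
    def mass_upper(self) -> np.ndarray:
        return self.f_upper * self.dt

    @property
    def mass_lower(self) -> np.ndarray:
        return self.f_lower * self.dt

    def conservation_defect(self) -> float:
        return abs(self.p_upper + self.p_lower + self.survival - 1.0)


def _jump_probs(delta: float, h: float, dt_sub: float, sigma2: float):
    r = sigma2 * dt_sub / h**2
    a = delta * dt_sub / h
    p_up, p_down = 0.5 * (r + a), 0.5 * (r - a)
    p_stay = 1.0 - r
    if min(p_up, p_down, p_stay) < -1e-15 or r > 1 + 1e-12:
        raise GridStabilityError(
            f"transition probabilities outside [0,1] for delta={delta}: "
            "shrink dt (or use auto_substep) and ensure |delta|*h <= noise_sd**2"
        )
    return max(p_up, 0.0), max(p_down, 0.0), p_stay


def _deposit(start: float, lower: float, h: float, m: int):
    """Initial mass, linearly split between the two nodes flanking ``start``.

    Returns (interior vector, mass_absorbed_lower, mass_absorbed_upper);
    a start within one cell of a boundary leaks the flanking weight into
    that boundary immediately.
    """
    pos = (start - lower) / h
    j = int(math.floor(pos))
    frac = pos - j
    v = np.zeros(m)
    lo0 = up0 = 0.0
    for node, w in ((j, 1.0 - frac), (j + 1, frac)):
        if w == 0.0:
            continue
        if node <= 0:
            lo0 += w
        elif node >= m + 1:
            up0 += w
        else:
            v[node - 1] += w
    return v, lo0, up0


def ddm_fpt_grid(
    delta_schedule,
    start: float = 0.0,
    lower: float = -1.0,
    upper: float = 1.0,
    noise_sd: float = 1.0,
    dt: float = 1e-3,
    n_bins: int = 200,
    t_max: float = 10.0,
    auto_substep: bool = True,
) -> FPTGridResult:
    """First-passage density over (time, boundary) for piecewise-constant drift.

    ``delta_schedule`` is a constant drift or a sequence of
    ``(start_time, delta)`` pairs covering ``[0, t_max)``.  ``dt`` is the
    output time resolution; internally the kernel steps at the largest
    stable sub-step (``auto_substep=True``, default).  With
    ``auto_substep=False`` the kernel must be stable at ``dt`` itself,
    otherwise :class:`GridStabilityError` is raised.
    """
    if not lower < start < upper:
        raise ValueError("start must lie strictly between the boundaries")
    if noise_sd <= 0 or dt <= 0 or t_max <= 0:
        raise ValueError("noise_sd, dt and t_max must be > 0")
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4 (>= 50 recommended)")
    seg_t, seg_d = _as_schedule(delta_schedule)
    h = (upper - lower) / n_bins
    sigma2 = noise_sd**2
    if np.max(np.abs(seg_d)) * h > sigma2 + 1e-12:
        raise GridStabilityError(
            "drift too large for this grid: need |delta|*h <= noise_sd**2; "
            "increase n_bins")
    n_sub = max(1, math.ceil(sigma2 * dt / h**2 - 1e-12))
    if n_sub > 1 and not auto_substep:
        raise GridStabilityError(
            f"dt={dt} is unstable for h={h:.4g}: shrink dt to <= "
            f"{h**2 / sigma2:.3g} or enable auto_substep")
    dt_sub = dt / n_sub

    m = n_bins - 1
    v, lo_acc, up_acc = _deposit(start, lower, h, m)

    n_out = int(round(t_max / dt))
    mass_up = np.zeros(n_out)
    mass_lo = np.zeros(n_out)
    mass_up[0] += up_acc
    mass_lo[0] += lo_acc

    # segment boundaries on the substep lattice
    total_sub = n_out * n_sub
    seg_k = np.clip(np.round(seg_t / dt_sub).astype(int), 0, total_sub)
    seg_end = np.append(seg_k[1:], total_sub)

    for (k0, k1, delta) in zip(seg_k, seg_end, seg_d):
        if k1 <= k0:
            continue
        p_up, p_down, p_stay = _jump_probs(delta, h, dt_sub, sigma2)
        for k in range(k0, k1):
            out_bin = k // n_sub
            up_flux = v[-1] * p_up
            lo_flux = v[0] * p_down
            new = v * p_stay
            new[1:] += v[:-1] * p_up
            new[:-1] += v[1:] * p_down
            v = new
            mass_up[out_bin] += up_flux
            mass_lo[out_bin] += lo_flux

    p_upper = float(mass_up.sum())
    p_lower = float(mass_lo.sum())
    survival = float(v.sum())
    times = np.arange(1, n_out + 1) * dt
    return FPTGridResult(
        times=times, f_upper=mass_up / dt, f_lower=mass_lo / dt,
        p_upper=p_upper, p_lower=p_lower, survival=survival,
        dt=dt, n_bins=n_bins,
    )


class SpectralFPT:
    """Spectral evaluator of the discretized first-passage problem.

    For each constant-drift segment the interior-node kernel ``A`` is
    similar to a symmetric tridiagonal matrix, so ``A**n`` is applied
    exactly through its eigendecomposition -- the cost of evaluating the
    density at one observed time is a few small matrix-vector products,
    independent of how many time steps the segment spans.  The sub-step is
    fixed at ``0.5 * h**2 / noise_sd**2`` (p_stay = 1/2), which avoids the
    parity oscillation of the pure binomial walk.
    """

    def __init__(self, start: float, lower: float, upper: float,
                 noise_sd: float = 1.0, n_bins: int = 80,
                 time_quantum: float | None = None):
        if not lower < start < upper:
            raise ValueError("start must lie strictly between the boundaries")
        if n_bins < 4:
            raise ValueError("n_bins must be >= 4")
        self.start, self.lower, self.upper = start, lower, upper
        self.noise_sd = noise_sd
        self.n_bins = n_bins
        self.h = (upper - lower) / n_bins
        self.sigma2 = noise_sd**2
        dt_stable = 0.5 * self.h**2 / self.sigma2
        if time_quantum is not None and time_quantum > 0:
            # snap the sub-step so observed times (multiples of the quantum)
            # land exactly on the sub-step lattice at every resolution
            self.dt_sub = time_quantum / math.ceil(time_quantum / dt_stable)
        else:
            self.dt_sub = dt_stable
        self.m = n_bins - 1
        self.p0, self._lo0, self._up0 = _deposit(start, lower, self.h, self.m)
        self._cache: dict[float, tuple] = {}

    def _eig(self, delta: float):
        key = round(float(delta), 12)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        p_up, p_down, p_stay = _jump_probs(delta, self.h, self.dt_sub, self.sigma2)
        if p_up <= 0 or p_down <= 0:
            raise GridStabilityError(
                f"|delta|={abs(delta)} too large for h={self.h:.4g}; "
                "increase n_bins")
        off = math.sqrt(p_up * p_down)
        w, V = eigh_tridiagonal(np.full(self.m, p_stay), np.full(self.m - 1, off))
        # d_j = (p_down/p_up)^(j/2) symmetrizes the kernel
        logr = 0.5 * (math.log(p_down) - math.log(p_up))
        d = np.exp(logr * np.arange(self.m))
        val = (w, V, d, p_up, p_down)
        self._cache[key] = val
        return val

    def _apply_power(self, v: np.ndarray, delta: float, n: int) -> np.ndarray:
        if n == 0:
            return v
        w, V, d, _, _ = self._eig(delta)
        y = V.T @ (d * v)
        y = V @ (w**n * y)
        return y / d

    def _steps(self, t: float) -> int:
        return int(round(t / self.dt_sub))

    def state_at(self, schedule, t: float) -> np.ndarray:
        """Interior mass vector after propagating to time ``t``."""
        seg_t, seg_d = _as_schedule(schedule)
        k_obs = self._steps(t)
        seg_k = np.clip(np.round(seg_t / self.dt_sub).astype(int), 0, k_obs)
        seg_end = np.append(seg_k[1:], k_obs)
        v = self.p0
        for k0, k1, delta in zip(seg_k, seg_end, seg_d):
            if k1 > k0:
                v = self._apply_power(v, delta, int(k1 - k0))
        return v

    def density(self, schedule, t: float, boundary: str) -> float:
        """First-passage density (per unit time) at ``(t, boundary)``.

        ``boundary`` is ``"upper"`` or ``"lower"``.  The density is the mass
        absorbed during the sub-step ending at ``t`` divided by the
        sub-step length.
        """
        k_obs = self._steps(t)
        if k_obs < 1:
            return 0.0
        seg_t, seg_d = _as_schedule(schedule)
        # drift in force during the final sub-step
        i_last = int(np.searchsorted(np.round(seg_t / self.dt_sub), k_obs - 1,
                                     side="right") - 1)
        delta_last = seg_d[max(i_last, 0)]
        v = self.state_at(schedule, (k_obs - 1) * self.dt_sub)
        _, _, _, p_up, p_down = self._eig(delta_last)
        flux = v[-1] * p_up if boundary == "upper" else v[0] * p_down
        return float(flux / self.dt_sub)

    def survival(self, schedule, t: float) -> float:
        """Probability of no decision by time ``t`` under the schedule."""
        return float(self.state_at(schedule, t).sum())
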