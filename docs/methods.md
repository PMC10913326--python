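# Methods

This note documents the models, the conventions the implementation fixes
where the underlying ideas leave freedom, the numerical machinery, and what
the synthetic scenarios do and do not establish.

## Social drift-diffusion model

Each agent's evidence state follows an Euler–Maruyama discretisation of a
Wiener process with drift,

    L(t + Δt) = L(t) + δ(t)·Δt + √Δt·ε,   ε ~ Normal(0, noise_sd),

between two absorbing thresholds (upper = option A, defined as the correct
option in all scenarios; lower = option B). The drift is the sum of a
personal part `δ_p` and a social part responding to the signed majority
`M = n_A − n_B` of group members that have already decided:

    δ_s(M) = s · sign(M) · |M|^q.

Conventions fixed by the package:

* **Noise scale.** `noise_sd = 1` by default. The Wiener likelihood is
  invariant to jointly rescaling drift, thresholds and diffusion, so fixing
  the noise defines the evidence unit (the standard DDM convention); it is
  also held fixed during fitting for the same identifiability reason.
* **Sign-preserving power.** `M^q` is undefined for negative majorities and
  non-integer `q`; the implementation uses `sign(M)·|M|^q`, the unique
  extension that keeps the social drift an odd function of `M` and hence
  treats A and B symmetrically. `q = 1` recovers the linear majority rule.
* **Time stepping.** Default `dt = 0.001` (scenarios use 0.002 for
  throughput; the oracle-equivalence tests use finer steps, see below).
  Within a step, every undecided agent moves with the drift implied by the
  majority at the **start** of the step; crossings are detected at the step
  end, and newly decided agents enter the majority from the **next** step.
  Agents crossing in the same step share the step-end decision time and are
  ranked by agent index — a documented, deterministic tie-break.
* **No bridge correction.** Crossing detection is end-of-step only. This
  biases absorption statistics like an effective boundary widening of
  ~`0.583·noise_sd·√dt` per side (the standard discrete-monitoring
  correction factor): at `dt = 0.005` the absorption probability of a
  drifting agent is several Monte-Carlo standard errors from the continuous
  closed form at 1e5 trials. Oracle-equivalence tests therefore run at
  `dt = 2.5e-4` (absorption probability) and `1e-4` (zero-drift mean
  first-passage time), where the bias is far below the tolerance being
  asserted. Bridge-corrected crossing is a possible refinement; the
  test-suite already uses an exact-bridge walker as an *oracle* when
  validating the numeric density.
* **Censoring.** Agents that never decide by `t_max` (default 20 time
  units) are returned as censored (`choice = NA`), never forced.

### Numeric first-passage machinery

The evidence interval is discretised into `n_bins` cells whose node set
contains both boundaries exactly (this placement avoids the O(h) boundary
bias of cell-centred grids). Interior mass evolves by the tridiagonal
kernel with `p_up/down = (σ²Δt/h² ± δΔt/h)/2`, matching the first two
moments of the diffusion increment; mass stepping past an end node is
absorbed there, so probability is conserved to machine precision
(checked to 1e−9 in tests).

The explicit kernel is stable only for `σ²Δt ≤ h²` (and `|δ|h ≤ σ²`).
`ddm_fpt_grid` therefore sub-steps internally to the largest stable step by
default; `auto_substep=False` restores strict rejection of an unstable
`Δt`. Initial mass is split linearly between the two nodes flanking the
starting point.

The social-DDM likelihood needs the density only at each observed decision
time under a piecewise-constant drift schedule (the other agents' decision
times, conditioned on as exogenous covariates — the standard conditional
factorisation; a joint path likelihood is out of scope). `SpectralFPT`
exploits that each constant-drift segment's kernel is similar to a
symmetric tridiagonal matrix: its eigendecomposition applies exact matrix
powers per segment at the cost of a few small matrix-vector products,
independent of segment length. The sub-step (`0.5·h²/σ²`, chosen away from
the parity-oscillating binomial limit) is snapped to the lattice of the
observed response times so densities are evaluated exactly at them; with
this snapping, doubling the spatial resolution moves fixture
log-likelihoods by well under 1e−3. Censored agents contribute the
surviving interior mass at the horizon.

Fitting estimates the shared `(δ_p, s)` with thresholds, starting point,
noise and `q` fixed and known (geometry supplied by a template), by
Nelder–Mead within bounds (`δ_p ∈ [−2.5, 2.5]`, `s ∈ [0, 1.5]`) and
multi-start jitter. Both shared and per-agent parameter modes are supported
in the likelihood; the fitter exposes the shared mode, which is the one the
recovery study exercises.

## Social reinforcement learning

Delta-rule value updating (`Q_i ← Q_i + α(π − Q_i)`, chosen option only),
softmax choice with inverse temperature `β`, and a mixture with
frequency-dependent copying weighted by `σ`; the copying term raises the
previous-trial choice counts to the conformity exponent `θ`.

Conventions fixed by the package:

* **Counts exclude the agent itself** (the social information is the
  *other* N−1 members' previous choices); `include_self=True` switches to
  all-member counts.
* **Trial 1 is asocial** (no previous choices exist), as is any trial whose
  counts are all zero: `0^θ := 0`, and an all-zero count vector raises a
  dedicated `NoSocialInformation` signal internally, upon which the mixture
  falls back to the pure softmax. This keeps the combined rule a proper
  probability for every trial.
* **Counts window** is the immediately preceding trial only, not a
  cumulative history.
* **Initial values** `q0 = 0` by default (configurable).
* **Payoff reversal** is implemented by reversing the option means after
  the changepoint (default: half the trials); payoffs are Gaussian with the
  stated SD, not truncated or rounded.

The likelihood reconstructs each agent's Q trajectory exactly from its
recorded choices and payoffs and scores each realized choice under the
mixture computed from the recorded counts; it is deterministic and
row-order invariant, and a validator cross-checks the recorded counts
against the recorded choices before fitting. Fitting is L-BFGS-B on
transformed parameters (logit for `α`, `σ`; log for `β`, `θ`) inside a
transformed-scale box (`θ ∈ [e^−3, e^3]`) with multi-start, standard errors
by delta method from the numeric Hessian. When the fitted `σ` is below
0.05 the copying term is effectively absent and `θ` is unidentifiable; the
result is flagged rather than silently reported. AIC (`2k − 2·loglik`)
compares the social (4-parameter) against the asocial (2-parameter) model.
A known property of this comparison: on truly asocial data AIC retains the
needless social model in roughly 14% of datasets (the usual
`P(2ΔLL > 2k)` over-selection), so perfect preference rates are expected
only on the social-data side.

## Scenarios and what they show

Six frozen scenarios (5 agents each) express the qualitative group-level
contrasts the models were designed to illustrate. The RL side uses the
published illustrative settings: Gaussian payoffs with means 15/20, SD 3,
100 trials with reversal at trial 50, `α = 0.3`, `β = 0.18`, and panels
`σ = 0`; `σ = 0.3, θ = 1.5`; `σ = 0.7, θ = 5`. The DDM side has no
canonical parameter values; the package fixes documented ones chosen so
that the captioned directional contrasts are clearly expressed, and the
test-suite asserts **only directions**, never magnitudes:

| scenario | δ_p | thresholds (±) | s |
|---|---|---|---|
| ddm-homogeneous | 0.15 ×5 | 1.15 ×5 | 0.45 |
| ddm-expertise | 0, .125, .25, .375, .5 | 1.5 ×5 | 0.2 |
| ddm-thresholds | 0.15 ×5 | .3, .725, 1.15, 1.575, 2.0 | 0.45 |

All use `start = 0`, `noise_sd = 1`, `q = 1`, `dt = 0.002`, `t_max = 20`.
The directional statistics (asserted at 1e4 trials for the DDM, ≥500
replicate groups for RL, each against an explicit Monte-Carlo error
budget): expertise ⇒ negative rank correlation between drift and mean RT
and a late-decider accuracy gain over the uncoupled control; threshold
heterogeneity ⇒ hasty agents faster and less accurate, with late deciders
worse than in a homogeneous-threshold control at the median threshold;
weak conformity ⇒ best post-reversal adaptation; strong conformity ⇒
fastest pre-reversal convergence but maladaptive herding afterwards.

The generators emulate idealized groups: stationary parameters, no
non-decision time (the trace format reserves no column for it beyond RT),
no trial-to-trial parameter drift, fully observed decision events, and
exchangeable agents within a parameter assignment. Passing tests establish
internal consistency of the models and estimators under these conditions —
not that real groups obey them; with empirical data, non-decision time,
parameter heterogeneity and partially observable choices would all need
modelling before these likelihoods apply.

## Recovery study and problem sizes

The recovery harness simulates replicate groups at known parameters and
refits each. Study sizes are chosen so the whole suite runs in minutes on
one CPU: RL recovery uses 12 replicate groups of 5 agents × 100 trials
(true values `α = 0.3, β = 0.18, σ = 0.3, θ = 1.5`); DDM recovery uses 6
datasets of 5 agents × 100 trials (true `δ_p = 0.3, s = 0.2`, thresholds
±1). Acceptance tolerances are twice the median absolute error of a
committed pilot run at the same scale with a dedicated seed
(`tests/data/recovery_pilot.json`); fresh-seed reruns sit comfortably
inside them (e.g. pilot MAEs: `α` 0.031, `β` 0.018, `σ` 0.044, `θ` 0.56;
`δ_p` 0.035, `s` 0.020). `θ` is the least identifiable parameter at this
scale — single-group estimates occasionally wander onto the flat ridge
that appears as `σ` shrinks, which the flagging logic and the wide pilot
tolerance both reflect.

## Known limitations

* Two options only; no multi-alternative or go/no-go accumulators, no
  collapsing bounds, no communication of continuous evidence states.
* Decision-biasing social learning only (copying affects choice
  probabilities, not values); value-shaping variants are not implemented.
* Plain MLE; hierarchical/random-effects estimation is an extension hook.
* The social-DDM likelihood conditions on others' decision times rather
  than modelling the joint first-passage problem; this is exact for
  inference about an agent given its social environment, but not a
  generative likelihood for the whole group's joint timing.
* End-of-step crossing detection requires small `dt` for unbiased
  absorption statistics (see above).
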