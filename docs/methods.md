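# Methods

## Model

A patient is described by age t (yr), rhythm S(t) ∈ {0, 1} and two
hazards: the activation rate A(t) (episode initiation while in sinus
rhythm) and the recovery rate R(t) (termination while in AF). Both are
piecewise-deterministic: they follow linear ODEs within each rhythm
segment and only the switching times are random. The model is therefore
a piecewise-deterministic Markov process in the extended state
(t, S, A_epi, R_epi), simulated exactly.

Activation has three components, A = A₀ + A_age + A_epi. A_age is a
sigmoid A₁/(1 + e^(−(t−t_c)/t_d)) — negligible in youth, rising through
a transition centred at t_c over width t_d to a plateau A₁. A_epi obeys
dA_epi/dt = −βA_epi in sinus rhythm and dA_epi/dt = α(A_max − A_epi) in
AF, and is continuous across switches, so A_epi ∈ [0, A_max] always.

Recovery is R = R_age + R_epi with R_age = R₀e^(−λt). In sinus rhythm
R_epi decays at rate ν. In AF the *total* rate obeys dR/dt = −μR with
μ > λ; the episode component is recovered by subtraction,
R_epi = R − R_age, and typically turns negative during a long episode
(only the total R is a physical rate, and it stays positive). At
termination, a negative R_epi is reflected and scaled, R_epi → −B·R_epi,
so total recovery overshoots the age baseline and decays back at rate ν:
this produces the post-episode clustering of short episodes. A
non-negative R_epi at termination is left unchanged.

Because R_epi is non-negative at every episode onset (it is zero at
birth and the boost rule keeps it ≥ 0 in sinus rhythm), the entry
recovery rate R_enter ≥ R_age > 0, and the AF cumulative hazard
Λ(τ) = R_enter(1 − e^(−μτ))/μ is bounded by R_enter/μ. A drawn
exponential deviate exceeding the bound means the episode cannot
self-terminate; it is recorded as a censored episode running to the
horizon and the patient is classified as in permanent AF from its start.
This is a modelled outcome, returned as an explicit `NEVER` sentinel,
not an error.

## Parameters

All rates are stored in 1/yr on a 365-day year (so R₀ = 2 s⁻¹ becomes
6.3072×10⁷ yr⁻¹ and the 14.4-minute threshold is 1% of a day =
2.74×10⁻⁵ yr). Defaults, from `baseline_parameters()`:

| symbol | default | meaning |
|---|---|---|
| A₀ | 10⁻⁵ /yr | genetic predisposition (arbitrarily small) |
| A₁ | 2920 /yr | age-activation plateau (8 episodes/day) |
| A_max | 5840 /yr | episode-activation ceiling (2·A₁: AF doubles the vulnerable window) |
| t_c, t_d | 70, 3 yr | centre/width of the age sigmoid (incidence peaks around 70 ± 10 yr) |
| α | 52 /yr | episode-activation saturation (~1 week in AF) |
| β | 182.5 /yr | episode-activation relaxation (~2 days in SR) |
| R₀ | 2 /s | newborn peak recovery (shortest conceivable episode 0.5 s) |
| λ | 1.2·ln(840)/50 /yr | age decay of recovery |
| μ | = α | total-recovery decay in AF (μ > λ is required) |
| ν | = β | episode-recovery relaxation in SR |
| B | 1 | post-episode recovery boost factor |

λ deserves a note: the constant derived from the requirement that the
mean age-related episode at age 50 be exactly 14.4 min is ln(864·2)/50 ≈
0.1491 /yr, exposed as `lambda_from_threshold()`; the default is the
slightly larger 1.2·ln(840)/50 ≈ 0.1616 /yr used in the reference
simulations. "log" here is the natural logarithm — only then is
1.2·ln(840)/50 larger than ln(1728)/50, as the derivation requires.

## Exact simulation

Waiting times are sampled by cumulative-hazard inversion: draw
E ~ Exp(1) (as −log1p(−u) from a `numpy.random.Generator`) and solve
Λ(τ) = E.

- Sinus rhythm: Λ(τ) = A₀τ + A₁t_d·[softplus((t+τ−t_c)/t_d) −
  softplus((t−t_c)/t_d)] + (A_epi/β)(1 − e^(−βτ)), the exact integral of
  the activation rate. Softplus is computed as x + log1p(e^(−x)) for
  x > 0 to avoid overflow. The root is bracketed (the next-event check
  uses Λ(horizon − t) first, so the bracket is [0, remaining time];
  the standalone API grows a bracket geometrically from the
  constant-rate guess E/A(t)) and solved by Newton iteration safeguarded
  by bisection to a residual of 10⁻⁹·max(1, E). β = 0 is handled as the
  A_epi·τ limit.
- AF: Λ(τ) = R_enter(1 − e^(−μτ))/μ inverts in closed form,
  τ = −log1p(−μE/R_enter)/μ, with the `NEVER` branch above; μ = 0 gives
  the homogeneous limit τ = E/R_enter.

A floor of 10⁻¹² yr on waiting times guards against zero-length events
from floating-point underflow. Total SR plus AF time equals the horizon
exactly (to 10⁻⁹ yr tolerance in tests). The event loop is numba-jitted;
if numba is unavailable the identical Python code path runs (same draw
sequence, bit-identical trajectories), only slower.

Ensembles spawn one child `SeedSequence` per patient from the master
seed, so results are reproducible and independent of execution order.

Correctness is cross-checked two independent ways in the test suite:
the closed-form propagation against adaptive ODE integration (10⁻⁸
relative) and adaptive quadrature of the hazards (10⁻⁹ relative); and
the exact sampler against a Lewis–Shedler thinning simulator of the same
process (two-sample KS on inter-event times and a two-sample chi-square
on episode counts, α = 0.01, n = 2000). The thinning sampler bounds the
activation rate on each short lookahead window by
A₀ + A_age(window end) + A_epi(now) (valid since A_age increases and
A_epi decays in SR) and the recovery rate by its current value (valid
since R decays in AF); it is exact for any window length and lives only
in the test suite.

## Classification and metrics

Stage onsets are timed at the earliest moment the criterion is knowable:
start + 14.4 min of the first episode of at least that duration
(paroxysmal), start + 7 d of the first 7-day episode (persistent), and
the start of the final censored episode (permanent). A censored episode
qualifies for the duration thresholds too, which creates one deliberate
quirk: if the first 7-day episode is the final censored one, persistent
onset falls 7 days after permanent onset. Persistent AF is computed but
excluded from the headline population summaries, which concern
paroxysmal and permanent AF only.

Burden is the fraction of an observation window spent in AF, computed by
exact interval overlap (windows: day = 1/365 yr, month = 30 days,
year = 365 days; only whole windows inside the horizon are reported).
Episode counts attribute each episode to the window containing its
start. Onset-aligned population curves recompute each patient's series
with the origin at their own anchor (paroxysmal onset, or whole windows
counting back from permanent onset) and average per relative bin;
patients lacking the anchor are excluded and counted. Dispersion bands
are population standard deviations, not standard errors.

## Problem sizes and what the outputs mean

Desk-scale ensemble defaults are 500 patients for onset statistics
(reference analyses used 5000; means of onset ages at n = 500 carry a
Monte-Carlo standard error of ~0.1 yr, far inside the reported bands)
and 100 sample paths for the parameter-variant comparisons, the
reference experiment size. One lifetime at baseline contains roughly
10⁴ episodes and simulates in a few milliseconds.

All simulated patients share identical parameters: ensemble spread
reflects intrinsic stochasticity only, not population heterogeneity.
The synthetic trajectories expose *every* episode, unlike clinical
records where short episodes go undetected; passing tests therefore
validate the model's internal consistency and its stated statistical
properties, not agreement with any monitored cohort. No interventions,
mortality before the horizon, or detection model are represented, and
per-patient parameter heterogeneity is out of scope (the variant
mechanism exists for cohort-level scans).

## Known limitations

- The one-at-a-time scan covers single-parameter perturbations only; no
  factorial or variance-based sensitivity analysis.
- `align` requires the anchor to sit on a window boundary of the series;
  for arbitrary anchors the series is recomputed with a shifted origin
  (that is what the population layer does).
- Permanent AF is irreversible by construction (no cardioversion), so
  stage timings over-estimate clinical transition times by design.
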