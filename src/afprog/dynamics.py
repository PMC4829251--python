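"""Closed-form rate dynamics of the AF switching process.

Between random switching events the activation and recovery rates evolve
deterministically (linear ODEs with age-dependent forcing), so the state
can be propagated in closed form and the cumulative hazards integrated
exactly.  This module provides those closed forms, the cumulative-hazard
integrals, and their inversion — the building blocks of the exact
(modified-Gillespie) simulator.

The scalar kernels are numba-jitted when numba is available; the public
functions operate on :class:`PatientState`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .parameters import ModelParameters

try:  # pragma: no cover - numba is an optional accelerator
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "PatientState",
    "NEVER",
    "age_activation",
    "age_recovery",
    "total_activation",
    "total_recovery",
    "evolve_sr",
    "evolve_af",
    "sr_cumulative_hazard",
    "invert_sr_hazard",
    "invert_af_hazard",
    "apply_termination_boost",
]

#: sentinel returned by :func:`invert_af_hazard` when the drawn hazard
#: exceeds the finite bound: the episode never self-terminates.
NEVER = math.inf

#: absolute floor on waiting times (yr), guarding against zero-length
#: events from floating-point underflow.
TIME_FLOOR = 1e-12

_INV_TOL = 1e-9  # residual tolerance of hazard inversion


@dataclass(frozen=True)
class PatientState:
    """Instantaneous state of one simulated patient.

    ``t`` is age in years; ``S`` the rhythm flag (0 = sinus rhythm,
    1 = AF); ``Aepi`` the episode-induced activation component in
    [0, Amax]; ``Repi`` the episode-induced recovery component, which may
    be negative during and at the end of an AF episode.
    """

    t: float
    S: int = 0
    Aepi: float = 0.0
    Repi: float = 0.0


# ---------------------------------------------------------------------------
# scalar kernels (shared with the simulation loop)

@njit(cache=True)
def _softplus(x: float) -> float:
    # log(1 + e^x), stable for large |x|
    if x > 0.0:
        return x + math.log1p(math.exp(-x))
    return math.log1p(math.exp(x))


@njit(cache=True)
def _age_activation(t: float, A1: float, tc: float, td: float) -> float:
    return A1 / (1.0 + math.exp(-(t - tc) / td))


@njit(cache=True)
def _age_recovery(t: float, R0: float, lam: float) -> float:
    return R0 * math.exp(-lam * t)


@njit(cache=True)
def _sr_hazard(t: float, Aepi: float, tau: float, A0: float, A1: float,
               tc: float, td: float, beta: float) -> float:
    # exact integral of A0 + Aage + Aepi*e^(-beta*s) over s in [0, tau]
    age = A1 * td * (_softplus((t + tau - tc) / td) - _softplus((t - tc) / td))
    if beta > 0.0:
        epi = Aepi / beta * -math.expm1(-beta * tau)
    else:
        epi = Aepi * tau
    return A0 * tau + age + epi


@njit(cache=True)
def _invert_sr_bracketed(t: float, Aepi: float, E: float, hi: float,
                         A0: float, A1: float, tc: float, td: float,
                         beta: float) -> float:
    # Solve _sr_hazard(tau) = E for tau in (0, hi], where the caller
    # guarantees _sr_hazard(hi) >= E.  Safeguarded Newton within a
    # shrinking bisection bracket; residual tolerance 1e-9 * max(1, E).
    tol = _INV_TOL * max(1.0, E)
    lo = 0.0
    rate0 = A0 + _age_activation(t, A1, tc, td) + Aepi
    x = E / rate0 if rate0 > 0.0 else 0.5 * hi
    if not (0.0 < x < hi):
        x = 0.5 * hi
    for _ in range(200):
        f = _sr_hazard(t, Aepi, x, A0, A1, tc, td, beta) - E
        if abs(f) <= tol:
            return x
        if f > 0.0:
            hi = x
        else:
            lo = x
        rate = A0 + _age_activation(t + x, A1, tc, td) + Aepi * math.exp(-beta * x)
        if rate > 0.0:
            step = x - f / rate
        else:
            step = -1.0
        if lo < step < hi:
            x = step
        else:
            x = 0.5 * (lo + hi)
        if hi - lo < 1e-16 * max(1.0, hi):
            break
    return x


@njit(cache=True)
def _grow_bracket(t: float, Aepi: float, E: float, A0: float, A1: float,
                  tc: float, td: float, beta: float) -> float:
    # geometric expansion until the cumulative hazard brackets E
    rate0 = A0 + _age_activation(t, A1, tc, td) + Aepi
    hi = E / rate0 if rate0 > 0.0 else 1.0
    if hi <= 0.0:
        hi = TIME_FLOOR
    for _ in range(2000):
        if _sr_hazard(t, Aepi, hi, A0, A1, tc, td, beta) >= E:
            return hi
        hi *= 2.0
    return hi


# ---------------------------------------------------------------------------
# public API

def age_activation(t: float, params: ModelParameters) -> float:
    """Age/co-morbidity activation: sigmoid rising to ``A1`` around ``tc``."""
    return _age_activation(t, params.A1, params.tc, params.td)


def age_recovery(t: float, params: ModelParameters) -> float:
    """Age-related recovery rate ``R0 * exp(-lam * t)``."""
    return _age_recovery(t, params.R0, params.lam)


def total_activation(state: PatientState, params: ModelParameters) -> float:
    """Total activation hazard ``A0 + Aage(t) + Aepi``."""
    return params.A0 + age_activation(state.t, params) + state.Aepi


def total_recovery(state: PatientState, params: ModelParameters) -> float:
    """Total recovery hazard ``Rage(t) + Repi``; must be positive."""
    r = age_recovery(state.t, params) + state.Repi
    if r <= 0.0:
        raise ValueError(f"non-positive total recovery rate {r} at t={state.t}")
    return r


def evolve_sr(state: PatientState, tau: float,
              params: ModelParameters) -> PatientState:
    """Propagate a sinus-rhythm segment by ``tau`` years.

    Both episode components relax exponentially: ``Aepi`` with rate
    ``beta`` and ``Repi`` with rate ``nu``.
    """
    if state.S != 0:
        raise ValueError("evolve_sr requires S = 0")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return replace(
        state,
        t=state.t + tau,
        Aepi=state.Aepi * math.exp(-params.beta * tau),
        Repi=state.Repi * math.exp(-params.nu * tau),
    )


def evolve_af(state: PatientState, tau: float,
              params: ModelParameters) -> PatientState:
    """Propagate an AF segment by ``tau`` years.

    ``Aepi`` saturates toward ``Amax`` with rate ``alpha``.  The *total*
    recovery rate decays with rate ``mu``; the episode component is
    recovered by subtracting the age baseline at the new time, and is
    typically negative by the end of a long episode.
    """
    if state.S != 1:
        raise ValueError("evolve_af requires S = 1")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    r_total = (age_recovery(state.t, params) + state.Repi) * math.exp(-params.mu * tau)
    t1 = state.t + tau
    return replace(
        state,
        t=t1,
        Aepi=params.Amax - (params.Amax - state.Aepi) * math.exp(-params.alpha * tau),
        Repi=r_total - age_recovery(t1, params),
    )


def sr_cumulative_hazard(state: PatientState, tau: float,
                         params: ModelParameters) -> float:
    """Integrated activation hazard over a sinus-rhythm wait of ``tau``.

    Exact: ``A0*tau`` plus the softplus antiderivative of the age sigmoid
    plus the exponential-relaxation integral of ``Aepi``.  Strictly
    increasing and unbounded in ``tau`` (for ``A0 > 0``).
    """
    if state.S != 0:
        raise ValueError("sr_cumulative_hazard requires S = 0")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return _sr_hazard(state.t, state.Aepi, tau, params.A0, params.A1,
                      params.tc, params.td, params.beta)


def invert_sr_hazard(state: PatientState, E: float,
                     params: ModelParameters) -> float:
    """Waiting time ``tau`` with cumulative SR hazard equal to ``E``.

    Bracket grown geometrically from the constant-rate guess ``E/A(t)``,
    then solved to a residual of ``1e-9 * max(1, E)``.  Unique by strict
    monotonicity of the hazard integral.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    hi = _grow_bracket(state.t, state.Aepi, E, params.A0, params.A1,
                       params.tc, params.td, params.beta)
    tau = _invert_sr_bracketed(state.t, state.Aepi, E, hi, params.A0,
                               params.A1, params.tc, params.td, params.beta)
    return max(tau, TIME_FLOOR)


def invert_af_hazard(state: PatientState, E: float,
                     params: ModelParameters) -> float:
    """Episode duration with cumulative termination hazard ``E``.

    With the total recovery rate decaying as ``R_enter * exp(-mu*tau)``
    the cumulative hazard is bounded by ``R_enter/mu``; if ``E`` reaches
    that bound the episode never self-terminates and the sentinel
    :data:`NEVER` is returned (the caller records a censored, permanent
    episode).  Otherwise the inversion is exact in closed form.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    r_enter = total_recovery(state, params)  # raises if <= 0
    mu = params.mu
    if mu <= 0.0:
        return max(E / r_enter, TIME_FLOOR)
    if E >= r_enter / mu:
        return NEVER
    return max(-math.log1p(-mu * E / r_enter) / mu, TIME_FLOOR)


def apply_termination_boost(state: PatientState,
                            params: ModelParameters) -> PatientState:
    """End an AF episode: flip to sinus rhythm, boosting the recovery rate.

    If the episode component ``Repi`` is negative just before termination
    it is reflected and amplified, ``Repi -> -B * Repi``, so the total
    recovery rate overshoots its age baseline (clustering of short
    episodes after a long one).  A non-negative ``Repi`` is left alone.
    ``Aepi`` is untouched: the activation rate is continuous across
    switching events.
    """
    if state.S != 1:
        raise ValueError("boost applies at an AF->SR transition")
    repi = state.Repi
    if repi < 0.0:
        repi = -params.B * repi
    return replace(state, S=0, Repi=repi)
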