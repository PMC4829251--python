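"""Exact event-driven simulation of lifetime AF trajectories.

One patient is a realisation of the two-state switching process: waiting
times are sampled by drawing ``E ~ Exp(1)`` and inverting the exact
cumulative hazard (a modified Gillespie scheme for time-dependent rates),
so no time discretisation error is introduced.  All stochasticity lives
in the Exp(1) draws; between events the rates evolve deterministically.

The hot loop is numba-jitted.  A Lewis–Shedler thinning simulator of the
same process is provided as an independent statistical oracle for tests;
it never sits in the production path.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .parameters import ModelParameters, TIME, PARAM_FIELDS
from .dynamics import (
    PatientState,
    TIME_FLOOR,
    njit,
    _age_activation,
    _age_recovery,
    _sr_hazard,
    _invert_sr_bracketed,
)

__all__ = [
    "Episode",
    "PatientTrajectory",
    "simulate_patient",
    "thinning_oracle",
    "write_trajectory",
    "read_trajectory",
]


@dataclass(frozen=True)
class Episode:
    """One AF interval.  ``censored`` marks truncation at the horizon."""

    start: float
    end: float
    censored: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class PatientTrajectory:
    """Ordered AF episodes of one simulated life, with provenance.

    Episode bounds are stored as arrays (``starts``, ``ends``); only the
    final episode may be censored (``last_censored``), in which case its
    end equals the horizon and the patient is in permanent AF.
    """

    starts: np.ndarray
    ends: np.ndarray
    last_censored: bool
    params: ModelParameters
    seed: object
    horizon: float = TIME.horizon

    @property
    def episodes(self) -> list[Episode]:
        n = len(self.starts)
        return [
            Episode(float(s), float(e), censored=(self.last_censored and i == n - 1))
            for i, (s, e) in enumerate(zip(self.starts, self.ends))
        ]

    @property
    def n_episodes(self) -> int:
        return len(self.starts)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    def af_time(self) -> float:
        """Total time spent in AF over the whole simulation."""
        return float(np.sum(self.ends - self.starts))

    def sr_time(self) -> float:
        return self.horizon - self.af_time()


@njit(cache=True)
def _simulate_kernel(rng, t0, aepi0, repi0, A0, A1, Amax, tc, td, alpha,
                     beta, R0, lam, mu, nu, B, horizon):
    cap = 1024
    starts = np.empty(cap)
    ends = np.empty(cap)
    n = 0
    censored = False
    t = t0
    aepi = aepi0
    repi = repi0
    while t < horizon:
        # --- sinus rhythm: wait for the next onset -----------------------
        E = -math.log1p(-rng.random())
        rem = horizon - t
        if _sr_hazard(t, aepi, rem, A0, A1, tc, td, beta) <= E:
            break  # no further onset before the horizon
        tau = _invert_sr_bracketed(t, aepi, E, rem, A0, A1, tc, td, beta)
        if tau < TIME_FLOOR:
            tau = TIME_FLOOR
        if tau >= rem:
            break
        aepi *= math.exp(-beta * tau)
        repi *= math.exp(-nu * tau)
        t += tau
        onset = t
        # --- AF: wait for termination (or censor at the horizon) ---------
        r_enter = _age_recovery(t, R0, lam) + repi
        E = -math.log1p(-rng.random())
        rem = horizon - t
        never = False
        if mu > 0.0:
            if E >= r_enter / mu:
                never = True
                tau = rem
            else:
                tau = -math.log1p(-mu * E / r_enter) / mu
        else:
            tau = E / r_enter
        if tau < TIME_FLOOR:
            tau = TIME_FLOOR
        if never or tau >= rem:
            # permanent AF: episode truncated at the horizon
            if n == cap:
                cap *= 2
                s2 = np.empty(cap)
                e2 = np.empty(cap)
                s2[:n] = starts[:n]
                e2[:n] = ends[:n]
                starts = s2
                ends = e2
            starts[n] = onset
            ends[n] = horizon
            n += 1
            censored = True
            t = horizon
            break
        aepi = Amax - (Amax - aepi) * math.exp(-alpha * tau)
        r_total = r_enter * math.exp(-mu * tau)
        t += tau
        repi = r_total - _age_recovery(t, R0, lam)
        if repi < 0.0:
            repi = -B * repi
        if n == cap:
            cap *= 2
            s2 = np.empty(cap)
            e2 = np.empty(cap)
            s2[:n] = starts[:n]
            e2[:n] = ends[:n]
            starts = s2
            ends = e2
        starts[n] = onset
        ends[n] = t
        n += 1
    return starts[:n].copy(), ends[:n].copy(), censored


def simulate_patient(params: ModelParameters, seed, horizon: float = TIME.horizon,
                     start: PatientState | None = None) -> PatientTrajectory:
    """Simulate one patient exactly from birth (or ``start``) to ``horizon``.

    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence`;
    identical inputs give bit-identical trajectories.  Initial conditions
    default to birth in sinus rhythm with no episode history
    (``t=0, S=0, Aepi=Repi=0``).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = np.random.default_rng(seed)
    if start is None:
        start = PatientState(t=0.0)
    if start.S != 0:
        raise ValueError("simulation must start in sinus rhythm")
    starts, ends, censored = _simulate_kernel(
        rng, float(start.t), float(start.Aepi), float(start.Repi),
        *params.as_tuple(), float(horizon))
    if not (np.all(np.isfinite(starts)) and np.all(np.isfinite(ends))):
        raise FloatingPointError("non-finite event time in trajectory")
    return PatientTrajectory(starts=starts, ends=ends, last_censored=censored,
                             params=params, seed=seed, horizon=horizon)


def thinning_oracle(params: ModelParameters, seed, horizon: float,
                    start: PatientState | None = None,
                    lookahead: float = 0.02) -> PatientTrajectory:
    """Simulate the same process by Lewis–Shedler rejection thinning.

    Over each short lookahead window the activation rate is bounded above
    by ``A0 + Aage(window end) + Aepi(now)`` (the age term is increasing,
    the episode term decaying in sinus rhythm) and the recovery rate by
    its current value (non-increasing in AF), so the thinning bound is
    valid and the sampler is statistically exact for any ``lookahead``.
    Intended for short horizons as an independent test oracle.
    """
    p = params
    rng = np.random.default_rng(seed)
    if start is None:
        start = PatientState(t=0.0)
    t, aepi, repi = float(start.t), float(start.Aepi), float(start.Repi)
    starts: list[float] = []
    ends: list[float] = []
    censored = False
    in_af = False
    onset = 0.0
    r_total = 0.0
    while t < horizon:
        if not in_af:
            dt = min(lookahead, horizon - t)
            bound = p.A0 + _age_activation(t + dt, p.A1, p.tc, p.td) + aepi
            w = rng.exponential() / bound if bound > 0 else math.inf
            if w > dt:
                aepi *= math.exp(-p.beta * dt)
                repi *= math.exp(-p.nu * dt)
                t += dt
                continue
            aepi *= math.exp(-p.beta * w)
            repi *= math.exp(-p.nu * w)
            t += w
            rate = p.A0 + _age_activation(t, p.A1, p.tc, p.td) + aepi
            if rng.random() * bound <= rate:
                in_af = True
                onset = t
                r_total = _age_recovery(t, p.R0, p.lam) + repi
        else:
            dt = min(lookahead, horizon - t)
            bound = r_total
            w = rng.exponential() / bound if bound > 0 else math.inf
            step = min(w, dt)
            aepi = p.Amax - (p.Amax - aepi) * math.exp(-p.alpha * step)
            r_total *= math.exp(-p.mu * step)
            t += step
            if w > dt:
                continue
            if rng.random() * bound <= r_total:
                repi = r_total - _age_recovery(t, p.R0, p.lam)
                if repi < 0.0:
                    repi = -p.B * repi
                in_af = False
                starts.append(onset)
                ends.append(t)
    if in_af:
        starts.append(onset)
        ends.append(horizon)
        censored = True
    return PatientTrajectory(starts=np.asarray(starts), ends=np.asarray(ends),
                             last_censored=censored, params=p, seed=seed,
                             horizon=horizon)


# ---------------------------------------------------------------------------
# plain-text persistence: episode CSV + JSON sidecar

_FMT = "{:.12g}"  # 12 significant digits round-trips the event times


def write_trajectory(traj: PatientTrajectory, csv_path: str | Path,
                     sidecar_path: str | Path | None = None,
                     patient_id: int = 0) -> None:
    """Write episodes as CSV and provenance (params, seed, horizon) as JSON."""
    csv_path = Path(csv_path)
    lines = ["patient_id,start_yr,end_yr,censored"]
    eps = traj.episodes
    for ep in eps:
        lines.append(f"{patient_id},{_FMT.format(ep.start)},"
                     f"{_FMT.format(ep.end)},{int(ep.censored)}")
    csv_path.write_text("\n".join(lines) + "\n")
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    meta = {
        "params": {k: getattr(traj.params, k) for k in PARAM_FIELDS},
        "seed": int(traj.seed) if np.isscalar(traj.seed) else str(traj.seed),
        "horizon": traj.horizon,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def read_trajectory(csv_path: str | Path,
                    sidecar_path: str | Path | None = None) -> PatientTrajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    params = ModelParameters(**meta["params"])
    starts, ends, censored = [], [], False
    rows = csv_path.read_text().strip().splitlines()[1:]
    for row in rows:
        _, s, e, c = row.split(",")
        starts.append(float(s))
        ends.append(float(e))
        censored = bool(int(c))
    return PatientTrajectory(starts=np.asarray(starts), ends=np.asarray(ends),
                             last_censored=censored, params=params,
                             seed=meta["seed"], horizon=float(meta["horizon"]))
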