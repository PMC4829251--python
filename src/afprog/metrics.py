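"""Burden and episode-count statistics over observation windows.

AF burden is the fraction of an observation window spent in AF, computed
by exact interval-overlap arithmetic on the episode list; episode counts
attribute each episode to the window containing its *start* (a censored
episode counts once, in its start window).  Series can be re-indexed
relative to a per-patient anchor (e.g. paroxysmal onset) for
onset-aligned population analyses.

Window conventions: a "day" is 1/365 yr, a "month" 30 days, a "year"
365 days.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .simulate import PatientTrajectory

__all__ = [
    "BurdenSeries",
    "EpisodeCountSeries",
    "burden",
    "episode_counts",
    "align",
    "duration_histogram",
    "DAY",
    "WEEK",
    "MONTH",
    "YEAR",
]

DAY = 1.0 / 365.0
WEEK = 7.0 / 365.0
MONTH = 30.0 / 365.0
YEAR = 1.0


@dataclass(frozen=True)
class BurdenSeries:
    """Fraction of each window spent in AF; values in [0, 1].

    ``t_grid`` holds window start times; window ``k`` covers
    ``[t_grid[k], t_grid[k] + window)``.
    """

    window: float
    t_grid: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class EpisodeCountSeries:
    """Number of episodes *starting* within each window."""

    window: float
    t_grid: np.ndarray
    counts: np.ndarray


def _af_time_before(trajectory: PatientTrajectory, x: np.ndarray) -> np.ndarray:
    """Cumulative AF time on [0, x) for each x, exact on episode intervals."""
    starts, ends = trajectory.starts, trajectory.ends
    if len(starts) == 0:
        return np.zeros_like(x, dtype=float)
    cum = np.concatenate(([0.0], np.cumsum(ends - starts)))
    idx = np.searchsorted(starts, x, side="right")
    f = cum[idx]
    partial = idx > 0
    if np.any(partial):
        j = idx[partial] - 1
        f[partial] -= np.clip(ends[j] - x[partial], 0.0, None)
    return f


def _grid(origin: float, window: float, horizon: float) -> np.ndarray:
    # full windows only; 1e-9 guard against edge representation error
    k = int(np.floor((horizon - origin) / window + 1e-9))
    return origin + window * np.arange(k)


def burden(trajectory: PatientTrajectory, window: float,
           origin: float = 0.0) -> BurdenSeries:
    """AF burden per window of the given width, starting at ``origin``.

    Overlaps are computed exactly on the episode intervals, clipped at
    window edges; only windows lying fully inside the horizon are kept.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    grid = _grid(origin, window, trajectory.horizon)
    edges = np.concatenate((grid, [grid[-1] + window])) if len(grid) else grid
    f = _af_time_before(trajectory, edges)
    vals = (f[1:] - f[:-1]) / window if len(grid) else np.zeros(0)
    return BurdenSeries(window=window, t_grid=grid, values=vals)


def episode_counts(trajectory: PatientTrajectory, window: float,
                   origin: float = 0.0) -> EpisodeCountSeries:
    """Episodes starting in each window (censored episodes count once)."""
    if window <= 0:
        raise ValueError("window must be positive")
    grid = _grid(origin, window, trajectory.horizon)
    if len(grid) == 0:
        return EpisodeCountSeries(window=window, t_grid=grid,
                                  counts=np.zeros(0, dtype=int))
    edges = np.concatenate((grid, [grid[-1] + window]))
    counts, _ = np.histogram(trajectory.starts, bins=edges)
    return EpisodeCountSeries(window=window, t_grid=grid, counts=counts)


def align(series: BurdenSeries | EpisodeCountSeries, anchor: float,
          direction: str = "after"):
    """Re-index a series relative to an anchor time.

    ``after`` keeps windows starting at or after the anchor, with the
    grid re-labelled as time since the anchor (window 0 covers
    ``[anchor, anchor + window)``).  ``before`` keeps windows ending at
    or before the anchor, the grid re-labelled as (negative) time until
    the anchor.  The anchor must lie on a window boundary of the series;
    for arbitrary anchors recompute the series with a shifted origin.
    Raises ``ValueError`` for a missing anchor (stage never reached).
    """
    if anchor is None:
        raise ValueError("anchor missing: patient never reached this stage")
    w = series.window
    offset = (anchor - series.t_grid[0]) / w if len(series.t_grid) else 0.0
    if abs(offset - round(offset)) > 1e-9:
        raise ValueError("anchor does not lie on a window boundary; "
                         "recompute the series with origin at the anchor")
    rel = series.t_grid - anchor
    if direction == "after":
        keep = rel >= -1e-9 * w
    elif direction == "before":
        keep = rel + w <= 1e-9 * w
    else:
        raise ValueError("direction must be 'after' or 'before'")
    data = series.values if isinstance(series, BurdenSeries) else series.counts
    field = "values" if isinstance(series, BurdenSeries) else "counts"
    return replace(series, t_grid=rel[keep], **{field: data[keep]})


def duration_histogram(trajectories, observation: tuple[float, float],
                       bins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of episode durations starting within an observation window.

    ``trajectories`` may be one trajectory or a sequence; for a sequence
    the per-patient counts are averaged over the ensemble.  Returns
    ``(counts, bin_edges)``; durations are in years.
    """
    t0, t1 = observation
    if not t0 < t1:
        raise ValueError("observation window must have t0 < t1")
    if isinstance(trajectories, PatientTrajectory):
        trajectories = [trajectories]
        average = False
    else:
        average = True
    bins = np.asarray(bins, dtype=float)
    total = np.zeros(len(bins) - 1)
    for traj in trajectories:
        sel = (traj.starts >= t0) & (traj.starts < t1)
        counts, _ = np.histogram(traj.durations[sel], bins=bins)
        total += counts
    if average and len(trajectories):
        total /= len(trajectories)
    return total, bins
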