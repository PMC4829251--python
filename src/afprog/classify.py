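"""Clinical-stage classification of simulated trajectories.

Stages are assigned from the full episode record (every episode is
observable in simulation, unlike in the clinic): paroxysmal AF from the
first episode lasting at least 14.4 minutes (1% of a day), persistent AF
from the first episode lasting 7 days, permanent AF from entry into the
final episode that continues to the simulation horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .parameters import TIME
from .simulate import PatientTrajectory

__all__ = ["StageTimeline", "classify", "write_timelines"]


@dataclass(frozen=True)
class StageTimeline:
    """Onset ages (yr) of the three stages; ``None`` if never reached."""

    paroxysmal_onset: float | None = None
    persistent_onset: float | None = None
    permanent_onset: float | None = None


def classify(trajectory: PatientTrajectory,
             paroxysmal_threshold: float = TIME.paroxysmal_threshold,
             persistent_threshold: float = TIME.persistent_threshold) -> StageTimeline:
    """Map a trajectory to stage-onset times.

    Onset of the duration-based stages is timed at the moment the
    qualifying episode has lasted the threshold (``start + threshold``) —
    the earliest time the criterion is knowable; a censored episode of at
    least threshold length also qualifies.  Permanent onset is the start
    of the censored final episode.  Pure: depends only on the episode
    list.

    Note the one admissible ordering quirk: when the first 7-day episode
    is itself the final censored episode, persistent onset falls 7 days
    after permanent onset under this timing convention.
    """
    starts, ends = trajectory.starts, trajectory.ends
    durations = ends - starts
    parox = persist = perm = None
    idx = np.nonzero(durations >= paroxysmal_threshold)[0]
    if idx.size:
        parox = float(starts[idx[0]] + paroxysmal_threshold)
    idx = np.nonzero(durations >= persistent_threshold)[0]
    if idx.size:
        persist = float(starts[idx[0]] + persistent_threshold)
    if trajectory.last_censored and len(starts):
        perm = float(starts[-1])
    return StageTimeline(paroxysmal_onset=parox, persistent_onset=persist,
                         permanent_onset=perm)


def write_timelines(timelines: list[StageTimeline], path: str | Path) -> None:
    """Write onset ages as CSV; empty cells for stages never reached."""
    def cell(x: float | None) -> str:
        return "" if x is None else f"{x:.12g}"

    lines = ["patient_id,paroxysmal_onset_yr,persistent_onset_yr,permanent_onset_yr"]
    for i, tl in enumerate(timelines):
        lines.append(f"{i},{cell(tl.paroxysmal_onset)},"
                     f"{cell(tl.persistent_onset)},{cell(tl.permanent_onset)}")
    Path(path).write_text("\n".join(lines) + "\n")
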