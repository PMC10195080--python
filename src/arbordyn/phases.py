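"""Targeting-phase segmentation of bulk-cadence recordings.

Developing projection-neuron dendrites pass through an *initial* phase of
exploration in three or more directions, a *transitional* phase in which
dendritic mass is found in exactly two directions, and a *final* phase of
single-direction targeting.  A direction counts as occupied when it holds
at least ``occupancy_threshold`` of the frame's dendritic mass.  Phase
boundaries are smoothed: a new occupancy count class must persist for
``phase_smoothing`` consecutive frames before a boundary is declared, and
frames that would move backwards in the admissible order
initial → transitional → final are absorbed into the preceding phase and
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bulk import DirectionProfile
from .errors import ArbordynError, SeriesTooShortError
from .geometry import DIRECTIONS
from .params import AnalysisParams

PHASES = ("initial", "transitional", "final")
_RANK = {p: i for i, p in enumerate(PHASES)}


def occupied_directions(
    fractions: Mapping[str, float], params: AnalysisParams | None = None
) -> frozenset[str]:
    """Directions holding at least ``occupancy_threshold`` of the frame mass."""
    params = params or AnalysisParams()
    return frozenset(
        d for d in DIRECTIONS if float(fractions.get(d, 0.0)) >= params.occupancy_threshold
    )


def _count_class(n_occupied: int) -> str:
    if n_occupied >= 3:
        return "initial"
    if n_occupied == 2:
        return "transitional"
    return "final"


@dataclass
class PhaseInterval:
    phase: str
    start_frame: int
    end_frame: int  #: inclusive
    occupied: frozenset[str]
    flagged_frames: list[int] = field(default_factory=list)


@dataclass
class PhaseSegmentation:
    """Contiguous, exhaustive decomposition of a series into phases."""

    intervals: list[PhaseInterval]
    per_frame: pd.DataFrame  #: frame, time_min, n_occupied, occupied, phase, flagged

    def phase_of(self, frame: int) -> str:
        for iv in self.intervals:
            if iv.start_frame <= frame <= iv.end_frame:
                return iv.phase
        raise ArbordynError(f"frame {frame} outside segmentation")

    def to_csv(self, path, times: np.ndarray | None = None) -> None:
        rows = []
        for iv in self.intervals:
            rows.append(
                {
                    "phase": iv.phase,
                    "start_frame": iv.start_frame,
                    "end_frame": iv.end_frame,
                    "occupied": "|".join(sorted(iv.occupied)),
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)


def segment_phases(
    profile: DirectionProfile, params: AnalysisParams | None = None
) -> PhaseSegmentation:
    """Segment a direction profile into initial/transitional/final phases.

    Per frame the occupied-direction count maps to a class (≥3 initial,
    2 transitional, ≤1 final).  Runs of the same class shorter than
    ``phase_smoothing`` are absorbed into the run before them (a leading
    short run joins its successor), then any run that would violate the
    admissible order is absorbed into the preceding phase with its frames
    flagged.  Invalid frames (zero dendritic cable) inherit the class of
    their predecessor.
    """
    params = params or AnalysisParams()
    frac = profile.fraction_matrix()
    frames = frac.index.to_numpy()
    n = len(frames)
    if n < 3 * params.phase_smoothing:
        raise SeriesTooShortError(
            f"phase segmentation needs ≥ {3 * params.phase_smoothing} frames, got {n}"
        )
    valid = profile.frames.set_index("frame")["valid"]
    occ_sets: list[frozenset[str]] = []
    classes: list[str] = []
    for k, f in enumerate(frames):
        if bool(valid.loc[f]):
            occ = occupied_directions(frac.loc[f].to_dict(), params)
        else:
            occ = occ_sets[-1] if occ_sets else frozenset()
        occ_sets.append(occ)
        classes.append(_count_class(len(occ)))

    # run-length encode and smooth short runs
    runs: list[list] = []  # [class, start_k, end_k]
    for k, c in enumerate(classes):
        if runs and runs[-1][0] == c:
            runs[-1][2] = k
        else:
            runs.append([c, k, k])
    smoothed: list[list] = []
    for run in runs:
        length = run[2] - run[1] + 1
        if smoothed and length < params.phase_smoothing:
            smoothed[-1][2] = run[2]  # absorb into preceding run
        elif not smoothed and length < params.phase_smoothing and len(runs) > 1:
            run = [None, run[1], run[2]]  # leading short run joins successor
            smoothed.append(run)
        else:
            if smoothed and smoothed[-1][0] is None:
                smoothed[-1][0] = run[0]
                smoothed[-1][2] = run[2]
            elif smoothed and smoothed[-1][0] == run[0]:
                smoothed[-1][2] = run[2]
            else:
                smoothed.append(run)
    if smoothed and smoothed[-1][0] is None:  # whole series one short run
        smoothed[-1][0] = runs[0][0]

    # enforce admissible ordering: absorb backward moves into the predecessor
    ordered: list[list] = []
    flagged: list[int] = []
    for run in smoothed:
        if ordered and _RANK[run[0]] < _RANK[ordered[-1][0]]:
            flagged.extend(range(run[1], run[2] + 1))
            ordered[-1][2] = run[2]
        elif ordered and run[0] == ordered[-1][0]:
            ordered[-1][2] = run[2]
        else:
            ordered.append(list(run))

    intervals: list[PhaseInterval] = []
    for c, k0, k1 in ordered:
        members = [occ_sets[k] for k in range(k0, k1 + 1)]
        counts: dict[frozenset, int] = {}
        for m in members:
            counts[m] = counts.get(m, 0) + 1
        top = max(counts.values())
        modal = sorted(
            (m for m, v in counts.items() if v == top),
            key=lambda s: tuple(sorted(s)),
        )[0]
        intervals.append(
            PhaseInterval(
                phase=c,
                start_frame=int(frames[k0]),
                end_frame=int(frames[k1]),
                occupied=modal,
                flagged_frames=[int(frames[k]) for k in flagged if k0 <= k <= k1],
            )
        )
    per_frame = pd.DataFrame(
        {
            "frame": frames,
            "time_min": profile.frames.set_index("frame").loc[frames, "time_min"].to_numpy(),
            "n_occupied": [len(s) for s in occ_sets],
            "occupied": ["|".join(sorted(s)) for s in occ_sets],
            "phase": [
                next(iv.phase for iv in intervals if iv.start_frame <= f <= iv.end_frame)
                for f in frames
            ],
            "flagged": [k in flagged for k in range(n)],
        }
    )
    return PhaseSegmentation(intervals=intervals, per_frame=per_frame)
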