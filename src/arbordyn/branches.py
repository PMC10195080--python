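"""Terminal-branch dynamics for short-cadence (30 s) recordings.

A terminal branch is the skeleton path from a leaf tip back to the
nearest branch point (node of degree ≥ 3) or to the main process.
Branches are tracked across frames by gated nearest-tip matching, then
classified into the four lifetime categories observed in developing
projection-neuron dendrites:

* **stable** — present throughout the entire imaging window;
* **transient** — produced and eliminated within the window;
* **emerging** — produced after imaging began and still present at the end;
* **retracting** — present at the start and eliminated within the window.

Per-interval tip speeds are changes in branch path length per minute
(positive = extension); an interval counts as extending or retracting
only when the speed strictly exceeds the 0.5 µm/min threshold, otherwise
it is stationary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArbordynError, InsufficientDataError, TrackContractError
from .geometry import DIRECTIONS, DirectionFrame, assign_sector
from .params import AnalysisParams
from .skeleton import AXON_LABEL, SkeletonFrame, SkeletonSeries

CATEGORIES = ("stable", "transient", "emerging", "retracting")
MOTION_LABELS = ("extending", "retracting", "stationary")

_DEGENERATE_TOL = 1e-9


@dataclass
class TerminalBranch:
    """One terminal branch in one frame.

    ``node_ids`` runs from the junction (branch point or main-process
    node, inclusive) to the tip; ``path_length`` sums the edge lengths
    along that path.
    """

    frame: int
    node_ids: list[int]
    tip_id: int
    tip_position: np.ndarray
    path_length: float
    sector: str | None = None


def extract_terminals(
    frame: SkeletonFrame,
    dframe: DirectionFrame | None = None,
    frame_index: int = 0,
    exclude_axon: bool = True,
) -> list[TerminalBranch]:
    """One :class:`TerminalBranch` per leaf of the skeleton.

    From each leaf the path is walked rootward until hitting a node with
    two or more children, a node of a different structure label (the
    main process), or the root.  With ``exclude_axon``, leaves on the
    main process itself are skipped.  If ``dframe`` is given each branch
    is labelled with the sector of its tip (tips projecting onto the
    origin get ``None``).
    """
    ids = frame.nodes["node_id"].to_numpy()
    pos = frame.nodes[["x", "y", "z"]].to_numpy(dtype=float)
    labels = frame.nodes["structure_label"].to_numpy()
    position = {int(i): pos[k] for k, i in enumerate(ids)}
    label_of = {int(i): int(labels[k]) for k, i in enumerate(ids)}
    cm = frame.children_map()
    parent = {int(i): int(p) for i, p in zip(ids, frame.nodes["parent_id"])}
    out: list[TerminalBranch] = []
    for leaf in frame.leaf_ids():
        leaf_label = label_of[leaf]
        if exclude_axon and leaf_label == AXON_LABEL:
            continue
        path = [leaf]
        node = leaf
        length = 0.0
        while True:
            p = parent[node]
            if p == -1:
                break
            length += float(np.linalg.norm(position[node] - position[p]))
            path.append(p)
            node = p
            if len(cm[node]) >= 2 or label_of[node] != leaf_label:
                break
        tip_pos = position[leaf]
        sector = None
        if dframe is not None:
            u, w = dframe.project(tip_pos[None, :])
            if float(np.hypot(u[0], w[0])) >= _DEGENERATE_TOL:
                sector = assign_sector(tip_pos, dframe)
        out.append(
            TerminalBranch(
                frame=frame_index,
                node_ids=list(reversed(path)),
                tip_id=leaf,
                tip_position=tip_pos,
                path_length=length,
                sector=sector,
            )
        )
    return out


@dataclass
class BranchTrack:
    """One terminal branch's identity across frames.

    Present frames are contiguous by construction (no resurrection after
    absence); ``branches[k]`` is the observation at frame
    ``first_frame + k``.
    """

    track_id: int
    first_frame: int
    branches: list[TerminalBranch] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    category: str | None = None

    @property
    def last_frame(self) -> int:
        return self.first_frame + len(self.branches) - 1

    @property
    def n_present(self) -> int:
        return len(self.branches)

    def presence_mask(self, n_frames: int) -> np.ndarray:
        mask = np.zeros(n_frames, dtype=bool)
        mask[self.first_frame : self.last_frame + 1] = True
        return mask

    def path_lengths(self) -> np.ndarray:
        return np.array([b.path_length for b in self.branches])

    def tip_positions(self) -> np.ndarray:
        return np.array([b.tip_position for b in self.branches])

    def modal_sector(self) -> str | None:
        sectors = [b.sector for b in self.branches if b.sector is not None]
        if not sectors:
            return None
        counts = Counter(sectors)
        top = max(counts.values())
        # deterministic tie-break: canonical direction order
        for d in DIRECTIONS:
            if counts.get(d, 0) == top:
                return d
        return None


def track_terminals(
    series: SkeletonSeries,
    params: AnalysisParams | None = None,
    dframe: DirectionFrame | None = None,
    exclude_axon: bool = True,
) -> list[BranchTrack]:
    """Greedy gated nearest-tip tracking across consecutive frames.

    Candidate matches between the previous and current frame's tips are
    taken in order of increasing Euclidean distance (ties broken by the
    previous then the new tip's node id) and accepted while the distance
    is at most ``match_gate`` and both tips are unmatched.  Unmatched
    previous tips close their tracks; unmatched new tips open tracks.  A
    missing frame closes every open track.  Crossing branches closer than
    the gate may swap identities — a documented limitation of greedy
    matching.
    """
    params = params or AnalysisParams()
    tracks: list[BranchTrack] = []
    open_tracks: dict[int, BranchTrack] = {}  # keyed by index in current tip list
    prev_tips: list[TerminalBranch] = []
    next_id = 0
    for i in range(len(series)):
        frame = series.frames[i]
        if frame is None:
            open_tracks = {}
            prev_tips = []
            continue
        tips = extract_terminals(frame, dframe=dframe, frame_index=i, exclude_axon=exclude_axon)
        new_open: dict[int, BranchTrack] = {}
        matched_new: set[int] = set()
        if prev_tips and tips:
            prev_pos = np.array([t.tip_position for t in prev_tips])
            cur_pos = np.array([t.tip_position for t in tips])
            dist = np.linalg.norm(prev_pos[:, None, :] - cur_pos[None, :, :], axis=2)
            pairs = [
                (dist[a, b], prev_tips[a].tip_id, tips[b].tip_id, a, b)
                for a in range(len(prev_tips))
                for b in range(len(tips))
                if dist[a, b] <= params.match_gate
            ]
            pairs.sort(key=lambda p: (p[0], p[1], p[2]))
            matched_prev: set[int] = set()
            for d, _, _, a, b in pairs:
                if a in matched_prev or b in matched_new or a not in open_tracks:
                    continue
                matched_prev.add(a)
                matched_new.add(b)
                tr = open_tracks[a]
                tr.branches.append(tips[b])
                tr.times.append(float(series.times[i]))
                new_open[b] = tr
        for b, tip in enumerate(tips):
            if b in matched_new:
                continue
            tr = BranchTrack(track_id=next_id, first_frame=i, branches=[tip], times=[float(series.times[i])])
            next_id += 1
            tracks.append(tr)
            new_open[b] = tr
        open_tracks = new_open
        prev_tips = tips
    return tracks


def categorize_presence(first: int, last: int, n_frames: int) -> str:
    """Four-way lifetime category from a contiguous presence run.

    stable: present for the whole window; transient: born after the start
    and gone before the end; emerging: born after the start, present at
    the end; retracting: present at the start, gone before the end.
    """
    starts_at_0 = first == 0
    ends_at_last = last == n_frames - 1
    if starts_at_0 and ends_at_last:
        return "stable"
    if not starts_at_0 and not ends_at_last:
        return "transient"
    if not starts_at_0:
        return "emerging"
    return "retracting"


def classify_tracks(tracks: list[BranchTrack], n_frames: int) -> list[str]:
    """Assign and return the lifetime category of each track."""
    cats = []
    for tr in tracks:
        if tr.n_present != tr.last_frame - tr.first_frame + 1:
            raise TrackContractError(f"track {tr.track_id}: non-contiguous presence")
        if tr.first_frame < 0 or tr.last_frame > n_frames - 1:
            raise TrackContractError(f"track {tr.track_id}: outside the window")
        tr.category = categorize_presence(tr.first_frame, tr.last_frame, n_frames)
        cats.append(tr.category)
    return cats


def tip_speeds(track: BranchTrack) -> np.ndarray:
    """Signed per-interval speed, µm/min (positive = extension).

    speed(k) = (path_length(k+1) − path_length(k)) / Δt over the track's
    present frames.
    """
    if track.n_present < 2:
        return np.empty(0)
    lengths = track.path_lengths()
    dt = np.diff(np.asarray(track.times, dtype=float))
    return np.diff(lengths) / dt


def label_motion(speeds: np.ndarray, params: AnalysisParams | None = None) -> list[str]:
    """Per-interval motion labels with strict thresholds.

    extending iff speed > speed_threshold; retracting iff
    speed < −speed_threshold; otherwise stationary (a speed of exactly
    the threshold is stationary).
    """
    params = params or AnalysisParams()
    out = []
    for s in np.asarray(speeds, dtype=float):
        if s > params.speed_threshold:
            out.append("extending")
        elif s < -params.speed_threshold:
            out.append("retracting")
        else:
            out.append("stationary")
    return out


@dataclass
class BranchSummary:
    """Per-direction and per-category summaries of a tracked cell.

    ``stable_abundance``: percentage of the cell's stable branches whose
    modal tip sector is each direction (sums to 100 when any stable
    branch exists).  ``stable_speed``: mean absolute per-interval speed
    of stable branches per direction, µm/min; NaN where a direction has
    no stable branch.  ``motion_fractions``: mean fraction of intervals
    spent extending/retracting/stationary, per lifetime category.
    """

    stable_abundance: pd.Series
    stable_speed: pd.Series
    motion_fractions: pd.DataFrame
    stable_counts: pd.Series


def summarize_branch_dynamics(
    tracks: list[BranchTrack], params: AnalysisParams | None = None
) -> BranchSummary:
    params = params or AnalysisParams()
    if not tracks:
        raise InsufficientDataError("no tracks to summarize")
    if any(tr.category is None for tr in tracks):
        raise ArbordynError("tracks must be classified before summarizing")
    if all(tr.modal_sector() is None for tr in tracks):
        raise ArbordynError(
            "tracks carry no sector labels; pass a DirectionFrame to the tracker"
        )
    stable_counts = pd.Series(0, index=list(DIRECTIONS), dtype=int)
    speed_sums = {d: [] for d in DIRECTIONS}
    frac_acc: dict[str, list[np.ndarray]] = {c: [] for c in CATEGORIES}
    for tr in tracks:
        d = tr.modal_sector()
        if tr.category == "stable" and d is not None:
            stable_counts[d] += 1
            sp = tip_speeds(tr)
            if sp.size:
                speed_sums[d].extend(np.abs(sp))
        sp = tip_speeds(tr)
        if sp.size:
            labels = label_motion(sp, params)
            fracs = np.array(
                [labels.count(m) / len(labels) for m in MOTION_LABELS]
            )
            frac_acc[tr.category].append(fracs)
    total_stable = int(stable_counts.sum())
    if total_stable > 0:
        abundance = 100.0 * stable_counts / total_stable
    else:
        abundance = pd.Series(0.0, index=list(DIRECTIONS))
    speed = pd.Series(
        {d: (float(np.mean(v)) if v else np.nan) for d, v in speed_sums.items()}
    )[list(DIRECTIONS)]
    motion = pd.DataFrame(
        {
            c: (np.mean(frac_acc[c], axis=0) if frac_acc[c] else np.full(3, np.nan))
            for c in CATEGORIES
        },
        index=list(MOTION_LABELS),
    ).T
    return BranchSummary(
        stable_abundance=abundance,
        stable_speed=speed,
        motion_fractions=motion,
        stable_counts=stable_counts,
    )


def track_table(tracks: list[BranchTrack]) -> pd.DataFrame:
    """Tidy per-observation table (track_id, frame, time, tip, length, sector, category)."""
    rows = []
    for tr in tracks:
        for b, t in zip(tr.branches, tr.times):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": b.frame,
                    "time_min": t,
                    "tip_x": b.tip_position[0],
                    "tip_y": b.tip_position[1],
                    "tip_z": b.tip_position[2],
                    "path_length": b.path_length,
                    "sector": b.sector,
                    "category": tr.category,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id", "frame", "time_min", "tip_x", "tip_y", "tip_z",
            "path_length", "sector", "category",
        ],
    )


def motion_raster(tracks: list[BranchTrack], n_frames: int, params: AnalysisParams | None = None) -> pd.DataFrame:
    """Track × interval matrix of motion labels (+1 extend, −1 retract, 0 stationary, NaN absent)."""
    params = params or AnalysisParams()
    mat = np.full((len(tracks), max(n_frames - 1, 0)), np.nan)
    code = {"extending": 1.0, "retracting": -1.0, "stationary": 0.0}
    for r, tr in enumerate(tracks):
        sp = tip_speeds(tr)
        for k, lab in enumerate(label_motion(sp, params)):
            mat[r, tr.first_frame + k] = code[lab]
    return pd.DataFrame(mat, index=[tr.track_id for tr in tracks])
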