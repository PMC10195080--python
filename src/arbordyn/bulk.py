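"""Bulk dendrite dynamics for long-cadence (20 min) recordings.

Per frame, every dendritic segment contributes its frustum volume (or
length) to the sector of its midpoint, giving per-direction volumes,
fractions and maximal radial extents over time.  Bulk extension and
retraction events are direction-wise changes in extent of strictly more
than ``bulk_threshold`` µm between two consecutive frames; frames flagged
missing break consecutiveness, so no event ever spans a gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ArbordynError, SeriesTooShortError
from .geometry import DIRECTIONS, DirectionFrame, assign_sectors, dendrite_edge_table, frustum_volumes
from .params import AnalysisParams
from .skeleton import AXON_LABEL, SkeletonSeries

_DEGENERATE_TOL = 1e-9


@dataclass
class DirectionProfile:
    """Per-frame, per-direction mass distribution of a series.

    ``table`` has one row per observed frame × direction with columns
    ``frame, time_min, direction, weight, fraction, extent``; ``frames``
    has one row per observed frame with ``frame, time_min, valid`` (a
    frame with zero dendritic cable is flagged invalid and its fractions
    are NaN).  ``n_series_frames`` is the length of the originating
    series including missing frames.
    """

    table: pd.DataFrame
    frames: pd.DataFrame
    weighting: str
    n_series_frames: int

    def pivot(self, value: str) -> pd.DataFrame:
        """Frame × direction matrix of one column (``extent``, ``fraction``, ``weight``)."""
        return self.table.pivot(index="frame", columns="direction", values=value)[
            list(DIRECTIONS)
        ]

    def extent_matrix(self) -> pd.DataFrame:
        return self.pivot("extent")

    def fraction_matrix(self) -> pd.DataFrame:
        return self.pivot("fraction")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def direction_profile(
    series: SkeletonSeries,
    dframe: DirectionFrame,
    weighting: Literal["volume", "length"] = "volume",
    exclude_axon: bool = True,
) -> DirectionProfile:
    """Partition each frame's dendritic mass into the four sectors.

    A segment is assigned the sector of its midpoint (segments are not
    split at boundaries; the error vanishes with tracing density).  The
    per-direction extent is the largest in-plane radial distance of any
    dendritic node in that sector from the frame origin.  Midpoints or
    nodes projecting onto the origin are excluded with a warning.
    """
    if len(series) == 0:
        raise ArbordynError("empty series")
    rows = []
    frame_rows = []
    for idx, frame in series.observed():
        edges = dendrite_edge_table(frame, exclude_axon)
        weights = np.zeros(4)
        extents = np.zeros(4)
        if len(edges) > 0:
            mids = 0.5 * (
                edges[["ax", "ay", "az"]].to_numpy() + edges[["bx", "by", "bz"]].to_numpy()
            )
            u, w = dframe.project(mids)
            ok = np.hypot(u, w) >= _DEGENERATE_TOL
            if not ok.all():
                warnings.warn(
                    f"frame {idx}: {int((~ok).sum())} segment midpoint(s) at the "
                    "sector origin excluded from the profile"
                )
            if weighting == "volume":
                edge_w = frustum_volumes(edges)
            elif weighting == "length":
                edge_w = edges["length"].to_numpy()
            else:
                raise ArbordynError(f"unknown weighting {weighting!r}")
            sectors = np.empty(len(edges), dtype=object)
            sectors[ok] = assign_sectors(mids[ok], dframe)
            for d_i, d in enumerate(DIRECTIONS):
                weights[d_i] = edge_w[ok & (sectors == d)].sum()
            # extents from dendritic *node* positions
            nodes = frame.nodes
            if exclude_axon:
                nodes = nodes[nodes["structure_label"] != AXON_LABEL]
            pts = nodes[["x", "y", "z"]].to_numpy(dtype=float)
            if len(pts) > 0:
                nu, nw = dframe.project(pts)
                r = np.hypot(nu, nw)
                nok = r >= _DEGENERATE_TOL
                if nok.any():
                    nsec = np.empty(len(pts), dtype=object)
                    nsec[nok] = assign_sectors(pts[nok], dframe)
                    for d_i, d in enumerate(DIRECTIONS):
                        sel = nok & (nsec == d)
                        extents[d_i] = r[sel].max() if sel.any() else 0.0
        total = weights.sum()
        valid = total > 0
        fractions = weights / total if valid else np.full(4, np.nan)
        frame_rows.append({"frame": idx, "time_min": frame.time, "valid": valid})
        for d_i, d in enumerate(DIRECTIONS):
            rows.append(
                {
                    "frame": idx,
                    "time_min": frame.time,
                    "direction": d,
                    "weight": weights[d_i],
                    "fraction": fractions[d_i],
                    "extent": extents[d_i],
                }
            )
    return DirectionProfile(
        table=pd.DataFrame(rows),
        frames=pd.DataFrame(frame_rows),
        weighting=weighting,
        n_series_frames=len(series),
    )


@dataclass(frozen=True)
class BulkEvent:
    """One bulk extension/retraction event on the interval frame i -> i+1."""

    direction: str
    interval: tuple[int, int]
    kind: str  #: "extension" or "retraction"
    magnitude: float  #: |Δextent|, µm; always > bulk_threshold


def detect_bulk_events(
    profile: DirectionProfile, params: AnalysisParams | None = None
) -> list[BulkEvent]:
    """Threshold direction-wise extent changes between consecutive frames.

    Δ = extent(i+1) − extent(i); extension iff Δ > bulk_threshold,
    retraction iff Δ < −bulk_threshold, both strict (a change of exactly
    the threshold is not an event).  Frame pairs separated by a missing
    frame are skipped.
    """
    params = params or AnalysisParams()
    ext = profile.extent_matrix()
    if len(ext) < 2:
        raise SeriesTooShortError("need at least 2 observed frames for events")
    frames = ext.index.to_numpy()
    events: list[BulkEvent] = []
    for k in range(len(frames) - 1):
        i, j = int(frames[k]), int(frames[k + 1])
        if j != i + 1:
            continue  # gap (missing frame): no event spans it
        for d in DIRECTIONS:
            delta = float(ext.loc[j, d] - ext.loc[i, d])
            if delta > params.bulk_threshold:
                events.append(BulkEvent(d, (i, j), "extension", abs(delta)))
            elif delta < -params.bulk_threshold:
                events.append(BulkEvent(d, (i, j), "retraction", abs(delta)))
    return events


def events_table(events: list[BulkEvent]) -> pd.DataFrame:
    """Tidy one-row-per-event table."""
    return pd.DataFrame(
        [
            {
                "direction": e.direction,
                "frame_from": e.interval[0],
                "frame_to": e.interval[1],
                "kind": e.kind,
                "magnitude": e.magnitude,
            }
            for e in events
        ],
        columns=["direction", "frame_from", "frame_to", "kind", "magnitude"],
    )


def event_matrix(events: list[BulkEvent], n_frames: int) -> pd.DataFrame:
    """Direction × interval raster with −1 (retraction), 0, +1 (extension)."""
    mat = pd.DataFrame(
        np.zeros((len(DIRECTIONS), max(n_frames - 1, 0)), dtype=int),
        index=list(DIRECTIONS),
    )
    for e in events:
        mat.loc[e.direction, e.interval[0]] = 1 if e.kind == "extension" else -1
    return mat


def event_counts_by_window(
    events: list[BulkEvent],
    profile: DirectionProfile,
    window: Literal["initial", "final"],
    n_frames: int = 6,
) -> pd.DataFrame:
    """Event counts per direction × kind within the first or last windows.

    The initial (final) window comprises the first (last) ``n_frames``
    frames of the series; an event counts only if its interval lies
    wholly inside the window.  The series must span at least
    ``2 * n_frames`` frames so the two windows cannot overlap.
    """
    total = profile.n_series_frames
    if total < 2 * n_frames:
        raise SeriesTooShortError(
            f"series has {total} frames; initial/final windows of {n_frames} "
            "frames require at least twice that"
        )
    if window == "initial":
        keep = lambda e: e.interval[1] <= n_frames - 1
    elif window == "final":
        keep = lambda e: e.interval[0] >= total - n_frames
    else:
        raise ArbordynError(f"unknown window {window!r}")
    counts = pd.DataFrame(
        0, index=list(DIRECTIONS), columns=["extension", "retraction"]
    )
    for e in events:
        if keep(e):
            counts.loc[e.direction, e.kind] += 1
    return counts
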