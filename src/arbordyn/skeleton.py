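"""Skeleton containers and SWC / manifest I/O.

A traced arbor at one time point is a :class:`SkeletonFrame` holding a node
table in standard SWC column order (node_id, structure_label, x, y, z,
radius, parent_id).  An ordered set of frames with acquisition times is a
:class:`SkeletonSeries`.  Units are fixed package-wide: micrometres for
space, minutes for time; manifests carrying seconds must be converted at
the boundary.

The SWC dialect is the common 7-column whitespace-delimited form with
``#`` comments, integer node ids, and parent ``-1`` for the root.  The
structure label (type column) is carried through unmodified; label ``2``
(axon) marks the main process in this package's conventions.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .errors import ManifestError, SkeletonStructureError, SWCParseError

SWC_COLUMNS = ["node_id", "structure_label", "x", "y", "z", "radius", "parent_id"]

#: SWC structure label conventionally used for axonal / main-process nodes.
AXON_LABEL = 2


def _validate_nodes(nodes: pd.DataFrame, context: str = "") -> int:
    """Check structural invariants of a node table; return the root id."""
    where = f" in {context}" if context else ""
    ids = nodes["node_id"].to_numpy()
    if len(ids) == 0:
        raise SkeletonStructureError(f"empty skeleton{where}")
    if len(np.unique(ids)) != len(ids):
        raise SkeletonStructureError(f"duplicate node ids{where}")
    if (nodes["radius"].to_numpy() < 0).any():
        raise SkeletonStructureError(f"negative radius{where}")
    parents = nodes["parent_id"].to_numpy()
    root_mask = parents == -1
    n_roots = int(root_mask.sum())
    if n_roots != 1:
        raise SkeletonStructureError(f"expected exactly one root, found {n_roots}{where}")
    id_set = set(int(i) for i in ids)
    dangling = [int(p) for p in parents[~root_mask] if int(p) not in id_set]
    if dangling:
        raise SkeletonStructureError(f"dangling parent id(s) {sorted(set(dangling))}{where}")
    # n nodes with n-1 parent edges: connected iff acyclic; networkx checks both.
    g = nx.Graph()
    g.add_nodes_from(id_set)
    g.add_edges_from(
        (int(c), int(p)) for c, p in zip(ids[~root_mask], parents[~root_mask])
    )
    if len(ids) > 1 and not nx.is_tree(g):
        raise SkeletonStructureError(f"skeleton is not a single connected tree{where}")
    return int(ids[root_mask][0])


@dataclass
class SkeletonFrame:
    """One traced arbor at one time point.

    Parameters
    ----------
    nodes:
        Node table with columns ``node_id, structure_label, x, y, z,
        radius, parent_id`` in original file order.
    time:
        Acquisition time in minutes since series start.
    """

    nodes: pd.DataFrame
    time: float = 0.0
    soma_id: int = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = self.nodes[SWC_COLUMNS].reset_index(drop=True)
        self.soma_id = _validate_nodes(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def positions(self) -> np.ndarray:
        """(n, 3) array of node coordinates, µm."""
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)

    def edges(self) -> pd.DataFrame:
        """One row per parent->child edge.

        Columns: ``child_id, parent_id, structure_label`` (of the child),
        ``ax..az`` (parent position), ``bx..bz`` (child position),
        ``r_a, r_b`` (parent/child radii) and ``length``.
        """
        child = self.nodes[self.nodes["parent_id"] != -1]
        parent = self.nodes.set_index("node_id")
        pa = parent.loc[child["parent_id"], ["x", "y", "z", "radius"]].to_numpy(dtype=float)
        out = pd.DataFrame(
            {
                "child_id": child["node_id"].to_numpy(),
                "parent_id": child["parent_id"].to_numpy(),
                "structure_label": child["structure_label"].to_numpy(),
                "ax": pa[:, 0],
                "ay": pa[:, 1],
                "az": pa[:, 2],
                "bx": child["x"].to_numpy(dtype=float),
                "by": child["y"].to_numpy(dtype=float),
                "bz": child["z"].to_numpy(dtype=float),
                "r_a": pa[:, 3],
                "r_b": child["radius"].to_numpy(dtype=float),
            }
        )
        d = out[["bx", "by", "bz"]].to_numpy() - out[["ax", "ay", "az"]].to_numpy()
        out["length"] = np.linalg.norm(d, axis=1)
        return out

    def children_map(self) -> dict[int, list[int]]:
        cm: dict[int, list[int]] = {int(i): [] for i in self.nodes["node_id"]}
        for c, p in zip(self.nodes["node_id"], self.nodes["parent_id"]):
            if p != -1:
                cm[int(p)].append(int(c))
        return cm

    def leaf_ids(self) -> list[int]:
        """Node ids with no children, excluding the root."""
        cm = self.children_map()
        return [i for i, kids in cm.items() if not kids and i != self.soma_id]

    def node_index(self) -> pd.DataFrame:
        return self.nodes.set_index("node_id")


def read_swc(path: str | os.PathLike, time: float = 0.0) -> SkeletonFrame:
    """Read a 7-column SWC file into a validated :class:`SkeletonFrame`.

    ``#`` comment lines and blank lines are skipped; node order is
    preserved.  Malformed lines raise :class:`SWCParseError` naming the
    1-based line number; structural problems (dangling parents, multiple
    roots, cycles) raise :class:`SkeletonStructureError`.
    """
    path = Path(path)
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                rows.append(
                    (
                        int(parts[0]),
                        int(parts[1]),
                        float(parts[2]),
                        float(parts[3]),
                        float(parts[4]),
                        float(parts[5]),
                        int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise SWCParseError(f"{path}:{lineno}: {exc}") from None
    nodes = pd.DataFrame(rows, columns=SWC_COLUMNS)
    try:
        return SkeletonFrame(nodes, time=time)
    except SkeletonStructureError as exc:
        raise SkeletonStructureError(f"{path}: {exc}") from None


def write_swc(frame: SkeletonFrame, path: str | os.PathLike) -> None:
    """Write a frame as standard 7-column SWC.

    Values are written with round-trippable float formatting and no
    clamping (a zero radius is preserved verbatim).
    """
    with open(path, "w") as fh:
        for row in frame.nodes.itertuples(index=False):
            fh.write(
                f"{int(row.node_id)} {int(row.structure_label)} "
                f"{float(row.x)!r} {float(row.y)!r} {float(row.z)!r} "
                f"{float(row.radius)!r} {int(row.parent_id)}\n"
            )


@dataclass
class SkeletonSeries:
    """Ordered skeleton frames with acquisition times.

    ``frames[i]`` is ``None`` exactly where ``missing[i]`` is true.
    ``frame_kind`` is ``"branch"`` for short-cadence recordings (30 s
    frames over ~15 min) and ``"bulk"`` for long-cadence ones (20 min
    frames over many hours).
    """

    frames: list[SkeletonFrame | None]
    times: np.ndarray
    missing: np.ndarray
    frame_kind: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (len(self.frames) == len(self.times) == len(self.missing)):
            raise ManifestError("frames, times and missing flags must align")
        if len(self.times) == 0:
            raise ManifestError("empty series")
        if np.any(np.diff(self.times) <= 0):
            raise ManifestError("frame times must be strictly increasing")
        for fr, miss in zip(self.frames, self.missing):
            if miss != (fr is None):
                raise ManifestError("missing flag inconsistent with absent frame")
        if self.frame_kind not in ("branch", "bulk"):
            raise ManifestError(f"unknown frame_kind {self.frame_kind!r}")
        self._check_cadence()

    def _check_cadence(self) -> None:
        if len(self.times) < 3:
            return
        diffs = np.diff(self.times)
        nominal = float(np.median(diffs))
        gap_ok = self.missing[:-1] | self.missing[1:]
        bad = (np.abs(diffs - nominal) / nominal > 0.1) & ~gap_ok
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} frame interval(s) deviate >10% from the "
                f"nominal cadence of {nominal:g} min",
                stacklevel=3,
            )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[SkeletonFrame | None]:
        return iter(self.frames)

    @property
    def frame_interval(self) -> float:
        """Nominal (median) inter-frame interval, minutes."""
        if len(self.times) < 2:
            return float("nan")
        return float(np.median(np.diff(self.times)))

    def observed(self) -> list[tuple[int, SkeletonFrame]]:
        """(index, frame) pairs for non-missing frames."""
        return [(i, f) for i, f in enumerate(self.frames) if f is not None]


def infer_frame_kind(times: Sequence[float]) -> str:
    """Infer cadence class from the median interval (≤1 min -> branch)."""
    diffs = np.diff(np.asarray(times, dtype=float))
    if len(diffs) == 0:
        return "bulk"
    return "branch" if float(np.median(diffs)) <= 1.0 else "bulk"


def _manifest_rows(manifest: Path) -> list[dict]:
    if manifest.suffix.lower() in (".yaml", ".yml"):
        with open(manifest) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, list):
            raise ManifestError(f"{manifest}: YAML manifest must be a list of entries")
        rows = data
    else:
        df = pd.read_csv(manifest)
        if not {"path", "time_min"}.issubset(df.columns):
            raise ManifestError(f"{manifest}: manifest needs columns 'path' and 'time_min'")
        rows = df.to_dict("records")
    return rows


def read_series(
    manifest: str | os.PathLike, frame_kind: str | None = None
) -> SkeletonSeries:
    """Load a skeleton time series from a manifest.

    The manifest is a CSV (columns ``path, time_min`` and optional
    ``missing``) or a YAML list of mappings with the same keys.  SWC paths
    are resolved relative to the manifest's directory.  Times must be
    strictly increasing; a listed file that does not exist and is not
    flagged missing is an error.  ``frame_kind`` is inferred from the
    median interval unless given.
    """
    manifest = Path(manifest)
    rows = _manifest_rows(manifest)
    if not rows:
        raise ManifestError(f"{manifest}: empty manifest")
    frames: list[SkeletonFrame | None] = []
    times: list[float] = []
    missing: list[bool] = []
    for row in rows:
        t = float(row["time_min"])
        raw = row.get("missing", False)
        if isinstance(raw, str):
            miss = raw.strip().lower() in ("1", "true", "yes")
        elif isinstance(raw, float) and np.isnan(raw):
            miss = False
        else:
            miss = bool(raw)
        times.append(t)
        missing.append(miss)
        if miss:
            frames.append(None)
            continue
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = manifest.parent / p
        if not p.exists():
            raise ManifestError(f"{manifest}: frame file {p} absent and not flagged missing")
        frames.append(read_swc(p, time=t))
    kind = frame_kind or infer_frame_kind(times)
    return SkeletonSeries(frames=frames, times=np.asarray(times), missing=np.asarray(missing), frame_kind=kind)


def write_series(
    series: SkeletonSeries, out_dir: str | os.PathLike, prefix: str = "frame"
) -> Path:
    """Write all frames as SWC plus a ``manifest.csv``; return the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recs = []
    for i, (frame, t, miss) in enumerate(zip(series.frames, series.times, series.missing)):
        name = f"{prefix}_{i:04d}.swc"
        if not miss:
            write_swc(frame, out_dir / name)
        recs.append({"path": name if not miss else "", "time_min": float(t), "missing": int(miss)})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(recs).to_csv(manifest, index=False)
    return manifest
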