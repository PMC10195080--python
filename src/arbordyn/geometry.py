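"""Antennal-lobe coordinate frame, directional sectors and arbor metrics.

The antennal lobe is partitioned into four 90° sectors — dorsolateral
(DL), dorsomedial (DM), ventromedial (VM) and ventrolateral (VL) — in the
frontal plane spanned by two orthonormal axes anchored at the point where
the neuron's main process enters the neuropil.  Dendritic mass is
partitioned by projecting positions into that plane; VM is antiparallel to
DL and VL antiparallel to DM.

Single-frame metrics provided here: traced-cable length and frustum
volume, convex-hull ("exploring") volume, terminal-branch count,
volume-weighted mass centre and voxelised core-region overlap between two
arbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import ConvexHull, QhullError

from .errors import ArbordynError, DegeneratePointError
from .skeleton import AXON_LABEL, SkeletonFrame

#: Canonical direction order used throughout the package.
DIRECTIONS = ("DL", "DM", "VM", "VL")

_DEGENERATE_TOL = 1e-9


@dataclass(frozen=True)
class DirectionFrame:
    """Orthonormal sector frame anchored at the neuropil entry point.

    ``origin`` is the sector apex (µm); ``axis_dl`` and ``axis_dm`` are
    orthonormal unit vectors pointing dorsolaterally and dorsomedially;
    the anterior axis is their cross product.
    """

    origin: np.ndarray
    axis_dl: np.ndarray
    axis_dm: np.ndarray
    axis_anterior: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        dl = np.asarray(self.axis_dl, dtype=float)
        dm = np.asarray(self.axis_dm, dtype=float)
        for name, v in (("origin", origin), ("axis_dl", dl), ("axis_dm", dm)):
            if v.shape != (3,):
                raise ArbordynError(f"{name} must be a 3-vector")
        if abs(np.linalg.norm(dl) - 1.0) > _DEGENERATE_TOL or abs(np.linalg.norm(dm) - 1.0) > _DEGENERATE_TOL:
            raise ArbordynError("direction axes must be unit length (within 1e-9)")
        if abs(float(dl @ dm)) > _DEGENERATE_TOL:
            raise ArbordynError("axis_dl and axis_dm must be orthogonal (within 1e-9)")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axis_dl", dl)
        object.__setattr__(self, "axis_dm", dm)
        object.__setattr__(self, "axis_anterior", np.cross(dl, dm))

    @classmethod
    def from_vectors(cls, origin, axis_dl, axis_dm) -> "DirectionFrame":
        """Build a frame from approximate axes (Gram-Schmidt orthonormalised)."""
        dl = np.asarray(axis_dl, dtype=float)
        dl = dl / np.linalg.norm(dl)
        dm = np.asarray(axis_dm, dtype=float)
        dm = dm - (dm @ dl) * dl
        n = np.linalg.norm(dm)
        if n < _DEGENERATE_TOL:
            raise ArbordynError("axis_dm is parallel to axis_dl")
        return cls(np.asarray(origin, dtype=float), dl, dm / n)

    def sector_axis(self, direction: str) -> np.ndarray:
        """In-plane unit vector at the centre of a sector."""
        return {
            "DL": self.axis_dl,
            "DM": self.axis_dm,
            "VM": -self.axis_dl,
            "VL": -self.axis_dm,
        }[direction]

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """In-plane coordinates (u along DL, w along DM) of points."""
        v = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        return v @ self.axis_dl, v @ self.axis_dm

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "origin": [float(x) for x in self.origin],
                    "axis_DL": [float(x) for x in self.axis_dl],
                    "axis_DM": [float(x) for x in self.axis_dm],
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "DirectionFrame":
        with open(Path(path)) as fh:
            d = yaml.safe_load(fh)
        return cls.from_vectors(d["origin"], d["axis_DL"], d["axis_DM"])


def canonical_frame() -> DirectionFrame:
    """Frame with origin at (0,0,0), DL = +x, DM = +y, anterior = +z."""
    return DirectionFrame(np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))


def assign_sectors(points: np.ndarray, dframe: DirectionFrame) -> np.ndarray:
    """Vectorised sector labels for an (n, 3) array of points.

    The sector of a point is determined by the angle θ of its in-plane
    projection, measured from the DL axis towards the DM axis: DL for
    θ ∈ [315°, 45°), DM for [45°, 135°), VM for [135°, 225°), VL for
    [225°, 315°) — half-open boundaries.  Implemented with exact sign
    comparisons of the two projections so the 45° family of boundaries is
    decided without floating-point angle round-off.

    Raises :class:`DegeneratePointError` if any projection lies within
    1e-9 µm of the origin.
    """
    u, w = dframe.project(points)
    if np.any(np.hypot(u, w) < _DEGENERATE_TOL):
        raise DegeneratePointError(
            "point projects onto the sector origin; direction undefined"
        )
    labels = np.empty(len(u), dtype=object)
    dl = (u > 0) & (w < u) & (w >= -u)
    dm = (w > 0) & (u <= w) & (u > -w)
    vm = (u < 0) & (w <= -u) & (w > u)
    vl = (w < 0) & (u >= w) & (u < -w)
    labels[dl] = "DL"
    labels[dm] = "DM"
    labels[vm] = "VM"
    labels[vl] = "VL"
    return labels


def assign_sector(point, dframe: DirectionFrame) -> str:
    """Sector label of a single point (see :func:`assign_sectors`)."""
    return str(assign_sectors(np.asarray(point, dtype=float)[None, :], dframe)[0])


def dendrite_edge_table(frame: SkeletonFrame, exclude_axon: bool = True) -> pd.DataFrame:
    """Edge table restricted to dendritic edges.

    An edge belongs to its child node; with ``exclude_axon`` edges whose
    child carries the axon structure label are dropped, removing the main
    process from dendrite metrics.
    """
    edges = frame.edges()
    if exclude_axon:
        edges = edges[edges["structure_label"] != AXON_LABEL].reset_index(drop=True)
    return edges


class CableMetrics(NamedTuple):
    length: float  #: total path length, µm
    volume: float  #: total frustum volume, µm³


def frustum_volumes(edges: pd.DataFrame) -> np.ndarray:
    """Per-edge conical-frustum volume (π/3)·L·(r_a² + r_a r_b + r_b²)."""
    ra = edges["r_a"].to_numpy()
    rb = edges["r_b"].to_numpy()
    return (np.pi / 3.0) * edges["length"].to_numpy() * (ra * ra + ra * rb + rb * rb)


def cable_metrics(frame: SkeletonFrame, exclude_axon: bool = True) -> CableMetrics:
    """Total traced path length (µm) and frustum volume (µm³)."""
    edges = dendrite_edge_table(frame, exclude_axon)
    return CableMetrics(
        length=float(edges["length"].sum()),
        volume=float(frustum_volumes(edges).sum()),
    )


def exploring_volume(frame: SkeletonFrame, exclude_axon: bool = True) -> float:
    """Convex-hull volume (µm³) of dendritic node positions.

    Returns 0 with a warning for fewer than four points or a degenerate
    (coplanar/collinear) point set.
    """
    nodes = frame.nodes
    if exclude_axon:
        nodes = nodes[nodes["structure_label"] != AXON_LABEL]
    pts = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    if len(pts) < 4:
        warnings.warn("fewer than 4 points: exploring volume undefined, returning 0")
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        warnings.warn("degenerate point set: exploring volume undefined, returning 0")
        return 0.0


def count_terminal_branches(frame: SkeletonFrame, exclude_axon: bool = True) -> int:
    """Number of leaf nodes (degree 1, non-root) of the skeleton tree."""
    leaves = frame.leaf_ids()
    if exclude_axon:
        labels = frame.node_index()["structure_label"]
        leaves = [i for i in leaves if labels.loc[i] != AXON_LABEL]
    return len(leaves)


def mass_center(
    frame: SkeletonFrame,
    subset: Iterable[int] | Callable[[pd.DataFrame], np.ndarray] | None = None,
    exclude_axon: bool = True,
    weighting: str = "volume",
) -> np.ndarray:
    """Frustum-volume-weighted centroid of edge midpoints, µm.

    ``subset`` restricts to edges whose child node passes the filter (a
    node-id collection or a boolean predicate on the node table).  With
    all radii equal, volume weighting reduces to length weighting; if the
    total frustum volume is zero (untraced radii), lengths are used.
    """
    edges = dendrite_edge_table(frame, exclude_axon)
    if subset is not None:
        if callable(subset):
            keep_ids = set(
                int(i)
                for i in frame.nodes.loc[np.asarray(subset(frame.nodes), dtype=bool), "node_id"]
            )
        else:
            keep_ids = set(int(i) for i in subset)
        edges = edges[edges["child_id"].isin(keep_ids)]
    if len(edges) == 0:
        raise ArbordynError("mass_center: empty edge subset")
    mids = 0.5 * (
        edges[["ax", "ay", "az"]].to_numpy() + edges[["bx", "by", "bz"]].to_numpy()
    )
    if weighting == "volume":
        w = frustum_volumes(edges)
        if w.sum() <= 0:
            w = edges["length"].to_numpy()
    elif weighting == "length":
        w = edges["length"].to_numpy()
    else:
        raise ArbordynError(f"unknown weighting {weighting!r}")
    if w.sum() <= 0:
        raise ArbordynError("mass_center: zero total weight")
    return (mids * w[:, None]).sum(axis=0) / w.sum()


def _voxel_density(frame: SkeletonFrame, voxel: float, exclude_axon: bool) -> dict[tuple, float]:
    """Deposit cable length into voxels; edges are subdivided below voxel/2."""
    edges = dendrite_edge_table(frame, exclude_axon)
    density: dict[tuple, float] = {}
    a = edges[["ax", "ay", "az"]].to_numpy()
    b = edges[["bx", "by", "bz"]].to_numpy()
    lengths = edges["length"].to_numpy()
    for i in range(len(edges)):
        L = lengths[i]
        if L <= 0:
            continue
        n_pieces = max(1, int(np.ceil(L / (voxel / 2.0))))
        frac = (np.arange(n_pieces) + 0.5) / n_pieces
        mids = a[i] + frac[:, None] * (b[i] - a[i])
        keys = np.floor(mids / voxel).astype(int)
        piece_len = L / n_pieces
        for k in map(tuple, keys):
            density[k] = density.get(k, 0.0) + piece_len
    return density


def _core_voxels(density: dict[tuple, float], quantile: float) -> set[tuple]:
    """Minimal set of highest-density voxels holding ≥ quantile of total length."""
    total = sum(density.values())
    if total <= 0:
        raise ArbordynError("core region undefined for an arbor with zero cable")
    items = sorted(density.items(), key=lambda kv: (-kv[1], kv[0]))
    core: set[tuple] = set()
    acc = 0.0
    for key, val in items:
        core.add(key)
        acc += val
        if acc >= quantile * total - 1e-12:
            break
    return core


def core_overlap(
    frame_a: SkeletonFrame,
    frame_b: SkeletonFrame,
    voxel: float = 1.0,
    density_quantile: float = 0.5,
    exclude_axon: bool = True,
) -> float:
    """Overlap of the two arbors' core targeting regions, in [0, 1].

    Cable length is rasterised into a shared voxel grid; each arbor's core
    is the smallest set of densest voxels holding ``density_quantile`` of
    its cable length; the overlap is |core_a ∩ core_b| normalised by the
    smaller core.
    """
    if voxel <= 0 or not (0 < density_quantile < 1):
        raise ArbordynError("voxel must be positive and 0 < density_quantile < 1")
    core_a = _core_voxels(_voxel_density(frame_a, voxel, exclude_axon), density_quantile)
    core_b = _core_voxels(_voxel_density(frame_b, voxel, exclude_axon), density_quantile)
    return len(core_a & core_b) / min(len(core_a), len(core_b))
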