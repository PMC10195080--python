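"""Minimal raster/line plots mirroring the standard event-raster style."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .bulk import BulkEvent, DirectionProfile, event_matrix
from .geometry import DIRECTIONS


def plot_event_raster(events: list[BulkEvent], n_frames: int, ax=None):
    """Direction × interval raster: green extension, magenta retraction."""
    mat = event_matrix(events, n_frames).to_numpy(dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2))
    from matplotlib.colors import ListedColormap

    ax.imshow(
        mat,
        aspect="auto",
        cmap=ListedColormap(["magenta", "lightgrey", "green"]),
        vmin=-1,
        vmax=1,
        interpolation="nearest",
    )
    ax.set_yticks(range(len(DIRECTIONS)), DIRECTIONS)
    ax.set_xlabel("interval")
    return ax


def plot_direction_fractions(profile: DirectionProfile, ax=None):
    """Per-direction volume-fraction traces over time."""
    if ax is None:
        _, ax = plt.subplots()
    frac = profile.fraction_matrix()
    times = profile.frames.set_index("frame").loc[frac.index, "time_min"]
    for d in DIRECTIONS:
        ax.plot(np.asarray(times), frac[d].to_numpy(), label=d)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("fraction of dendritic volume")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
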