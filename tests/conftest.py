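"""Shared helpers: programmatic skeleton builders used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from arbordyn.skeleton import SWC_COLUMNS, SkeletonFrame


def frame_from_rows(rows, time=0.0) -> SkeletonFrame:
    """Build a frame from (id, label, x, y, z, radius, parent) tuples."""
    return SkeletonFrame(pd.DataFrame(rows, columns=SWC_COLUMNS), time=time)


def random_tree_frame(rng: np.random.Generator, n_nodes: int = 20,
                      scale: float = 10.0, label: int = 3) -> SkeletonFrame:
    """Random rooted tree: node i+1 attaches to a uniformly chosen earlier node."""
    rows = [(1, 1, 0.0, 0.0, 0.0, 1.0, -1)]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        x, y, z = rng.uniform(-scale, scale, size=3)
        rows.append((i, label, float(x), float(y), float(z), float(rng.uniform(0.1, 1.0)), parent))
    return frame_from_rows(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
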