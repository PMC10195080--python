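"""Shared analysis parameters.

The two thresholds that carry scientific meaning are ``bulk_threshold``
(bulk extension/retraction events are direction-wise extent changes of
*more than* 2 µm between consecutive frames) and ``speed_threshold``
(terminal-branch extension/retraction requires the tip speed to *exceed*
0.5 µm/min); both comparisons are strict.  The remaining fields are
pipeline plumbing: occupancy cut-off for "dendrites found in a
direction", phase-smoothing window, tip-matching gate for tracking, and
the voxel/quantile pair for core-overlap maps.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ArbordynError


@dataclass(frozen=True)
class AnalysisParams:
    bulk_threshold: float = 2.0  #: µm, strict, per consecutive-frame pair
    speed_threshold: float = 0.5  #: µm/min, strict
    occupancy_threshold: float = 0.05  #: fraction of frame volume
    phase_smoothing: int = 3  #: frames a count-class must persist
    match_gate: float = 3.0  #: µm, max tip displacement accepted by the tracker
    voxel: float = 1.0  #: µm, core-overlap raster size
    density_quantile: float = 0.5  #: cable-length quantile defining the core

    def __post_init__(self) -> None:
        for name in ("bulk_threshold", "speed_threshold", "occupancy_threshold",
                     "phase_smoothing", "match_gate", "voxel", "density_quantile"):
            if getattr(self, name) <= 0:
                raise ArbordynError(f"{name} must be strictly positive")
        if self.occupancy_threshold >= 0.25:
            raise ArbordynError(
                "occupancy_threshold must be < 0.25 (four directions must be "
                "able to co-occur)"
            )
        if not (0 < self.density_quantile < 1):
            raise ArbordynError("density_quantile must lie in (0, 1)")
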