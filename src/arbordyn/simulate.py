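"""Synthetic skeleton time series with full ground truth.

The generator embodies the selective-branch-stabilization picture of
dendrite targeting: terminal branches nucleate per direction as
independent Poisson processes, live exponentially distributed lifetimes
(stabilization = longer mean lifetime), and while alive their path
length follows a two-state extend/retract process with tip speeds around
1.5 µm/min.  Frames are emitted as valid SWC trees hanging off a static
main process entering the neuropil, at either branch cadence (30 s over
15 min) or bulk cadence (20 min over ~21 h).

Bulk-cadence scenarios script per-direction radial extents directly: the
``stepwise_targeting`` preset reduces the occupied directions 4 → 2 → 1
(the surviving pair always contains DL and never VM, the final direction
is DL), inserting extension/retraction jumps of known magnitude whose
log is the ground-truth bulk-event record.

All randomness flows from one seeded generator: identical seeds give
bit-identical SWC output and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ArbordynError
from .geometry import DIRECTIONS, DirectionFrame, canonical_frame
from .skeleton import SkeletonFrame, SkeletonSeries, SWC_COLUMNS

PRESETS = ("uniform", "vm_destabilized", "stepwise_targeting", "static")

_SECTOR_CENTER_DEG = {"DL": 0.0, "DM": 90.0, "VM": 180.0, "VL": 270.0}


@dataclass(frozen=True)
class StepwiseScript:
    """Schedule of the scripted bulk-cadence targeting scenario (frames)."""

    base_extent: float = 13.0  #: µm, per-direction starting extent (±1 µm seed noise)
    fluctuation: float = 0.7  #: µm, max sub-threshold per-frame wobble
    ramp_step: float = 3.0  #: µm, per-frame retraction while a direction is eliminated
    jump_lo: float = 2.5  #: µm, min inserted event magnitude
    jump_hi: float = 4.0  #: µm, max inserted event magnitude
    n_initial_jumps: int = 3  #: inserted events per direction in the initial phase
    n_dl_transitional_jumps: int = 2  #: extra DL events in the transitional phase
    vm_drop_frame: int = 14  #: VM elimination starts here (VM never survives)
    second_drop_frame: int = 17  #: the non-partner of {DM, VL} is eliminated
    partner_drop_frame: int = 30  #: the partner is eliminated, leaving DL alone


@dataclass
class SynthConfig:
    """Parameters of the synthetic arbor-dynamics generator.

    Rates are per minute, lifetimes in minutes, lengths in µm.  The tip
    speed magnitude defaults to the ~1.5 µm/min regime of developing
    projection-neuron terminal branches; the extend/retract state flips
    with probability ``flip_prob_per_min`` per minute and an interval is
    spent stationary with probability ``dwell_prob``.
    """

    seed: int = 0
    kind: str = "branch"  #: "branch" (30 s cadence) or "bulk" (20 min cadence)
    duration: float = 15.0
    frame_interval: float = 0.5
    nucleation_rate: dict[str, float] = field(
        default_factory=lambda: {d: 0.5 for d in DIRECTIONS}
    )
    mean_lifetime: dict[str, float] = field(
        default_factory=lambda: {d: 5.0 for d in DIRECTIONS}
    )
    speed_mean: float = 1.5
    speed_sd: float = 0.4
    speed_clip: tuple[float, float] = (0.2, 2.8)
    flip_prob_per_min: float = 0.3
    dwell_prob: float = 0.1
    tip_jitter_sd: float = 0.1
    initial_length: tuple[float, float] = (4.0, 10.0)
    standoff_range: tuple[float, float] = (3.0, 16.0)  #: µm, attachment radius on the parent shaft
    initialize_population: bool = True
    initial_count: dict[str, int] | None = None  #: overrides Poisson(λτ) seeding
    anterior_tilt_deg: float = 50.0
    neuropil_radius: float = 25.0
    main_process_length: float = 12.0
    dframe: DirectionFrame = field(default_factory=canonical_frame)
    bulk_drift: dict[str, float] | None = None  #: µm/frame, plain-drift bulk mode
    bulk_script: StepwiseScript | None = None
    max_concurrent: int = 100_000
    preset_name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("branch", "bulk"):
            raise ArbordynError(f"unknown series kind {self.kind!r}")
        if self.duration <= 0 or self.frame_interval <= 0:
            raise ArbordynError("duration and frame_interval must be positive")
        for d in DIRECTIONS:
            if self.nucleation_rate.get(d, 0.0) < 0:
                raise ArbordynError("nucleation rates must be ≥ 0")
            if self.mean_lifetime.get(d, 1.0) <= 0:
                raise ArbordynError("mean lifetimes must be > 0")
        if self.speed_mean <= 0:
            raise ArbordynError("speed_mean must be > 0")


@dataclass
class GroundTruth:
    """Everything the generator knows about what it emitted.

    ``branches``: one row per simulated branch (including branches never
    visible at any frame, category ``unobserved``) with birth/death
    times, direction, the lifetime category under the observation window
    and the largest inter-frame tip displacement.  ``tips``: one row per
    (branch, present frame) with the realized tip position and path
    length; ``speed_to_next`` is the realized per-interval speed to the
    next present frame.  ``occupancy`` and ``bulk_events``: per-frame
    occupied-direction sets and the inserted bulk-event log (bulk
    scenarios only).
    """

    branches: pd.DataFrame
    tips: pd.DataFrame
    occupancy: pd.DataFrame
    bulk_events: pd.DataFrame

    def to_csv(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.branches.to_csv(out / "truth_branches.csv", index=False)
        self.tips.to_csv(out / "truth_tips.csv", index=False)
        self.occupancy.to_csv(out / "truth_occupancy.csv", index=False)
        self.bulk_events.to_csv(out / "truth_bulk_events.csv", index=False)


_BRANCH_COLS = [
    "branch_id", "direction", "birth_min", "death_min", "first_frame",
    "last_frame", "category", "max_tip_step",
]
_TIP_COLS = ["branch_id", "frame", "time_min", "x", "y", "z", "length", "speed_to_next"]
_OCC_COLS = ["frame", "time_min", "n_occupied", "occupied"]
_EVENT_COLS = ["frame_from", "frame_to", "direction", "kind", "magnitude"]


def _categorize(first: int, last: int, n_frames: int) -> str:
    if first == 0 and last == n_frames - 1:
        return "stable"
    if first > 0 and last < n_frames - 1:
        return "transient"
    if first > 0:
        return "emerging"
    return "retracting"


def _main_process(dframe: DirectionFrame, length: float) -> list[tuple]:
    """Static soma + main process ending at the neuropil entry (the frame origin)."""
    rows = []
    n = 4
    for i in range(n):
        s = length * (1 - i / (n - 1))
        pos = dframe.origin - s * dframe.axis_anterior
        label = 1 if i == 0 else 2
        radius = 1.0 if i == 0 else 0.5
        rows.append((i + 1, label, pos[0], pos[1], pos[2], radius, i if i > 0 else -1))
    return rows


def _branch_axis(rng: np.random.Generator, direction: str, cfg: SynthConfig) -> np.ndarray:
    theta = math.radians(
        _SECTOR_CENTER_DEG[direction] + rng.uniform(-45.0, 45.0)
    )
    phi = math.radians(rng.uniform(-cfg.anterior_tilt_deg, cfg.anterior_tilt_deg))
    df = cfg.dframe
    inplane = math.cos(theta) * df.axis_dl + math.sin(theta) * df.axis_dm
    return math.cos(phi) * inplane + math.sin(phi) * df.axis_anterior


def _simulate_branch(cfg: SynthConfig) -> tuple[SkeletonSeries, GroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration / cfg.frame_interval)) + 1
    times = np.arange(n_frames) * cfg.frame_interval

    # --- draw branches --------------------------------------------------
    # Each branch hangs off the static main process via a radial "stalk"
    # of length R0 (its attachment point on the parent shaft), so tips are
    # spread through the neuropil wedge the way real terminal branches are
    # rather than all emanating from one point.
    specs = []  # (direction, birth, L0, state, death_exp, axis, standoff)
    for direction in DIRECTIONS:
        lam = cfg.nucleation_rate.get(direction, 0.0)
        tau = cfg.mean_lifetime.get(direction, 5.0)
        if cfg.initial_count is not None:
            n0 = int(cfg.initial_count.get(direction, 0))
        elif cfg.initialize_population:
            n0 = int(rng.poisson(lam * tau))
        else:
            n0 = 0
        for _ in range(n0):
            L0 = rng.uniform(*cfg.initial_length)
            state = 1 if rng.random() < 0.5 else -1
            death = float(rng.exponential(tau))
            specs.append(
                (direction, 0.0, L0, state, death,
                 _branch_axis(rng, direction, cfg), rng.uniform(*cfg.standoff_range))
            )
        n_new = int(rng.poisson(lam * cfg.duration))
        births = np.sort(rng.uniform(0.0, cfg.duration, size=n_new))
        for tb in births:
            death = float(tb + rng.exponential(tau))
            specs.append(
                (direction, float(tb), 0.0, 1, death,
                 _branch_axis(rng, direction, cfg), rng.uniform(*cfg.standoff_range))
            )
    if len(specs) > cfg.max_concurrent:
        raise ArbordynError(
            f"{len(specs)} branches exceed the max_concurrent guard of {cfg.max_concurrent}"
        )
    specs.sort(key=lambda s: (s[1], DIRECTIONS.index(s[0])))

    # --- evolve path lengths on the frame grid --------------------------
    branch_rows = []
    tip_rows = []
    per_frame_branches: list[list[tuple[int, np.ndarray, float, float, np.ndarray]]] = [
        [] for _ in range(n_frames)
    ]  # frame -> (branch_id, axis, standoff, length, tip_pos)
    lo_clip, hi_clip = cfg.speed_clip
    for bid, (direction, tb, L0, state, death, axis, r0) in enumerate(specs):
        lengths: dict[int, float] = {}
        if tb <= times[0] + 1e-12 and L0 > 1e-6:
            lengths[0] = L0
        t_cur, L = tb, L0
        dead_at = death
        newborn = L0 == 0.0
        # piecewise-constant speed over [t_cur, next grid time]
        for k_next in range(int(np.searchsorted(times, tb, side="right")), n_frames):
            t_next = times[k_next]
            if dead_at < t_next:  # exponential death mid-interval
                break
            if (not newborn) and rng.random() < cfg.dwell_prob:
                v = 0.0
            else:
                mag = float(np.clip(rng.normal(cfg.speed_mean, cfg.speed_sd), lo_clip, hi_clip))
                v = mag * (1 if newborn else state)
            newborn = False
            dt = t_next - t_cur
            L_new = L + v * dt
            if L_new <= 1e-6:  # retracted to nothing: elimination
                dead_at = t_cur + (L / -v if v < 0 else 0.0)
                break
            L = L_new
            t_cur = t_next
            lengths[k_next] = L
            if rng.random() < 1.0 - (1.0 - cfg.flip_prob_per_min) ** dt:
                state = -state
        present = sorted(lengths)
        if not present:
            branch_rows.append(
                (bid, direction, tb,
                 dead_at if dead_at <= times[-1] else np.nan,
                 -1, -1, "unobserved", np.nan)
            )
            continue
        first, last = present[0], present[-1]
        tip_positions = {}
        for fk in present:
            tip = cfg.dframe.origin + (r0 + lengths[fk]) * axis
            if cfg.tip_jitter_sd > 0:
                tip = tip + rng.normal(0.0, cfg.tip_jitter_sd, size=3)
            tip_positions[fk] = tip
            per_frame_branches[fk].append((bid, axis, r0, lengths[fk], tip))
        steps = [
            float(np.linalg.norm(tip_positions[a] - tip_positions[b]))
            for a, b in zip(present[1:], present[:-1])
        ]
        death_rec = dead_at if dead_at <= times[-1] else np.nan
        branch_rows.append(
            (
                bid, direction, tb, death_rec, first, last,
                _categorize(first, last, n_frames),
                max(steps) if steps else 0.0,
            )
        )
        # realized per-observation records (path length exactly as the
        # pipeline walks it: entry -> stalk -> midpoint -> tip)
        for fk in present:
            mid = cfg.dframe.origin + (r0 + 0.5 * lengths[fk]) * axis
            plen = float(
                r0
                + 0.5 * lengths[fk]
                + np.linalg.norm(tip_positions[fk] - mid)
            )
            tip_rows.append(
                [bid, fk, times[fk], *tip_positions[fk], plen, np.nan]
            )
    tips = pd.DataFrame(tip_rows, columns=_TIP_COLS)
    if len(tips):
        tips = tips.sort_values(["branch_id", "frame"]).reset_index(drop=True)
        dt_next = tips.groupby("branch_id")["time_min"].diff(-1)
        dl_next = tips.groupby("branch_id")["length"].diff(-1)
        contiguous = tips.groupby("branch_id")["frame"].diff(-1) == -1
        tips["speed_to_next"] = np.where(contiguous, dl_next / dt_next, np.nan)

    # --- emit SWC frames -------------------------------------------------
    frames = []
    base_rows = _main_process(cfg.dframe, cfg.main_process_length)
    entry_id = len(base_rows)  # last main-process node sits at the origin
    for fk in range(n_frames):
        rows = list(base_rows)
        nid = entry_id
        for bid, axis, r0, L, tip in sorted(per_frame_branches[fk], key=lambda x: x[0]):
            stalk = cfg.dframe.origin + r0 * axis
            mid = cfg.dframe.origin + (r0 + 0.5 * L) * axis
            rows.append((nid + 1, 3, stalk[0], stalk[1], stalk[2], 0.3, entry_id))
            rows.append((nid + 2, 3, mid[0], mid[1], mid[2], 0.3, nid + 1))
            rows.append((nid + 3, 3, tip[0], tip[1], tip[2], 0.3, nid + 2))
            nid += 3
        frames.append(
            SkeletonFrame(pd.DataFrame(rows, columns=SWC_COLUMNS), time=float(times[fk]))
        )
    series = SkeletonSeries(
        frames=frames,
        times=times,
        missing=np.zeros(n_frames, dtype=bool),
        frame_kind="branch" if cfg.frame_interval <= 1.0 else "bulk",
    )
    truth = GroundTruth(
        branches=pd.DataFrame(branch_rows, columns=_BRANCH_COLS),
        tips=tips if len(tips) else pd.DataFrame(columns=_TIP_COLS),
        occupancy=pd.DataFrame(columns=_OCC_COLS),
        bulk_events=pd.DataFrame(columns=_EVENT_COLS),
    )
    return series, truth


def _scripted_extents(cfg: SynthConfig, rng: np.random.Generator, n_frames: int):
    """Scripted per-direction extents, the inserted event log, and the partner."""
    sc = cfg.bulk_script or StepwiseScript()
    partner = str(rng.choice(["DM", "VL"]))
    non_partner = "VL" if partner == "DM" else "DM"
    drop_at = {"VM": sc.vm_drop_frame, non_partner: sc.second_drop_frame,
               partner: sc.partner_drop_frame, "DL": None}
    extents = np.zeros((n_frames, 4))
    events = []
    for d_i, d in enumerate(DIRECTIONS):
        # one guaranteed early event (inside the first six windows) plus
        # further events scattered over the initial phase
        jump_frames = {int(rng.integers(2, 6))}
        jump_frames |= set(
            int(j)
            for j in rng.choice(
                np.arange(2, min(13, n_frames - 1)),
                size=max(sc.n_initial_jumps - 1, 0),
                replace=False,
            )
        )
        if d == "DL" and n_frames > 30:
            jump_frames |= set(
                rng.choice(np.arange(22, 29), size=sc.n_dl_transitional_jumps, replace=False)
            )
        e = sc.base_extent + rng.uniform(-1.0, 1.0)
        extents[0, d_i] = e
        for k in range(1, n_frames):
            drop = drop_at[d]
            if e <= 0:
                delta = 0.0
            elif drop is not None and k >= drop:
                delta = -min(sc.ramp_step, e)
            elif k in jump_frames:
                mag = rng.uniform(sc.jump_lo, sc.jump_hi)
                sign = 1 if rng.random() < 0.5 else -1
                if e + sign * mag < 4.0 or e + sign * mag > 2.0 * sc.base_extent:
                    sign = -sign
                delta = sign * mag
            else:
                delta = rng.uniform(-sc.fluctuation, sc.fluctuation)
                if e + delta < 3.0:
                    delta = abs(delta)
            e = max(e + delta, 0.0)
            extents[k, d_i] = e
            if abs(delta) > 2.0:
                events.append(
                    (k - 1, k, d, "extension" if delta > 0 else "retraction", abs(delta))
                )
    events.sort(key=lambda ev: (ev[0], DIRECTIONS.index(ev[2])))
    return extents, events, partner


def _simulate_bulk(cfg: SynthConfig) -> tuple[SkeletonSeries, GroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration / cfg.frame_interval)) + 1
    times = np.arange(n_frames) * cfg.frame_interval
    if cfg.bulk_script is not None or cfg.bulk_drift is None:
        extents, events, _ = _scripted_extents(cfg, rng, n_frames)
    else:
        base = 12.0
        extents = np.zeros((n_frames, 4))
        events = []
        for d_i, d in enumerate(DIRECTIONS):
            drift = cfg.bulk_drift.get(d, 0.0)
            e = base
            extents[0, d_i] = e
            for k in range(1, n_frames):
                new = max(e + drift, 0.0)
                if abs(new - e) > 2.0:
                    events.append(
                        (k - 1, k, d, "extension" if new > e else "retraction", abs(new - e))
                    )
                e = new
                extents[k, d_i] = e

    frames = []
    base_rows = _main_process(cfg.dframe, cfg.main_process_length)
    entry_id = len(base_rows)
    occ_rows = []
    for k in range(n_frames):
        rows = list(base_rows)
        nid = entry_id
        for d_i, d in enumerate(DIRECTIONS):
            e = extents[k, d_i]
            if e <= 1e-9:
                continue
            axis = cfg.dframe.sector_axis(d)
            prev = entry_id
            for f in (1.0 / 3.0, 2.0 / 3.0, 1.0):
                pos = cfg.dframe.origin + f * e * axis
                rows.append((nid + 1, 3, pos[0], pos[1], pos[2], 0.4, prev))
                prev = nid + 1
                nid += 1
        frames.append(
            SkeletonFrame(pd.DataFrame(rows, columns=SWC_COLUMNS), time=float(times[k]))
        )
        total = extents[k].sum()
        occ = frozenset(
            d for d_i, d in enumerate(DIRECTIONS)
            if total > 0 and extents[k, d_i] / total >= 0.05
        )
        occ_rows.append((k, float(times[k]), len(occ), "|".join(sorted(occ))))
    series = SkeletonSeries(
        frames=frames,
        times=times,
        missing=np.zeros(n_frames, dtype=bool),
        frame_kind="bulk",
    )
    truth = GroundTruth(
        branches=pd.DataFrame(columns=_BRANCH_COLS),
        tips=pd.DataFrame(columns=_TIP_COLS),
        occupancy=pd.DataFrame(occ_rows, columns=_OCC_COLS),
        bulk_events=pd.DataFrame(events, columns=_EVENT_COLS),
    )
    return series, truth


def simulate(config: SynthConfig) -> tuple[SkeletonSeries, GroundTruth]:
    """Run the generator; identical configs (and seeds) give identical output."""
    if config.kind == "branch":
        return _simulate_branch(config)
    return _simulate_bulk(config)


def preset(name: str, seed: int = 0) -> SynthConfig:
    """Named study conditions.

    * ``uniform`` — no directional bias: λ = 0.5/min and τ = 5 min in
      every direction, 30 s cadence over 15 min.  Null condition.
    * ``vm_destabilized`` — selective destabilization of the
      ventromedial sector: τ_VM is a quarter of the other directions'
      40 min, so VM branches rarely survive the window while the other
      sectors keep of order ten stable branches each.
    * ``stepwise_targeting`` — scripted bulk-cadence scenario (20 min
      frames, 21 h) whose occupied directions drop 4 → 2 → 1 with DL
      always retained and VM eliminated first.
    * ``static`` — frozen arbor: three permanent, motionless branches
      per direction; the end-to-end null (no events, all stationary).
    """
    if name == "uniform":
        return SynthConfig(seed=seed, preset_name=name)
    if name == "vm_destabilized":
        return SynthConfig(
            seed=seed,
            mean_lifetime={"DL": 40.0, "DM": 40.0, "VM": 10.0, "VL": 40.0},
            preset_name=name,
        )
    if name == "stepwise_targeting":
        return SynthConfig(
            seed=seed,
            kind="bulk",
            duration=1260.0,
            frame_interval=20.0,
            bulk_script=StepwiseScript(),
            preset_name=name,
        )
    if name == "static":
        return SynthConfig(
            seed=seed,
            nucleation_rate={d: 0.0 for d in DIRECTIONS},
            mean_lifetime={d: 1e12 for d in DIRECTIONS},
            initial_count={d: 3 for d in DIRECTIONS},
            dwell_prob=1.0,
            tip_jitter_sd=0.0,
            preset_name=name,
        )
    raise ArbordynError(f"unknown preset {name!r}; choose from {PRESETS}")
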