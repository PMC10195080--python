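# Methods

This note documents the quantitative conventions of `arbordyn`: what each
pipeline stage computes, the defaults and why, what the synthetic
generator does and does not emulate, and the numerical corner cases.

## Coordinate frame and directional sectors

All directional quantities live in a frontal plane spanned by two
orthonormal axes (dorsolateral `DL` and dorsomedial `DM`) anchored at an
*origin*, by default the point where the neuron's main process enters the
neuropil. The apex location is user-configurable: published descriptions
of directional dendrite quantification do not fix it, and soma-anchored
frames are equally expressible by supplying a different origin.

A point's sector is determined by the angle θ of its in-plane projection
measured from `DL` toward `DM`: `DL` for θ ∈ [315°, 45°), `DM` for
[45°, 135°), `VM` for [135°, 225°), `VL` for [225°, 315°). Intervals are
half-open, so every non-degenerate point has exactly one label; the
implementation decides boundaries by exact sign comparisons of the two
projections (`u = v·DL`, `w = v·DM`), which is algebraically identical to
the angular definition but free of atan2 round-off exactly on the 45°
boundary family. Points projecting within 1 nm of the origin are
*degenerate* and raise an error; callers exclude the soma upstream.

Sectors are defined on the 2-D projection, not as 3-D solid angles: for
antennal-lobe dendrites the frontal projection carries the targeting
logic, and a projection-based rule is rotation-consistent and cheap to
reason about. A dendritic segment is assigned the sector of its midpoint;
segments are not split at boundaries. The resulting discretization error
shrinks with tracing density — densify tracings if sub-segment accuracy
matters.

## Single-frame metrics

- **Cable metrics** — per edge, length is the Euclidean distance between
  nodes and volume is the conical frustum
  `V = (π/3)·L·(r_a² + r_a·r_b + r_b²)`; totals are edge sums. Frustum
  volume is the standard volume proxy for SWC tracings; wherever volume
  weighting is used, plain length weighting is available as an
  alternative (they coincide up to a constant when radii are uniform).
- **Exploring volume** — convex-hull volume of dendritic node positions;
  degenerate point sets (<4 points, coplanar) give 0 with a warning
  rather than an exception, since early frames of a recording genuinely
  can be degenerate.
- **Mass centre** — frustum-volume-weighted centroid of edge midpoints,
  falling back to length weights when all radii are zero.
- **Core overlap** — cable length is rasterised into a shared voxel grid
  (edges subdivided below half a voxel, default voxel 1 µm); an arbor's
  *core* is the smallest set of densest voxels holding a given quantile
  (default 0.5) of its cable; overlap is `|A∩B| / min(|A|,|B|)`.
- The **axon / main process** (structure label 2) is excluded from all
  dendritic metrics by default.

## Bulk dynamics (20-min cadence)

Per direction and frame the profile records cable weight, weight
fraction, and *extent* — the largest in-plane radial distance of any
dendritic node in that sector from the origin. Extension/retraction
events are defined on extent: `Δ = extent(i+1) − extent(i)` with an event
iff `|Δ|` strictly exceeds the 2 µm threshold between *consecutive*
frames. The threshold is printed in µm, so the quantity it applies to
must be a length; maximal radial extent is the length that directly
captures "dendrites extending/retracting in a direction". Missing frames
break consecutiveness — no event spans a gap. Initial/final summaries
count events whose interval lies wholly inside the first/last six frames
(2 h at 20-min cadence), requiring at least twelve frames.

Event counts are monotonically non-increasing in the threshold, and
time-reversing a series exactly swaps extension and retraction — both are
enforced by tests.

## Branch dynamics (30-s cadence)

A **terminal branch** is the path from a leaf back to the nearest node of
degree ≥3 or to the main process (structure-label change), whichever
comes first; its path length sums edge lengths along that path. Branches
deeper in the arbor are out of scope — at this density only terminal
branches are resolvable in the source imaging modality.

**Tracking** is greedy gated nearest-tip matching: candidate pairs
between consecutive frames are taken in order of increasing tip distance
(ties broken by node ids), accepted while the distance is ≤ the 3 µm
match gate; unmatched old tips close their track, unmatched new tips open
one, and a track never resurrects after an absence. The gate is twice the
distance a tip travelling at the typical ~1.5 µm/min covers in one 30-s
frame, so correct continuations are comfortably inside it while distinct
branches (several µm apart in realistic arbors) stay outside. Known
limitation: branches that cross within the gate can swap identities;
multi-hypothesis tracking is deliberately out of scope.

**Lifetime categories** follow from the first/last present frames of a
track over an n-frame window: stable (0 … n−1), transient (>0 … <n−1),
emerging (>0 … n−1), retracting (0 … <n−1). The four cases are exhaustive
and mutually exclusive over all contiguous presence runs (verified
exhaustively for window lengths 2–8).

**Speeds** are per-interval path-length differences per minute, positive
for extension — growth of the branch, not displacement of the tip, which
is insensitive to a branch pivoting in place. An interval is *extending*
or *retracting* only when |speed| strictly exceeds 0.5 µm/min; otherwise
*stationary*. A branch's direction is the modal sector of its tip over
its present frames (first-frame sector is available as an alternative);
per-direction summaries report the percentage of the cell's stable
branches in each direction, their mean absolute speed (absent, not zero,
for directions with no stable branch), and mean time fractions spent in
each motion state per category.

## Phase segmentation

Per frame, the occupied-direction count maps to a class: initial (≥3),
transitional (exactly 2), final (≤1). A direction is occupied when it
holds ≥5% of the frame's dendritic weight; the cut-off separates genuine
occupancy from tracing noise and is exposed in `AnalysisParams`
(sensitivity analysis recommended — the underlying biology offers no
sharp definition of "found in a direction"). Runs shorter than the
3-frame smoothing window (1 h at 20-min cadence — single-frame flicker
should not split hour-scale phases) are absorbed into the preceding run;
runs that would move backwards in the admissible order
initial → transitional → final are absorbed into the preceding phase and
their frames flagged. The segmentation therefore always covers every
frame exactly once, in admissible order. Frames with zero dendritic cable
inherit their predecessor's occupancy instead of propagating NaN.

## Statistics

`compare_groups` implements the two planned-comparison tests: Welch's
two-sided *t*-test (unequal variances are the safe default when the
variant is unspecified) and one-way fixed-effects ANOVA, both via
`scipy.stats` with degrees of freedom computed explicitly. Degenerate
inputs resolve by convention: all groups constant and equal → statistic
0, p = 1; constant but different → statistic ∞, p = 0, flagged
`degenerate`. Raw p-values only; no multiple-testing machinery, since the
intended use is single planned comparisons.

## The synthetic generator

The generator's purpose is to emit skeleton series with the statistical
structure the analysis assumes, plus complete ground truth, so every
stage can be validated without imaging data.

**Branch cadence.** Terminal branches per direction nucleate as
independent Poisson processes (rate λ_d per minute) and live
Exp(τ_d)-distributed lifetimes — the simplest memoryless embodiment of
"stabilization = longer lifetime"; it is a modelling choice, not a claim
about the underlying biology. While alive, a branch's path length follows
a two-state extend/retract process evaluated on the frame grid: per
interval the tip is stationary with probability 0.1, otherwise moves at
|N(1.5, 0.4²)| µm/min (clipped to [0.2, 2.8]) with the sign of the
current state, which flips with probability 0.3 per minute. A branch
retracting to zero length is eliminated. Series start from the stationary
population (Poisson(λτ) pre-existing branches with memoryless residual
lifetimes and initial lengths 4–10 µm), so stable branches can exist at
frame 0.

Geometry: each branch is a straight radial chain (stalk node, midpoint,
tip) attached to the main process, its axis drawn uniformly within the
branch's 90° sector and tilted up to ±50° out of the frontal plane, with
a per-branch attachment standoff of 3–16 µm emulating the parent shaft it
would sprout from. These spreads put nearest-neighbour tip spacing well
above the per-frame tip displacement — the regime in which gated
nearest-tip tracking is the appropriate tool, and the regime real
terminal branches occupy. Tip positions carry Gaussian jitter
(sd 0.1 µm) emulating tracing noise; ground-truth lengths and speeds are
recorded from the *realized* (jittered) geometry exactly as the pipeline
walks it, so recovery comparisons isolate tracking errors rather than
jitter.

**Bulk cadence.** Per-direction extents are scripted directly: background
wobble below ±0.7 µm, inserted extension/retraction jumps of 2.5–4 µm
(each logged as ground truth — one guaranteed within the first six
windows per direction), and direction eliminations as 3 µm-per-frame
retraction ramps. The `stepwise_targeting` preset reduces occupancy
4 → 2 → 1 over 21 h at 20-min cadence: VM is always eliminated first,
the transitional pair is always DL plus one of DM/VL (seed-chosen), and
the final direction is always DL. Because wobble is suppressed on event
frames, the inserted-event log is exactly what a correct detector must
return after the full SWC → profile → detection round trip.

**Presets.**

| preset | cadence | λ (min⁻¹) | τ (min) | notes |
|---|---|---|---|---|
| `uniform` | 30 s / 15 min | 0.5 all | 5 all | no directional bias; null condition |
| `vm_destabilized` | 30 s / 15 min | 0.5 all | 40, VM 10 | τ_VM = τ/4; VM branches rarely survive the window |
| `stepwise_targeting` | 20 min / 21 h | scripted | scripted | occupancy 4 → 2 → 1, DL retained, VM first out |
| `static` | 30 s / 15 min | 0 | ∞ | 3 frozen branches/direction; end-to-end null |

The destabilized preset's base lifetime (40 min, well above the 15-min
window) makes stable branches the common outcome in favoured directions
(≈10 per direction) while the quartered VM lifetime leaves ≈1 — the
regime in which a per-cell "VM has the fewest stable branches" call and a
four-direction ANOVA across 10 cells are both decisive. The uniform
preset keeps τ = 5 min so that lifetime-scale turnover, not direction,
dominates — a stringent null for the same test battery.

**What the generator does not emulate:** curved or arborizing branch
shapes (an optional bifurcation is not implemented; branches are straight
chains), image formation and tracing errors beyond tip jitter,
registration drift between frames, branch crossings/fasciculation, and
interactions between branches. Passing recovery tests therefore
demonstrates correctness of the measurement pipeline under the stated
stochastic model, not robustness to tracing artefacts in real data.

## Problem sizes and determinism

The verification battery uses 10 simulated cells for the destabilized
condition and 10 batches × 10 cells for the null (31 frames each, of
order 10² branches per cell), and 64-frame bulk series — sizes at which
every statistic of interest is already stable across seeds. All
randomness flows from one seeded NumPy generator per simulation; identical
seeds give bit-identical SWC bytes, ground-truth tables and downstream
CSVs (float formatting uses round-trippable `repr`).

## Degenerate inputs, ties, tolerances

- Orthonormality of the direction frame is enforced to 1e-9; a
  Gram-Schmidt constructor is provided for approximate axes.
- Zero-length edges contribute zero length/volume; zero radii are
  preserved verbatim in SWC round trips.
- Matching ties (equal distances) break by node ids; modal-sector and
  modal-occupancy ties break by canonical direction order / sorted set
  order, keeping every pipeline output deterministic.
- Fractions sum to 1 within 1e-9 on every valid frame; frames with zero
  dendritic cable are flagged rather than NaN-propagated.
- Manifest times must be strictly increasing (hard error); cadence
  irregularity beyond 10% of nominal warns but loads.
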