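"""Synthetic 3D vascular networks with known caliber ground truth.

Real confocal stacks of CD31-stained microvasculature are rarely shareable,
so this module grows random branching tubular networks on a voxel grid with a
fully known generating geometry.  Vessels are capsules (cylinders with
spherical caps): trees grow from evenly spaced seed roots with bounded
turning angles (capillary beds are locally smooth), radii shrink by a tapering
ratio at near-regular branching intervals, and growth stops below a pruning
radius.  Tips reaching a stack face are reflected back inside: the acquired
field is a crop of a statistically stationary network in which vessels
leaving the field are balanced by vessels entering it, and reflection
emulates that balance without modelling the exterior.

A *rarefaction* parameter deletes a fraction of the terminal small-caliber
subtrees, emulating the capillary loss of a diseased, rarefied network
versus a dense healthy one: reduced signal concentrated in the small-caliber
classes, a steeper fingerprint slope and a shorter X-projection.

Default geometry is sized for desk-scale runs: 96×192×192 voxels at 0.64 µm
isotropic spacing, radii spanning ~0.7–3.2 µm so rasterized cross-sections
populate the whole analyzed caliber range (~4–136 voxels, 1.6–56 µm²).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stacks_io import BinaryStack

__all__ = [
    "SynthConfig",
    "Segment",
    "GroundTruth",
    "CohortStack",
    "rasterize_segments",
    "generate_network",
    "make_cohort",
    "cohort_manifest",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic vascular-tree generator.

    Attributes
    ----------
    grid_shape
        Stack shape ``(z, y, x)`` in voxels.
    spacing_iso
        Isotropic voxel side, µm.
    n_roots
        Number of seed vessels (root trees) grown in the volume.
    root_radius_um
        Radius of each root segment, µm.
    taper
        Mean child/parent radius ratio applied at every bifurcation.
    taper_jitter
        Log-normal sigma of the per-child radius ratio, so calibers vary
        continuously instead of being quantized to powers of the taper.
    branch_prob
        Reciprocal mean number of segments between bifurcations.  Branch
        spacing is near-regular (the interval is the rounded reciprocal with
        ±1 segment of jitter) rather than memoryless: real microvascular
        beds branch at fairly regular intervals, and regular spacing keeps
        the per-stack caliber spectrum statistically stable.
    segment_len_um
        Mean segment length, µm.
    min_radius_um
        Pruning floor: branches thinner than this are not grown.
    rarefaction
        Fraction of terminal small-caliber subtrees deleted after growth
        (in [0, 1)).  A subtree is eligible where the vessel radius first
        drops below ``rarefaction_radius_um``; deleting it removes the entry
        segment and all its descendants, emulating capillary rarefaction
        that thins the smallest caliber classes while leaving the larger
        vessels in place.
    rarefaction_radius_um
        Entry radius (µm) below which a distal subtree counts as
        small-caliber; the default 1.7 µm is the disk radius at the
        boundary between the analyzed mid and small caliber classes
        (~9.4 µm² cross-section), so rarefaction thins the three smallest
        analyzed classes.
    max_turn_deg
        Maximal turning angle per segment for a continuing vessel.
    branch_angle_deg
        Typical half-opening angle between the two children of a bifurcation.
    max_segments
        Safety cap on the total number of grown segments.
    seed
        RNG seed; identical configs and seeds give bit-identical stacks.
    """

    grid_shape: tuple[int, int, int] = (96, 192, 192)
    spacing_iso: float = 0.64
    n_roots: int = 14
    root_radius_um: float = 3.2
    taper: float = 0.73
    taper_jitter: float = 0.10
    branch_prob: float = 0.55
    segment_len_um: float = 10.0
    min_radius_um: float = 0.7
    rarefaction: float = 0.0
    rarefaction_radius_um: float = 1.7
    max_turn_deg: float = 40.0
    branch_angle_deg: float = 55.0
    max_segments: int = 60000
    seed: int = 0

    def validate(self) -> list[str]:
        """Return a list of human-readable violations (empty = valid)."""
        errors = []
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            errors.append("grid_shape must be three positive integers")
        for name in ("spacing_iso", "root_radius_um", "segment_len_um", "min_radius_um"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if not 0 < self.taper <= 1:
            errors.append("taper must be in (0, 1]")
        if not 0 <= self.branch_prob <= 1:
            errors.append("branch_prob must be in [0, 1]")
        if not 0 <= self.rarefaction < 1:
            errors.append("rarefaction must be in [0, 1)")
        if self.n_roots < 1:
            errors.append("n_roots must be >= 1")
        if self.max_segments < 1:
            errors.append("max_segments must be >= 1")
        if len(self.grid_shape) == 3 and all(int(s) >= 1 for s in self.grid_shape):
            extent = min(self.grid_shape) * self.spacing_iso
            if self.root_radius_um * 2 >= extent:
                errors.append("grid too small to hold a root radius")
        return errors

    def require_valid(self) -> None:
        errors = self.validate()
        if errors:
            raise ValueError("invalid SynthConfig: " + "; ".join(errors))


@dataclass(frozen=True)
class Segment:
    """A vessel segment: a capsule from ``start`` to ``end`` (µm, zyx order)."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius_um: float
    parent: int  # index of parent segment, -1 for roots
    is_terminal: bool = False


@dataclass(frozen=True)
class GroundTruth:
    """Generating geometry of a synthetic stack.

    ``segments`` lists the capsules that were rasterized (after rarefaction);
    ``radius_map`` holds, per foreground voxel, the largest generating radius
    (µm) among the segments covering it.
    """

    segments: tuple[Segment, ...]
    radius_map: np.ndarray


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _perturb(d: np.ndarray, max_angle_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate ``d`` by a uniform angle in [0, max] around a random ⊥ axis."""
    theta = rng.uniform(0.0, max_angle_rad)
    axis = np.cross(d, _random_unit(rng))
    n = np.linalg.norm(axis)
    if n < 1e-12:
        return d
    axis /= n
    # Rodrigues rotation
    return _unit(
        d * math.cos(theta)
        + np.cross(axis, d) * math.sin(theta)
        + axis * float(np.dot(axis, d)) * (1 - math.cos(theta))
    )


def _grow_segments(cfg: SynthConfig, rng: np.random.Generator) -> list[Segment]:
    extent = np.asarray(cfg.grid_shape, dtype=float) * cfg.spacing_iso
    margin = cfg.root_radius_um
    segments: list[Segment] = []
    has_child: list[bool] = []
    # FIFO queue => breadth-first growth, so the segment cap (if ever hit)
    # truncates all trees evenly instead of starving the last roots.
    tips: deque[tuple[np.ndarray, np.ndarray, float, int, int]] = deque()

    def branch_interval() -> int:
        base = 1.0 / cfg.branch_prob if cfg.branch_prob > 0 else math.inf
        if not math.isfinite(base):
            return 10**9
        return max(1, int(round(base)) + rng.integers(-1, 2))

    # Roots are stratified on a jittered in-plane grid (z free): penetrating
    # vessels in real tissue are fairly evenly spaced, and stratification
    # keeps the large-caliber architecture statistically comparable between
    # stacks instead of leaving random clusters and voids.
    gy = max(1, int(round(math.sqrt(cfg.n_roots * extent[1] / extent[2]))))
    gx = max(1, math.ceil(cfg.n_roots / gy))
    cells = [(iy, ix) for iy in range(gy) for ix in range(gx)][: cfg.n_roots]
    cy, cx = extent[1] / gy, extent[2] / gx
    for iy, ix in cells:
        pos = np.array(
            [
                rng.uniform(margin, extent[0] - margin),
                np.clip(rng.uniform(iy * cy, (iy + 1) * cy), margin, extent[1] - margin),
                np.clip(rng.uniform(ix * cx, (ix + 1) * cx), margin, extent[2] - margin),
            ]
        )
        tips.append((pos, _random_unit(rng), cfg.root_radius_um, -1, branch_interval()))
    max_turn = math.radians(cfg.max_turn_deg)
    branch_angle = math.radians(cfg.branch_angle_deg)
    while tips and len(segments) < cfg.max_segments:
        pos, d, r, parent, countdown = tips.popleft()
        if r < cfg.min_radius_um:
            continue
        length = rng.normal(cfg.segment_len_um, 0.1 * cfg.segment_len_um)
        length = max(length, 0.2 * cfg.segment_len_um)
        nd = _perturb(d, max_turn, rng)
        end = pos + length * nd
        # Reflective boundaries: the acquired field is a crop of a
        # statistically stationary network, where vessels leaving the field
        # are balanced by vessels entering it; bouncing tips at the faces
        # emulates that without modelling the exterior.
        end, nd = _reflect(end, nd, extent)
        idx = len(segments)
        segments.append(Segment(tuple(pos), tuple(end), r, parent))
        has_child.append(False)
        if parent >= 0:
            has_child[parent] = True
        if countdown <= 1:
            for _ in range(2):
                rc = r * cfg.taper * math.exp(rng.normal(0.0, cfg.taper_jitter))
                cd = _perturb(nd, branch_angle, rng)
                tips.append((end, cd, min(rc, r), idx, branch_interval()))
        else:
            tips.append((end, nd, r, idx, countdown - 1))
    return [replace(s, is_terminal=not c) for s, c in zip(segments, has_child)]


def _reflect(end: np.ndarray, direction: np.ndarray, extent: np.ndarray):
    """Mirror a tip position back into the field, flipping its heading."""
    end = end.copy()
    direction = direction.copy()
    for ax in range(3):
        # at most a couple of bounces for realistic segment lengths
        while end[ax] < 0 or end[ax] > extent[ax]:
            if end[ax] < 0:
                end[ax] = -end[ax]
            else:
                end[ax] = 2 * extent[ax] - end[ax]
            direction[ax] = -direction[ax]
    return end, direction


def _rarefy(
    segments: list[Segment],
    fraction: float,
    cutoff_radius_um: float,
    rng: np.random.Generator,
) -> list[Segment]:
    """Delete a fraction of the terminal small-caliber subtrees.

    Eligible entry points are the segments whose radius is below the cutoff
    while their parent's is not (or that are thin roots); a chosen entry is
    removed together with all its descendants.
    """
    if fraction <= 0:
        return segments
    children: dict[int, list[int]] = {}
    for i, s in enumerate(segments):
        children.setdefault(s.parent, []).append(i)
    entries = [
        i
        for i, s in enumerate(segments)
        if s.radius_um < cutoff_radius_um
        and (s.parent < 0 or segments[s.parent].radius_um >= cutoff_radius_um)
    ]
    n_remove = int(round(fraction * len(entries)))
    if n_remove == 0:
        return segments
    chosen = rng.choice(entries, size=n_remove, replace=False).tolist()
    removed: set[int] = set()
    stack = list(chosen)
    while stack:
        i = stack.pop()
        if i in removed:
            continue
        removed.add(i)
        stack.extend(children.get(i, ()))
    return [s for i, s in enumerate(segments) if i not in removed]


def rasterize_segments(
    segments: list[Segment], shape: tuple[int, int, int], spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize capsules onto a voxel grid.

    A voxel is foreground when its center lies inside at least one capsule;
    ``radius_map`` keeps the largest covering radius (µm) per voxel.
    """
    fg = np.zeros(shape, dtype=bool)
    radius_map = np.zeros(shape, dtype=np.float32)
    shape_arr = np.asarray(shape)
    for seg in segments:
        p0 = np.asarray(seg.start) / spacing
        p1 = np.asarray(seg.end) / spacing
        r = seg.radius_um / spacing
        lo = np.maximum(np.floor(np.minimum(p0, p1) - r).astype(int), 0)
        hi = np.minimum(np.ceil(np.maximum(p0, p1) + r).astype(int) + 1, shape_arr)
        if np.any(lo >= hi):
            continue
        zz = np.arange(lo[0], hi[0], dtype=float)[:, None, None]
        yy = np.arange(lo[1], hi[1], dtype=float)[None, :, None]
        xx = np.arange(lo[2], hi[2], dtype=float)[None, None, :]
        axis_v = p1 - p0
        len2 = float(np.dot(axis_v, axis_v))
        dz, dy, dx = zz - p0[0], yy - p0[1], xx - p0[2]
        if len2 < 1e-12:
            d2 = dz**2 + dy**2 + dx**2
        else:
            t = (dz * axis_v[0] + dy * axis_v[1] + dx * axis_v[2]) / len2
            t = np.clip(t, 0.0, 1.0)
            d2 = (dz - t * axis_v[0]) ** 2 + (dy - t * axis_v[1]) ** 2 + (dx - t * axis_v[2]) ** 2
        mask = d2 <= r * r
        box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        fg[box] |= mask
        np.maximum(radius_map[box], np.where(mask, seg.radius_um, 0.0), out=radius_map[box])
    return fg, radius_map


def generate_network(cfg: SynthConfig) -> tuple[BinaryStack, GroundTruth]:
    """Grow, rarefy and rasterize one random vascular network.

    Deterministic for a fixed config (including the seed).  Growth draws are
    made before rarefaction draws, so two configs differing only in
    ``rarefaction`` share the exact same underlying tree and the rarefied
    stack's foreground is a subset of the dense one's.
    """
    cfg.require_valid()
    rng = np.random.default_rng(cfg.seed)
    segments = _grow_segments(cfg, rng)
    segments = _rarefy(segments, cfg.rarefaction, cfg.rarefaction_radius_um, rng)
    fg, radius_map = rasterize_segments(segments, tuple(int(s) for s in cfg.grid_shape), cfg.spacing_iso)
    stack = BinaryStack(voxels=fg, spacing_iso=cfg.spacing_iso)
    return stack, GroundTruth(segments=tuple(segments), radius_map=radius_map)


@dataclass(frozen=True)
class CohortStack:
    """One synthetic stack of a labeled cohort."""

    unit_id: str
    stack_id: str
    group: str
    seed: int
    stack: BinaryStack
    truth: GroundTruth = field(repr=False, default=None)


def _derive_seed(master_seed: int, group_index: int, unit: int, stack: int) -> int:
    # fixed arithmetic so cohorts are reproducible piecewise; stays < 2**31
    return (int(master_seed) * 100_003 + group_index * 10_007 + unit * 101 + stack) % (2**31)


def make_cohort(
    cfg_wt: SynthConfig,
    cfg_twi: SynthConfig,
    n_units: int = 4,
    stacks_per_unit: int = 3,
    master_seed: int = 0,
    groups: tuple[str, str] = ("wt", "twi"),
    keep_truth: bool = False,
) -> list[CohortStack]:
    """Generate a two-group labeled cohort of synthetic stacks.

    Per unit (animal) and stack, a fresh seed is derived from ``master_seed``
    by fixed arithmetic, so the whole cohort — and any single stack of it —
    is reproducible.  ``n_units`` animals per group, ``stacks_per_unit``
    stacks per animal.
    """
    if n_units < 1 or stacks_per_unit < 1:
        raise ValueError("n_units and stacks_per_unit must be >= 1")
    out: list[CohortStack] = []
    for gi, (group, cfg) in enumerate(zip(groups, (cfg_wt, cfg_twi))):
        for u in range(n_units):
            for s in range(stacks_per_unit):
                seed = _derive_seed(master_seed, gi, u, s)
                stack, truth = generate_network(replace(cfg, seed=seed))
                out.append(
                    CohortStack(
                        unit_id=f"{group}-u{u + 1}",
                        stack_id=f"{group}-u{u + 1}-s{s + 1}",
                        group=group,
                        seed=seed,
                        stack=stack,
                        truth=truth if keep_truth else None,
                    )
                )
    return out


def cohort_manifest(cohort: list[CohortStack]) -> pd.DataFrame:
    """Tabular manifest (unit, group, stack, seed) of a cohort."""
    return pd.DataFrame(
        [
            {"unit_id": c.unit_id, "stack_id": c.stack_id, "group": c.group, "seed": c.seed}
            for c in cohort
        ]
    )
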