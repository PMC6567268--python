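"""Caliber classification by minimal projected cross-section.

Every foreground voxel is assigned to a vessel-caliber class according to the
smallest area of the 2D vascular cross-section through it, measured in the
three axis-aligned (Euclidean) planes.  The class boundaries form a geometric
ladder: an initial offset area (default 4 voxels ≈ 1.64 µm² at 0.64 µm
spacing, i.e. a theoretical circular diameter of ~1.4 µm) multiplied by a
fixed ratio (default 1.8) up to six analyzed classes, topping out at ~56 µm²
(~8.4 µm diameter).  Cross-sections at or below the offset fall into a
seventh, sub-offset class used only for normalization; cross-sections above
the top threshold are flagged over-range and excluded from the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as sk_label

from .stacks_io import BinaryStack

__all__ = [
    "CaliberLadder",
    "ClassMap",
    "build_ladder",
    "min_cross_section",
    "cross_section_map",
    "classify_vessels",
    "equivalent_diameter_um",
    "geometric_mean_ratio",
]


@dataclass(frozen=True)
class CaliberLadder:
    """Geometric ladder of cross-section thresholds.

    ``thresholds_voxels[k] = round(offset_voxels * ratio**k)`` for
    ``k = 0..n_classes``; ``thresholds_um2`` is the same ladder scaled by the
    voxel face area.  Integer-voxel rounding at each rung is what reproduces
    the printed class boundaries (e.g. 9.4 µm² where the unrounded product
    would give 9.56 µm²).
    """

    offset_voxels: int
    ratio: float
    n_classes: int
    voxel_area: float
    thresholds_voxels: tuple[int, ...]
    thresholds_um2: tuple[float, ...]

    @property
    def sub_offset_label(self) -> int:
        """Label of the normalizing sub-offset class (= n_classes + 1)."""
        return self.n_classes + 1

    @property
    def over_range_label(self) -> int:
        """Sentinel label for voxels whose cross-section exceeds the ladder."""
        return self.n_classes + 2


def build_ladder(
    offset_voxels: int, ratio: float, n_classes: int, voxel_area: float
) -> CaliberLadder:
    """Build the threshold ladder ``round(offset * ratio**k)``, k = 0..n_classes.

    Parameters
    ----------
    offset_voxels
        Smallest analyzed cross-section, in voxels (>= 1).
    ratio
        Dimensionless multiplier between adjacent thresholds (> 1).
    n_classes
        Number of analyzed caliber classes (>= 1).
    voxel_area
        Voxel face area in µm², used to express the thresholds physically.
    """
    if int(offset_voxels) < 1:
        raise ValueError("offset_voxels must be >= 1")
    if not ratio > 1:
        raise ValueError("ratio must be > 1 (thresholds must ascend)")
    if int(n_classes) < 1:
        raise ValueError("n_classes must be >= 1")
    if not voxel_area > 0:
        raise ValueError("voxel_area must be positive")
    tv = tuple(int(round(offset_voxels * ratio**k)) for k in range(n_classes + 1))
    if any(b <= a for a, b in zip(tv, tv[1:])):
        raise ValueError(f"thresholds not strictly ascending: {tv}")
    tu = tuple(t * voxel_area for t in tv)
    return CaliberLadder(
        offset_voxels=int(offset_voxels),
        ratio=float(ratio),
        n_classes=int(n_classes),
        voxel_area=float(voxel_area),
        thresholds_voxels=tv,
        thresholds_um2=tu,
    )


def equivalent_diameter_um(area_um2: float) -> float:
    """Diameter of the circle with the given area (theoretical vessel caliber)."""
    if area_um2 < 0:
        raise ValueError("area must be non-negative")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def geometric_mean_ratio(t_low: float, t_high: float, n_steps: int) -> float:
    """Per-step ratio implied by two thresholds ``n_steps`` rungs apart."""
    if t_low <= 0 or t_high <= 0 or n_steps < 1:
        raise ValueError("thresholds must be positive and n_steps >= 1")
    return (t_high / t_low) ** (1.0 / n_steps)


@dataclass(frozen=True)
class ClassMap:
    """Per-voxel caliber labels plus the ladder that produced them.

    Label semantics: 0 = background; 1 = largest analyzed class …
    ``n_classes`` = smallest analyzed class; ``n_classes + 1`` = sub-offset
    normalizing class; ``n_classes + 2`` = over-range sentinel (excluded from
    every architecture and from normalization).
    """

    labels: np.ndarray
    ladder: CaliberLadder

    @property
    def n_classes(self) -> int:
        return self.ladder.n_classes

    @property
    def sub_offset_label(self) -> int:
        return self.ladder.sub_offset_label

    @property
    def over_range_label(self) -> int:
        return self.ladder.over_range_label

    def class_counts(self) -> dict[int, int]:
        """Voxel count per nonzero label (including sub-offset and over-range)."""
        counts = np.bincount(self.labels.ravel(), minlength=self.over_range_label + 1)
        return {lab: int(counts[lab]) for lab in range(1, self.over_range_label + 1)}


def _plane_slices(voxels: np.ndarray, axis: int, index: int) -> np.ndarray:
    sl = [slice(None)] * 3
    sl[axis] = index
    return voxels[tuple(sl)]


def min_cross_section(b: BinaryStack, voxel: tuple[int, int, int]) -> int:
    """Minimal cross-section area (in voxels) of the vessel through ``voxel``.

    For each of the three axis-aligned planes through the voxel, the size of
    the 2D 8-connected foreground component containing it is measured; the
    minimum of the three is returned.  Querying a background voxel is an
    error.
    """
    z, y, x = voxel
    if not b.voxels[z, y, x]:
        raise ValueError(f"voxel {voxel} is background")
    areas = []
    for axis, idx, inplane in ((0, z, (y, x)), (1, y, (z, x)), (2, x, (z, y))):
        plane = _plane_slices(b.voxels, axis, idx)
        lab = sk_label(plane, connectivity=2)
        areas.append(int((lab == lab[inplane]).sum()))
    return min(areas)


def cross_section_map(b: BinaryStack) -> np.ndarray:
    """Minimal cross-section area for every voxel, vectorized over slices.

    Equivalent to calling :func:`min_cross_section` on every foreground voxel
    (8-connected in-plane components), but computed by labeling each 2D slice
    of the stack once per axis.  Background voxels get 0.
    """
    v = b.voxels
    out = np.full(v.shape, np.iinfo(np.int64).max, dtype=np.int64)
    for axis in range(3):
        moved = np.moveaxis(v, axis, 0)
        res = np.moveaxis(out, axis, 0)
        for i in range(moved.shape[0]):
            plane = moved[i]
            if not plane.any():
                continue
            lab = sk_label(plane, connectivity=2)
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            np.minimum(res[i], sizes[lab], out=res[i])
    out[~v] = 0
    return out


def classify_vessels(b: BinaryStack, ladder: CaliberLadder) -> ClassMap:
    """Assign every foreground voxel to a caliber class.

    With ``a`` the minimal cross-section (voxels) and thresholds
    ``T0 < … < Tn``: label ``n_classes + 1`` (sub-offset) if ``a <= T0``;
    label ``k`` (1 = largest … n = smallest) if ``T[n-k] < a <= T[n-k+1]``;
    the over-range sentinel if ``a > Tn``.  Intervals are half-open,
    upper-inclusive, so adjacent classes never overlap.
    """
    area = cross_section_map(b)
    n = ladder.n_classes
    thresholds = np.asarray(ladder.thresholds_voxels)
    labels = np.zeros(b.shape, dtype=np.uint8)
    fg = b.voxels
    a = area[fg]
    idx = np.searchsorted(thresholds, a, side="left")
    lab = np.where(idx == 0, ladder.sub_offset_label, n + 1 - idx)
    lab = np.where(idx > n, ladder.over_range_label, lab)
    labels[fg] = lab.astype(np.uint8)
    return ClassMap(labels=labels, ladder=ladder)
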