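"""Progressively reconstituted vascular trees and percent volume occupancy.

The classified signal is rearranged into a nested family of architectures:
architecture k is the union of caliber classes 1..k (largest caliber first),
always intersected with the originally observed signal.  The last analyzed
architecture (k = n_classes) is the complete tree of analyzed vessels; adding
the sub-offset class on top yields the *normalizing total* used only to equate
signal amounts between samples.  Over-range voxels never enter any
architecture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .caliber import ClassMap
from .stacks_io import BinaryStack

__all__ = ["ProgressiveSet", "build_progressive", "percent_volume"]


def percent_volume(b) -> float:
    """Percent of foreground voxels in the whole grid (Vol%)."""
    v = b.voxels if isinstance(b, BinaryStack) else np.asarray(b, dtype=bool)
    return 100.0 * float(v.sum()) / v.size


@dataclass(frozen=True)
class ProgressiveSet:
    """Nested cumulative vascular trees with their Vol% occupancies.

    ``architectures[k-1]`` is the union of classes 1..k (k = 1..n_classes);
    ``normalizing_total`` additionally includes the sub-offset class.
    ``vol_pct[k-1]`` is the Vol% of architecture k; ``total_vol_pct`` that of
    the normalizing total.  Nestedness (architecture k ⊆ k+1 ⊆ total) and
    non-decreasing Vol% hold by construction.
    """

    architectures: tuple[BinaryStack, ...]
    normalizing_total: BinaryStack
    vol_pct: tuple[float, ...]
    total_vol_pct: float

    @property
    def n_classes(self) -> int:
        return len(self.architectures)


def build_progressive(cm: ClassMap, original: BinaryStack) -> ProgressiveSet:
    """Assemble the nested architecture set from a class map.

    Architecture k contains the voxels with label <= k intersected with the
    original signal; the normalizing total also includes the sub-offset label.
    The over-range sentinel (label n_classes + 2) is excluded everywhere.
    """
    if cm.labels.shape != original.shape:
        raise ValueError(f"shape mismatch: {cm.labels.shape} vs {original.shape}")
    n = cm.n_classes
    labels = np.where(original.voxels, cm.labels, 0)
    archs = []
    vols = []
    for k in range(1, n + 1):
        v = (labels >= 1) & (labels <= k)
        arch = BinaryStack(voxels=v, spacing_iso=original.spacing_iso)
        archs.append(arch)
        vols.append(percent_volume(arch))
    total = BinaryStack(
        voxels=(labels >= 1) & (labels <= cm.sub_offset_label),
        spacing_iso=original.spacing_iso,
    )
    return ProgressiveSet(
        architectures=tuple(archs),
        normalizing_total=total,
        vol_pct=tuple(vols),
        total_vol_pct=percent_volume(total),
    )
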