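"""Vessel-map preparation: size-capped close-and-fill, original-signal masking.

Immunostaining labels vessel walls, so lumina show up hollow and walls can be
broken where signal drops out.  :func:`close_and_fill` recovers solid vessel
maps with a 3D morphological closing followed by cavity filling, where any
single filled cavity must stay below a voxel cap so that intervascular spaces
are never mistaken for lumina.  After caliber classification the signal is
intersected back with the originally observed voxels
(:func:`restrict_to_original`) so only real signal enters the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .stacks_io import BinaryStack

__all__ = ["FillParams", "close_and_fill", "restrict_to_original"]

# Complementary connectivities avoid topological paradoxes: 26-neighbourhood
# for foreground morphology, 6-neighbourhood for background cavities.
_SE26 = np.ones((3, 3, 3), dtype=bool)
_SE6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class FillParams:
    """Parameters of the close-and-fill vessel reconstruction.

    ``close_cycles`` dilations (26-neighbourhood) followed by the same number
    of erosions close small wall gaps; ``max_fill_voxels`` caps the size of
    any single cavity that may be filled afterwards.  Defaults (2 cycles,
    1200 voxels) are the values established for ~0.64 µm isotropic confocal
    stacks of brain cortex microvasculature.
    """

    close_cycles: int = 2
    max_fill_voxels: int = 1200

    def __post_init__(self) -> None:
        if int(self.close_cycles) < 0:
            raise ValueError("close_cycles must be >= 0")
        if int(self.max_fill_voxels) < 1:
            raise ValueError("max_fill_voxels must be >= 1")


def close_and_fill(b: BinaryStack, p: FillParams = FillParams()) -> BinaryStack:
    """Recover solid vessel maps by closing then cap-limited cavity filling.

    Steps:

    1. morphological closing: ``close_cycles`` dilations with the full
       26-neighbourhood followed by as many erosions (computed on a
       zero-padded grid so the closing is not distorted at stack faces);
    2. every 6-connected background component of the closed image that does
       not touch any stack face and contains fewer than ``max_fill_voxels``
       voxels is set to foreground;
    3. the result is the union of the input with all additions — no original
       foreground voxel is ever removed.
    """
    v = b.voxels
    n = int(p.close_cycles)
    if n > 0:
        pad = n
        vp = np.pad(v, pad, constant_values=False)
        closed = ndimage.binary_closing(vp, structure=_SE26, iterations=n)
        sl = (slice(pad, -pad),) * 3
        closed = closed[sl]
    else:
        closed = v.copy()

    filled = _fill_cavities(closed, int(p.max_fill_voxels))
    return replace(b, voxels=v | filled)


def _fill_cavities(closed: np.ndarray, max_fill_voxels: int) -> np.ndarray:
    """Fill 6-connected enclosed background cavities smaller than the cap."""
    bg = ~closed
    labels, nlab = ndimage.label(bg, structure=_SE6)
    if nlab == 0:
        return closed
    # Components touching any face are exterior space by construction.
    face_labels = np.unique(
        np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
    )
    sizes = np.bincount(labels.ravel(), minlength=nlab + 1)
    fillable = sizes < max_fill_voxels
    fillable[0] = False
    fillable[face_labels[face_labels > 0]] = False
    return closed | fillable[labels]


def restrict_to_original(classified, original: BinaryStack):
    """Keep classified signal only where the original binary signal exists.

    ``classified`` may be a :class:`BinaryStack` or a caliber label map (any
    object with an integer ``labels`` grid, e.g. ``caliber.ClassMap``); the
    same type is returned with background outside the original foreground.
    """
    mask = original.voxels
    if isinstance(classified, BinaryStack):
        if classified.shape != original.shape:
            raise ValueError(f"shape mismatch: {classified.shape} vs {original.shape}")
        return replace(classified, voxels=classified.voxels & mask)
    labels = getattr(classified, "labels", None)
    if labels is not None:
        if labels.shape != mask.shape:
            raise ValueError(f"shape mismatch: {labels.shape} vs {mask.shape}")
        return replace(classified, labels=np.where(mask, labels, 0))
    arr = np.asarray(classified)
    if arr.shape != mask.shape:
        raise ValueError(f"shape mismatch: {arr.shape} vs {mask.shape}")
    return np.where(mask, arr, 0)
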