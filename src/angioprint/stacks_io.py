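"""Image-stack I/O, isotropic resampling and automatic binarization.

The analysis pipeline works on confocal z-stacks of immunostained
microvasculature.  Everything downstream of this module operates on
*isotropic* binary grids, so the two jobs here are (a) moving multi-page
TIFF stacks (plus their physical voxel spacing, which TIFFs do not carry
reliably) in and out of memory, and (b) turning a greyscale stack into a
:class:`BinaryStack` by resampling the z-axis to the in-plane spacing and
thresholding with the iterative-intermeans (IsoData-variant) algorithm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import tifffile
from skimage.filters import threshold_isodata

__all__ = [
    "GreyStack",
    "BinaryStack",
    "DegenerateImageError",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "make_isotropic",
    "isodata_threshold",
    "binarize",
]

log = logging.getLogger(__name__)

#: Relative tolerance used when deciding whether spacings are equal.
_SPACING_RTOL = 1e-6


class DegenerateImageError(ValueError):
    """Raised when an image has no information to threshold (constant stack)."""


@dataclass(frozen=True)
class GreyStack:
    """A 3D greyscale intensity grid with physical voxel spacing.

    Parameters
    ----------
    voxels
        Array of shape ``(z, y, x)`` with non-negative intensities.
    spacing
        Physical voxel size ``(z, y, x)`` in micrometres.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"expected a 3D stack, got shape {v.shape}")
        if np.issubdtype(v.dtype, np.number) and v.size and v.min() < 0:
            raise ValueError("intensities must be non-negative")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def is_isotropic(self) -> bool:
        sz, sy, sx = self.spacing
        return (
            math.isclose(sz, sx, rel_tol=_SPACING_RTOL)
            and math.isclose(sy, sx, rel_tol=_SPACING_RTOL)
        )


@dataclass(frozen=True)
class BinaryStack:
    """An isotropic 3D boolean grid — the universal currency of the pipeline.

    Parameters
    ----------
    voxels
        Boolean array of shape ``(z, y, x)``; ``True`` marks vascular signal.
    spacing_iso
        Isotropic voxel side in micrometres.
    """

    voxels: np.ndarray
    spacing_iso: float

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"expected a 3D stack, got shape {v.shape}")
        if v.dtype != bool:
            v = v.astype(bool)
        if float(self.spacing_iso) <= 0:
            raise ValueError("spacing_iso must be positive")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing_iso", float(self.spacing_iso))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_area(self) -> float:
        """Area of one voxel face in µm²."""
        return self.spacing_iso**2

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.spacing_iso**3

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.voxels.sum())


def read_stack(path, spacing: tuple[float, float, float]) -> GreyStack:
    """Read a multi-page greyscale TIFF into a :class:`GreyStack`.

    The page count becomes the z-dimension; intensities are preserved
    bit-exact.  ``spacing`` is the physical ``(z, y, x)`` voxel size in µm.
    """
    voxels = tifffile.imread(str(path))
    if voxels.ndim == 2:
        voxels = voxels[np.newaxis]
    if voxels.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel z-stack, got shape {voxels.shape}")
    return GreyStack(voxels=voxels, spacing=spacing)


def write_stack(g: GreyStack, path) -> None:
    """Write a greyscale stack as a multi-page TIFF (bit-exact for integers)."""
    tifffile.imwrite(str(path), np.asarray(g.voxels), photometric="minisblack")


def write_mask(b: BinaryStack, path) -> None:
    """Write a binary stack as an 8-bit TIFF with values {0, 255}."""
    tifffile.imwrite(
        str(path), np.where(b.voxels, 255, 0).astype(np.uint8), photometric="minisblack"
    )


def read_mask(path, spacing_iso: float) -> BinaryStack:
    """Read an 8-bit binary mask written by :func:`write_mask`."""
    v = tifffile.imread(str(path))
    if v.ndim == 2:
        v = v[np.newaxis]
    return BinaryStack(voxels=v > 0, spacing_iso=spacing_iso)


def make_isotropic(g: GreyStack) -> GreyStack:
    """Resample the z-axis so all three voxel spacings equal the in-plane one.

    The in-plane (x/y) resolution is preserved; the z-dimension is rescaled
    by ``spacing_z / spacing_xy`` with linear interpolation.  Already
    isotropic input is returned unchanged (idempotence).
    """
    sz, sy, sx = g.spacing
    if not math.isclose(sy, sx, rel_tol=_SPACING_RTOL):
        raise ValueError(f"in-plane spacing must be square, got y={sy} x={sx}")
    if g.is_isotropic:
        return g
    scale = sz / sx
    nz = g.voxels.shape[0]
    nz_out = max(1, int(round(nz * scale)))
    # Output plane j sits at physical depth j*sx == input index j/scale.
    zi = np.arange(nz_out) / scale
    zi = np.clip(zi, 0, nz - 1)
    lo = np.floor(zi).astype(int)
    hi = np.minimum(lo + 1, nz - 1)
    w = (zi - lo)[:, None, None]
    v = g.voxels.astype(np.float64)
    out = (1.0 - w) * v[lo] + w * v[hi]
    if np.issubdtype(g.voxels.dtype, np.integer):
        out = np.rint(out).astype(g.voxels.dtype)
    return GreyStack(voxels=out, spacing=(sx, sy, sx))


def isodata_threshold(voxels: np.ndarray, nbins: int = 256) -> float:
    """Iterative-intermeans (IsoData-variant) threshold of a whole stack.

    The histogram uses ``nbins`` bins (256 matches 8-bit behaviour).  The
    returned value ``t`` separates the classes as ``foreground = voxels > t``.
    """
    v = np.asarray(voxels)
    if v.size == 0 or v.min() == v.max():
        raise DegenerateImageError("constant stack: no threshold exists")
    return float(threshold_isodata(v, nbins=nbins))


def binarize(g: GreyStack, nbins: int = 256) -> BinaryStack:
    """Threshold a greyscale stack into a binary one.

    Foreground are the voxels strictly above the iterative-intermeans
    threshold computed on the whole-stack histogram.  The stack must already
    be isotropic (run :func:`make_isotropic` first); the threshold used is
    emitted to the module logger.
    """
    if not g.is_isotropic:
        raise ValueError("binarize expects an isotropic stack; run make_isotropic first")
    t = isodata_threshold(g.voxels, nbins=nbins)
    log.info("isodata threshold = %g", t)
    return BinaryStack(voxels=g.voxels > t, spacing_iso=g.spacing[2])
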