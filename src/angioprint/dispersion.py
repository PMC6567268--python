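"""Dilation-based spatial dispersion index (Hv) and its normalization (nHv).

The dispersion of a vascular signal in its reference volume is measured by
counting how many structured binary dilation steps are needed for the signal
to occupy a target fraction of the volume (90/95/99 Vol%).  Dilations follow
a *rhombicuboctahedral* scheme: the repeating structuring-element cycle
6-neighbourhood → 18-neighbourhood → 26-neighbourhood, whose three-step
composite growth solid (cube ⊕ octahedron ⊕ cuboctahedron Minkowski sum) is a
rhombicuboctahedral polyhedron approximating isotropic Euclidean expansion.
Fractional steps are resolved by linear interpolation between the bracketing
occupancies.

Raw step counts (Hv) depend on the amount of signal as well as on its
dispersion.  The normalized index nHv subtracts, from each sample's raw
count, the fractional number of steps needed to dilate that sample up to the
initial Vol% of the densest sample in the comparison set (the *normalizing
image*), isolating dispersion from amount.  All compared samples must use the
same dilation scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .stacks_io import BinaryStack

__all__ = [
    "DEFAULT_TARGETS",
    "SCHEMES",
    "DilationTrace",
    "HvResult",
    "dilate_step",
    "fill_to_target",
    "steps_to_occupancy",
    "normalize_hv",
    "hv_analysis",
]

DEFAULT_TARGETS = (90.0, 95.0, 99.0)

_RHOMBI = (
    ndimage.generate_binary_structure(3, 1),  # 6-neighbourhood (faces)
    ndimage.generate_binary_structure(3, 2),  # 18-neighbourhood (faces+edges)
    ndimage.generate_binary_structure(3, 3),  # 26-neighbourhood (full cube)
)

#: Pluggable dilation schemes: name -> repeating structuring-element cycle.
SCHEMES: dict[str, tuple[np.ndarray, ...]] = {"rhombicuboctahedral": _RHOMBI}


@dataclass(frozen=True)
class DilationTrace:
    """Vol% occupancy after each dilation step (step 0 = initial signal)."""

    occupancy: tuple[float, ...]
    scheme: str = "rhombicuboctahedral"

    def __post_init__(self) -> None:
        occ = tuple(float(o) for o in self.occupancy)
        if not occ or occ[0] <= 0:
            raise ValueError("trace must start from a non-empty signal")
        object.__setattr__(self, "occupancy", occ)


@dataclass(frozen=True)
class HvResult:
    """Raw and normalized dilation-cycle indices at the requested targets.

    ``raw[p]`` is the fractional number of dilation steps to reach p Vol%;
    ``normalized[p] = raw[p] - norm_offset`` where ``norm_offset`` is the
    fractional number of steps to dilate this sample from its own initial
    Vol% up to the normalizing image's Vol%.
    """

    raw: dict[float, float]
    normalized: dict[float, float]
    norm_offset: float
    scheme: str = "rhombicuboctahedral"

    def _get(self, d: dict[float, float], p: float) -> float:
        try:
            return d[p]
        except KeyError:
            raise KeyError(f"target {p}% was not computed (targets: {sorted(d)})") from None

    @property
    def hv90(self) -> float:
        return self._get(self.raw, 90.0)

    @property
    def hv95(self) -> float:
        return self._get(self.raw, 95.0)

    @property
    def hv99(self) -> float:
        return self._get(self.raw, 99.0)

    @property
    def nhv90(self) -> float:
        return self._get(self.normalized, 90.0)

    @property
    def nhv95(self) -> float:
        return self._get(self.normalized, 95.0)

    @property
    def nhv99(self) -> float:
        return self._get(self.normalized, 99.0)


def _scheme_elements(scheme: str) -> tuple[np.ndarray, ...]:
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown dilation scheme {scheme!r}; known: {sorted(SCHEMES)}") from None


def dilate_step(b: BinaryStack, step_index: int, scheme: str = "rhombicuboctahedral") -> BinaryStack:
    """One binary dilation with the scheme's element for ``step_index``.

    ``step_index`` counts from 0; the element is taken from the scheme's
    repeating cycle.  Dilation is clipped at the stack faces (the reference
    volume is the acquired field).  Output is a superset of the input.
    """
    if not b.voxels.any():
        raise ValueError("cannot dilate an empty stack (no seed)")
    elems = _scheme_elements(scheme)
    se = elems[step_index % len(elems)]
    return replace(b, voxels=ndimage.binary_dilation(b.voxels, structure=se))


def steps_to_occupancy(trace: DilationTrace, p: float) -> float:
    """Fractional number of steps at which the trace reaches p Vol%.

    If the initial occupancy already meets p the count is 0; otherwise, with
    k the first step whose occupancy v_k >= p, the count is
    ``(k-1) + (p - v_{k-1}) / (v_k - v_{k-1})`` (linear interpolation inside
    the final step).
    """
    occ = trace.occupancy
    if not 0 < p <= 100:
        raise ValueError("target must be in (0, 100]")
    if occ[0] >= p:
        return 0.0
    for k in range(1, len(occ)):
        if occ[k] >= p:
            return (k - 1) + (p - occ[k - 1]) / (occ[k] - occ[k - 1])
    raise ValueError(f"trace never reaches {p}% (max occupancy {occ[-1]:.3f}%)")


def fill_to_target(
    b: BinaryStack,
    targets: tuple[float, ...] = DEFAULT_TARGETS,
    scheme: str = "rhombicuboctahedral",
) -> tuple[DilationTrace, dict[float, float]]:
    """Iterate dilation steps until every target occupancy is bracketed.

    Returns the occupancy trace and, per target p, the fractional raw step
    count (the Hv index at p).
    """
    if not targets:
        raise ValueError("at least one target required")
    targets = tuple(float(t) for t in targets)
    if any(not 0 < t <= 100 for t in targets):
        raise ValueError("targets must be in (0, 100]")
    v = b.voxels
    if not v.any():
        raise ValueError("cannot measure dispersion of an empty stack")
    elems = _scheme_elements(scheme)
    size = v.size
    occ = [100.0 * v.sum() / size]
    goal = max(targets)
    step = 0
    while occ[-1] < goal:
        v = ndimage.binary_dilation(v, structure=elems[step % len(elems)])
        step += 1
        occ.append(100.0 * v.sum() / size)
    trace = DilationTrace(occupancy=tuple(occ), scheme=scheme)
    return trace, {p: steps_to_occupancy(trace, p) for p in targets}


def normalize_hv(
    trace: DilationTrace, raw: dict[float, float], norm_vol_pct: float
) -> HvResult:
    """Normalize raw Hv counts for the amount of signal.

    ``norm_vol_pct`` is the initial Vol% of the normalizing image — by
    construction the maximal total-architecture Vol% of the comparison set,
    so it can never be below this sample's own initial occupancy.  The offset
    subtracted from every raw count is the fractional number of steps needed
    to dilate this sample from its own Vol% up to ``norm_vol_pct``, using the
    same interpolation rule as the raw counts.
    """
    if norm_vol_pct < trace.occupancy[0] - 1e-9:
        raise ValueError(
            f"normalizing Vol% ({norm_vol_pct:.4f}) below sample Vol% "
            f"({trace.occupancy[0]:.4f}); the normalizing image must be maximal"
        )
    offset = steps_to_occupancy(trace, min(norm_vol_pct, 100.0)) if norm_vol_pct > trace.occupancy[0] else 0.0
    normalized = {p: r - offset for p, r in raw.items()}
    return HvResult(raw=dict(raw), normalized=normalized, norm_offset=offset, scheme=trace.scheme)


def hv_analysis(
    b: BinaryStack,
    norm_vol_pct: float | None = None,
    targets: tuple[float, ...] = DEFAULT_TARGETS,
    scheme: str = "rhombicuboctahedral",
) -> HvResult:
    """Convenience wrapper: trace, raw counts and normalization in one call.

    With ``norm_vol_pct=None`` the sample is treated as its own normalizing
    image (offset 0) — appropriate for the maximal-Vol% sample itself.
    """
    trace, raw = fill_to_target(b, targets=targets, scheme=scheme)
    if norm_vol_pct is None:
        norm_vol_pct = trace.occupancy[0]
    return normalize_hv(trace, raw, norm_vol_pct)
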