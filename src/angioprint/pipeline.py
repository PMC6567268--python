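"""End-to-end pipeline: stacks in, fingerprint points and group statistics out.

Per stack the stages are: isotropic resampling → binarization (for greyscale
input) → close-and-fill → caliber classification → restriction to the
original signal → progressive architectures → Vol% and Hv/nHv per
architecture.  The normalizing image is the total architecture of the sample
with the maximal percent volume over the whole comparison set (both groups
jointly by default), so exactly one sample receives a zero normalization
offset in every run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fingerprint as fp
from .caliber import build_ladder, classify_vessels
from .dispersion import DEFAULT_TARGETS, SCHEMES, fill_to_target, normalize_hv
from .progressive import build_progressive
from .stacks_io import BinaryStack, binarize, make_isotropic, read_stack
from .vessel_prep import FillParams, close_and_fill, restrict_to_original

__all__ = [
    "PipelineParams",
    "RunConfig",
    "StageError",
    "StackInput",
    "CohortResult",
    "analyze_stack",
    "analyze_binary_cohort",
    "validate_config",
    "run_pipeline",
]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed for one stack; carries stack id and stage name."""

    def __init__(self, stack_id: str, stage: str, cause: Exception):
        super().__init__(f"stack {stack_id!r}, stage {stage!r}: {cause}")
        self.stack_id = stack_id
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineParams:
    """All knobs of the analysis stages (not of data generation or I/O)."""

    close_cycles: int = 2
    max_fill_voxels: int = 1200
    offset_voxels: int = 4
    ratio: float = 1.8
    n_classes: int = 6
    targets: tuple[float, ...] = DEFAULT_TARGETS
    scheme: str = "rhombicuboctahedral"
    include_suboffset_point: bool = False
    per_group_normalization: bool = False

    @property
    def fill(self) -> FillParams:
        return FillParams(self.close_cycles, self.max_fill_voxels)


@dataclass(frozen=True)
class StackInput:
    """One binary stack entering a cohort analysis, with its grouping."""

    unit_id: str
    stack_id: str
    group: str
    stack: BinaryStack


def analyze_stack(original: BinaryStack, params: PipelineParams = PipelineParams()):
    """Classify one binary stack and build its progressive architecture set.

    Returns ``(ProgressiveSet, ClassMap)``.  The caliber ladder is built from
    the stack's own voxel area; classification runs on the filled map, then
    labels are restricted to the originally observed signal.
    """
    filled = close_and_fill(original, params.fill)
    ladder = build_ladder(params.offset_voxels, params.ratio, params.n_classes,
                          original.voxel_area)
    cm = classify_vessels(filled, ladder)
    cm = restrict_to_original(cm, original)
    return build_progressive(cm, original), cm


@dataclass(frozen=True)
class CohortResult:
    """Outputs of a cohort analysis.

    ``points`` has one row per (stack, architecture) with Vol%, raw Hv and
    normalized nHv at every target; ``norm_vol_pct`` maps each normalization
    scope (group name, or ``"all"``) to the normalizing image's Vol%.
    """

    points: pd.DataFrame
    norm_vol_pct: dict[str, float]
    params: PipelineParams


def analyze_binary_cohort(
    stacks: list[StackInput], params: PipelineParams = PipelineParams()
) -> CohortResult:
    """Run the full analysis on a set of binary stacks forming one comparison.

    Two passes: the first classifies every stack and finds the normalizing
    Vol% (maximal total-architecture Vol% over the comparison scope); the
    second measures dilation traces and normalized dispersion per
    architecture.  Stage failures are reported with stack id and stage name;
    an empty architecture yields NaN dispersion rows rather than aborting the
    cohort.
    """
    if not stacks:
        raise ValueError("empty cohort")
    progressive_sets = {}
    for s in stacks:
        try:
            ps, _ = analyze_stack(s.stack, params)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise StageError(s.stack_id, "classification", exc) from exc
        progressive_sets[s.stack_id] = ps

    def scope_of(s: StackInput) -> str:
        return s.group if params.per_group_normalization else "all"

    norm_vol_pct: dict[str, float] = {}
    for s in stacks:
        scope = scope_of(s)
        v = progressive_sets[s.stack_id].total_vol_pct
        norm_vol_pct[scope] = max(norm_vol_pct.get(scope, 0.0), v)

    rows = []
    for s in stacks:
        ps = progressive_sets[s.stack_id]
        norm = norm_vol_pct[scope_of(s)]
        ks = list(range(1, ps.n_classes + 1))
        archs = list(ps.architectures)
        vols = list(ps.vol_pct)
        if params.include_suboffset_point:
            ks.append(ps.n_classes + 1)
            archs.append(ps.normalizing_total)
            vols.append(ps.total_vol_pct)
        for k, arch, vol in zip(ks, archs, vols):
            row = {
                "unit_id": s.unit_id,
                "stack_id": s.stack_id,
                "group": s.group,
                "k": k,
                "vol_pct": vol,
                "norm_vol_pct": norm,
            }
            if arch.count() == 0:
                log.warning("stack %s architecture %d is empty; dispersion set to NaN",
                            s.stack_id, k)
                for t in params.targets:
                    row[f"hv{t:g}"] = np.nan
                    row[f"nhv{t:g}"] = np.nan
                row["norm_offset"] = np.nan
            else:
                try:
                    trace, raw = fill_to_target(arch, targets=params.targets,
                                                scheme=params.scheme)
                    hv = normalize_hv(trace, raw, norm)
                except Exception as exc:  # noqa: BLE001
                    raise StageError(s.stack_id, f"dispersion(k={k})", exc) from exc
                for t in params.targets:
                    row[f"hv{t:g}"] = hv.raw[t]
                    row[f"nhv{t:g}"] = hv.normalized[t]
                row["norm_offset"] = hv.norm_offset
            rows.append(row)
    return CohortResult(points=pd.DataFrame(rows), norm_vol_pct=norm_vol_pct, params=params)


# ---------------------------------------------------------------------------
# File-based runs


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a file-based pipeline run.

    ``inputs`` maps stack id -> dict with keys ``path``, ``unit``, ``group``.
    Greyscale TIFFs are resampled and thresholded; files flagged
    ``binary: true`` are read as masks directly.
    """

    inputs: dict[str, dict] = field(default_factory=dict)
    spacing_z: float = 1.0
    spacing_xy: float = 0.64
    params: PipelineParams = PipelineParams()
    out_dir: str = "angioprint-out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pp = raw.pop("params", {})
        if "targets" in pp:
            pp["targets"] = tuple(float(t) for t in pp["targets"])
        return cls(
            inputs=raw.get("inputs", {}),
            spacing_z=float(raw.get("spacing_z", 1.0)),
            spacing_xy=float(raw.get("spacing_xy", 0.64)),
            params=PipelineParams(**pp),
            out_dir=raw.get("out_dir", "angioprint-out"),
        )

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"]["targets"] = list(d["params"]["targets"])
        return d


def validate_config(cfg: RunConfig) -> list[str]:
    """Check every config invariant; returns actionable findings (empty = ok)."""
    errors = []
    if cfg.spacing_z <= 0:
        errors.append("spacing_z must be positive")
    if cfg.spacing_xy <= 0:
        errors.append("spacing_xy must be positive")
    p = cfg.params
    if p.close_cycles < 0:
        errors.append("params.close_cycles must be >= 0")
    if p.max_fill_voxels < 1:
        errors.append("params.max_fill_voxels must be >= 1")
    if p.offset_voxels < 1:
        errors.append("params.offset_voxels must be >= 1")
    if not p.ratio > 1:
        errors.append("params.ratio must be > 1")
    if p.n_classes < 1:
        errors.append("params.n_classes must be >= 1")
    if not p.targets or any(not 0 < t <= 100 for t in p.targets):
        errors.append("params.targets must be percentages in (0, 100]")
    if p.scheme not in SCHEMES:
        errors.append(f"params.scheme {p.scheme!r} is unknown")
    for sid, spec in cfg.inputs.items():
        if "path" not in spec:
            errors.append(f"input {sid!r}: missing path")
        elif not Path(spec["path"]).exists():
            errors.append(f"input {sid!r}: path {spec['path']!r} does not exist")
        for key in ("unit", "group"):
            if key not in spec:
                errors.append(f"input {sid!r}: missing grouping key {key!r}")
    return errors


def run_pipeline(cfg: RunConfig) -> CohortResult:
    """Run the complete file-based pipeline and write all outputs.

    Writes per-architecture points as CSV, group statistics as JSON (when
    exactly two groups are present) and the resolved configuration as YAML
    next to the outputs; returns the in-memory :class:`CohortResult`.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    from .stacks_io import read_mask

    stacks = []
    for sid, spec in sorted(cfg.inputs.items()):
        try:
            if spec.get("binary", False):
                b = read_mask(spec["path"], spacing_iso=cfg.spacing_xy)
            else:
                g = read_stack(spec["path"], (cfg.spacing_z, cfg.spacing_xy, cfg.spacing_xy))
                b = binarize(make_isotropic(g))
        except Exception as exc:  # noqa: BLE001
            raise StageError(sid, "input", exc) from exc
        stacks.append(StackInput(unit_id=spec["unit"], stack_id=sid,
                                 group=spec["group"], stack=b))

    result = analyze_binary_cohort(stacks, cfg.params)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.points.to_csv(out / "points.csv", index=False)
    (out / "resolved-config.yaml").write_text(yaml.safe_dump(cfg.resolved()))

    groups = sorted(result.points["group"].unique())
    if len(groups) == 2:
        import json

        pa = result.points[result.points["group"] == groups[0]]
        pb = result.points[result.points["group"] == groups[1]]
        cmp_res = fp.compare_groups(pa, pb)
        report = {
            "groups": groups,
            "slope_F": cmp_res.slope_F,
            "slope_p": cmp_res.slope_p,
            "parameters": {
                name: {
                    "test": t.test,
                    "statistic": t.statistic,
                    "p_value": t.p_value,
                    "significant": t.significant,
                }
                for name, t in cmp_res.parameters.items()
            },
        }
        (out / "comparison.json").write_text(json.dumps(report, indent=2))
        lines = pd.concat(
            [
                fp.per_unit_lines(pa).assign(group=groups[0]),
                fp.per_unit_lines(pb).assign(group=groups[1]),
            ]
        )
        lines.to_csv(out / "unit-parameters.csv", index=False)
    return result
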