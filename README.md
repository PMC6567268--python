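# angioprint

Quantitative analysis of 3D microvascular architecture ("microangioarchitecture")
from confocal z-stacks of immunostained vessels — for vascular-biology and
neuroscience labs that need to compare whole microvascular networks between
experimental groups (e.g. a disease model versus controls) rather than measure
vessels one by one.

## What it computes

Starting from a binary (or thresholded greyscale) isotropic stack, the
pipeline:

1. solidifies hollow/broken vessels with a size-capped 3D close-and-fill;
2. assigns every voxel a **caliber class** from the minimal area *a* of the
   vascular cross-section through it in the three Euclidean planes, using the
   geometric threshold ladder `T_k = round(4 · 1.8^k)` voxels — at 0.64 µm
   isotropic spacing the boundaries 1.6 / 2.9 / 5.3 / 9.4 / 17 / 31 / 56 µm²,
   i.e. theoretical vessel diameters from 1.4 to 8.4 µm, with a sub-offset
   seventh class used only for normalization;
3. rebuilds the network as **progressively reconstituted architectures**
   (cumulative unions of classes, largest calibers first), each quantified by
   its percent volume Vol%;
4. measures the **spatial dispersion** of each architecture as the number of
   structured dilation steps (rhombicuboctahedral scheme: the repeating
   6-/18-/26-neighbourhood cycle) needed to fill 95% of the volume — the
   Hv 95% index — normalized for signal amount against the densest sample to
   give **nHv 95%**;
5. fits the near-linear **fingerprint** nHv95 = c · Vol% + const over the six
   architectures and extracts seven parameters: left end (a, b), right end
   (e, f), projections d = e − a and g = b − f, and the slope c. A steep
   slope and short X-projection signal a rarefied network with increased
   intervascular distances;
6. compares groups: F-test for slope equality (ANCOVA on pooled points),
   unpaired t-tests for the amounts (a, d, e), Mann–Whitney with normal
   approximation for the dispersions (b, f, g).

A synthetic-data module (`angioprint.synthvasc`) grows random branching
capsule networks with known per-voxel caliber ground truth, including a
*rarefaction* mode that deletes small-caliber subtrees — so the whole chain is
testable without microscope data.

## Worked example

Compare a healthy-like cohort against a 50%-rarefied one (4 animals × 3
stacks each, 96×128×128 voxels at 0.64 µm):

```python
from dataclasses import replace
from angioprint import SynthConfig, make_cohort, StackInput, analyze_binary_cohort
from angioprint.fingerprint import compare_groups, per_unit_lines

healthy = SynthConfig(grid_shape=(96, 128, 128), n_roots=6)
rarefied = replace(healthy, rarefaction=0.5)
cohort = make_cohort(healthy, rarefied, n_units=4, stacks_per_unit=3, master_seed=11)
result = analyze_binary_cohort(
    [StackInput(c.unit_id, c.stack_id, c.group, c.stack) for c in cohort]
)
pts = result.points
wt, twi = pts[pts.group == "wt"], pts[pts.group == "twi"]
print(per_unit_lines(wt)[["unit_id", "slope", "r2", "a", "e", "d"]].round(3))
cmp = compare_groups(wt, twi)
print(f"slope F = {cmp.slope_F:.1f}, p = {cmp.slope_p:.2g}")
for name in ("d", "e", "g"):
    t = cmp.parameters[name]
    print(f"{name}: {t.test} p = {t.p_value:.4f} significant = {t.significant}")
```

Output (a few minutes on one CPU):

```
  unit_id  slope     r2      a      e      d
0   wt-u1 -3.669  0.918  1.345  4.873  3.528
1   wt-u2 -4.139  0.817  1.400  4.605  3.206
2   wt-u3 -4.473  0.935  1.370  4.310  2.939
3   wt-u4 -5.188  0.938  1.373  4.443  3.070
slope F = 12.9, p = 0.00046
d: t p = 0.0017 significant = True
e: t p = 0.0003 significant = True
g: mann-whitney p = 0.6650 significant = False
```

Each healthy animal's fingerprint runs from ~1.4 Vol% (largest vessels only)
to ~4.5 Vol% (all analyzed calibers) with slope ≈ −4: every caliber class
added fills the tissue and shortens intervascular distances at a steady rate.
The rarefied group's slope is significantly steeper (F-test p ≈ 5 × 10⁻⁴),
its X-projection d shorter and its right end e left-shifted — less signal
down to the smallest vessels — while the Y-projection g does not differ: the
small-vessel loss is spread through the volume rather than clustered.

There is also a CLI for file-based work:

```bash
angioprint synth --out-dir cohort/ --n-units 4 --stacks-per-unit 3
angioprint classify cohort/wt-u1-s1.tif --out labels.tif
angioprint dispersion cohort/wt-u1-s1.tif
angioprint run --config run.yaml     # full pipeline from TIFFs + grouping
```

## Documentation

`docs/methods.md` describes the model, parameter defaults and units, the
synthetic-network generator and its limits, and all numerical conventions
(threshold quantization, interpolation of fractional dilation steps,
normalization scope, degenerate-input handling).
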