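# Methods

`angioprint` quantifies the 3D architecture of a microvascular network — its
*microangioarchitecture* — from binary (or thresholded greyscale) confocal
z-stacks of immunostained vessels, reducing each stack to a near-linear
fingerprint in the (signal amount, spatial dispersion) plane. This note
documents the model, the parameters that matter, the numerical choices, what
the synthetic-data generator does and does not emulate, and the package's
known limitations.

## Pipeline model

1. **Isotropy and binarization** (`stacks_io`). Confocal stacks are sampled
   coarser axially than in-plane, so the z-axis is linearly resampled to the
   in-plane spacing (the target spacing equals the in-plane pixel size;
   default geometry 327 µm / 512 px = 0.64 µm). Morphology and dilation
   schemes below assume cubic voxels. Greyscale signal is binarized with the
   iterative-intermeans (IsoData-variant) threshold on a 256-bin whole-stack
   histogram, foreground strictly above the threshold. A constant stack has
   no threshold and is rejected explicitly. Thresholding runs after the
   isotropic conversion. The interpolation kernel of the resampling is
   linear: smooth, order-preserving and constant-preserving; results of
   other kernels would differ marginally.

2. **Close-and-fill** (`vessel_prep`). Immunostaining marks vessel walls, so
   lumina are dark and walls can be broken. Vessels are solidified by a
   3D morphological closing (default 2 dilations then 2 erosions with the
   full 26-neighbourhood, computed on a zero-padded grid so the closing is
   not distorted at stack faces) followed by cavity filling: every
   6-connected background component of the closed image that does not touch
   a stack face and is smaller than a cap (default 1200 voxels) becomes
   foreground. The cap prevents intervascular spaces from being mistaken for
   lumina; components touching a face are exterior by construction. The
   output is the union of the input with all additions — no observed voxel
   is ever removed. Complementary connectivities (26 for foreground, 6 for
   background) avoid topological paradoxes. The cap is applied once, after
   the complete closing, not inside each cycle.

3. **Caliber classification** (`caliber`). Every foreground voxel is scored
   by the *minimal projected cross-section*: the smallest of the three
   2D 8-connected foreground components containing it in the axis-aligned
   planes (8-connectivity keeps a thin oblique vessel one cross-section).
   Class boundaries form a geometric ladder: `T_k = round(offset · ratio^k)`
   voxels, defaults offset = 4 voxels (1.64 µm² at 0.64 µm spacing, a
   theoretical circular diameter of 1.4 µm), ratio = 1.8, six analyzed
   classes. Integer-voxel rounding at every rung is deliberate — it is the
   only quantization that reproduces the conventional printed boundaries
   1.6/2.9/5.3/9.4/17/31/56 µm² (unrounded, 4·1.8³·0.41 would give
   9.56 µm², not 9.4). Class intervals are half-open and upper-inclusive
   (`T_low < a ≤ T_high`). Cross-sections at or below the offset form a
   seventh *sub-offset* class used only for normalization; cross-sections
   above the top threshold (over-range) are excluded from every architecture
   and from normalization. Classification runs on the filled map; the labels
   are then intersected with the original binary signal so only observed
   voxels are analyzed.

4. **Progressive architectures** (`progressive`). The classified signal is
   rearranged into nested cumulative trees: architecture k is the union of
   classes 1..k (largest calibers first), intersected with the original
   signal. The six analyzed architectures are the fingerprint's points; the
   *normalizing total* (classes 1..7) is used only to equate signal amounts.
   Percent volume (Vol%) is foreground voxels over all voxels × 100.

5. **Dispersion index** (`dispersion`). The spatial dispersion of a signal
   is the number of structured dilation steps needed to occupy a target
   fraction of the volume (targets 90/95/99%; the 95% index is the analysis
   index). Steps cycle through the 6-, 18- and 26-neighbourhood structuring
   elements; the three-step composite growth solid (the Minkowski sum
   cube ⊕ octahedron ⊕ cuboctahedron) is a rhombicuboctahedral polyhedron
   approximating isotropic Euclidean growth. The scheme is a named, pluggable
   strategy, and all compared samples must use the same one. Fractional steps
   are resolved by linear interpolation between the bracketing occupancies:
   with v_k the occupancy after step k and v_k the first to reach target p,
   the raw index is `(k−1) + (p − v_{k−1})/(v_k − v_{k−1})`. Dilation is
   clipped at the stack faces — the reference volume is the acquired field.
   The raw index confounds amount with dispersion, so it is normalized: the
   *normalizing image* is the total architecture of the sample with the
   maximal Vol% among all samples being compared (both groups jointly by
   default; per-group normalization is available behind a flag), and the
   offset subtracted from each sample's raw counts is the fractional number
   of steps needed to dilate that sample from its own Vol% up to the
   normalizing Vol%, with the same interpolation rule. The normalizing
   sample itself therefore always has offset 0. An exact Euclidean distance
   transform would measure a related but different quantity; the iterated
   dilation scheme *is* the method here, and absolute index values are
   scheme-dependent even though comparative conclusions (slopes,
   differences) are scheme-stable.

6. **Fingerprint and statistics** (`fingerprint`). For each analysis unit
   (animal), the (Vol%, nHv95) points of its stacks' six architectures are
   pooled and fitted by ordinary least squares. Seven interdependent
   parameters summarize the line: the left-end point (a, b) — amount and
   dispersion of the largest-caliber vessels; the right-end point (e, f) —
   amount and dispersion of the whole analyzed tree; the projections
   d = e − a and g = b − f — the contribution of the smaller calibers to
   amount and dispersion; and the slope c — the rate at which intervascular
   distances shrink as smaller calibers are deployed (shallow = packed,
   steep = rarefied). The endpoint X positions are the mean Vol% of the
   first and last architectures over the unit's stacks; the endpoint Y
   values are read off the fitted line at those positions (a raw-point
   option exists). Two groups are compared with: an ANCOVA-style F-test for
   slope equality on the groups' pooled points (full model with separate
   slopes vs reduced model with a common slope; F on (1, n−4) df); unpaired
   two-sided t-tests for the amount-like parameters a, d, e; and two-sided
   Mann–Whitney tests under the normal approximation for the dispersion-like
   parameters b, f, g. The Mann–Whitney default uses the continuity
   correction and no tie correction (dispersion indices are effectively
   continuous); both are toggleable. Per-unit slopes are reported
   descriptively; the inferential slope comparison is the pooled F-test.
   Differences are flagged at p < 0.05 with no multiple-testing correction.

## Synthetic vascular networks (`synthvasc`)

Real stacks of this kind are rarely public, so the generator grows random
branching capsule trees with a fully known geometry, designed to emulate the
statistical structure the analysis assumes: a space-pervading hierarchical
network whose cross-sections populate the whole analyzed caliber range and
whose progressive architectures produce a near-linear fingerprint.

* **Roots.** `n_roots` seed vessels (default 14 on the default
  96×192×192-voxel grid at 0.64 µm) of radius `root_radius_um`
  (default 3.2 µm, i.e. a perpendicular cross-section of ~78 voxels, inside
  the largest analyzed class even for oblique cuts) are placed on a jittered
  in-plane grid. Stratified placement mirrors the fairly even spacing of
  penetrating vessels in real tissue and keeps the large-caliber
  architecture statistically comparable between stacks.
* **Growth.** Segments of mean length 10 µm advance with a bounded turning
  angle (≤ 40° per segment; capillary paths are locally smooth). Branching
  occurs at near-regular intervals (mean spacing 1/`branch_prob` segments,
  default ≈ 1.8, with ±1 segment of jitter); each bifurcation multiplies the
  radius by `taper` (default 0.73) with a log-normal jitter (σ = 0.10) so
  calibers vary continuously rather than in powers of the taper. Branches
  thinner than 0.7 µm are pruned.
* **Boundaries.** A tip crossing a stack face is reflected back inside. The
  acquired field is a crop of a statistically stationary network — vessels
  leaving the field are balanced by vessels entering it — and reflection
  emulates that balance without modelling the exterior. (With absorbing
  boundaries, trees truncate at random depths, the thin-caliber classes
  starve, and stack-to-stack variability grows several-fold.)
* **Rarefaction.** The disease-like condition deletes a fraction
  (`rarefaction`) of the terminal small-caliber subtrees: a subtree is
  eligible where the vessel radius first drops below
  `rarefaction_radius_um` (default 1.7 µm — the disk radius at the 9.4 µm²
  boundary between the mid and small analyzed classes), and a selected
  subtree is removed whole. This thins the three smallest caliber classes
  while leaving larger vessels in place, the physical picture of capillary
  rarefaction. Growth consumes its random draws before rarefaction does, so
  two configs differing only in `rarefaction` share the same underlying tree
  and the rarefied stack is a strict subset of its dense twin.
* **Rasterization.** A voxel is foreground when its center lies inside at
  least one capsule; the ground truth records every generating segment and a
  per-voxel map of the largest covering radius.

Defaults produce stacks with ~5–7 Vol% of signal, all six analyzed classes
populated, roughly a third of the analyzed signal in the three smallest
classes, and a median per-stack fingerprint R² of ~0.98.

**What the generator does not emulate:** imaging noise and staining dropout
(stacks are clean rasterizations — the close-and-fill stage is exercised by
dedicated hollow-wall fixtures instead), anastomoses and capillary loops
(trees only), hemodynamics, intussusceptive remodelling, and anisotropic
point-spread blur. Passing tests on synthetic cohorts therefore demonstrate
the correctness and discriminative behaviour of the measurement chain on
model-conforming networks, not the biological effect sizes of any real
tissue.

## Numerical and design choices

* Threshold quantization to integer voxels, upper-inclusive class intervals,
  and the 6/18/26 dilation cycle are fixed conventions documented above.
* The fingerprint uses the six analyzed architectures as points; the
  sub-offset-inclusive total is a normalization device, not a plotted point
  (`include_suboffset_point` switches to the seven-point variant).
* Degenerate inputs are explicit: constant stacks cannot be thresholded;
  empty stacks cannot be dilated; an empty architecture yields NaN dispersion
  rows rather than aborting a cohort; zero-variance t-tests are flagged
  degenerate instead of returning infinities silently.
* The normalizing image may not have a smaller Vol% than the sample being
  normalized (it is maximal by construction); violating calls raise.
* Seeds: cohorts derive per-stack seeds from one master seed by fixed
  arithmetic, so any single stack is reproducible in isolation.

## Problem sizes used by the test suite

Synthetic checks run at the default 96×192×192 grid for the linearity
property (median per-stack R² over six to ten stacks) and at a reduced
96×128×128 grid with 6 roots (the same root density) for the two-group
experiments: one 4-animal × 3-stack cohort per condition for the
rarefaction signature, and a pool of 24 independent same-condition animals
re-partitioned into 300 random 4-vs-4 comparisons for the null calibration
of the slope test. At fields much smaller than ~80 µm across, the sparsest
architecture spans only a few intervascular distances, the near-linear model
itself degrades and the pooled slope F-test becomes anti-conservative; the
reduced grid was chosen as the smallest that preserves the model structure.

## Known limitations

* The absolute nHv values depend on the dilation scheme; only a scheme
  identical to the original plugin's unpublished element sequence would
  reproduce absolute historical values. Slopes and group contrasts are
  scheme-stable.
* The pooled slope F-test treats all points of a group as exchangeable; with
  strongly heterogeneous animals it is anti-conservative (its null rejection
  rate exceeds α). The per-unit parameter tests (t, Mann–Whitney) do not
  share this caveat. Users with heterogeneous cohorts should read the
  per-unit slope distributions alongside the pooled test.
* `min_cross_section` measures plane sections, so oblique vessels are scored
  by an enlarged (1/cos θ) section; the caliber ladder absorbs this by
  construction (classes are bands, not exact diameters), but per-vessel
  diameters are out of scope.
* The generator grows trees; it guarantees no loops, so graph-theoretic
  vascular metrics (redundancy, collateralization) cannot be validated with
  it.
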