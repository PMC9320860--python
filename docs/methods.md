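# Methods

This note records the model behind `ebusreg`, the conventions and
numerical choices the implementation fixes, what the synthetic phantoms
do and do not emulate, and the known limitations.

## Device model and conventions

A pose is `p = (a, b, c, tx, ty, tz)`: intrinsic Z–Y–X Euler angles in
degrees (wrapped to (−180, 180]) and a world position in mm. In the
canonical body frame the bronchoscope tip axis `nB` is +z and the
ultrasound probe axis `nUS` is +x; the pose's rotation maps this frame
into the world. Derived quantities:

* camera axis `nC = cos Δ · nB + sin Δ · nUS`, i.e. tilted by
  Δ (default 20°) within the tip–probe plane, toward the fan;
* probe-plane origin `sUS = sB + offset · nB` (default offset 6 mm);
* fan plane spanned by `nUS` and an in-plane "up" vector, chosen as
  `up = nB` so the scan plane contains the scope axis — matching the
  physical device, where the fan extends forward of the probe.

The Euler convention, the `up` choice, and the plane of the camera tilt
are all conventions the hardware documentation does not force; each is
fixed once here, tested by an independent rotation-matrix oracle and an
Euler round-trip, and configurable where it matters (`FanSpec`).

The rendered raster puts the fan apex at pixel `(0, width // 2)` with
the central ray pointing down the image and `up` toward increasing
column. Default raster 300 × 300 with pixel spacing `range / height`
(0.1333 mm/px for the 40 mm range), so the full depth fills the image.

## Rendering

Virtual views resample the CT over the fan plane: trilinear
interpolation for HU (then an affine window onto 256 gray levels),
nearest-neighbour for labels (preserving the binary ROI). The default
window [−1000, 200] HU spans air through airway-wall attenuation; the
transfer function is a free choice — registration only sees gray-level
co-occurrence statistics — and is exposed in the config. Rounding is
round-half-to-even (the default window midpoint −400 HU maps to 128).
Out-of-fan and out-of-volume pixels are 0. Volumes are treated as
axis-aligned (`world = origin + index · spacing`); rotated direction
cosines are out of scope, which is adequate for the phantoms and a
documented limitation for clinical volumes.

## Cost

`C = CN − CD` with `CN = 1 − (h(a) + h(b)) / h(a, b)` from 256-bin
hard-binned histograms (no Parzen smoothing; an ε-per-bin option exists
for experiments) and `CD` the Dice overlap of the ROI masks. Natural
logarithms — the entropy ratio is base-invariant. Note that since
`max(h(a), h(b)) ≤ h(a,b) ≤ h(a) + h(b)`, `CN` actually lives in
[−1, 0]: −1 for perfectly correlated images and → 0 in the independence
limit. The often-quoted upper value 1 ("no correlation") is not
attainable from the formula; the package documents and tests the
correct limit. `C` therefore spans [−2, 0] ⊂ [−2, 1] in practice.

Histogram pixels are restricted to the smallest polar box
`[r_lo, r_hi] × [θ_lo, θ_hi]` about the fan apex that bounds the EBUS
frame's segmented ROI, clipped to the fan — the natural axis-aligned box
in fan coordinates, uniquely defined, whose raster footprint is the
familiar trapezoid. The box is computed once per registration from the
EBUS ROI (the text's singular construction) and reused for every
candidate virtual view. Degenerate ROIs are expanded to ≥ 8 px radially
and in arc length so region entropies stay meaningful. Dice of two
empty masks is defined as 0 (no evidence of overlap). The virtual view
is rendered directly in the frame's raster geometry, so no extra
resampling precedes the joint histogram.

## Wall constraint

Candidate poses must touch the airway wall. The operative point is the
probe-plane origin `sUS`; after any wall adjustment the pose position is
recomputed as `sUS − offset · nB`, and angular components are kept as
generated. Three mechanisms:

* **Ray march**: advance along a ray in steps of half the minimum voxel
  spacing until the containing voxel's HU exceeds −600 (air ≈ −1000,
  wall 50–200; −600 is deliberately conservative). Accuracy is bounded
  by the step; the origin's own voxel is tested first.
* **Projection**: nearest surface voxel `ps` by exact k-d tree query
  (ties to the lowest index, verified against brute force). A candidate
  already above threshold and within 1 mm of `ps` is accepted unchanged
  (walls are thicker than the one-voxel surface layer). Otherwise, if
  `(pv − pi) · (pv − ps) > 0` the projection is on the same branch as
  the reference `pi` and `ps` is used; if not, the nearest centerline
  point to `pi` is found and the ray from it toward `pv` is marched to
  the wall. The fallback search starts at the centerline point, as the
  branch-test construction reads.
* **Initial simplex**: the wall-adjusted `pi` plus six vertices, each
  perturbing one pose parameter by its increment — defaults 2.5 mm and
  25°, the sensitivity protocol's step sizes — then wall-projected.

## Optimizer

Standard Nelder–Mead coefficients (α = 1, γ = 2, ρ = 0.5, σ = 0.5);
the source method does not state its coefficients, so the textbook
values are adopted and exposed. Angles are scaled to mm-equivalents
through a characteristic length equal to the probe range (40 mm →
0.698 mm/°) so one simplex geometry covers all six parameters. Every
geometric move is wall-projected *before* evaluation; a projection
failure rejects the move and falls through to a shrink (a failed shrink
vertex stays put). Cost is evaluated at the projected pose with its
orientation as generated. Termination: the inner loop stops when the
best vertex's wall-voxel index is unchanged for `T` consecutive
iterations (voxel-level stability, consistent with the outer criterion);
the outer loop restarts the simplex from the optimum until the voxel
containing it stops changing. Safety caps (500 inner iterations, 20
restarts) return the best-so-far with a status flag. Ties in cost go to
the lowest vertex index; the optimizer is deterministic and uses no
randomness. The reported trace is the running best cost and is
non-increasing by construction.

Degenerate regions (both images constant over the trapezoid) make `CN`
undefined; the cost layer raises unless the caller opts in to treating
them as perfect correlation (−1). The registration loop opts in: such
poses arise transiently at extreme candidate positions and must not
abort the search.

## Error metrics

`ep = ‖po − pG‖`, `ed = arccos(do · dG)` in degrees, and
`eN = ‖(po + lN do) − (pG + lN dG)‖` for a needle extended `lN` along
each direction. The direction vector defaults to the probe axis `nUS`
(the needle exits along the scan plane); the tip axis is selectable.
`lN` defaults to 20 mm — a typical transbronchial needle throw; every
report prints the `lN` used. The triangle bound
`eN ≤ ep + 2 lN sin(ed/2)` is property-tested.

## Phantoms and the pseudo-EBUS simulator

The phantom is a straight (optionally Y-branched) air tube of 8 mm
inner radius and 2 mm wall (125 HU) through soft tissue (40 HU), with
an ellipsoidal node (30 HU, default semi-axes 6 × 8 × 7 mm — long axis
16 mm, matching clinically targeted nodes) pressed against the wall and
a 4 mm vessel (60 HU) opposite, plus 10 HU Gaussian noise. Default grid
160 × 160 × 200 at 0.7 mm isotropic — clinical-CT-like resolution at a
volume small enough for desk-scale runs. The node is deliberately
low-contrast against tissue so the Dice term, not raw intensity, drives
registration — mirroring the clinical rationale for the combined cost.
Ground-truth poses sit with `sUS` exactly at a wall-voxel centre
(reached by marching from the centerline toward the node centroid) with
`nUS` aimed at the node, so wall adjustment is a bitwise fixed point of
each ground-truth pose and self-registration can be checked for exact
recovery.

The pseudo-EBUS simulator inverts the rendered gray values (node
hypoechoic), applies exponential depth attenuation (0.015/mm), mean-one
multiplicative Rayleigh speckle (blended at weight 0.5), and a 1 px
Gaussian blur. The speckle stays in the linear domain without log
compression so the ensemble mean converges to the clean frame — a
property the tests verify — at the cost of a less compressed dynamic
range than a real scanner displays. The frame's ROI mask is copied from
the clean rendering, standing in for an external EBUS-frame segmenter.
None of this claims acoustic realism: no refraction, shadowing,
directional scattering, or transducer point-spread; passing tests show
the optimizer's behaviour under geometric truth plus heavy multiplicative
noise, not performance on clinical frames.

## Sensitivity harness

One parameter at a time over the protocol ranges (positions ±10 mm step
2.5 mm; angles ±100° step 25°; `T` 5…25 step 5), aggregated as
mean ± std and [min, max] per metric, one row per value. Whether a swept
Δ sets the initial-pose offset or the simplex increment is genuinely
ambiguous in the protocol's phrasing; both modes are implemented, with
offset as the default (runs start at the ground-truth pose and are then
displaced).

## Problem sizes used in the shipped checks

The automated checks run self-registration over 10 wall poses, pose
recovery over 10 perturbed trials (≤ 5 mm / 25°, speckled frames),
brute-force grid parity over 3 cases with a 3⁶-point 5 mm / 15° grid,
and a two-point `T` trend with 6 trials per value, all on the default
phantom — sizes chosen to give stable medians on a single CPU in a few
minutes.

## Known limitations

* Axis-aligned volumes only (identity direction cosines).
* The fan's roll about `nUS` is a convention; real probes may be
  mounted rotated, which a config rotation would absorb.
* The phantom airway is a cylinder/Y-tube, not an anatomic tree; the
  wrong-branch fallback is exercised by a two-tube construction rather
  than realistic branching geometry.
* EBUS-frame ROI segmentation is an input, not provided here.
* Single-threaded reference implementation; no GPU paths.
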