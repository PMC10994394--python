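# Methods

## Problem and measurement principle

In hospital pharmacy dispensing (e.g. a Pharmacy Intravenous Admixture
Service), a prescribed liquid volume is drawn into a syringe and must be
verified. Reading the printed graduations from a photograph is unreliable:
the scale may face away from the camera, be washed out by lighting, or be
occluded, and the piston often sits between two marks. `syrdose` instead
measures the *geometry* of the syringe silhouette. Three landmarks are
located in the image — the barrel vertex at the tip end `(x1, y1)`, the
piston position `(x2, y2)`, and the barrel vertex at the other end
`(x3, y3)` — and the recognized dose is the distance ratio

    L = d((x1,y1),(x2,y2)) / d((x1,y1),(x3,y3)) * R

where `d` is the Euclidean pixel distance and `R` the syringe's nominal
capacity in ml. Because the estimate is a ratio of distances within one
image, it is invariant to translation, in-plane rotation and scale, and it
never needs the graduations themselves.

Assumptions: one syringe per image, viewed side-on (no perspective
foreshortening), barrel fully inside the frame, on a background that
contrasts with the barrel; the graduated section of the barrel spans the
nominal capacity linearly, so the piston's fractional position along it
equals the drawn fraction of capacity.

## Pipeline

1. **Grayscale** — Rec.601 luma (0.299, 0.587, 0.114), rounded to the
   nearest integer in [0, 255].
2. **Otsu threshold** — the gray level `k` maximizing the between-class
   variance `w0*w1*(mu1-mu0)^2` over all splits `C0 = {i < k}`,
   `C1 = {i >= k}`; ties broken toward the smallest `k`. The within-class
   variances are computed and reported (they complete the total-variance
   decomposition used in testing) but play no role in selection.
3. **Polarity** — whichever binary class touches fewer image-border pixels
   is taken as the syringe. This replaces any manual background
   preparation: a syringe photographed on a tray never touches the frame.
4. **Morphology** — opening (erosion then dilation) removes specks such as
   graduation marks and noise; closing (dilation then erosion) bridges
   pinholes and narrow gaps; hole filling turns enclosed background
   pockets into foreground. Flat 3x3 square structuring element by
   default.
5. **Gaussian smoothing** — discrete kernel sampled from
   `exp(-(x^2+y^2)/(2*sigma^2))`, renormalized to sum 1 (sigma 1.0 px,
   5x5 by default), convolved with reflect padding, then re-binarized at
   0.5 to hand a crisp silhouette to the corner detector.
6. **Harris corners** — Sobel gradients (reflect padding); structure
   tensor accumulated under a Gaussian window (sigma 1.0 px); response
   `CRF = det(M) - k*tr(M)^2` with sensitivity k = 0.04; keep responses
   at or above 1% of the global maximum; greedy non-maximum suppression
   with Chebyshev radius 5 px, ties broken by (row, column).
7. **Landmarks and dose** — described next.

## Landmark selection

The barrel axis is taken from the minimum-area bounding rectangle of the
largest silhouette component (rotating calipers over the convex hull).
A mass-covariance eigenvector was tried first and rejected: when an
occluder band over the graduations makes the silhouette asymmetric across
the axis while the liquid column makes it asymmetric along the axis, the
eigenvector tilts by several degrees and downstream scans leave the
barrel interior. The bounding-rectangle axis is exact for a rectangular
barrel regardless of interior content, and its center gives the true
centerline even when the silhouette's mass is lopsided.

Corners are projected onto the axis. The tip and end vertices are the
corners at the extreme projections (within 4 px of the silhouette's own
extent), chosen as the pair lying on the same barrel side. Which extreme
is the tip is decided by liquid coverage: a thin corridor (half-width
2 px) along the centerline is foreground (liquid, then piston) next to
the tip and empty (air gap) next to the end, so the end windows (15% of
the span each) are compared by corridor coverage. `tip_end = left|right`
overrides this when a scene is known.

The piston landmark is the corner nearest the corridor's
foreground-to-background transition — the junction between the piston's
air-side face and the barrel wall — preferring, among corners at the same
axial position, the one on the tip vertex's barrel side (a graduation
mark ending at the same position sits nearer the axis and is thereby
rejected). The *air-side* face is used because liquid and piston merge
into one foreground block in the silhouette: only that face produces
corners. At least three corners, extreme corners at both ends, and a
corner within 6 px of the transition are all required; otherwise the
measurement fails with "landmarks not found" rather than guessing.

**Axial refinement.** Harris response peaks on a smoothed, re-binarized
silhouette sit up to ~1 px inside their corner, and the three biases are
coherent, so the raw ratio is biased by roughly `2*delta/L`. At 20 ml
capacity and a 420 px barrel, a 1 px coherent bias is ~0.05 ml — visible
in the second decimal. The corner set therefore fixes landmark *roles*
and barrel side, while each landmark's along-axis coordinate is snapped
to the silhouette itself: the foreground extent for tip and end, the
corridor transition for the piston, each with a half-pixel correction
(a pixel spans ±0.5 around its index). With this refinement the recovered
ratio is exact whenever the rendered edges are, and doses reproduce to
0.01–0.02 ml.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `levels` | 256 | gray-level count L |
| `se_size` | 3 | structuring element side (px, odd) |
| `gaussian.sigma` | 1.0 | smoothing scale (px) |
| `gaussian.size` | 5 | smoothing kernel side (px, odd) |
| `harris.window_sigma` | 1.0 | structure-tensor window scale (px) |
| `harris.sensitivity` | 0.04 | Harris k, classical 0.04–0.06 range |
| `harris.rel_threshold` | 0.01 | response cut as fraction of max |
| `harris.nms_radius` | 5 | corner suppression radius (px) |
| `tip_end` | auto | which image side holds the tip |
| `rounding` | 2 | reported decimals (ml) |

Defaults favor a crisp binary silhouette: small smoothing preserves
corner localization; the 1% response threshold keeps all genuine barrel
and piston corners (their responses are within a factor ~40 of each
other) while discarding edge noise.

## The synthetic scene generator

No public photograph set accompanies the measurement task, so validation
uses a deterministic renderer whose ground truth is exact. A scene is the
graduated barrel section viewed side-on: wall strips (6 px at the
480x640 reference size) open at both ends (nozzle and plunger rod out of
frame), a liquid column flush with the tip-end vertex, a dark piston band
whose air-side face sits exactly at `fill_fraction` of the barrel length,
and graduation ticks on one wall. Gray palette: background 230, wall 120,
colorless liquid 170, colored liquid 80, piston 40, ticks 20 (210 when
light-washed), occluder band 160. The palette was chosen by between-class
variance analysis so that Otsu's split always lands between the syringe
and the background: the occluder must stay lighter than the colorless
liquid, or a large occluded region drags the threshold below the liquid
intensity and the silhouette loses the liquid column entirely.

Scenario knobs mirror the degraded conditions a dispensing bench
produces: `scale_marks` visible / blurred (light-washed ticks) /
occluded (a band hiding the whole graduation strip), in-plane rotation
(nearest-neighbor, exact landmark transform), additive Gaussian noise
(sigma in gray levels, clipped), and random rectangular erasures. The
seed fully determines a scene; renders are byte-reproducible.
`table_scenarios()` enumerates the full validation grid — 2 liquid types
x capacities {5, 10, 20} ml x 10 scenario groups (visible scale,
piston between marks, washed-out scale, occluded scale).

What the renderer does **not** emulate: perspective and lens distortion,
specular highlights on the barrel, meniscus curvature, partial
transparency of the walls, soft shadows, and cluttered backgrounds.
Passing the synthetic suite therefore demonstrates the geometric method
and its noise/occlusion robustness, not performance on real photographs;
on real images the binarization step is the likely failure point and the
palette margins here say nothing about it.

## Numerical choices and degenerate inputs

- Threshold search over k in [0, 255]; a single-occupied-level histogram
  raises "degenerate image" (an all-white frame has no silhouette).
- Erosion pads the border with foreground, dilation with background.
  Under this convention closing is exactly the complement-dual of
  opening on every mask, border pixels included; padding both with
  background breaks duality in the border ring.
- Hole filling uses 4-connectivity for the background, so diagonal
  background leaks do not fill.
- Convolutions (smoothing, structure tensor) use reflect padding.
- Rounding of the reported dose is half-away-from-zero at 2 decimals.
- Corner ties in non-maximum suppression and all landmark tie-breaks are
  lexicographic in (row, column), making every result scan-order
  independent and reproducible.
- An isotropic silhouette (bounding-rectangle aspect below 1.5) has no
  usable axis and raises "no principal axis".

## Validation summary

The test suite checks each stage against independent oracles (brute-force
histogram tally, exhaustive threshold scan, sliding-window morphology,
border flood fill, direct convolution, Sobel stencil), algebraic
invariants (duality, idempotence, variance decomposition, Cauchy-Schwarz,
transpose symmetry), and end-to-end recovery: on 50 seeded scenes with
fill fractions uniform in [0.1, 0.95] and capacities {5, 10, 20} ml the
recognized dose stays within 2% of capacity on clean scenes and within 5%
with noise sigma 10 plus a fully occluded scale; reference scenes
reproduce their expected doses to 0.02 ml; rotations {0, 15, 45, 90} deg
and scales {1x, 1.5x, 2x} of a fixed scene move the dose by at most
0.05 ml. Problem sizes: 480x640 px scenes (up to 960x1280 in the scale
sweep), chosen to match the renderer's reference geometry.

## Known limitations

- Fill fractions above ~0.95 leave too little air gap for reliable
  tip-end disambiguation; `tip_end` should be forced in that regime.
- A completely full or completely empty syringe has no interior
  transition distinct from the barrel ends; doses at the extremes are
  reported but the piston-width offset (16 px at reference scale)
  bounds accuracy near zero fill.
- The method reads one syringe; multiple syringes or a needle in frame
  would corrupt the principal-axis estimate (the largest connected
  component wins).
- Out-of-plane tilt violates the linear-scale assumption and biases the
  ratio; the renderer cannot express it, so it is untested.
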