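# Methods

## Problem and measurement model

Chronic-wound care tracks the wound surface area over weeks: the percentage
contraction in the first two to four weeks of treatment is an established
predictor of whether a wound will heal under the current regimen.  The input
to this package is not a photograph of the wound but a *tracing*: the
clinician lays a transparent ruler printed with a 1 cm² grid over the wound
and draws the wound margin with a pen; the sheet (22.0 × 17.0 cm, 374 cm² of
ruled area by default) is then scanned.  The package automates the
planimetry of that scan and the downstream healing statistics.

The automated pipeline is:

1. **Binarize** the grayscale scan into an ink mask (Otsu threshold by
   default; a fixed threshold can be supplied).  Ink is assumed dark on a
   light background.
2. **Calibrate** the pixel scale from the grid itself.  Ink pixel
   coordinates are projected onto each axis after a small deskew-angle
   search; grid rules appear as tall narrow peaks in the projection
   profiles and the scale is the median inter-peak spacing divided by the
   cell size, independently per axis (anisotropic pixels are allowed).
   This removes the manual "tell the software what 1 cm is" step and with
   it one source of user variability.
3. **Remove the grid rules** with axis-aligned line openings, then restore
   the stroke pixels cut where the pen crosses a rule.
4. **Close** residual pen gaps with a disk closing (`max_gap`, default
   0.25 cm).
5. **Fill the exterior** from the image border (4-connected flood) and keep
   the single enclosed region as the wound interior.

Area is the interior pixel count divided by the product of the axis scales;
perimeter, principal axes (C = maximum Feret diameter, L = maximum width
perpendicular to C) and the grid-square count are measured from the same
mask.  The classical bedside estimators are computed from C and L: the
rectangle C × L and the Kundin ellipse C × L × 0.785.  The constant is kept
at exactly 0.785 — the value used in bedside arithmetic — rather than
π/4 = 0.7853981…, so hand-worked examples reproduce digit for digit.  A
consequence worth knowing: for a shape that *is* an exact ellipse, the
Kundin estimate lands ~0.05% below the true (pixel) area, so the intuitive
ordering rectangle ≥ Kundin ≥ pixel area holds only up to that margin at
the ellipse equality case.

## Healing statistics

For a weekly area series S0, S1, … the contraction statistic is

    CO_i = 100 · (S0 − S_i) / S0        (percent; negative = growth)

and the normalized trajectory is S_i / S0 ≡ 1 − CO_i/100.  Four literal
threshold rules classify a series as `predicted_to_heal` / `reassess` /
`indeterminate`:

| rule | criterion (inclusive bounds) |
|---|---|
| `weekly_10_15` | mean week-over-week contraction ≥ 10% |
| `two_week_25` | CO at week 2 ≥ 25% |
| `two_to_four_week_20_40` | CO reaches ≥ 20% in weeks 2–4 |
| `four_week_40` | CO at week 4 ≥ 40%, else reassess |

Two aggregation choices were genuinely open and are resolved as follows.
The weekly rule averages the *week-over-week* contractions
100·(S_{i-1} − S_i)/S_{i-1} (each week measured against its own baseline),
since a per-week rate stated without aggregation most naturally compounds.
Range boundaries are inclusive — reaching the quoted lower bound counts as
predicted to heal — the conservative-to-heal reading of ranges quoted
without open/closed qualification.  `indeterminate` is returned only by the
2–4-week rule when the threshold is unmet but the series ends before week 4
(the window is still open).

Method comparison follows the standard planimetric-agreement layout: signed
percent differences of each estimator against a chosen reference, signed
per-method means (absolute-error means are reported alongside, never
instead), and pairwise Pearson correlations of the per-wound area vectors.

## Synthetic traces and what they do (not) show

The generator renders the ruled sheet plus a closed pen stroke for circles,
ellipses and seeded irregular "blob" outlines (radial perturbation
r(θ) = r0·(1 + Σₖ aₖ sin(kθ+φₖ)), k = 2…6, spectral decay set by a
smoothness exponent, total amplitude capped at 60% of r0 so the curve stays
simple).  Ground truth is the shoelace area and edge-length perimeter of
the polygon itself, i.e. of the stroke **centreline**.  Defaults — 100
px/cm scan resolution, 0.03 cm stroke, 0.02 cm rule thickness — are
realistic choices of ours; no clinical scan parameters were published.
Rendering is binary (no anti-aliasing) by default so binarization is exact
in tests; Gaussian intensity noise and an anti-aliased rim are optional.

The generator emulates the geometry and the grid, not the appearance, of a
clinical scan: there is no exudate staining, skin texture, uneven pen
pressure, sheet wrinkling or perspective distortion.  Passing the synthetic
suite therefore demonstrates the correctness of the calibration,
segmentation and measurement chain at known scale and geometry — not
robustness to photographic artefacts.

## Numerical choices

- **Interior convention.**  The wound interior is everything enclosed by
  the stroke, *excluding* the stroke: measurement to the stroke's inner
  rim.  This is deliberately conservative and biases area low by about
  perimeter × stroke_width/2 (≈0.3% at 20 cm², ≈3% at 4 cm²).  Accuracy
  tests therefore compare against the centreline truth shrunk by half a
  stroke width; with that correction the pipeline is accurate to a few
  tenths of a percent across 4–50 cm².
- **Perimeter modes.**  `edge_count` sums exposed pixel-face lengths — the
  literal adjacency rule.  It is exact for axis-aligned rectangles but
  converges to the Manhattan length on smooth curves (8r for a circle of
  radius r, a 4/π ≈ 27% overestimate); it is retained, labelled, as the
  faithful reading of pixel-adjacency counting.  `contour` (default)
  measures the marching-squares boundary polyline after a circular moving
  average over 7 vertices, which suppresses the residual stair-step; on
  digitized disks it is accurate to well under 1%.
- **Grid-rule detection.**  Line openings use a structuring element 1.6×
  the calibrated cell spacing.  Rules span the whole sheet and survive;
  a pen stroke tangent to a rule stays within one pixel row for only about
  2·√(2Rw) px (R = curvature radius, w = stroke thickness) — roughly
  100 px at R = 3 cm — and cannot be matched.  Detection is additionally
  restricted to ±4 px bands around the detected rule positions when the
  scan is not rotated.
- **Crossing restoration.**  Removed pixels are restored where they fall
  inside a 12 px disk closing of the surviving trace.  The closing bridges
  perpendicular crossings (gap = rule thickness) and the longer cuts left
  where the stroke runs almost parallel to a rule, but cannot reach the
  rule stubs flanking the stroke, which stay deleted.  An unbounded
  geodesic reconstruction would regrow the entire rule (rules touch the
  stroke at crossings) and is deliberately avoided.
- **Residual tangency.**  Where the stroke runs exactly *along* a rule the
  overlapping pixels are removed with the rule; `max_gap = 0.25` cm
  re-closes the boundary there.  The stroke should be drawn thicker than
  the rule (defaults: 0.03 vs 0.02 cm), otherwise a stroke perfectly
  centred on a rule can vanish into it.
- **Connectivity.**  Ink is 8-connected (diagonal pen strokes stay
  connected); the exterior flood fill is 4-connected (it cannot leak
  through a diagonal joint) — the standard duality.
- **Deskew.**  The grid angle is found by maximising projection-profile
  sharpness over a coarse-then-fine angle scan; because the score is
  flat-topped, the smallest |angle| within 0.1% of the maximum wins (plain
  argmax picks spurious ±0.1° angles that smear 1-px rules at low
  resolution).  Angles ≤ 3° are only reported; larger angles trigger a
  bilinear resampling to upright before segmentation.
- **Ambiguity handling.**  If no enclosed region ≥ 0.1 cm² exists the
  boundary is reported open; if several exist (e.g. nested rings) the
  candidate areas are reported in an explicit error instead of silently
  picking the largest-but-one interpretation.
- **Calibration guards.**  At least 4 rules per axis are required; a
  spacing coefficient of variation above 20% is rejected as unreliable.
  Median (not mean) spacing tolerates a missed rule.

## Problem sizes used in the checks

The accuracy suite runs 20 seeded traces (7 circles, 6 ellipses, 7 blobs;
areas ≈ 4–50 cm²) rendered on the full default sheet at 100 px/cm — a
2200 × 1700 px raster per trace, the size of a real 100 dpi-per-cm scan —
and segments each end to end.  Staircase-limit convergence is checked on
digitized disks at 50–200 px/cm.  These sizes were chosen to exercise the
same pixel counts as clinical scans while keeping the whole suite under a
minute of compute.

## Known limitations

- Input must be a traced boundary on the ruled sheet; the package does not
  segment wound photographs.
- Depth/volume (the accessory millimetre ruler of the physical device) is
  out of scope, as are perspective and lens-distortion correction.
- A stroke thinner than the grid rule, or a wound whose boundary coincides
  with a rule for much more than `max_gap`, can still produce an open
  boundary; the error message names the failing stage.
- The published subset-level mean errors of the traditional instruments
  (rigid ruler, caliper, scalimeter) are not recomputable from printed
  data and are not asserted anywhere.
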