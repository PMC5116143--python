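# Methods

## The counting problem

*Aedes aegypti* females glue their eggs one by one onto solid substrates
(typically sandpaper strips lining a water container). Fecundity assays
and oviposition-choice experiments therefore reduce to counting dark,
roughly ellipsoidal eggs (~0.6 mm) on a light, textured background —
tens to hundreds per strip, across many strips. Manual counting is slow
and error-prone; this package automates it with a deliberately simple,
tunable pipeline, and recovers exactness through a targeted human
review of only the objects the algorithm distrusts.

## Detection model

For a grayscale image `I` (8-bit, dark eggs on light substrate):

1. **Binarization.** Foreground is `I < T` with a single global
   threshold `T` (default 80). There is deliberately no adaptive or
   Otsu thresholding: a fixed, user-visible threshold is trivial to
   tune per imaging setup, saves per-image fiddling, and its failure
   modes are transparent. Images with inverted polarity must be
   inverted upstream.
2. **Labelling.** Maximal connected components of the foreground under
   8-connectivity (default; 4 available). 8-connectivity makes
   diagonally touching eggs merge into one component, which is what we
   want: merges get flagged rather than split arbitrarily.
   Components are ordered by the (top, left) corner of their bounding
   box so object ids are reproducible run to run.
3. **Box-area classification.** Each component's *bounding-box* area
   `A_box` (height x width, px) is compared with a single-egg band
   `[A_min, A_max]` (defaults 800 and 1400 px):
   - `A_box < A_min` — **rejected** (noise, debris), count 0;
   - `A_min <= A_box <= A_max` — **confident** single egg, count 1;
   - `A_box > A_max` — **uncertain**: several eggs merged into one
     object, count estimated below.
4. **Cluster estimation.** Per image, a single-egg reference area `R`
   is the median *pixel* area of the confident objects (median, not
   mean, for robustness to the occasional merged-but-in-band object).
   An uncertain object with pixel area `P` is estimated to hold
   `max(1, round(P / R))` eggs (round half-up). This is the classic
   particle-analysis ratio of total area to average single-particle
   area, applied per flagged object.
5. **Total.** Sum of per-object counts.

Two distinct areas are used on purpose: classification uses the
bounding box (rotation-invariant *size gate*, cheap and matching the
boxes a reviewer sees on the overlay), while cluster estimation uses
pixel area, which is what actually scales linearly with egg count.

When an image has no confident object, `R` falls back to
`0.7 x (A_min + A_max) / 2` (770 px at defaults): 0.7 approximates the
fill fraction of a rotated ellipse in its bounding box, between pi/4 ~
0.79 when axis-aligned and lower when rotated. The reference is
per-image, never global, so magnification differences between images
self-calibrate.

### Other modes

- **Macro** (whole-strip photographs): the total is the foreground
  pixel count divided by `R`, with no per-object analysis — fast and
  adequate at strip scale where individual boxes are tiny. The CLI
  still runs the labelling pass to obtain `R` from the image itself.
- **Raft** (*Culex*-style floating egg rafts): rafts cannot be split
  into eggs by area, so every component at or above `A_min` counts as
  exactly one and nothing is flagged as uncertain. Raft totals are
  never larger than micro totals on the same image.

## Semi-automatic review

Uncertain and rejected objects are exported to a plain CSV
(`image_id,object_id,status,auto_count,corrected_count,note`); a
reviewer fills `corrected_count` per object (0 is valid: the object was
an artefact) and the corrections are folded back per object, keeping
the original status for audit. Per-object corrections, rather than a
single adjusted total, record *where* the automatic count was wrong.
Applying corrections is pure (the input result is untouched) and
idempotent. When every counting error lives in a flagged object —
which the default synthetic cluster geometry guarantees, see below —
review drives the error to exactly zero.

## Calibration and assay statistics

Validation against a manual reference uses ordinary least squares on
`Y = a + b x` (x = manual count, Y = estimate) with `R² = 1 −
SSres/SStot` and the standard two-sided t-test on the slope (n − 2 df).
A stratified option fits separately for manual counts at or below and
above a split (default 100 eggs/image), because counting degrades with
crowding; permutation alternatives were considered unnecessary for a
calibration with hundreds of images.

Error metrics against ground truth are the mean absolute error, mean
absolute percent error (images with true count 0 are excluded from the
percent mean and tallied separately), and the fraction of images
counted exactly.

Dual-choice assays transform egg numbers to percentages per replicate
(`100 x eggs(choice) / total eggs`; the two arms of a replicate sum to
100) and compare arms with Welch's unequal-variance t-test
(Welch–Satterthwaite df, two-sided). Normality pre-checks and
multi-factor ANOVA are left to general statistics packages.

## Synthetic strip generator

No public corpus of annotated oviposition-strip photographs exists, so
the test bed is a seeded generator that emulates the properties the
algorithm actually consumes — contrast and geometry — and records
exact ground truth per egg and per expected merged object.

- **Background**: per-pixel Gaussian, mean 200, sd 10 (light, noisy
  substrate). **Eggs**: filled rotated ellipses, per-pixel Gaussian
  intensity mean 30, sd 10. The default threshold 80 sits 5 sd above
  the egg mean and 12 sd below the background mean, so binarization is
  clean by construction; threshold-sensitivity tests vary these.
- **Egg geometry**: full axes 44 x 22 px (aspect 2:1, jitter ±5% per
  axis, orientation uniform on [0, pi)). Chosen so a single egg's
  bounding box stays inside the default [800, 1400] band at every
  orientation: the box ranges from ~874 px (smallest jitter,
  axis-aligned) to ~1334 px (largest jitter, 45°).
- **Placement**: rejection sampling (capped at 10,000 attempts per
  placement, then a capacity error) against an occupancy mask dilated
  by `min_gap` (default 6 px, minimum 2 so separate placements can
  never 8-connect). Densities therefore approach the crowded regime
  naturally rather than on a lattice.
- **Clusters**: a fraction of eggs is laid in groups of 2–4 strung
  along the seed egg's minor-axis direction with centre separation
  0.8–0.9 minor axes (default). Members overlap, so each group merges
  into one component; offsetting along the *minor* direction adds the
  separation to the smaller bbox extent in every rotation, so the
  merged box provably exceeds 1400 px for a pair already
  (44 x (22 + 17.6) ≈ 1742 px at worst-case orientation). Every
  synthetic merge is thus flagged — the precondition for the
  100%-after-review property.
- **Superimposition regime**: `cluster_sep_range` can be tightened
  (down to 0.2 minor axes). Below ~0.45 a pair's merged box drops
  inside the single-egg band and is silently counted as one egg — the
  undercount mechanism that dominates crowded strips. Evaluation
  configurations that scale `cluster_fraction` with density under this
  geometry reproduce the characteristic two-regime calibration: the
  low-density slope stays near 1 while the high-density slope falls
  below it.

What the generator does **not** emulate: photorealistic sandpaper
texture, illumination gradients, specular highlights, lens distortion,
debris, and eggshell colour variation. Passing tests therefore
demonstrate the correctness of the algorithmic pipeline in its design
regime (sharp dark-on-light contrast, in-band egg sizes), not
robustness to poorly lit or low-contrast field photographs — on real
images the threshold and box band must be tuned to the imaging setup.

## Numerical choices

- Luminance conversion is ITU-R BT.601 (0.299/0.587/0.114), rounded
  half-up; all other rounding in the pipeline (cluster ratios,
  histogram totals, reference areas) is also half-up for
  reproducibility across platforms.
- Binarization is strict (`<` threshold), so threshold 0 yields no
  objects for any image.
- Classification band edges are inclusive on both sides of
  `[A_min, A_max]`.
- Cluster estimates are floored at 1 and have no ceiling; a very large
  blob may estimate many eggs and remains flagged for review.
- Degenerate inputs raise typed errors (`ParameterError`,
  `BoundsError`, `StatisticsError`, `CapacityError`, ...) rather than
  returning sentinels.

## Problem sizes used in the shipped checks

The accuracy suites run on generated strips of 1000 x 1400 px: 50
strips of 10–100 eggs (light clustering, 5%) for the automatic-error
figure, 30 strips of 30–150 eggs (15% clustering) for the
after-review exactness figure, 20 seeds x {20, 55, 120} eggs for the
zero-error regime, and a 30-strip mixed-density batch (20–200 eggs,
crowding-scaled clustering under the superimposition geometry) for the
two-regime calibration. These sizes mirror the egg densities of real
strips (a blood-fed female lays ~20–140 eggs) while keeping the whole
suite comfortably reproducible on a laptop.

## Known limitations

- A fixed global threshold cannot rescue uneven illumination; trim or
  flatten images upstream.
- Cluster estimation assumes merged eggs overlap only moderately;
  heavily superimposed eggs are under-estimated (by design this is the
  flagged/reviewable case at default geometry, but real crowded strips
  can hide merges inside the single-egg band).
- The raft mode counts rafts, not eggs per raft.
- Species cannot be distinguished from egg morphology here.
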