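# Methods

## Scoring model

A well image is scored in four steps, all in double-precision floating
point on the 0–255 intensity scale:

1. **Background.** The background level *b* is the arithmetic mean of the
   pixels inside a centered axis-aligned rectangle whose sides are
   `max(1, round(rect_fraction · dim))` pixels (`rect_fraction` default
   0.8). Rounding is half-away-from-zero; when the leftover margin is odd,
   the extra row/column of margin sits at the bottom/right, with pixel
   (0, 0) at the top-left. Fixing these conventions makes the rectangle —
   and therefore every downstream number — bit-reproducible.
2. **Subtraction and clipping.** Residuals `p − b` are clipped below at 0.
   The original formulation leaves clipping unstated; 8-bit saturation
   semantics (clip to [0, 255] after contrast as well) are the natural
   reading of a mask that writes the value 255.
3. **Contrast.** `v = v · alpha + beta` with `alpha > 0` (default 1.0) and
   `beta` (default 0.0), then clipped to [0, 255].
4. **Threshold and count.** A pixel is positive iff `v ≥ pixel_threshold`
   (default 50, in 8-bit units); the score is the count of positive pixels.

The defaults for `alpha`, `beta` and `pixel_threshold` are neutral
conventions — appropriate values depend on the microscope, exposure and
reporter — and every one of them is exposed in the YAML config and as CLI
flags. 16-bit images are divided by 257 (so 65535 maps to 255) before the
pipeline; consequently one threshold setting means the same fluorescence
level at either bit depth.

Because the background rectangle covers most of the organoid, *b* is not
the dark-field level but a mixture of background and organoid body; the
score therefore counts pixels substantially brighter than the *average*
well content. This is intentional: it makes the score insensitive to
uniform intensity shifts (adding a constant to every pixel leaves the score
unchanged as long as nothing clips), which the property tests assert.

## Threshold calibration

Given scores with human positive/negative labels, the cutoff is the
inverse-ECDF (order-statistic) 95% quantile of the negative scores:
`threshold = x_(⌈q·n⌉)` with `q = 0.95`. An interpolated quantile would not
guarantee anything about finite samples; the order statistic makes the
contamination bound exact for every n: the number of calibration negatives
strictly above the threshold is at most `⌊(1 − q)·n⌋`. Classification is
strict (`score > threshold`; ties are negative), which is what makes the
bound hold with `≥`-quantiles at repeated values. Positives never influence
the fit; they are only summarized as sensitivity (fraction of labeled
positives above the cutoff).

Calibration is reporter-line- and day-specific in practice, so the model
stores a free-text provenance tag and the CLI refuses to apply a model to
data tagged with a different provenance unless `--force` is given. Whether
to pool labeled organoids across batches is left to the caller.

## Plate analytics

The unit of analysis for group comparisons is the plate: each plate
contributes its positive fraction as one observation. Organoid-level
comparisons of raw score distributions are available behind
`per_organoid=True` for questions about retinal area rather than rate.

The Mann-Whitney U test is two-sided. With both groups ≤ 8 and no ties the
exact permutation null is used; otherwise the normal approximation with tie
correction and continuity correction. Two samples that are a single tied
value have zero variance under the null, so the test returns p = 1
explicitly. Welch's t-test (n−1 sample SDs) is offered as a clearly labeled
secondary output, because plate-level summaries are conventionally reported
as mean ± SD. Half-plate counts default to a column split (1–6 vs 7–12);
which plate axis corresponds to a physical gradient (e.g. incubator-door
side) is apparatus-specific, so the axis and boundary are configurable.

## Synthetic data generator

A synthetic well is composited as
`background (+ optional linear gradient) + organoid body + patches + N(0, noise_sd)`,
clipped to the bit range. Disks are rasterized with the center-in-circle
rule (`dx² + dy² ≤ r²`), so ground-truth areas are exact integer lattice
counts independent of any implementation detail (a radius-5 disk is exactly
81 pixels). Default geometry mimics a full-well scan: 512×512 image,
organoid radius ≈ 0.29 of the image side (~150 px), background 10,
organoid body +40, patches +100, noise SD 3 on the 8-bit scale, and a
default positive well carries two patches totalling ≈ 8% of the organoid's
projected area (realistic positives span roughly 1–10%). Plate generation
draws each well's label independently with a column-adjustable positive
probability (the edge-effect knob) and derives one RNG stream per well from
the plate seed, so individual wells are reproducible in isolation.

What the generator does *not* emulate: organoid texture, out-of-focus
blur/PSF, vignetting, debris, multiple organoids or empty wells, or
intensity statistics of any particular reporter line. Passing tests
therefore demonstrate the correctness of the computations on images
matching the model's assumptions — not that the default `pixel_threshold`
is right for a given microscope. On real data the pixel threshold and the
calibration set are the user's responsibility.

## Numerical and design choices

- The scorer is required to agree *exactly* (no tolerance) with a naive
  per-pixel reference; both use the same clipping and comparison order, and
  randomized thresholds make comparisons tie-free almost surely.
- Score CSVs are ordered by (plate, row letter, column number) so reruns
  are byte-identical.
- Validation sizes: synthetic validation wells are rendered at 128×128 with
  organoid radius 40 px and patch radius 8 px — a scaled-down version of the
  default geometry that keeps every disk area exact while making the full
  validation suite run in seconds.
- Degenerate inputs: empty score lists classify to empty lists; a plate
  with no scored wells has positive fraction 0; single-plate groups compare
  with p = 1 and a warning that the test is uninformative.

## Known limitations

- One image per well is assumed; multi-field tiling and stitching are out
  of scope, as are OME metadata, segmentation and per-vesicle object
  statistics.
- The contamination guarantee is a statement about the calibration set;
  generalization to new wells assumes they are exchangeable with it.
- No multiple-testing correction is applied across ad-hoc group
  comparisons.
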