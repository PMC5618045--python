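# Methods

This note documents the models, defaults, and numerical choices behind
`sicklescreen`, and what the synthetic-data generator does and does not
emulate.

## The assay and the S-index

The screening test exploits the insolubility of deoxygenated sickle
hemoglobin (deoxy-HbS) in concentrated phosphate buffer. Blood is lysed
with saponin, deoxygenated with a reducing agent — sodium metabisulfite
(MS) or sodium hydrosulfite (HS) — and spotted onto chromatography paper.
Insoluble deoxy-HbS polymers are retained at the deposition point (dark
center spot); soluble hemoglobin wicks laterally (pink peripheral ring).

The scanned stain is quantified by the S-index, the ratio of the mean red
color intensity (255 − blue channel) over the center-spot pixels to that
over the ring pixels. Only the blue channel enters; the red and green
channels carry no information for this statistic, which the test suite
verifies by perturbing them.

## Segmentation

The original study quantified stains with an unpublished image-analysis
routine, so the segmentation here is this package's own design, built to
use only the quantity the S-index is built on:

1. Otsu two-class thresholding of 255 − B separates stain from background;
   the largest connected component (8-connectivity) is the footprint.
   Components below 500 px raise `NoStainFound`; a second component at
   least half the largest raises `AmbiguousStain`.
2. The stain center is the footprint centroid.
3. The radial red-intensity profile is computed in 1-px annular bins over
   unsaturated footprint pixels (pure white and B = 0 pixels are excluded,
   since scanner clipping biases regional means).
4. The center/ring boundary is the bin edge of the steepest profile drop
   (at least 8 intensity units per bin step, searched inside 80% of the
   footprint radius); if no drop that large exists — as for HbS-free
   stains — the boundary falls back to 0.35 × the footprint radius, so
   negative stains still get a defined partition and S ≈ 1.

Masks are pixel-aligned, 0-based row/column; no sub-pixel boundaries. On
generator ground truth the recovered masks reach IoU 1.0 without noise and
stay ≥ 0.90 across per-pixel noise SD ∈ {0, 2, 5} and %HbS ∈ {0, 10, 40, 80}.

## The synthetic generator

The generator renders concentric discs: a ring of red intensity 90
(B = 165) inside a white background, and a center disc of red intensity
90·g, where the contrast function g is a shifted and rescaled logistic in
%HbS with g(0) = 1 exactly:

    g(x) = 1 + A · (σ(k(x − x0)) − σ(−k·x0)) / (1 − σ(−k·x0))

| formulation | A | k (per %HbS) | x0 (%HbS) |
|---|---|---|---|
| MS 10% w/v | 1.1 | 0.06 | 25 |
| MS 15% w/v (default) | 1.6 | 0.06 | 25 |
| MS 20% w/v | 1.7 | 0.06 | 35 |
| HS 3% w/v | 1.6 | 0.06 | 45 |

No functional form for stain contrast is published; the logistic family was
chosen as the simplest saturating curve, and the parameters were fixed once
so that (a) the 15%-MS S-index clears the default observer cutpoint (1.10)
at 10% HbS while HS first clears it at 15% HbS, matching the two
formulations' reported detection limits; (b) MS contrast dominates HS at
every %HbS; and (c) 15% MS maximizes the S(20%) − S(0%) separation among
the three MS concentrations, reproducing the study's formulation choice.
On the five-level reconstitution grid {0, 10, 20, 40, 80}% the lowest level
above the HS onset is 20%, so ROC-based LOD recovery on that grid returns
20% for HS and 10% for MS.

Defaults: 128-px images, stain radius 48 px, center radius 17 px
(≈ 0.35 × 48, so the negative-stain fallback partition coincides with the
truth), per-channel additive truncated-Gaussian noise with SD 2 clipped to
[0, 255], no boundary jitter. Optional radial jitter perturbs both
boundaries with low-order random harmonics.

Reagent aging is a **step function**: full activity through the limit of
stability (LOS), none after, because the study reports reagents "100%
stable" up to a day and total loss thereafter. LOS values: HS 36 d (dry),
6 d (wet); MS is modeled as indefinitely stable at room temperature (no
failure was observed through the 168-day window, so any finite value would
be invented); wet MS at ≥ 40 °C has LOS 7 d (the observed one-week bound at
62 °C — the only hot condition modeled). A dead reagent renders exactly
like a 0%-HbS stain.

The observer model thresholds the stain's measured S-index (computed over
the ground-truth masks) after adding logistic read noise of scale
1/slope, so slope → ∞ is deterministic thresholding and a stain exactly at
a cutpoint is called above it with probability 1/2. Default cutpoints:
1.10 (binary negative/positive) and (1.10, 2.28) for AA/AS/SS; default
slope 40, i.e. a read SD of ≈ 0.045 S-index units, small relative to the
contrast steps but enough to produce occasional errors near 10% HbS.
Study-level seeds spawn per-stain render seeds, so a study config is
byte-reproducible.

**What the generator does not emulate:** paper-fiber microstructure,
chromatography physics, gradual reagent decay, color-calibration or
illumination drift, multi-stain sheets, HbF interference, and real
biological between-stain variability beyond pixel noise. Passing recovery
tests therefore show the *analysis* is correct under the generator's
assumptions, not that the assay itself performs as reported on real blood.

## Statistics

- **Performance metrics**: sensitivity TP/(TP+FN), specificity TN/(FP+TN),
  PPV TP/(TP+FP), NPV TN/(TN+FN), accuracy (TP+TN)/total, computed after
  collapsing the pooled K×K confusion matrix to 2×2. Zero-denominator
  metrics are reported as undefined, never coerced to 0. Percentages are
  reported to one decimal, κ to two; unrounded values are always kept.
- **Fleiss' κ** uses the standard equal-raters formulation. Inter-observer:
  stains are subjects, observers are raters. Intra-observer: per observer,
  replicate readings act as the raters (the original replicate structure is
  unpublished; this is the natural reading). Perfect agreement on a single
  category (chance agreement 1) is reported as κ = 1. Agreement summaries
  use the population SD (divisor n), which is what reproduces the published
  0.93 ± 0.04 and 0.85 ± 0.09 from the individual scores.
- **LOD by ROC**: visual calls are a single binary operating point, so the
  AUC against the truth "%HbS ≥ c" is (sensitivity + specificity)/2; the
  LOD is the AUC-maximizing candidate, ties broken toward the lowest c
  (the LOD is the *lowest* detectable percentage). Candidates whose truth
  is single-class are excluded as undefined.
- **Readout time**: per genotype class, the stable time is the earliest
  recorded minute from which every observer scores correctly at all later
  minutes (a transient correct spell followed by an error does not count);
  the total is the 10-min incubation plus the slowest class's stable time.
  A class never uniformly correct is reported as having no stable readout.
- **Stability**: Welch's two-sample t-test (two-sided, unequal variances)
  on 0%-HbS vs at-LOD S-index replicates per storage day; the published
  criterion states only "p < 0.05" without naming a test, and Welch is the
  robust default for possibly unequal variances (a permutation test is the
  cross-check oracle in the suite). At-LOD levels follow the study: 10%
  HbS for MS, 20% for HS. No multiple-testing correction across days —
  stability is a per-day criterion. LOS is the last significant day
  strictly before the earliest non-significant day; 0 if the first day
  fails; censored at the last day (a lower bound) if no day fails. If both
  groups have zero variance and equal means, p = 1 by convention.
- **Shelf-life ratios** are reported in weeks, rounded to the nearest
  integer, with a "~" qualifier when fractional or when the numerator is
  censored (e.g. 24/5 = 4.8 → "~5").

## Design notes and limitations

- Exact LOS recovery from one simulated series is inherently a ~95% event:
  after the activity step both groups are null, so each post-step day has
  a 5% type-I chance of deferring the detected failure. The recovery
  checks therefore take the mode over three independent series (a design
  choice fixed in advance), and the calibration test asserts the type-I
  rate of the stability test itself at 1000 null runs.
- The §-style confusion-matrix cells behind the published five-metric sets
  are not printed anywhere; `consistent_binary_counts` recovers them by
  exhaustive integer search over 2×2 tables at the pooled total (555) that
  round to all five printed values at one decimal.
- Problem sizes in tests and the acceptance script (60 stains/class for
  recovery studies, 12 replicates per stability group, 1000 null runs)
  were chosen as the smallest sizes at which the checked properties are
  statistically stable.
- Hematocrit is metadata only: components are Hct-matched physically
  before mixing, and the mixture equation involves only [Hb]·V products.
- Costs use `decimal.Decimal`, so cent sums are exact.
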