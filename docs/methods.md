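# Methods

## The measurement model

Every capsule still frame is analysed inside a circular field of view (FOV):
a centred disc of radius 0.48 × min(width, height). Pixels outside the disc
are black padding from the optics and are excluded from every statistic.
Capsule vendors do not document the exact optic geometry, so the radius is a
package choice; it only matters that the generator and the scorers agree on
the analysed region.

### Bubble abundance (GLCM contrast)

The frame is converted to luminance (0.299 R + 0.587 G + 0.114 B) and
quantised into `n_levels = 32` equal-width bins over [0, 255]. A grey-level
co-occurrence matrix is accumulated by counting ordered pixel pairs at
distance 1 in the four standard orientations (0°, 45°, 90°, 135°), keeping
only pairs whose two pixels both lie inside the FOV. Counts are pooled over
orientations, symmetrised by adding the transpose, and normalised to a
probability table `p(i, j)`. The Haralick contrast

    C = Σ_{i,j} (i − j)² p(i, j)

is zero for a constant frame and grows with the frequency and magnitude of
local grey-level transitions. Bubbles present as bright specular rings on a
darker mucosa, so their rim length — roughly proportional to the covered
area at a given bubble size — drives C up nearly linearly with coverage.

A frame is classified *abundant in bubbles* when `C ≥ τ`. The criterion the
label encodes is a surface one: bubbles covering ≥ 10% of the FOV (coverage
exactly 0.10 is abundant). The cut-off τ of the original clinical detector
is not public, so τ is calibrated on synthetic frames with known coverage:
contrasts are computed for a labelled set (coverage uniform on [0, 0.3],
n = 500), candidate thresholds are the midpoints between consecutive
distinct contrast values, and τ maximises the Youden index
(sensitivity + specificity − 1), breaking ties toward the higher threshold
(higher specificity). With the default generator this yields τ ≈ 11.6 with
sensitivity/specificity ≈ 0.97–0.99, and held-out balanced accuracy ≈ 0.98.

Parameters (defaults): `n_levels` 32 — fine enough to resolve the
rim/mucosa gap, coarse enough that pixel noise (σ = 6 grey levels) stays
mostly within one bin; `distance` 1 pixel; 4 orientations, symmetric
accumulation — the standard Haralick convention, which also makes the
matrix orientation-agnostic for isotropic structures like bubbles.

### Cleanliness (R/G score)

The score is the ratio of the mean red to the mean green intensity over the
FOV, and a frame is *adequately cleansed* when R/G > 1.6 (strict: exactly
1.6 is inadequate). The ratio-of-means form (rather than a mean of per-pixel
ratios) is immune to individual zero-green pixels and is undefined only when
the whole FOV has zero mean green, which is treated as an error. A uniform
frame with R = 160, G = 100 scores exactly 1.6.

### Video aggregation

The small-bowel (SB) segment runs from the first to the last SB frame of a
recording. It is split into four quartiles **by frame index**, with
boundaries at ⌊kN/4⌋ (k = 0..4), so the quartiles partition the sequence
exactly and remainders land in Q2/Q4. Quartiles could alternatively be
defined on elapsed time; with the near-uniform frame timing the generator
produces, the two definitions coincide, and frame-count quartiles are what
per-frame proportions are naturally pooled over. Per quartile we report the
fraction of abundant and of adequate frames. Reader-level outcomes come from
the sidecar metadata: gastric transit time (first SB timestamp − ingestion),
SB transit time (last − first SB timestamp), completion (≥ 1 colonic frame),
and diagnostic yield (≥ 1 finding of pertinence P1 or P2; P0 does not
count).

### Cohort statistics

The per-video 4-vectors of quartile fractions enter a two-way mixed
(split-plot) ANOVA: preparation arm is the between-subjects factor, quartile
the within-subjects factor, and the video is the subject. The classical
decomposition is computed directly:

    SS_total = SS_group + SS_subjects(group) + SS_quartile
             + SS_group:quartile + SS_residual

with F tests group vs subjects-within-groups (df 1, n₁+n₂−2) and
quartile/interaction vs the subject×quartile residual (df 3 and 3,
3(n₁+n₂−2)). Marginal quartile means are weighted by group size, which keeps
the decomposition exact for unequal arms; this matches `pingouin.mixed_anova`,
which serves as an independent oracle in the tests. No sphericity correction
is applied by default (Greenhouse–Geisser is available via
`correction="gg"`), matching the single uncorrected p-value convention of
clinical reports.

Continuous outcomes are compared with Welch's unequal-variance t-test and
categorical outcomes with the Pearson chi-square without continuity
correction (both choices exposed as flags; the plain forms are the defaults
because nothing in the study design argues for pooled variances or Yates'
correction). Percentages in report tables are rounded half-up to one
decimal. Degenerate 2×2 tables (a zero margin, e.g. a 100% completion rate
in both arms) yield a missing p-value rather than an error in the report.

### Screening

Roster filters run in the flow-chart's narrative order — washout-period
removal, OGIB-indication restriction, outpatient restriction, arm
assignment, then the per-patient exclusion criteria (age < 18,
contraindication, active bleeding, technical defect, endoscopic delivery,
recent CE, gastric retention) — so every intermediate node count is
reported. The final included set is order-independent (it is the
conjunction of all criteria); only the node counts depend on the order.

## The synthetic generator

The generator's job is to plant known quantities, not to be photorealistic.

**Frames** are 128×128 by default (large enough for stable GLCM statistics,
small enough to score tens of thousands of frames per minute). A frame is
composed of: a reddish mucosa (base RGB ≈ (152, 96, 72)) with smoothed
coarse-noise texture; 2–4 greenish debris blotches; non-overlapping bubbles
drawn as bright rings (rim at grey 240, interior blended 38% toward 222)
with a fixed nominal radius of 5 px, placed by rejection sampling until the
covered FOV fraction is within ±0.005 of the planted coverage (contract:
±0.01; coverage > 0.95 is refused); Gaussian pixel grain (σ = 6); and a
final channel-balancing step that rescales the mucosa/debris pixels —
leaving the specular bubble pixels and the mean luminance unchanged — until
the FOV's mean-R/mean-G is within 2% (typically 0.4%) of the planted
balance. The fixed bubble radius and the luminance-preserving balance are
deliberate: they keep the contrast-versus-coverage relation tight and
independent of the planted cleanliness, which is what makes a single
contrast threshold meaningful. Everything is deterministic under the frame
seed.

**Videos** draw each SB frame's abundant indicator i.i.d. from its
quartile's planted rate (coverage then uniform on [0.105, 0.40] for abundant
frames, [0, 0.095] for scarce — kept a rendering tolerance away from the
0.10 boundary) and likewise the adequacy indicator (R/G uniform on
[1.65, 2.30] vs [0.95, 1.55]). Four gastric and, for complete videos, two
colonic frames bracket the SB segment; timestamps place the SB frames
uniformly across a truncated-normal SB transit time (sd = 0.35 × mean,
floor 2 min). Per-video random streams derive from
(master seed, arm, video index), so arms regenerate independently.

**Findings and completion** are planted as exact per-arm quotas
(round-half-up of rate × n, assigned through seeded permutations, P1 and P2
to disjoint videos) rather than i.i.d. draws: with 48- and 57-video arms,
Bernoulli sampling would almost never land on the two-decimal percentages
the report fixtures are checked against, whereas quota planting reproduces
them exactly at any seed while remaining random at the video level. Note
one consequence of integer counts: a planted completion probability of
0.929 over 57 videos yields 53/57 = 93.0%, the closest attainable rate.

**The packaged study profile** encodes the two-arm study this pipeline is
designed around: 48 videos (SMT−) vs 57 (SMT+), 200 SB frames per video
(a desk-scale stand-in for the ~6,000-frame clinical recordings), Q3/Q4
abundant-frame rates (27.7%, 30.5%) vs (22.1%, 20.6%), completion 87.5% vs
92.9%, P1/P2 rates 14.6/27.1% vs 15.8/26.3%, and gastric/SB transit means
40/199 vs 39/232 min. Q1/Q2 abundant rates (19.0%, 22.5% vs 18.5%, 20.5%)
and the per-quartile adequate-cleanliness curves (0.82→0.60 vs 0.83→0.63)
are package choices — the source tables publish only Q3/Q4 for bubbles —
picked so the between-arm difference grows along the small bowel and
cleanliness declines over quartiles similarly in both arms. The screening
roster plants the flow-chart strata exactly: 345 screened = 18 washout + 61
non-OGIB + 122 OGIB inpatients + 66/78 eligible outpatients of whom 18/21
carry one exclusion criterion each, leaving 48/57.

### What the generator does *not* model

Real recordings have correlated frames (the capsule dwells), heterogeneous
per-patient bubble loads (overdispersion beyond the binomial), lighting
drift, lesions, and bubble shapes far from rings. Consequently the
synthetic ANOVA is much better powered than a clinical dataset of the same
size — between-video variance is purely binomial — so a significant group
effect here validates the machinery (it recovers planted differences), not
the clinical effect size. Likewise the classifier's ~0.98 balanced accuracy
is an upper bound tied to the ring model of bubbles, not an estimate of
performance on real images.

## Numerical and design notes

* Quantisation is `floor(grey × n_levels / 256)` clamped to the top bin;
  luminance values landing exactly on a bin boundary can flip bins at
  floating-point resolution, which matters only for synthetic constant
  images (tests use mid-bin values).
* The GLCM is accumulated from counts pooled over orientations and then
  normalised once; with symmetric accumulation the four orientations are
  offset-sign invariant.
* `glcm_contrast` refuses matrices whose entries do not sum to 1 (±1e−6).
* Calibration is deterministic given the input multiset: candidates are
  sorted midpoints and ties break toward higher τ.
* The ANOVA returns NaN F/p when a denominator mean square is zero (all
  responses constant), and refuses missing cells or groups with fewer than
  two subjects.
* Bubble placement falls back to radius-2 fill circles when the nominal
  radius no longer fits; dense targets up to ~0.6 coverage remain reachable
  within tolerance. Placement failure beyond tolerance raises rather than
  silently under-covering.
* Problem sizes used by the shipped checks: 500 calibration + 1,000
  held-out frames for the classifier; 105 videos × 200 SB frames for the
  pipeline recovery run; 1,000 replicates (16 + 16 subjects, 40 frames per
  quartile) for the null ANOVA calibration; 100 seeds for the group-effect
  simulation.

## Known limitations

* The contrast threshold τ is meaningful only for the synthetic image
  distribution it was calibrated on; applying the scorer to real CE frames
  requires recalibration against expert labels.
* The ring-bubble model cannot probe failure modes like foam sheets,
  overlapping bubble rafts, or specular highlights from fluid menisci.
* Quartile splitting assumes ≥ 4 SB frames and excludes gastric-retention
  videos upstream (they have no SB segment by definition).
* The mixed ANOVA assumes complete 4-vectors; videos with missing quartile
  scores must be filtered before analysis.
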