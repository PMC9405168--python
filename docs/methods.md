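# Methods

## The measurement problem

Olfactory-bulb granule cells carry dendritic spines on their secondary
dendritic trunks; the shape and abundance of these spines track synaptic
maturity and plasticity. In the European eel (*Anguilla anguilla*), spine
density and class composition change across the continental life stages
(glass eel → elver → yellow eel → silver eel), and those changes were
quantified on Golgi–Cox-stained reconstructions as spine counts per 10 µm
of secondary-trunk arc length, with each spine assigned to one of the four
conventional classes. `spinemorph` implements that analysis as a tested
pipeline: geometry measurement, rule-based classification, density
aggregation, nonparametric inference, and a calibrated generator that lets
every stage be exercised without the original microscopy material.

## Spine measurement from diameter profiles

A protrusion is represented as a diameter profile d(s), s ∈ [0, L], from
its attachment point. The original study measured spines interactively in
commercial rendering software and published only the classification
criteria ("head diameter greater than the maximum diameter of the neck",
"well-formed head"), not a measurement algorithm, so the profile algorithm
here is this package's own deterministic, parameter-explicit analogue of
the visual judgement:

1. find the global diameter minimum (the neck waist) at position s*;
2. find the widest point distal to the waist, d_head;
3. declare a head iff d_head ≥ `head_min_diameter` (default **0.3 µm**,
   operationalising "well-formed"), d_head ≥ `head_prominence_ratio` ×
   d(s*) (default **1.2**, the bulb must stand clear of the waist), and
   d_head exceeds every diameter in the proximal region (rejects
   attachment flares that taper into a modest distal bulge — without this
   guard a "head" thinner than the neck maximum could be reported, which
   is geometrically contradictory);
4. if a head is found, the neck spans [0, s*]: `neck_length` = s*,
   `neck_max_diameter` = max of d over the neck span (the *maximum*, not
   the mean, following the criterion text literally), `head_diameter` =
   d_head. `total_length` = L always.

Both thresholds are keyword arguments; the defaults are the package's
operational choice, not published values. The measurement is
scale-consistent: scaling all diameters by c (and the head threshold with
them) scales the measured diameters by c and changes nothing else.

## Classification rules

Given measured metrics the classifier is total and deterministic:

| condition | class |
|---|---|
| head present, neck_max_diameter > neck_length | mushroom (M) |
| head present, neck_length ≥ neck_max_diameter | long thin (LT) |
| no head, total length < 1 µm | stubby (S) |
| no head, total length > 10 µm | filopodium (F) |

Two edge cases are resolved explicitly. The neck tie
(neck_length = neck_max_diameter) goes to LT because the mushroom rule
demands a strictly thicker-than-long neck. Headless protrusions with total
length in [1 µm, 10 µm] satisfy neither the S nor the F rule; they are
assigned to S but flagged (`S_EXT`) and tallied separately, keeping the
partition exhaustive while leaving the ambiguity auditable. The 10 µm
filopodium threshold is unusually long by the wider literature but is
applied exactly as published; it is configurable
(`headless_filopodium_min_length`).

## Density and summaries

Each traced segment must be at least 10 µm long (the tracing rule); traced
lengths vary, so densities are normalised by each segment's true arc
length: density_c = count_c / arc_length × 10. Class densities therefore
partition the total exactly on every record. Stage summaries report
mean ± SE (sample SD / √n) over segments — segments, not animals, are the
unit of analysis, matching the source design — plus a pooled row over all
segments. Gap-flagged stubbies count toward S and the total.

## Inference

Spine densities are quotients of small counts, so ties are pervasive and
the path is nonparametric throughout:

- **Kruskal–Wallis** with mid-ranks and the tie correction
  1 − ΣT/(N³ − N), T = t³ − t; p from the χ² upper tail, df = k − 1.
- **Dunn's post hoc Z** on pooled mean ranks with the tie-corrected
  variance N(N+1)/12 − ΣT/(12(N−1)); two-sided normal p. No
  multiple-testing adjustment by default (matching raw-Z reporting);
  Bonferroni and Holm are available by flag and never reduce p.
- **Shapiro–Wilk** (delegated to scipy) as an advisory gate: it is logged
  but never switches the pipeline to a parametric branch.
- **Significance codes** `****/***/**/*/ns` at 0.0001/0.001/0.01/0.05;
  the published code map is silent at p = 0.05 exactly, which maps to ns
  here (the `*` rule requires strictly < 0.05).
- **Biometric regressions**: per-animal mean density OLS-regressed on
  log10 of total length, total weight and brain weight (body measures span
  orders of magnitude across stages, hence the log; base 10 chosen, the
  source stating only "log-transformation"). A correlation counts as
  significant only when R² ≥ 0.7 *and* slope p < 0.05. Whether the
  original analysis regressed per-animal means or pooled segments is not
  stated; this package uses per-animal means.

The published K–W/Z statistics themselves are internally inconsistent
between text and tables in the source (e.g. the glass-eel class comparison
appears as both 23.52 and 130.19), and in any case depend on the real
data's unknown dispersion; the package makes no attempt to reproduce them
numerically. What is reproduced instead is qualitative: at study scale the
four-stage comparison of total density rejects overwhelmingly and the
glass > yellow ordering is stable (tested over repeated simulations).

## The synthetic-study generator

The generator emulates the study design, not the microscopy: four stages ×
77 segments (308 total) of uniform 10–14 µm length ("at least 10 µm" with
no stated upper bound), 19 animals split 5/5/5/4, biometrics drawn from
zero-truncated normals with the published per-stage means/SDs, segments
assigned round-robin to their stage's animals. Everything is a pure
function of (config, seed) through one `numpy` Generator.

**Rate-table calibration.** Only part of the stage × class mean-density
matrix was published. The calibration fixes the printed cells and fills
the rest under three constraints: each stage row sums to its printed
total; the balanced pooled class means match the printed pooled values
(±0.02, ±0.01 for F); and the filopodia rates decrease across stages (they
"almost disappear" by the silver stage). The filopodia residual
(4 × 0.07 − 0.18 = 0.10) is shipped as the decreasing fixture split
0.06/0.03/0.01; rows left with two unknowns (elver S and LT) split their
residual equally, since exactly those two classes were reported as
statistically indistinguishable. Every cell carries a `printed`/`derived`
provenance tag, and infeasible inputs (a printed class mean exceeding its
stage total) raise a calibration error. The resulting table:

| stage | M | LT | S | F | total |
|---|---|---|---|---|---|
| glass | 2.65 | 2.60 | 1.24* | 0.18 | 6.67 |
| elver | 2.33 | 1.03* | 1.03* | 0.06* | 4.45 |
| yellow | 1.50 | 0.92* | 1.28 | 0.03* | 3.73 |
| silver | 2.52 | 1.53* | 1.65 | 0.01* | 5.71 |

(* derived.) The balanced pooled LT mean of this table is 1.52 vs the
printed 1.51 — inside the stated ±0.02 band; the other pooled means match
to the printed precision.

**Counts.** Per class, a segment of length L gets a count with mean
rate × L/10 and variance φ × mean. φ = 1 (the default) is Poisson; φ < 1
uses a moment-matched binomial, φ > 1 a gamma-mixed Poisson. The published
SEs (0.15 at mean 6.67 with n ≈ 77 → SD ≈ 1.32) hint at sub-Poisson
spread, but the real per-segment distribution is unknowable from printed
summaries, so no φ is claimed as "the study's"; φ = 1 is the stated test
condition and the knob is exposed.

**Geometries.** Class-conditional draws sit strictly inside the
classification rules, so the generator→classifier round trip is exact by
construction: M has neck_max ∈ [0.2, 0.5] µm, neck_length ∈ [0.3, 0.95] ×
neck_max, head = neck_max × U[1.3, 2.5]; LT has neck_max ∈ [0.10, 0.35] µm
(no published range; chosen slender so heads stay sub-micron),
neck_length ∈ [1.1 × neck_max, 4 × neck_max + 1]; S draws total length in
[0.3, 0.95] µm and F in [10.5, 15] µm. Headed total lengths are
neck_length + head_diameter (the head modelled as an axial bulb). No
headless geometry ever lands in the ambiguous 1–10 µm band. Biometrics are
drawn independently of density, reproducing the null regression finding
without inventing a coupling.

**What the generator does not emulate** — staining sparsity (~5% of
neurons), tracing/measurement error, observer disagreement, within-animal
correlation of segments, and any real dispersion structure. Passing
recovery tests therefore demonstrate that the pipeline is an unbiased,
correctly-normalised estimator under the stated design, not that the
biological effect sizes would re-emerge from new material.

## Numerical and scale choices

Problem sizes: recovery checks use 2000 segments/stage (Monte-Carlo SE
≈ 0.05 spines/10 µm at the glass-stage mean, so ±2 SE ≈ ±0.11); the
generator→classifier round trip uses 10,000 draws/class; the Dunn
permutation oracle 200,000 permutations; the type-I-error simulation 2,000
replicates (k = 4, n = 20, empirical α required in [0.035, 0.065]); the
null-regression check 200 study repeats; the qualitative stage-contrast
check 100 repeats. Degenerate inputs fail loudly: all-identical
observations raise a dedicated error rather than returning H = 0/0;
stages with a single segment are rejected (SE undefined); constant density
returns R² = 0 by definition. Ties in the profile minimum resolve to the
first (most proximal) occurrence.

## Known limitations

- The head-detection algorithm is an in-silico stand-in for an
  interactive judgement; its two thresholds are conventions, and real
  reconstructions may need different values.
- Segments are treated as independent; no mixed-effects structure per
  animal or neuron (deliberately matching the source design).
- The SWC spine encoding (single child node, custom tag 7) stores spine
  tips, not full spine profiles; round-tripping geometry through SWC
  preserves the node table, not per-spine diameter profiles.
- Published inferential statistics are not reproduction targets (see
  above); only calibration arithmetic, mean recovery, the null
  regressions and qualitative contrasts are.
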