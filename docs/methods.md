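# Methods

This note records the models, conventions, and numerical choices behind
`myosize`, and what the synthetic-data tests do and do not demonstrate
about real histology.

## Fiber-size model

Per-fiber minimum Feret diameters within a normal biopsy are modeled as
i.i.d. lognormal. The lognormal is the natural choice for a positive,
right-skewed size variable and qualitatively reproduces the mean > median
pattern seen in the packaged normative cells; the normative source data
name no distributional family. Parameters are moment-matched to a target
mean m and SD s:

    sigma^2 = ln(1 + s^2/m^2),    mu = ln(m) − sigma^2/2,

so the lognormal's first two moments equal the targets exactly; the
zero-variance limit degenerates to all fibers at m. Packaged cohort
medians are reported alongside but are *not* calibration targets: they
are not jointly consistent with a single lognormal matched to the mean
and SD (e.g. the oldest male cell's printed median exceeds its
lognormal-implied one), so matching them too would require a different
family with no supporting evidence. "Pooled" parameters for a cohort
combine the two sexes' moments as a fiber-count-weighted mixture before
moment matching.

Fiber cross-sectional areas in measurement-level synthesis are derived
from the diameter as π(d/2)² times a shape factor uniform in [1.0, 1.4]
— enough to exercise the area filter; no joint area/diameter model is
claimed. Synthetic cohorts add a per-biopsy lognormal scale jitter with
CV 0.15, chosen from the typical between-biopsy SD/mean ratios of the
packaged percentile cells (≈0.10–0.26), so normative SDs are realistic
rather than pure sampling noise.

## Synthetic sections

Section images emulate a transverse pediatric muscle section: fibers are
the cells of a Voronoi tessellation of uniformly seeded points after 3
Lloyd relaxations, shrunk by half the interstitium width (default 2 μm)
on each side, rendered eosin-pink with per-fiber tint jitter on a pale
background, with dark nuclei at a third of the boundary vertices and a
few capillary-like disks (default 6, 20–200 μm², deliberately straddling
the 50 μm² area filter) in the background margin. Pixel size defaults to
0.25 μm/px, a 40× scan scale.

Point density is calibrated so the mean cell minFeret hits the cohort
target: for hexagon-like cells of area A the across-flats width is
√(2A/√3), and Lloyd-relaxed random cells measure 0.94× that prediction
(constant measured once on an independent calibration tessellation);
the generator enforces its contract that the realized ground-truth mean
is within 10% of target. Only the *mean* fiber size is geometric ground
truth in sections; the minFeret *spread* of a tessellation (CV ≈ 0.17)
is narrower than real biopsies, so distribution-shape claims are tested
on measurement-level synthesis, not on rendered sections.

What the pseudo-H&E is not: a stain-realistic simulator. There is no
freezing artifact, no stain variability, no fiber typing, no touching
fibers without interstitium. Passing segmentation QC here shows the
pipeline is correct on well-separated convex fibers with clean contrast
— the regime the QC rule itself presumes — not that it matches
commercial software on degraded slides.

Rasterization of ground-truth polygons erodes each outline by a quarter
pixel before center-inclusion scan conversion, so the union of pixel
squares tracks the true outline without systematic dilation. Boundary
quantization still perturbs each caliper contact point by up to half a
pixel; the measured mask-vs-polygon minFeret error is mean ≈ +0.13 px
with ~98–99% of fibers within 1 px and worst cases ≈ 1.3 px, which is
the attainable limit for center-based rasterization.

## Segmentation and sampling

Tissue detection: Otsu threshold on inverted luminance, morphological
closing (disk radius 5 px) to absorb interstitial gaps, hole filling,
largest connected component. Binary inputs are taken as already-detected
tissue. Fiber/interstitium classification: Otsu on the red−green
("pinkness") channel within tissue for RGB inputs, inverted-luminance
Otsu for grayscale. Instances: Euclidean distance transform, Gaussian
smoothing (σ = max(1, r/6) px where r is the median per-component
inscribed radius), peak markers at min separation 1.4 r, one fallback
marker per unmarked component, then marker-based watershed constrained
to the fiber mask. All steps are deterministic.

The counting frame is the Gundersen unbiased frame: inclusion edges top
and right, exclusion edges bottom and left together with their
extensions. For connected pixel objects the extended exclusion line is
equivalent to two forbidden regions — any pixel left of the frame above
the bottom line, or below the bottom line left of the right line — and
tiling a field with adjacent frames counts every object exactly once
(verified by brute force on random fields). Default frame fraction 0.70
of the field, configurable within the stereological 0.5–0.75 range.

Recognition QC: ground-truth fibers are matched one-to-one to predicted
labels greedily by descending IoU with a 0.5 threshold (a visual
"appropriately recognized" judgment made concrete); QC passes when the
matched fraction exceeds 0.95.

## Morphometry conventions

Object outlines follow the outer pixel-corner convention (pixels are
closed unit squares), so an n×n-pixel object measures n pixel-sizes and
small objects are not underestimated. minFeret is exact rotating
calipers on the convex hull: the minimal width is attained flush against
a hull edge, so it equals the minimum over edges of the farthest-vertex
distance. The brute-force sweep oracle evaluates projection widths every
`angle_step` degrees and upper-bounds the exact value; its overshoot is
bounded by maxFeret·tan(step/2), i.e. relative error ≈ aspect ratio ×
8.7·10⁻⁴ at 0.1°, which is why oracle-equivalence tests use a 0.02°
sweep for a uniform 10⁻³ bound and the geometric bound at 0.1°.
Degenerate (collinear) polygons report width 0 with a warning.

Filters are inclusive on both ends: area in [50, 50 000] μm², and
per-cohort minFeret plausibility ranges shipped as an editable CSV
(columns `cohort, minferet_min_um, minferet_max_um`). The shipped
defaults (2–120 μm for every cohort) are permissive placeholders — the
study-derived per-age thresholds are not published in the main tables —
so users should substitute laboratory-specific ranges.

## Statistics

Percentiles are linear interpolation between order statistics
(`numpy.percentile` default); SDs use the n−1 denominator. Histograms
use half-open bins [k·w, (k+1)·w) anchored at 0, default width 5 μm.
Cumulative curves are the empirical CDF at the sorted values.

Age cohorts partition [0, 312) completed months: quarterly bins through
the first year (12 months belongs to "10-12 months"), "1 year" = months
13–23, yearly bins through age 9, then 10-12, 13-15, 16-18, 19-21 and
22-25 years (through the 25th year). Normative tables are two-stage
(per-biopsy percentiles, then mean ± SD across biopsies per cohort/sex
cell); a single-biopsy cell reports no SD. The source study's
fiber-level mixed-effects regressions are deliberately replaced by this
two-stage procedure plus per-level Welch two-sample contrasts between
sexes — it matches the structure of the published percentile tables,
avoids an unidentifiable model family choice, and is calibrated (type-I
error ≈ 5% in null simulations). No multiple-testing correction is
applied across the 18 cohorts × 5 levels, matching how the reference
p-values are reported. Growth-curve exports optionally pool the sexes
through the "2 years" cohort (biopsy-count-weighted), where no sex
effect exists.

Two cells of the packaged percentile reference are internally
non-monotone as printed in the source (4-6-month male p50 > p75;
13-15-year male p25 < p5, presumably typographic); they are shipped
verbatim, and the monotonicity invariant is enforced only on tables the
package computes.

## Query comparison

z(level) = (query percentile − normative mean)/normative SD; shift
index = query median / normative mean median; dispersion index = query
IQR / normative mean IQR. Flags: uniform-smallness iff all five z ≤ −2
and dispersion < 1.5; excess-variation iff dispersion ≥ 1.5 and
|z(50)| < 2; mixed iff all z ≤ −2 and dispersion ≥ 1.5; else
within-normal. The −2/1.5 thresholds are this package's
operationalization of qualitative disease patterns — not published
cutoffs — and are arguments of `compare_to_norms`. Normative bands in
overlay checks use the min-max envelope of cohort curves; the
variance-inflation transform floors diameters at 0.5 μm to preserve
positivity, which only affects the extreme lower tail at large factors.

## Validation protocol

Seven size percentiles (min, 10, 25, 50, 75, 90, max) per measurement
set, symmetric percent difference 100·(a−m)/((a+m)/2) reported to one
decimal, pass iff every size percentile is within 15%. The symmetric
denominator is inferred from the published validation counts, all six of
which it reproduces exactly to the printed decimal; the published size-
percentile cells were computed from unrounded data and cannot be
recovered from the printed values, so they are not targets. Total counts
are reported but excluded from the pass criterion, since compared
regions need not contain identical fiber sets.

## Problem sizes and determinism

Default test and acceptance scales: 2·10⁵ draws for moment recovery
(standard error of the mean ≈ 0.012 μm for the infant cell), 10⁶ draws
per cell for the 1% moment-matching property, 300–500-fiber sections
(≈1700–2200 px square at 0.25 μm/px) for segmentation QC, 12 biopsies ×
15 000 fibers for pattern-flag recovery. Every stochastic step takes an
integer seed into `numpy.random.default_rng`; identical seeds give
bit-identical tables, masks, and images. Output files carry a
provenance header (version, seed, config hash).

## Known limitations

- The pseudo-H&E renderer is schematic; segmentation performance on real
  slides (stain variation, freezing artifact, touching fibers) is out of
  scope and untested.
- Sections reproduce target mean size but not the full size
  distribution; distributional claims rest on measurement-level
  synthesis.
- The packaged normative constants are summary statistics; per-biopsy
  reference data are unavailable, so sex contrasts cannot be recomputed
  for the reference table, only for user- or synthetically-built tables.
- Cohort minFeret filter defaults are placeholders, not study values.
- No fiber typing, no whole-slide pyramid formats, no smoothed
  (LMS/GAMLSS-style) growth-chart fitting.
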