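# Methods

## Vessel caliber summarization

Branch widths are combined with the revised branching formula
ω = k·√(w₁² + w₂²), k = 0.88 for arterioles and 0.95 for venules. (Published
restatements of the formula pair sometimes mislabel the venule line; the
constants, not the labels, are authoritative here: 0.95 belongs to veins.)
The iterative reduction sorts widths descending and pairs widest with
narrowest; an odd median carries unchanged to the next round. For n = 4 the
result equals k²·√(Σwᵢ²) and is provably independent of the pairing order,
so the tie-breaking order among equal widths is irrelevant there; for n ≥ 5
the pairing convention matters in principle and the sorted
largest-with-smallest rule is the contract. Full floating precision is
carried through every round — the familiar two-decimal intermediates are
display rounding, and both conventions agree at the printed precision for
the four-vein case.

Widths are millimeters end to end; the CSV reader accepts μm with an
explicit unit column or flag and divides by 1000 on ingest. Single widths
pass through unchanged; empty lists and non-positive or implausibly large
widths (≥ 1 mm on a 6 mm scan) are rejected. The protocol mode
(`strict_four`) requires exactly four widths per vessel type — the largest
vessel in each peripapillary quadrant; the lenient default accepts 1–8 per
type and logs deviations, since the revised formula is robust to the number
of vessels measured.

## Calibration and ONH morphometry

All physical measurements flow through one linear scale: mm_per_px =
known_distance_mm / known_distance_px, with the 6 mm scan width as the
canonical known distance. Image pixel dimensions vary by device, so the
pixel distance is always a per-image input. Coordinates follow the image
convention (origin top-left, y down); "vertical" is the image y axis with
no rotation correction, matching how annotation tools report it. Polygon
areas use the shoelace formula on the (possibly sub-pixel) vertices;
self-intersecting outlines are rejected at ingest (shapely validity test)
rather than silently folded into a signed-area artifact. The vertical
cup/disc ratio is the ratio of ROI vertical extents — an interpretation:
"vertical diameter" could also mean the widest vertical chord, which for
convex, roughly elliptical discs and cups coincides with the extent.
Neuroretinal rim height is a pass-through input from the OCT device
software; no algorithm for it is implemented. Cup-inside-disc is enforced
on areas and vertical extents only (never clamped, always rejected);
hand-drawn ROIs guarantee nothing stronger than that.

## Statistics

Group comparisons are two-sided independent-samples t-tests, pooled
variance by default with a Welch option — reported cohort tables in this
field are typically the pooled (primary SPSS) line, and the pooled variant
also reproduces the expected borderline non-significance of the CRAE
comparison at the default scenario's moments. Categorical variables use
Pearson chi-square without continuity correction by default (Yates optional
by flag). Missingness is listwise within each analysis block (RNFL / ONH /
vessels), so block Ns differ, mirroring real per-section exclusions.
Correlations with HGB are Pearson, within the HAPC group only, with R² = r²
annotated on the HGB–CRVE scatter. Raw p-values only; no multiplicity
adjustment; significance fixed at 0.05. One record per subject (right eye)
is enforced at ingest to avoid inter-eye correlation.

## Synthetic cohort generator

The generator emulates the study design: ~51 HAPC and ~50 healthy
high-altitude subjects with group means/SDs for every variable, per-block
missingness (43/42 ONH, 47/33 vessel eyes by default) and a bivariate
Gaussian dependence between HGB and CRVE in the HAPC group (default
r = 0.469). Distribution shapes are an assumption — the study conditions
state only means and SDs — and truncated normals with physiological bounds
are used throughout (RNFL 30–300 μm, CRVE 0.05–0.6 mm, CDR 0.02–0.98,
etc.).

Two numerical choices matter:

* **Moment matching.** The underlying Gaussian (μ, σ) of each truncated
  normal is solved (2-D root find on the truncated mean/SD) so that the
  *truncated* distribution has the configured moments. For mildly truncated
  variables this is a no-op; for CRAE (0.16 ± 0.12 mm on positive support)
  naive truncation would inflate the realized mean by ~0.02 mm and shrink
  the SD by ~15%, distorting both mean recovery and the power of the CRAE
  group test. An infeasible request (an SD larger than the bounds can
  support, or a mean more than 6 SD outside the bounds) raises a config
  error rather than sampling from the wrong distribution.
* **Target-first vessel generation.** Each eye's CRVE/CRAE is drawn first
  and then decomposed into four branch widths: a log-normal spread model
  (log-SD 0.3, consistent with the dispersion of the published four-vein
  example) is rescaled by target/equivalent — exact by degree-1 homogeneity
  of the trunk formula. The stored equivalent is the *re-summarized* value
  of the stored branches, so pipeline round trips are bit-exact. Branch-first
  generation would have required calibrating branch moments by search to hit
  group-level vessel moments.

ONH values are rendered as 64-gon circle (disc) and ellipse (cup)
annotations whose polygon area and vertical-extent ratio equal the drawn
disc area, cup area and CDR exactly (the polygon radius absorbs the ~0.16%
n-gon/circle area deficit). Disc/cup/CDR triples are redrawn until
cup ≤ disc (rejection mass ~1e-4 at default moments, so marginal means are
unaffected); a rare wide shallow cup may extend horizontally past the disc
circle — containment is checked on area and vertical extent only, matching
the measurement contract. HGB–CRVE pairs are drawn jointly before
truncation; at the default moments both truncation boundaries lie > 5 SD
out, so the realized correlation equals the configured one to sampling
precision. The effective pair count for correlation-recovery checks
defaults to 38 (configurable): the analyzable overlap between vessel eyes
and the correlation analysis is ambiguous in practice, and 38 sits midway
between the plausible extremes (33–47).

The generator does **not** emulate: measurement error of the human
annotator (targets are hit exactly), inter-eye or intra-rater correlation,
age/sex effects on retinal parameters (covariates are drawn independently),
non-Gaussian tails, or any altitude-exposure dynamics. Passing recovery
tests therefore demonstrates that the pipeline's arithmetic and plumbing
are faithful — not that the biological effect sizes would replicate in new
cohorts.

## Problem sizes and determinism

Recovery and significance-pattern checks use batches of 200 replicate
cohorts (~10⁴ eyes per variable), enough to pin batch standard errors well
below the effects of interest; type-I calibration uses 2000 null
replicates. Every stochastic path takes a single integer seed through
`numpy.random.default_rng`; identical config + seed reproduces cohorts,
CSVs and report hashes byte for byte (SVG output uses a fixed hash salt and
no timestamp).

## Known limitations

* The iterative pairing rule for n ≥ 5 vessels follows the sorted
  convention; published practice varies and ties are broken by sort
  stability.
* The chi-square consistency of the demographic sex table is checked
  directionally (non-significance), not as an exact value; printed
  p-values for 2×2 tables depend on unstated correction choices.
* `compare_groups` assumes approximate normality within groups; no
  nonparametric fallback is provided.
* The CLI's `full` subcommand regenerates ONH rim heights from the cohort
  covariate file rather than the annotation JSON, which carries geometry
  only.
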