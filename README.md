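# retina-quant

Quantification of retinal structure for two-cohort high-altitude studies:
summarization of branch retinal vessel calibers into central vessel
equivalents, scale-calibrated optic-nerve-head (ONH) morphometry from manual
image annotations, and the cross-sectional statistical comparison of a
high-altitude polycythemia (HAPC) cohort against healthy high-altitude
residents, including the hemoglobin (HGB) correlation analysis.

It is written for ophthalmic researchers who measure branch vessel widths
and draw disc/cup regions of interest on en-face OCT scans (e.g. with
ImageJ) and need a reproducible, auditable path from those raw annotations
to the summary tables of a cohort paper. A parameterized synthetic-cohort
generator makes the whole pipeline testable without patient data.

## The model

The caliber of the central retinal artery/vein is summarized from the
calibers of its branches with the revised branching (Knudtson) formula

    ω = k · √(w₁² + w₂²),   k = 0.88 (arterioles), 0.95 (venules)

where w₁ and w₂ are a pair of branch widths and ω the implied parent-trunk
width. With the four largest branches per type (the largest vessel crossing
a 3.4 mm peripapillary circle in each quadrant), the formula is applied
iteratively — widest with narrowest, second-widest with second-narrowest,
the survivors re-paired — until one value remains: the central retinal
artery equivalent (CRAE) or vein equivalent (CRVE). AVR = CRAE/CRVE. For
four branches the reduction collapses to the closed form k²·√(Σwᵢ²) and is
independent of pairing order.

ONH morphometry converts pixel annotations into physical units through a
single scale calibration (the 6 mm scan width against the image width in
pixels): shoelace polygon areas for cup and disc (mm²), and the vertical
cup/disc ratio as the ratio of the ROI vertical extents. Group comparisons
use independent-samples t-tests (pooled by default, Welch optional) and
Pearson chi-square for categorical variables; associations with HGB are
Pearson correlations within the HAPC group. Raw p-values, significance at
0.05.

## Worked example

The four largest branch veins of one eye measured 0.148, 0.101, 0.195 and
0.204 mm:

```python
>>> import retina_quant as rq
>>> rq.knudtson_pair(0.204, 0.101, "vein")   # widest with narrowest
0.21625180346068792                           # -> 0.22 mm
>>> rq.knudtson_pair(0.195, 0.148, "vein")
0.23256380307347915                           # -> 0.23 mm
>>> rq.summarize_equivalent([0.148, 0.101, 0.195, 0.204], "vein")
0.3016915898935534                            # CRVE -> 0.3 mm
```

The two first-round reductions (0.22 and 0.23 mm at display rounding) pair
into a CRVE of 0.30 mm — full precision is carried throughout; rounding is
display-only.

A complete synthetic study, from generation to report:

```
retina-quant full --scenario paper_default --seed 1 --out run/
```

writes `branches.csv`, `annotations.json` and `cohort.csv`, re-summarizes
and re-measures them through the pipeline, and produces a report whose
vessel block reads (seed 1):

```
CRVE (mm)   0.26 ± 0.03   0.20 ± 0.02   < 0.001*
CRAE (mm)   0.14 ± 0.11   0.12 ± 0.04     0.296
AVR         0.54 ± 0.44   0.59 ± 0.22     0.595
```

i.e. dilated veins in the HAPC cohort at p < 0.001 with comparable arterial
caliber — alongside a nasal RNFL comparison (75.87 ± 13.72 vs
67.93 ± 14.99 μm, p = 0.007 at this seed) and a within-HAPC HGB–CRVE
Pearson correlation with its R² annotation on the scatter plot. Library
equivalents: `generate_cohort`, `build_report`, `compare_groups`,
`correlate_hgb`.

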