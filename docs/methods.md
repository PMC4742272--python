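# Methods

## The measurement model

All analysis happens on 8-bit grayscale transmission-EM images (digital
numbers, DN, 0–255) at a fixed magnification; areas are pixel counts and
lengths pixel units, so both scores are magnification-bound quantities.

### Intensity scale and thresholds

The method's thresholds are stated on a 256-level grayscale counted 1–256,
in which the "highest quartile" spans the top 64 levels.  Internally DN run
0–255 and each threshold is converted by subtracting one and applied
inclusively:

| parameter | default | meaning |
|---|---|---|
| `t_peri` | 145 | perinuclear condensed chromatin: DN ≥ 145 |
| `t_cond` | 192 | condensed chromatin (top quartile): DN ≥ 192 |
| `zdisk_lo`, `zdisk_hi` | 154, 164 | accepted Z-disk window after calibration |
| `zdisk_target` | 159 | calibration gain target (window midpoint) |
| `closing_radius` | 1 px | morphological closing of the rim mask |
| `min_interior_area` | 500 px | smallest enclosure that counts as a nucleus interior |
| `nucleolus_min_frac` | 0.05 | smallest interior fraction a nucleolus may occupy |

Whether the original software's 256-value scale was 0–255 or 1–256 is not
documented; the off-by-one convention above is a package choice, and every
threshold is overridable in `ThresholdConfig`.

### Z-disk calibration

EM image brightness varies with exposure and staining.  The sarcomeric
Z-disk serves as an internal density reference: the image is mapped by
`DN → round(gain · DN)` clamped to [0, 255] with
`gain = zdisk_target / mean(DN in Z-disk ROI)`.  The map is gain-only
(anchored at DN 0), not affine: the correction is a *ratio* to the
reference density and DN 0 must remain "no signal".  Calibration fails
loudly when the recomputed ROI mean leaves the accepted window (saturated
image); clipping more than 1% of pixels logs a warning.  Properties that
hold by construction and are tested: idempotence to ±1 DN (rounding),
monotonicity in DN, and equivariance under pre-clamp rescaling of the
input.

### Ring extraction and continuity

Perinuclear condensed chromatin is the thresholded set DN ≥ `t_peri`
inside the nucleus ROI (one nucleus per ROI), closed with a disk of radius
`closing_radius` to bridge sub-resolution staining cracks.  Among its
8-connected components the *rim* is the one enclosing the most area
(largest hole-filled pixel count, raw count as tie-break).  Ranking by raw
pixel count alone would misbehave: a large solid nucleolus can outweigh a
thin rim, and it must not displace it.

Continuity is a topological decision, not an arc-length measurement: the
rim is continuous iff hole-filling it leaves an enclosed interior (fill
minus rim, largest component) of at least `min_interior_area` pixels.
This matches the operational definition of the first-step classifier —
a discontinuous nucleus is exactly one that cannot be clipped out of the
field.  Foreground uses 8-connectivity, the background flood
4-connectivity (the standard complementary pair).  The verdict provably
equals "a border-seeded background flood fill reaches no qualifying
enclosed region", and the test suite checks that equivalence directly.

### Nucleolus

The nucleolus is excluded from both the numerator and denominator of
Nuc-CS.  Automatic detection takes the largest condensed
(DN ≥ `t_cond`) component of the interior and accepts it only when it
covers at least `nucleolus_min_frac` (default 5%) of the interior —
scattered heterochromatin specks never qualify.  A user-supplied nucleolus
mask overrides detection.  Note the semantic consequence: a dense body
below the qualification fraction is, by definition, indistinguishable from
condensed chromatin and is scored as such.

### Inner perimeter

The inner nuclear perimeter is the length of the 0.5-level iso-contour of
the interior region (marching squares with sub-pixel interpolation).  The
raw contour of a *binary* digitized disk systematically overestimates the
smooth circumference by ~5%, so the indicator is Gaussian-smoothed
(σ = 1 px) before contouring; the smoothed level set tracks the underlying
boundary to well under 2% for both squares and disks (+0.4% on a
radius-100 disk, −0.9% on a 100-px square).  Regions too small to survive
smoothing fall back to the raw contour so degenerate inputs still return a
small positive length.

### Scores, classification, aggregation

- `Nuc-CS = 100 · |{DN ≥ t_cond} ∩ interior \ nucleolus| / |interior \ nucleolus|`
- `Per-CS = |{DN ≥ t_cond} ∩ rim| / inner perimeter`

The Per-CS numerator is the condensed subset of the rim mask (delineated
at the lower `t_peri` threshold); this is the only reading that reconciles
the two stated thresholds.  Scores are undefined for discontinuous nuclei.

A patient is Group A when all nuclei are discontinuous and Group N when
all are continuous; observed cohorts show no mixing, so mixed verdicts are
resolved by majority vote (ties to A, the high-risk group) and flagged
inconsistent.  The patient-level score is the arithmetic mean over nuclei
(the aggregation rule is not fixed by precedent; the per-patient
variability report also carries the 10/25/50/75/90th percentiles).  The
two-step rule assigns Group A to high risk outright; a Group N patient is
elevated-risk when *either* mean score falls at or below its cutoff
(OR-combination — each score is independently discriminative).  No
validated cutoffs exist, so both default to "none" and the rule is
report-only.

### Fibrosis

Collagen in Masson-trichrome scans is detected by an HSV band test (hue
180–260°, saturation ≥ 0.2, value ≥ 0.2 — the minima reject near-gray and
near-black pixels whose hue is meaningless), and percent fibrosis is the
blue fraction of the tissue mask after subtracting the user-supplied
endocardium mask.  Band thresholding was chosen over stain deconvolution:
the reference procedure is simple color detection, and the band is
configurable for stain variability.

### Cohort statistics

- Two-sample comparisons: Student's t with pooled variance, or
  Mann-Whitney U — exact by full enumeration of group assignments
  (tie-safe) when both arms have ≤ 9 observations, tie-corrected normal
  approximation otherwise.
- 2×2 outcome table: per-group event percentages rounded half-up
  (presentation convention), chi-square without continuity correction
  (df = 1) or Fisher's exact test (default, appropriate with a zero cell).
- ROC: all-pairs concordance AUC (ties half), DeLong structural-components
  95% CI truncated to [0, 1].  Orientation is explicit ("low" = smaller
  score predicts events, the convention for both chromatin scores) and is
  never auto-flipped.
- ICC: two-way random, absolute agreement, single measures — ICC(2,1) —
  from the two-way ANOVA mean squares, CI by the Satterthwaite F
  approximation.  Identical-rater grids short-circuit to ICC 1 with a
  degenerate CI.

## The synthetic world

The generator emulates what the measurement model needs, not EM
photorealism: a dense perinuclear annulus (optionally interrupted by gap
arcs), non-overlapping condensed particles in the nucleoplasm
(dart-throwing with rejection, ≤ 10,000 attempts; density is an
expectation and the realized value is recorded), an optional central
nucleolus disk, Z-disk stripes outside the nucleus, and additive truncated
Gaussian noise (seeded NumPy PCG64, portable across platforms).

Default DN levels put each structure on the correct side of the default
thresholds: background 60, nucleoplasm 100, ring 200, particles 210,
nucleolus 230, Z-disk 159.  Ground truth carries the noiseless masks, the
realized particle count, and analytic expectations:
`expected Nuc-CS = 100 · particle px / (interior px − nucleolus px)` and
`expected Per-CS = t + t²/(2r)` (annulus area over inner circumference)
for inner radius `r` and thickness `t`.

Stated-world parameter choices, made once:

- Random sweeps draw inner radius U(40, 70) px and ring thickness
  U(2.3, 6.5) px, so expected Per-CS spans the 2.3–6.3 px range the method
  reports in practice; particle density U(1, 7) per 1,000 px spans Nuc-CS
  ~1–9%.
- A nucleolus, when present, has radius 0.25–0.35 of the inner radius
  (6–12% of the section area) — the realistic size, and above the 5%
  detector qualification; smaller bodies are semantically condensed
  chromatin (see above).
- The default nucleus center is subpixel-jittered (seeded).  A circle
  centered exactly on a lattice point is a degenerate case whose
  rasterized area shows resonant deviations of up to ~2.5% from the
  analytic value; under a uniform subpixel shift the expected pixel count
  equals the analytic area.  An explicitly supplied center is honored
  verbatim.
- The synthetic cohort mirrors the reference study design: 11
  discontinuous-ring patients (all with a 12-month event: VAD except the
  last two, deaths) and 52 continuous-ring patients with 7 events;
  Poisson(10) nuclei per patient (minimum 3); clinical covariates drawn
  from the two groups' published baseline profiles (age, LVEF, LVEDD,
  log-normal BNP, fibrosis).  A per-patient brightness gain U(0.85, 1.15)
  scales all DN levels so the cohort genuinely exercises calibration.
- The score–event link is perfectly separated by default: event patients
  draw particle density from U(0.85, 2.0) and ring thickness from
  U(2.3, 2.8), non-event patients from U(2.7, 6.7) and U(3.4, 6.0).

What a green synthetic test does *not* establish: performance on real
micrographs.  The generator has ideal circular geometry, piecewise-constant
densities, isolated particles and exactly known annotations; real nuclei
are irregular, chromatin is textured rather than binary, rim density
varies continuously, and ROI/Z-disk annotations carry human error.  The
published per-patient score ranges, AUCs and ICCs depend on the original
micrographs, which are not deposited, and are therefore not reproducible
at the desk; the synthetic suite verifies the *method* (formulas,
topology, calibration, statistics), not the clinical effect sizes.

## Known limitations

- Per-CS is magnification-bound (pixel units at 10,000×); no
  cross-magnification normalization is attempted.
- No automatic nucleus detection: one nucleus per user-supplied ROI.
- Cardiomyocyte vs fibroblast/endothelial nuclei must be distinguished
  upstream (done visually in the reference workflow).
- The exact discontinuity detector of the original (closed-source)
  analysis software is unpublished; the enclosure definition used here is
  a reconstruction with one tunable (`closing_radius`).
- The DeLong CI is symmetric on the AUC scale; published asymmetric
  intervals for this method were presumably computed by another
  (unidentified) method.
- 12-month outcomes are treated as binary; no time-to-event modeling.
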