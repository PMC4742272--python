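# chromoscore

Morphometry of cardiomyocyte nuclear chromatin from transmission electron
micrographs, for quantitative histopathology of severe heart failure.

In dilated cardiomyopathy, the ultrastructure of nuclear chromatin in
cardiomyocytes carries prognostic information: nuclei whose perinuclear
condensed-chromatin rim is *discontinuous* mark patients at very high risk
of a cardiac event (ventricular assist device implantation or death) within
twelve months, and among patients with *continuous* rims, low chromatin
scores mark elevated risk.  `chromoscore` implements that two-step analysis
as a tested Python library and command-line tool:

1. **Z-disk calibration** — each 8-bit EM image is rescaled by a single
   gain so the mean digital number (DN) of the sarcomeric Z-disk reference
   lands in the window [154, 164] (target 159); chromatin DN are thereby
   relative to an internal density standard.
2. **Ring continuity (Group A vs N)** — perinuclear condensed chromatin is
   the dense band at DN ≥ 145.  A nucleus is *Group N* when that rim
   topologically encloses a nucleoplasmic interior, *Group A* when it does
   not.
3. **Chromatin scores** (continuous-ring nuclei only), with condensed
   chromatin the top grayscale quartile, DN ≥ 192:

   - Nuc-CS (%) = 100 · (condensed area in the nucleoplasm, nucleolus
     excluded) / (nucleoplasm area, nucleolus excluded)
   - Per-CS (px) = (condensed area of the perinuclear rim) / (inner
     nuclear perimeter)

4. **Fibrosis** — percent blue-stained area of Masson-trichrome scans,
   endocardium excluded.
5. **Cohort statistics** — Student's t / Mann-Whitney U (exact for small
   samples), chi-square and Fisher's exact test on the 2×2 outcome table,
   ROC/AUC with DeLong 95% confidence intervals, and interobserver
   ICC(2,1).
6. **Synthetic ground truth** — a generator of EM-like nuclei (ring, gap
   arcs, chromatin particles, nucleolus, Z-disk stripes, noise), whole
   cohorts and trichrome slides with analytic expected scores, so every
   stage is verifiable without real micrographs.

## Worked example

Score one synthetic nucleus end-to-end (calibrate → segment → score):

```python
from chromoscore import SyntheticNucleusSpec, make_nucleus, process_nucleus

spec = SyntheticNucleusSpec(seed=42, inner_radius=55, ring_thickness=5,
                            particle_density=4, nucleolus_radius=15)
nucleus = make_nucleus(spec)
res = process_nucleus(nucleus.image, nucleus.roi, zdisk_mask=nucleus.zdisk_mask)
print(f"continuous ring : {res.continuous}")
print(f"Nuc-CS          : {res.nuc_cs:.2f} %")
print(f"Per-CS          : {res.per_cs:.2f} px")
print(f"inner perimeter : {res.inner_perimeter:.1f} px")
```

prints

```
continuous ring : True
Nuc-CS          : 6.58 %
Per-CS          : 5.20 px
inner perimeter : 347.4 px
```

The rim is closed, so the nucleus is Group N.  6.58% of the nucleolus-free
nucleoplasm is condensed chromatin (the generator's analytic expectation is
6.58%), and the rim carries an effective 5.20 px of condensed chromatin per
pixel of inner perimeter (analytic 5.23 px — the residual is rasterization
error).  A discontinuous nucleus would report `continuous ring : False`
with no scores, which is itself the high-risk first-step verdict.

## Command line

```sh
chromoscore calibrate --image img.tif --zdisk-mask z.png --out cal.tif --report cal.json
chromoscore segment   --image cal.tif --roi roi.png --out-prefix nucleus1
chromoscore score     --image img.tif --roi roi.png --zdisk-mask z.png --out scores.csv
chromoscore fibrosis  --image trichrome.png --out fib.json
chromoscore cohort    --table cohort.csv --score-col nuc_cs --out report.json
chromoscore simulate  nucleus|cohort|trichrome --out DIR
chromoscore run       --manifest batch.yaml --out results/
```

Thresholds and segmentation parameters live in a flat YAML config
(`t_peri`, `t_cond`, `zdisk_lo`, `zdisk_hi`, `zdisk_target`,
`closing_radius`, `min_interior_area`, `nucleolus_min_frac`) passed via
`--config`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's headline behaviour from scratch: it generates
the default synthetic cohort (11 discontinuous-ring patients, 52
continuous-ring patients, ~10 nuclei each, per-patient brightness gain),
runs every nucleus through calibration, segmentation, classification and
scoring, and prints the recovered group split, the per-group 12-month
event rates with Fisher's exact test, and the ROC AUC of both chromatin
scores in the continuous-ring group.

See `docs/methods.md` for the model, parameter defaults, numerical choices
and known limitations.
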