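# nervequant

Quantitative sural-nerve biopsy histology and cross-compartmental
neurofilament light chain (NfL) analysis.

## The problem

NfL is a neuron-specific cytoskeletal protein released into cerebrospinal
fluid (CSF) and blood when axons break down, and serum NfL (sNfL) is an
attractive blood-based marker of disease activity in vasculitic neuropathy —
a condition that is hard to diagnose and to monitor. Whether sNfL reflects
*ongoing* axonal degeneration in the peripheral nerve, rather than the
cumulative axonal loss visible in a biopsy, can only be settled by linking
biomarker levels to histology from the same patients.

`nervequant` implements that linkage as a reusable, fully tested pipeline
for researchers working with sural-nerve biopsy material and matched
biosamples:

* **Histological quantification** of nerve fascicles on calibrated
  brightfield micrographs:
  * NF70 (axonal neurofilament, DAB) % fascicular area — color
    deconvolution, Laplacian-of-Gaussian enhancement, Otsu binarization,
    and a 20–30,000 µm² object-size gate (*chronic axonal loss*);
  * myelinated-fiber density (fibers/mm²) in methylene-blue semithin
    sections via annulus detection (*chronic axonal loss*);
  * degenerating-fiber density — filled dark profiles without an axoplasm
    lumen (*acute axonal degeneration*);
  * CD68 (macrophage, DAB) % fascicular area — rolling-ball background
    subtraction, Yen thresholding, despeckle; normalized to the dataset
    maximum (%max) and averaged over transverse/longitudinal sections;
  * ovoid-fiber fraction in teased single-fiber preparations (Wallerian
    fragmentation).
* **An acute composite score**: degenerating-fiber density, ovoid fraction,
  and CD68 %max are each expressed as % of their dataset maximum and
  averaged per patient (patients without teased fibers are scored from the
  two available components). The two chronic-loss parameters are kept
  separate.
* **NfL post-processing**: detection-limit capping (25,000 pg/mL CSF,
  7,800 pg/mL tissue) with a cap-multiplier sensitivity analysis, tissue
  NfL as % of total protein, serum/CSF ratio (to discount central release),
  and age-specific Z-scores `z = (ln s − µ(age)) / σ(age)` from a pluggable
  log-normal reference.
* **Statistics**: Spearman rank correlation (average ranks under ties) with
  a Fisher-z 95% CI (`tanh(atanh r ∓ 1.96/√(n−3))`) and a two-tailed
  t-approximation p-value; |r| ≥ 0.5 flags a moderately strong
  correlation. A panel runner evaluates every NfL measure against the
  acute composite and both chronic parameters, on all patients and on the
  subgroup without CNS disease.
* **Synthetic data with known truth**: a cohort simulator (log-normal NfL
  with age trend, an acute-degeneration effect on serum, and a CNS-disease
  effect on CSF) and a slide renderer for all four preparation types whose
  stained areas, fiber counts, and ovoid fractions are recorded exactly
  from the painted masks — so every stage is testable without patient
  data.

## Worked example

```python
from nervequant.render import render_ihc_slide, render_semithin
from nervequant.ihc import nf70_area_fraction
from nervequant.morphometry import detect_fibers, fiber_density

slide, rois, truth = render_ihc_slide(target_pct_area=10.0, seed=3,
                                      noise_sd=0.0, illumination=0.0)
print(f"truth {truth.pct_area:.3f}%  measured "
      f"{nf70_area_fraction(slide, rois).pct_area:.3f}%")

slide, rois, _ = render_semithin(50, 7, seed=5, noise_sd=0.0, illumination=0.0)
dets = detect_fibers(slide, rois)
res = fiber_density(dets, rois, slide.microns_per_pixel)
print(f"{res.fiber_count} myelinated fibers ({res.fiber_density:.0f}/mm^2), "
      f"{res.degen_count} degenerating")
```

prints

```
truth 10.139%  measured 10.139%
50 myelinated fibers (1816/mm^2), 7 degenerating
```

— the NF70 chain recovers the rendered truth exactly on a noiseless slide,
and the semithin detector finds all 50 healthy annuli and all 7 filled
(degenerating) profiles.

The full pipeline, end to end:

```bash
nervequant run-all --seed 1 --out results/synthetic_study
nervequant report src/nervequant/data/reference_cohort.csv
```

The first command simulates a 35-patient study, renders and quantifies
every slide, scores patients, and writes the correlation panel and report;
the second summarizes the packaged 35-patient cohort table (23 m / 12 f,
9 with CNS disease, 10 vasculitis of which 6 acute/subacute, median
sample-to-biopsy interval 4 days).

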