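# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `nervequant`, in the order data flows through the package.

## Cohort model

A patient record carries age, sex, free-text clinical and
neuropathological diagnoses, the disease timecourse at biosample
collection, the signed interval Δd (days) between biosample collection and
biopsy (positive = sample first), a three-valued CNS-disease flag
(`yes`/`no`/`unclear`, judged by relevance for serum NfL), and a
vasculitis assignment (`definite_or_probable`/`other`). Records with
|Δd| > 30 days are rejected: beyond a month the biosample no longer
reflects the biopsied state of the nerve.

Timecourse categories follow the clinical convention: **acute** < 1 week
after onset or exacerbation, **subacute** 1–8 weeks, **chronic** > 8
weeks. The 8-week boundary (56 days) is subacute, since chronic is
defined strictly as "more than 8 weeks". The cohort median of Δd is taken
over the *signed* values; on the packaged 35-patient table this gives the
published 4-day median, which an absolute-value median would also give
here, but the signed convention is the one that generalizes (a sample
drawn after the biopsy is not the same as one drawn before).

The vasculitis assignment is stored as an explicit column because it is a
chart-review judgment, not derivable from the diagnosis strings.

## IHC quantification

Both DAB chains start from optical densities: `OD = −log10(I/255)` per
RGB channel (zero flux clipped at 1/255), unmixed by the inverse of the
stain matrix whose rows are per-stain RGB absorbance unit vectors. The
packaged default is the published H-DAB matrix shipped with scikit-image;
negative unmixed densities are clipped at zero, and a near-singular stain
matrix (condition number > 1e8) is an error.

**NF70 (% fascicular area).** The DAB channel is sharpened by unsharp
masking with a Laplacian-of-Gaussian kernel (`enhanced = dab −
σ²·∇²G_σ(dab)`, default σ = 2 px — the scale of the original macro is not
documented, so it is exposed in `Nf70Params`), binarized by Otsu's
threshold computed **from within-ROI pixels only** (background outside
fascicles would bias the threshold; whether the original analysis
thresholded per slide or per ROI is unknown, so per-ROI-union is the
default), labeled with 8-connectivity, and gated to components whose
physical area lies in the inclusive range [20, 30,000] µm² (converted
through the slide calibration). The stained fraction is reported per
fascicle and pooled (total stained area / total fascicular area).

**CD68 (% fascicular area → %max → orientation average).** The DAB
channel is background-corrected with a rolling ball, thresholded by Yen's
method within the ROI union, and despeckled with one pass of a 3×3 median
filter on the binary mask. The rolling-ball radius must exceed the
largest stained structure that is not background; confluent macrophage
clusters can be large, so the default is 120 px, affordable because the
background is estimated on a bilinearly downscaled copy (it is smooth by
construction) and upsampled. Section values are expressed as a
percentage of the dataset's maximum (ties all map to 100; the maximum is
taken over patients with data), and the transverse and longitudinal %max
values are averaged; a patient with only one orientation passes through
unchanged.

**Threshold floor.** Otsu and Yen always return *some* threshold, even on
a slide with no staining, where they would binarize sensor noise. Both
chains therefore floor the automatic threshold at a minimum optical
density (`min_threshold_od`, default 0.10): blank slides measure exactly
0%. A completely uniform ROI (automatic threshold undefined) also yields
0% with a warning.

## Semithin morphometry

Healthy myelinated fibers appear in methylene-blue semithin sections as
dark annuli (myelin) around a pale lumen (axoplasm); acutely degenerating
fibers are collapsed, filled dark profiles. The detector thresholds dark
pixels at the midrange of the within-ROI intensity span — myelin contrast
is high but fibers can occupy an arbitrarily small pixel fraction, which
makes histogram-criterion thresholds (Otsu and relatives) unstable here —
fills holes per 8-connected component, and gates components by equivalent
outer diameter (default 2–20 µm) and circularity 4πA/P² (default floor
0.6). The lumen fraction (filled minus dark, over filled) classifies each
component: **strictly below** 0.10 is degenerating, at or above is
healthy. The strict inequality implements a conservative convention:
borderline profiles count as healthy, so the degenerating count can only
fall as the threshold is lowered. This rule-based classifier replaces the
manual two-reader consensus counting used in diagnostic practice; the
consensus protocol itself is out of scope.

Densities are counts over the summed area of *usable* fascicles (mm²);
fascicles flagged unusable after review contribute neither fibers nor
area, and their number is reported. Detections are assigned to fascicles
by centroid containment (with a 1 px buffer for boundary centroids).

**Teased fibers.** Fibers are traced as horizontal dark bands. A fiber is
*assessable* when its dark span covers ≥ 90% of the strip width (an
operational definition; no published one exists), and *ovoid* when its
longitudinal profile shows ≥ 2 cleared gaps of ≥ 4 px — chains of myelin
ovoids interrupt the osmicated fiber shadow. Fewer than 20 assessable
fibers triggers a warning (20–53 per case is the expected range); zero is
an error.

## Composite score

The three acute parameters are made commensurable by percent-of-maximum
normalization (degenerating-fiber density and ovoid fraction normalized
over patients with data; CD68 is already %max) and averaged per patient.
Teased preparations exist only for a subset of patients, so patients
without an ovoid fraction are scored as the mean of the two available
components (`n_components` records which); fewer than two components
yields a missing score. The score is scale-free in every raw component,
bounded by the extreme components, and exactly the patients holding a
dataset maximum reach 100 in that component. The two chronic parameters
are reported separately — they capture different aspects of axonal loss
and are not composited.

## NfL derivation

CSF and tissue concentrations above the validated assay limits (25,000
and 7,800 pg/mL respectively) are capped at the limit with a flag;
capping is idempotent. Tissue NfL is expressed as % of total protein
(`pg/mL / (mg/mL × 1e9) × 100`). The serum/CSF ratio discounts central
NfL release; when the CSF denominator was capped the true ratio can only
be smaller, so the ratio is flagged lower-bound-uncertain. The
sensitivity analysis replaces capped values by `limit × m` for a ladder
of multipliers (default 1, 1.5, 2, 5; multiplier 1 reproduces the primary
analysis exactly) and re-runs a caller-supplied analysis per rung.

Age-specific Z-scores are computed on the natural-log scale (sNfL is
right-skewed): `z = (ln s − µ(age))/σ(age)`. The packaged reference —
`µ(age) = ln 8 + 0.025·(age − 20)` log-pg/mL, constant σ = 0.5, supported
on ages 18–90 — is a **synthetic stand-in** with plausible adult values
(a baseline of 8 pg/mL at age 20 rising ~2.5%/year). Clinical use
requires supplying reference parameters fitted to a real normative
database via `ReferenceModel`.

## Statistics

Spearman's correlation is computed as the Pearson correlation of average
ranks (scipy's midrank assignment under ties). The 95% CI back-transforms
`atanh(r) ∓ 1.96/√(n−3)` — the Fisher-z construction used by common
commercial packages, an approximation under ties; with n ≤ 3 or |r| = 1
the interval degenerates and is reported as such. The two-tailed p uses
`t = r·√((n−2)/(1−r²))` with n−2 degrees of freedom; an exact permutation
p is available for n ≤ 10. |r| ≥ 0.5 is flagged as moderately strong.
No multiple-testing correction is applied anywhere in the panel.

The analysis panel crosses {serum NfL, tissue NfL, serum/CSF ratio,
age-Z} with {acute composite, NF70 % area, fiber density}, on all
patients and on the subgroup without CNS disease. Patients flagged
`unclear` are **retained** in the restricted subgroup by default
(configurable): the flag marks uncertain relevance, not established
disease, and excluding them would discard usable observations.

## Synthetic data generator

The cohort simulator draws two latent injury levels per patient —
`acute_level` and `chronic_level`, each uniform on [0, 1] via a Gaussian
copula whose correlation defaults to 0 (a knob exists because real
cohorts confound them) — and generates observables:

* `serum = exp(ln 10 + 0.022·(age−50) + 1.5·acute + ε)`, ε ~ N(0, 0.4);
* `csf = exp(ln 500 + 0.022·(age−50) + 1.0·cns + ε)`;
* `tissue = exp(ln 800 + 1.0·acute + ε)`;

ages are uniform on 26–82 years, P(male) = 23/35, P(CNS disease) = 9/35,
P(vasculitis) = 10/35 — the composition of the packaged cohort. The
log-normal form with rank statistics downstream reflects the skew of real
sNfL. The serum↔tissue coupling strength has no published quantitative
anchor; the value here is a modeling choice. Histology targets are
deterministic monotone maps of the latents: fiber density
`700·(1 − 0.85·chronic)` /mm², NF70 area `30·(1 − 0.8·chronic)` %,
degenerating density `250·acute` /mm², CD68 area `0.5 + 12·acute` %,
ovoid fraction `0.75·acute`.

The slide renderer composites DAB chromogen with the same H-DAB
optical-density model the segmentation inverts, over a pale hematoxylin
counterstain (OD 0.15) inside elliptical fascicles; semithin fibers are
placed by rejection sampling without overlap; teased strips draw intact
fibers as continuous bands and ovoid fibers as fragment chains. Ground
truth is always measured from the painted masks, never echoed from the
request. Sensor effects are additive Gaussian noise (SD 3 intensity
units) plus a ±3% linear illumination ramp — enough to make thresholding
non-trivial, far short of real slide variability. Default calibration is
0.5 µm/px (a 40× scan analogue), configurable.

**What the generator does not emulate:** stain variability between
laboratories, tissue artifacts (folds, edge effects, crush), non-circular
and overlapping fiber profiles, partial-volume edges, scanner focus
gradients, and any pharmacokinetics of NfL release or clearance. Passing
the recovery tests therefore demonstrates the correctness of the
quantification logic, not performance on real slides.

**Problem sizes.** The replicated end-to-end experiment (200 synthetic
studies of 35 patients, five images per patient) uses small rasters —
64 px IHC fascicles and 160 px semithin sections at 1 µm/px, rolling-ball
radius 8 px — chosen so a full replication run completes in minutes on a
single core. The nominal fiber densities (healthy 700/mm², far below the
several-thousand/mm² of a real sural nerve) keep non-overlapping fiber
placement feasible at these raster sizes; rank correlations are
unaffected by the common scale factor. Single-slide accuracy checks use
256–768 px rasters at 0.5 µm/px.

## Numerical conventions

* Pixel coordinates are 0-based, x = column (rightward), y = row
  (downward); polygon areas use the shoelace formula (shapely), raster
  masks pixel-center containment.
* Connected components use 8-connectivity throughout.
* Threshold ties inside Otsu/Yen resolve to scikit-image's standard
  lowest-bin maximizer.
* Size and diameter gates use inclusive bounds.
* All randomness flows from explicit integer seeds; per-patient,
  per-stage render seeds are spawned from the master seed with
  `numpy.random.SeedSequence`, so any study is bit-reproducible and
  output CSVs are byte-identical across re-runs.

## Known limitations

* The fiber detector assumes well-separated, roughly circular profiles;
  touching fibers merge into one component and large or crenated axons
  may fail the circularity gate.
* The Fisher-z CI and t-approximation p are asymptotic; at n < 10 with
  heavy ties both are rough (the exact permutation option exists for the
  p-value only).
* The packaged age reference is synthetic; Z-scores from it are for
  pipeline exercise, not clinical interpretation.
* %max normalization makes scores dataset-relative: scores are not
  comparable across cohorts, only within one.
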