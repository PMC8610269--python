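# Methods

## Problem and scope

`cavquant` quantifies a target protein — caveolin-1 (Cav-1), a marker whose
loss in tumor stroma indicates an aggressive cancer-associated-fibroblast
(CAF) phenotype — separately in the stromal and epithelial compartments of
tissue-microarray (TMA) cores, and carries the resulting per-subject scores
through the clinical-association analyses typical of a two-cohort biomarker
study: group comparisons across clinicopathologic subgroups, responder
classification, and overall-survival analysis. Two assay arms are modeled:

* **multiplex immunofluorescence (IF)** with digital image analysis —
  pixel-level compartment masks from marker logic and an
  exposure-normalized intensity-per-area score;
* **immunohistochemistry (IHC)** with semi-quantitative pathologist scoring
  — the H-score as the product of categorical intensity and percent-positive
  bins.

## Compartment segmentation

Compartments are pixel sets defined by marker logic, not cell segmentation:

* *epithelium* = pancytokeratin-positive (panCK+) pixels;
* *stroma* = vimentin-positive pixels that are panCK-negative **and** lie
  within a nucleus-association radius of a DAPI-positive pixel.

Because vimentin is a promiscuous mesenchymal marker that can also stain
tumor epithelium, vimentin+/panCK+ pixels are assigned to epithelium only;
this exclusion makes the two masks disjoint by construction. DAPI is
nuclear while vimentin is cytoplasmic, so the two signals rarely share
pixels; "stroma requires a nucleus" is therefore implemented as proximity
(default radius 10 px, configurable) to a DAPI+ pixel rather than pixelwise
conjunction, which would yield an empty compartment. Whether the original
assay applied the nucleus requirement per pixel or per object is not
knowable from the outside; the radius rule is this package's reading and is
recorded in the segmentation parameters.

Positivity thresholds default to Otsu's method per channel — reproducible
and data-driven — with a fixed-threshold override for controlled
experiments; the thresholds actually used are returned with the masks. A
constant (e.g. all-zero) channel produces a warning and an empty mask, not
an error. Connected regions below `min_region_px` (default 0, i.e. off)
can be removed to suppress speckle.

## The compartment score

For a compartment mask M with area |M| pixels and target-channel exposure
time e (milliseconds),

    score = scale · ( Σ_{p∈M} I(p) / |M| ) · ( e_ref / e )

i.e. mean target intensity per unit area normalized to a reference exposure
(e_ref = 100 ms), making the score proportional to protein concentration
(molecules per unit area) in arbitrary units. Only the whole-cell
("overall") score is computed; nuclear/cytoplasmic sub-scores are out of
scope. The multiplier `scale` (default 500) is an arbitrary-units choice
that places typical scores in the 100–300 range seen in practice; scores
are comparable within a run, not across instruments. An empty mask yields
a *missing* score — never zero, which would masquerade as biological
absence. Duplicate cores from the same subject × region are averaged
(arithmetic mean of non-missing scores, with the count of cores used
recorded); IF scores are dichotomized at the cohort median with ties going
to "high".

## IHC H-score

Staining intensity is scored 0 (negative) / 1 (weak) / 2 (moderate) /
3 (strong); percent-positive cells is binned 0 (0%), 1 (1–33%], 2 (33–66%],
3 (66–100%]. Fractional percentages use half-open intervals, consistent
with the printed integer bin edges. The H-score is the product
(range 0–9, attainable values {0,1,2,3,4,6,9}); presence/absence
dichotomizes at zero. Intensity categories must be integers — the scoring
is per region, and fractional "averaged" intensities are rejected rather
than silently rounded.

## Clinical definitions

* **Analysis set**: serous histology, chemotherapy-naive, primary (not
  recurrent) tissue; the three exclusions commute, and counts per reason
  are reported. Benign controls pass through untouched.
* **Response**: complete responder (CR) on complete disappearance of all
  measurable disease sustained ≥ 4 weeks after first-line platinum
  chemotherapy, or — without measurable lesions — CA-125 normalization
  sustained ≥ 4 weeks; partial response (≥ 50% tumor-burden reduction or
  CA-125 drop > 50% without normalization), stable disease, or progression
  during adjuvant therapy is an incomplete responder (IR). Missing response
  fields propagate as missing; a record claiming both a complete lesion
  response and progression during adjuvant therapy is rejected as
  contradictory.
* **Overall survival**: diagnosis to death or last contact, in months of
  30.4375 days (registry convention; the conversion is a package choice and
  is documented because no standard is universal); censored if alive.
* **Survivor groups**: long-term > 60 months (vital status not required —
  a subject alive at 61 months has demonstrably survived long), short-term
  = death within 36 months; all other cases are excluded from that
  contrast, so the three labels partition every record.
* **Age dichotomy**: ≤ 65 vs > 65 years.

## Statistics

All tests are two-sided; missing data are removed per analysis and the
resulting group sizes reported. The Wilcoxon rank-sum test uses exact
enumeration when both groups have ≤ 8 observations and the pooled sample is
tie-free, otherwise the normal approximation with mid-ranks and
tie-corrected variance and no continuity correction (so identical samples
give p = 1 exactly). Kruskal-Wallis (≥ 3 groups) is tie-corrected, with the
all-constant degenerate case defined as H = 0, p = 1. Mean differences use
Student's t (one-sample on paired stroma−epithelium deltas, pooled-variance
two-sample) or one-way ANOVA; zero-variance input yields t = 0, p = 1 when
the tested difference is itself zero and a flagged missing p otherwise.
Kaplan-Meier curves use the product-limit estimator with the median defined
as the smallest t with S(t) ≤ 0.5 ("not reached" when the curve never gets
there); group differences use the (multivariate) log-rank test. Cox
proportional-hazards models use Efron tie handling and report hazard ratios
with Wald 95% CIs; the Newton tolerance is tightened to 1e-9 on the step
norm because the library default (1e-7) leaves ~1e-3 coefficient error on
very small datasets. Monotone likelihood (separation) in Cox or logistic
fits is reported as non-convergence, not an exception. Logistic regression
is plain maximum likelihood with Wald CIs. No multiple-testing correction
is applied. scipy, lifelines and statsmodels provide the numerics behind
this module surface; the tests check them against independent enumeration,
closed-form, and hand-computed product-limit oracles.

## Synthetic data: what it emulates, and what it does not

**Images.** A square field is partitioned into epithelial nests (smoothed
Gaussian-noise blobs thresholded at a quantile, so the configured area
fraction is exact) and complementary stroma. Nuclei are disks placed on a
jittered grid dense enough that every tissue pixel is near a nucleus — the
geometry the stroma marker logic assumes. Each channel renders as
`base · (exposure / e_ref)`, plus optional additive Gaussian noise and
Poisson shot noise, clipped to [0, 1] (16-bit on export); Cav-1 intensity
over a compartment is exactly `concentration · exposure / e_ref` when noise
is off, so the score's closed form can be checked without tolerance. A
configurable bleed-through fraction leaks panCK signal into the vimentin
channel, exercising the double-positive exclusion. Geometry is deliberately
simple — the score contract does not depend on tissue morphology — and the
simulator makes no attempt at realistic optics (no point-spread function,
no autofluorescence, no spectral overlap beyond the single bleed-through
term). Scanner signal-to-noise and dynamic range are free parameters
(defaults: noise off; `noise_sd = 0.01` in recovery studies). Passing
recovery tests therefore show the *algorithm* inverts its own rendering
model, not that it is robust to every real-world artifact.

**Cohorts.** Subject-level compartment scores are gamma-distributed around
configurable means with a between-subject coefficient of variation of 0.28
(set to the spread observed in practice for such scores) and a
within-subject duplicate-core CV of 0.10; two duplicate cores per region by
default. Score means default to the observed compartment medians of the
study conditions this package emulates (benign stroma 308.9, tumor stroma
152.6, tumor epithelium 124.0 score units — a roughly 2:1 benign:tumor
stroma effect); note that because the gamma is right-skewed, sample
*medians* run a few percent below these configured means. Stroma and
epithelium scores are drawn independently, so the SD of the
stroma−epithelium difference is somewhat larger than in real tissue, where
the compartments correlate within subject. The IHC cohort draws intensity
categories from per-compartment probability vectors whose implied mean
H-scores echo the observed means (tumor stroma ≈ 0.3, tumor epithelium
≈ 2.6, benign stroma ≈ 0.8, benign epithelium ≈ 3.1), with percent-positive
uniform on (1, 45)% for stroma and (10, 90)% for epithelium given any
staining.

Survival times are exponential with the lymphovascular-invasion (LVI) flag
carrying the only systematic log-hazard (default ln 3.56, prevalence 0.77,
annotated in a 70% pathology-review subset). The baseline (covariate-zero)
median is 140 months so that, mixed over the LVI distribution, the marginal
cohort median lands near the observed ~50 months. Censoring is an
independent exponential calibrated so roughly the configured fraction
(default 0.25) of subjects are censored, with an administrative horizon at
200 months. Covariate distributions (age, stage, grade, response,
debulking, TIL/cystic flags) match the cohort compositions of the study
conditions. Response is generated independently of expression — the
cohort-level null — so logistic models on defaults recover OR ≈ 1.

All randomness flows from a single integer seed per generator call; the
same seed reproduces byte-identical outputs.

## Numerical and design choices

* Intensities are non-negative floats on a nominal 0–1 scale; TIFF export
  scales by 65535, so round-trips are lossless to 16-bit quantization.
* Score algebra is exact in the noise-free path (no hidden offsets), which
  is what permits equality-up-to-float tests rather than tolerance bands.
* Compartment tie-break: panCK wins (vimentin+/panCK+ → epithelium).
* Missing scores propagate as missing; they are excluded from duplicate
  averaging and dichotomization, never imputed as zero.
* Median dichotomization sends ties at the cutoff to "high".
* Reported p-values are never compared against each other across assays;
  the IF and IHC arms are analyzed separately, as their score scales are
  incommensurable.

## Problem sizes used in validation

The recovery studies simulate 50 cores of 128² px (exact proportionality
and rank-correlation checks), cohorts of n = 500 tumor subjects for Cox and
logistic parameter recovery — pooled over five replicate cohorts by inverse
variance, since a single draw lands outside 2 SE about 5% of the time even
for a correct generator — and 10,000 null replicates of 30-vs-30 rank-sum
tests for type-I-error calibration. The default cohort sizes (105 tumor +
30 benign IF; 73 + 33 IHC) match the study conditions emulated.

## Known limitations

* The score is proportional to concentration only within a run; the
  exposure-normalization constant and bit depth of real scanners vary, so
  absolute values are not portable across instruments.
* Marker-logic compartments are not cell segmentation: a stromal pixel far
  from any nucleus is dropped, and epithelial vimentin is handled only
  through the exclusion rule.
* The cohort simulator draws compartment scores independently within
  subject and encodes no expression–outcome association; it validates the
  analysis machinery, not biological effect sizes.
* Real per-case data enter through the spreadsheet reader with an external
  column mapping; analyses degrade gracefully to the subset of tables the
  available columns support.
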