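# cavquant

Digital-pathology quantification of stromal vs epithelial caveolin-1
(Cav-1) in tissue-microarray (TMA) cores, with the downstream
clinical-association analysis. Loss of Cav-1 in tumor stroma marks an
aggressive cancer-associated-fibroblast phenotype; this package provides
the full measurement-to-inference chain a biomarker study of that
phenotype needs, for two assay arms:

* **Multiplex immunofluorescence (IF)**: compartments are defined at the
  pixel level by marker logic — epithelium = panCK+; stroma = vimentin+,
  panCK−, and near a DAPI+ nucleus (vimentin+/panCK+ pixels are excluded
  from stroma, since vimentin also stains tumor epithelium). Each
  compartment gets an exposure-normalized intensity-per-area score

  ```
  score = scale · (Σ target intensity over mask / mask area) · (e_ref / e_target)
  ```

  proportional to protein concentration (molecules per unit area) in
  arbitrary units; duplicate cores per subject are averaged and cohorts are
  dichotomized at the median score.
* **Immunohistochemistry (IHC)**: the semi-quantitative H-score =
  intensity category (0–3) × percent-positive category (0–3), dichotomized
  as presence (> 0) vs absence (0).

Downstream, the package encodes the study's clinical definitions
(serous/chemo-naive/primary-tissue analysis set, complete vs incomplete
responder to platinum chemotherapy, overall survival, long- vs short-term
survivor groups) and the statistics: Wilcoxon rank-sum (exact for small
samples), Kruskal-Wallis, t/ANOVA, Pearson correlation, Kaplan-Meier with
log-rank, Cox proportional hazards (Efron ties), and logistic regression.
A synthetic-data module simulates multiplex cores with exact ground truth
and two-cohort clinical tables with known effect sizes, so every stage is
testable without any external download.

Intended users: computational-pathology and biostatistics folk who want a
transparent, testable re-implementation of AQUA-style compartment scoring
and its companion clinical analysis.

## Worked example

```python
import cavquant as cq

# simulate a multiplex core with known truth: stromal Cav-1 at 0.35,
# epithelial at 0.20 concentration units, no noise
img, truth = cq.generate_core_image(cq.ImageSimConfig(
    stroma_cav1_conc=0.35, epi_cav1_conc=0.20, seed=11))

masks = cq.build_compartment_masks(img)           # Otsu thresholds, 10 px nucleus radius
s = cq.compute_aqua_score(img, masks, "stroma")
e = cq.compute_aqua_score(img, masks, "epithelium")
print(f"stroma {s.value:.1f} over {s.area_px} px; epithelium {e.value:.1f}")
```

prints

```
stroma 175.0 over 45875 px; epithelium 100.0
```

— exactly `scale (500) × concentration`, because the masks recover the
ground truth pixel-for-pixel on noise-free input and the score inverts the
rendering model.

The numbered drivers under `analysis/` run the full study on synthetic
cohorts (`01` simulate → `02` quantify images → `03` H-score IHC →
`04` group comparisons → `05` survival), writing tables under `results/`.
A run of `04`/`05` reports, among others:

```
[IF] tumor stroma vs epithelium (medians): 166.45 vs 111.06 (rank-sum p = 6.95e-13)
[IF] benign vs tumor stroma: 307.81 vs 166.45 (rank-sum p = 3.57e-11)
[IHC] tumor stroma vs epithelium (means): 0.25 vs 3.25 (rank-sum p = 6.66e-19)
overall KM median OS: 61.8 months (82/105 deaths)
LVI hazard ratio: 4.56 (95% CI 2.19-9.48, p = 4.95e-05, n = 78)
```

i.e. the simulated benign:tumor stroma ratio (configured 2:1) and the
lymphovascular-invasion hazard (configured HR 3.56) are recovered within
sampling error, and the direction of every contrast matches its
configuration. A `cavquant` console script exposes the same stages
(`simulate`, `quantify`, `score-ihc`, `annotate`, `analyze`, `reproduce`,
`end-to-end`).

Real per-case data can be analyzed by placing the clinicopathologic
workbook under `data/` with a column-mapping YAML (see `data/README.md`)
and running `cavquant reproduce`.

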