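#!/usr/bin/env python
"""Simulate the study inputs: multiplex TMA cores with ground truth, and the
two cohorts (IF-scored and IHC-scored) with clinical covariates.

Writes core images (TIFF + sidecars + truth) under scratch/cores/ and the
cohort tables under results/.
"""

from pathlib import Path

import numpy as np

import cavquant as cq
from cavquant import io as cio

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cores"
RESULTS = ROOT / "results"
SEED = 20210


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    # a small core series spanning stromal Cav-1 concentrations
    concs = np.linspace(0.1, 0.6, 6)
    for i, c in enumerate(concs):
        cfg = cq.ImageSimConfig(stroma_cav1_conc=float(c), noise_sd=0.01, seed=SEED + i)
        image, truth = cq.generate_core_image(cfg)
        stem = f"core_{i + 1:03d}"
        image.core_id = stem
        image.subject_id = f"S{i + 1:03d}"
        cio.write_core_image(image, SCRATCH, stem)
        cio.write_ground_truth(truth, SCRATCH, stem)
    print(f"wrote {len(concs)} simulated cores (stroma Cav-1 {concs[0]:.2f}-{concs[-1]:.2f}) -> {SCRATCH}")

    expr, clin = cq.generate_cohort(cq.CohortSimConfig(seed=SEED + 50))
    expr.to_csv(RESULTS / "if_expression_cores.csv", index=False)
    clin.to_csv(RESULTS / "if_clinical.csv", index=False)
    print(f"IF cohort: {len(clin)} subjects, {len(expr)} core scores -> results/if_*.csv")

    obs, clin1 = cq.generate_ihc_cohort(cq.IhcCohortSimConfig(seed=SEED + 60))
    obs.to_csv(RESULTS / "ihc_observations.csv", index=False)
    clin1.to_csv(RESULTS / "ihc_clinical.csv", index=False)
    print(f"IHC cohort: {len(clin1)} subjects, {len(obs)} scored regions -> results/ihc_*.csv")


if __name__ == "__main__":
    main()
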