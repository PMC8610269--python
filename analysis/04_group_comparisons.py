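#!/usr/bin/env python
"""Clinical-association tables for both cohorts: compartment expression
overall and by clinicopathologic subgroup, benign-vs-tumor stroma contrast,
and within-tumor stroma-vs-epithelium comparison.

Reads the cohort tables from results/ (01_simulate_data.py); writes the
subgroup tables and summary JSON under results/.
"""

import json
from pathlib import Path

import pandas as pd

from cavquant import pipeline as pl

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATE_COLS = ["dx_date", "last_contact_or_death_date"]


def run(assay: str, expr_file: str, clin_file: str) -> None:
    expr = pd.read_csv(RESULTS / expr_file)
    clin = pd.read_csv(RESULTS / clin_file, parse_dates=DATE_COLS)
    tables = pl.reproduce_tables(expr, clin, assay=assay)
    tables["by_subgroup"].to_csv(RESULTS / f"{assay}_expression_by_subgroup.csv", index=False)
    scalar = {k: v for k, v in tables.items() if k != "by_subgroup"}
    (RESULTS / f"{assay}_analysis_summary.json").write_text(json.dumps(pl._jsonable(scalar), indent=2))

    sve = tables["stroma_vs_epithelium"]
    label = "median" if assay == "if" else "mean"
    print(f"[{assay.upper()}] tumor stroma vs epithelium ({label}s): "
          f"{sve['stroma_center']:.2f} vs {sve['epithelium_center']:.2f} "
          f"(rank-sum p = {sve['p_ranksum']:.3g}; paired-t on delta p = {sve['p_paired_t']:.3g})")
    bvt = tables.get("benign_vs_tumor_stroma")
    if bvt:
        print(f"[{assay.upper()}] benign vs tumor stroma: {bvt['benign_center']:.2f} vs "
              f"{bvt['tumor_center']:.2f} (rank-sum p = {bvt['p']:.3g})")


def main() -> None:
    run("if", "if_expression_cores.csv", "if_clinical.csv")
    run("ihc", "ihc_observations.csv", "ihc_clinical.csv")
    print("tables -> results/*_expression_by_subgroup.csv, *_analysis_summary.json")


if __name__ == "__main__":
    main()
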