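#!/usr/bin/env python
"""Survival analyses for the IF cohort: Kaplan-Meier curves by dichotomized
compartment expression, Cox models for continuous expression, and the
lymphovascular-invasion hazard.

Reads results/if_*.csv; writes results/survival.json and KM curve CSVs.
"""

import json
from pathlib import Path

import pandas as pd

from cavquant import pipeline as pl
from cavquant import stats as st
from cavquant.clinical import annotate, filter_analysis_set
from cavquant.quantify import dichotomize_if

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    expr = pd.read_csv(RESULTS / "if_expression_cores.csv")
    clin = pd.read_csv(
        RESULTS / "if_clinical.csv", parse_dates=["dx_date", "last_contact_or_death_date"]
    )
    wide = pl.aggregate_expression(expr)
    kept, _ = filter_analysis_set(annotate(clin))
    out = pl.survival_analyses(wide, kept, assay="if")
    (RESULTS / "survival.json").write_text(json.dumps(pl._jsonable(out), indent=2))

    merged = wide[wide["group"] == "tumor"].merge(kept, on="subject_id")
    merged = merged[merged["os_months"].notna()]
    labels, cutoff = dichotomize_if(merged["stroma"].to_numpy())
    fit = st.km_fit(merged["os_months"], merged["os_event"], labels)
    for name, curve in fit.km_curves.items():
        curve.to_csv(RESULTS / f"km_stroma_{name}.csv", index=False)

    print(f"overall KM median OS: {out['overall_km_median']:.1f} months "
          f"({out['n_events']}/{out['n']} deaths)")
    km = out["stroma_km"]
    print(f"stromal Cav-1 split at median ({km['cutoff']:.1f}): "
          f"KM medians low={km['medians'].get('low'):.1f}, high={km['medians'].get('high'):.1f} "
          f"months (log-rank p = {km['logrank_p']:.2f})")
    if "lvi_cox" in out:
        lv = out["lvi_cox"]
        print(f"LVI hazard ratio: {lv['hr']:.2f} (95% CI {lv['ci_low']:.2f}-{lv['ci_high']:.2f}, "
              f"p = {lv['p']:.3g}, n = {lv['n']})")
    print("curves -> results/km_stroma_*.csv, summary -> results/survival.json")


if __name__ == "__main__":
    main()
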