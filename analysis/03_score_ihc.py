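#!/usr/bin/env python
"""H-score the IHC cohort's categorical observations and summarize the
stroma/epithelium contrast.

Reads results/ihc_observations.csv; writes results/ihc_hscores.csv.
"""

from pathlib import Path

import pandas as pd

from cavquant.ihc import score_table

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    obs = pd.read_csv(RESULTS / "ihc_observations.csv")
    scored = score_table(obs)
    scored.to_csv(RESULTS / "ihc_hscores.csv", index=False)
    summary = scored.groupby("roi_class")["h_score"].agg(["mean", "std", "count"])
    print("mean H-score by region:")
    print(summary.round(2).to_string())
    absent = (scored[scored["roi_class"] == "tumor_stroma"]["presence"] == "absent").mean()
    print(f"tumor stroma with absent Cav-1 (H-score 0): {absent:.0%}")


if __name__ == "__main__":
    main()
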