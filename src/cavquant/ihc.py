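"""Semi-quantitative immunohistochemistry H-scoring.

A pathologist scores each region for staining intensity (0 negative, 1 weak,
2 moderate, 3 strong) and percent of positive cells, binned as 0 (0%),
1 (1-33%), 2 (34-66%), 3 (67-100%).  The H-score is the product of the two
categories (range 0-9); presence/absence dichotomizes at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

VALID_H_SCORES = frozenset({0, 1, 2, 3, 4, 6, 9})


@dataclass
class IhcObservation:
    subject_id: str
    roi_class: str
    intensity_cat: int
    percent_positive: float

    def __post_init__(self) -> None:
        if self.intensity_cat not in (0, 1, 2, 3):
            raise ValueError(f"intensity_cat must be 0-3, got {self.intensity_cat!r}")
        if not 0.0 <= self.percent_positive <= 100.0:
            raise ValueError(f"percent_positive must be in [0, 100], got {self.percent_positive!r}")


def percent_to_category(percent_positive: float) -> int:
    """Bin percent-positive into categories 0 (0%), 1 (1-33], 2 (33-66], 3 (66-100].

    Fractional percentages fall into half-open bins, consistent with the
    integer bin edges.
    """
    p = float(percent_positive)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percent_positive must be in [0, 100], got {p}")
    if p == 0.0:
        return 0
    if p <= 33.0:
        return 1
    if p <= 66.0:
        return 2
    return 3


def compute_h_score(obs: IhcObservation) -> int:
    """H-score = intensity category x percent-positive category (0-9)."""
    return obs.intensity_cat * percent_to_category(obs.percent_positive)


def dichotomize_ihc(h_score: int) -> str:
    """Presence/absence of staining, using an H-score of zero as the cutoff."""
    if h_score not in VALID_H_SCORES:
        raise ValueError(f"invalid H-score {h_score!r}")
    return "absent" if h_score == 0 else "present"


def score_table(obs: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scoring of an observation table.

    Expects columns (subject_id, roi_class, intensity_cat, percent_positive);
    returns the table with h_score and presence columns appended.
    Non-integer intensity categories are rejected — intensities are scored
    per region, not averaged.
    """
    out = obs.copy()
    h, presence = [], []
    for row in out.itertuples(index=False):
        rec = IhcObservation(
            subject_id=str(row.subject_id),
            roi_class=str(row.roi_class),
            intensity_cat=int(row.intensity_cat)
            if float(row.intensity_cat).is_integer()
            else row.intensity_cat,
            percent_positive=float(row.percent_positive),
        )
        hs = compute_h_score(rec)
        h.append(hs)
        presence.append(dichotomize_ihc(hs))
    out["h_score"] = h
    out["presence"] = presence
    return out
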