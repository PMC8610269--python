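"""Clinical definitions: analysis-set filters, chemotherapy response class,
overall survival, and long/short survivor groups.

The analysis set keeps serous, chemotherapy-naive cases sampled from primary
(not recurrent) tissue.  Response to first-line platinum chemotherapy is a
complete response (CR) when all measurable disease disappears for at least
four weeks, or — absent measurable lesions — when CA-125 normalizes for at
least four weeks; partial response, stable disease, or progression during
adjuvant therapy counts as an incomplete response (IR, chemoresistant).
Overall survival runs from diagnosis to death or last contact (censored if
alive).  Survivor groups contrast long-term (> 60 months) against short-term
(death within 36 months); everything else is excluded from that contrast.
"""

from __future__ import annotations

import pandas as pd

DAYS_PER_MONTH = 30.4375


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or v is pd.NA


def filter_analysis_set(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain serous, chemo-naive, primary-tissue tumor cases.

    Benign-control rows (``group == 'benign'``) are passed through untouched;
    the histology/treatment exclusions apply to tumor cases.  Returns the
    retained table and counts excluded per reason (a case failing several
    rules is counted under each).  The three filters commute, so application
    order cannot change the retained set.
    """
    tumor = records["group"] == "tumor" if "group" in records else pd.Series(True, index=records.index)
    non_serous = tumor & (records["histology"] != "serous")
    neoadj = tumor & records["neoadjuvant"].fillna(False).astype(bool)
    recurrent = tumor & records["recurrent_tissue"].fillna(False).astype(bool)
    counts = {
        "non_serous": int(non_serous.sum()),
        "neoadjuvant": int(neoadj.sum()),
        "recurrent_tissue": int(recurrent.sum()),
    }
    kept = records[~(non_serous | neoadj | recurrent)].copy()
    return kept, counts


def classify_response(record) -> str | None:
    """Classify a treated case as complete (CR) or incomplete (IR) responder.

    ``record`` is a mapping/Series with fields measurable_disease,
    lesion_response, ca125_normalized_4wk, ca125_drop_gt50_4wk, and
    progressed_during_adjuvant.  Returns 'CR', 'IR', or None when the
    response fields are missing.  A record claiming both a complete lesion
    response and progression during adjuvant therapy is contradictory.
    """
    lesion = record.get("lesion_response")
    progressed = bool(record.get("progressed_during_adjuvant") or False)
    if not _is_missing(lesion) and lesion == "complete" and progressed:
        raise ValueError("contradictory record: complete response and progression during adjuvant therapy")
    if progressed:
        return "IR"

    measurable = record.get("measurable_disease")
    if not _is_missing(measurable) and measurable:
        if _is_missing(lesion):
            return None
        return "CR" if lesion == "complete" else "IR"

    # no measurable lesion: CA-125 criteria
    normalized = record.get("ca125_normalized_4wk")
    dropped = record.get("ca125_drop_gt50_4wk")
    if not _is_missing(normalized) and normalized:
        return "CR"
    if (not _is_missing(dropped) and dropped) or (not _is_missing(lesion) and lesion in ("partial", "stable", "progression")):
        return "IR"
    if not _is_missing(normalized):
        return "IR"  # CA-125 followed but never normalized nor halved
    return None


def compute_os(record) -> tuple[float, int] | tuple[None, None]:
    """Overall survival in months: (diagnosis -> death or last contact).

    Months use a 30.4375-day month.  Event flag is 1 iff dead.  Death (or
    contact) before diagnosis is an error; fully missing dates yield
    ``(None, None)``.
    """
    dx, last = record.get("dx_date"), record.get("last_contact_or_death_date")
    status = record.get("vital_status")
    if _is_missing(dx) or _is_missing(last):
        return None, None
    dx, last = pd.Timestamp(dx), pd.Timestamp(last)
    if last < dx:
        raise ValueError(f"follow-up date {last.date()} precedes diagnosis {dx.date()}")
    months = (last - dx).days / DAYS_PER_MONTH
    event = 1 if status == "dead" else 0
    return months, event


def assign_survival_group(os_months: float, event: int) -> str:
    """Long-term (> 60 months, dead or alive) vs short-term (death <= 36 months).

    Cases alive with under 36 months of follow-up, or dying between 36 and
    60 months, fit neither definition and are excluded from the contrast.
    """
    if os_months is None:
        return "excluded"
    if os_months > 60.0:
        return "long"
    if event and os_months <= 36.0:
        return "short"
    return "excluded"


def age_group(age_years: float) -> str:
    """Young (<= 65 years) vs old (> 65 years)."""
    return "<=65" if age_years <= 65.0 else ">65"


def annotate(records: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns: response, os_months, os_event, survival_group, age_grp."""
    out = records.copy()
    resp, osm, ev, grp, ageg = [], [], [], [], []
    for _, row in out.iterrows():
        resp.append(classify_response(row) if row.get("group", "tumor") == "tumor" else None)
        m, e = compute_os(row)
        osm.append(m)
        ev.append(e)
        grp.append(assign_survival_group(m, e) if m is not None else "excluded")
        a = row.get("age_dx")
        ageg.append(age_group(a) if not _is_missing(a) else None)
    out["response"] = resp
    out["os_months"] = osm
    out["os_event"] = ev
    out["survival_group"] = grp
    out["age_grp"] = ageg
    return out
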