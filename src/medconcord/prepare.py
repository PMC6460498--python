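"""Record cleaning ahead of matching: classify, annotate, exclude, de-duplicate.

Stages (in pipeline order):

1. :func:`classify_records` — attach (name, class, spectrum) from the lexicon;
   unclassified codes are dropped with a logged count.
2. :func:`annotate_same_day` — attach a same-day encounter type and a same-day
   infection-diagnosis tier to every medication record.
3. :func:`exclude_ip_ed` — remove records tied to inpatient/ED encounters,
   leaving ambulatory and unknown/missing settings.
4. :func:`dedup_same_day` — collapse to one record per (patient, day, stream),
   keeping the broadest-spectrum medication of the day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexicon import Lexicon

__all__ = [
    "PrepLog",
    "classify_records",
    "annotate_same_day",
    "exclude_ip_ed",
    "dedup_same_day",
    "prepare_stream",
]

logger = logging.getLogger(__name__)

# When a patient has several encounters on one day the record inherits the
# highest-priority type, so any inpatient/ED contact that day triggers
# exclusion (conservative: IP > ED > AV > OT > UN).
_ENC_PRIORITY = {"IP": 0, "ED": 1, "AV": 2, "OT": 3, "UN": 4}

_TIER_PRIORITY = {"1": 0, "2": 1, "3": 2, "other_missing": 3}


@dataclass
class PrepLog:
    """Structured counts from each cleaning stage (reconciles the pipeline audit)."""

    n_input: int = 0
    n_unclassified: int = 0
    n_excluded_ip_ed: int = 0
    n_dedup_removed: int = 0
    n_final: int = 0
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("n_input", "n_unclassified", "n_excluded_ip_ed",
              "n_dedup_removed", "n_final")}
        d.update(self.extra)
        return d


def classify_records(records: pd.DataFrame, lexicon: Lexicon) -> tuple[pd.DataFrame, int]:
    """Attach medication attributes; drop records whose code is not in the lexicon.

    Returns (classified records, count of unclassified records dropped).
    """
    out = lexicon.classify_frame(records, code_col="code")
    unclassified = out["name"].isna()
    n_bad = int(unclassified.sum())
    if n_bad:
        logger.warning("dropped %d record(s) with unclassifiable codes", n_bad)
    return out.loc[~unclassified].reset_index(drop=True), n_bad


def annotate_same_day(records: pd.DataFrame, encounters: pd.DataFrame,
                      diagnoses: pd.DataFrame) -> pd.DataFrame:
    """Attach ``same_day_enc`` and ``tier`` to each medication record.

    A record's same-day encounter type is the highest-priority encounter the
    patient had on the record's day, or ``"missing"`` when the patient had no
    encounter that day (a common situation for pharmacy fills).  The same-day
    tier is the most antibiotic-appropriate (lowest-numbered) infection tier
    diagnosed that day, or ``"other_missing"``.
    """
    out = records.copy()

    if len(encounters):
        enc = encounters.copy()
        enc["_prio"] = enc["enc_type"].map(_ENC_PRIORITY)
        best_enc = (enc.sort_values("_prio")
                    .drop_duplicates(["patid", "day"])
                    .set_index(["patid", "day"])["enc_type"])
        out["same_day_enc"] = (
            pd.MultiIndex.from_frame(out[["patid", "day"]]).map(best_enc))
    else:
        out["same_day_enc"] = np.nan
    out["same_day_enc"] = out["same_day_enc"].fillna("missing")

    if len(diagnoses):
        dx = diagnoses.copy()
        dx["_prio"] = dx["tier"].map(_TIER_PRIORITY)
        best_dx = (dx.sort_values("_prio")
                   .drop_duplicates(["patid", "day"])
                   .set_index(["patid", "day"])["tier"])
        out["tier"] = pd.MultiIndex.from_frame(out[["patid", "day"]]).map(best_dx)
    else:
        out["tier"] = np.nan
    out["tier"] = out["tier"].fillna("other_missing")
    return out


def exclude_ip_ed(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop records whose same-day encounter is inpatient or ED.

    Idempotent; records with ambulatory, other, unknown or missing same-day
    encounters survive.
    """
    keep = ~records["same_day_enc"].isin(("IP", "ED"))
    kept = records.loc[keep].reset_index(drop=True)
    return kept, int((~keep).sum())


def dedup_same_day(records: pd.DataFrame) -> pd.DataFrame:
    """One record per (patid, day, stream), broadest spectrum first.

    Survivor choice is deterministic: spectrum broad > narrow, then
    lexicographic class name, then record_id — so the result is invariant
    under input row order.
    """
    if records.empty:
        return records.copy()
    df = records.copy()
    df["_spec_rank"] = (df["spectrum"] != "broad").astype(int)  # broad first
    df = df.sort_values(["patid", "day", "stream", "_spec_rank", "med_class",
                         "record_id"], kind="mergesort")
    df = df.drop_duplicates(["patid", "day", "stream"], keep="first")
    return df.drop(columns="_spec_rank").reset_index(drop=True)


def prepare_stream(records: pd.DataFrame, encounters: pd.DataFrame,
                   diagnoses: pd.DataFrame, lexicon: Lexicon,
                   *, apply_enc_filter: bool = True) -> tuple[pd.DataFrame, PrepLog]:
    """Run the full cleaning chain on one stream; returns (records, audit log).

    ``apply_enc_filter=False`` skips the inpatient/ED exclusion, for analyses
    that do not restrict on encounter type.
    """
    log = PrepLog(n_input=len(records))
    out, log.n_unclassified = classify_records(records, lexicon)
    out = annotate_same_day(out, encounters, diagnoses)
    if apply_enc_filter:
        out, log.n_excluded_ip_ed = exclude_ip_ed(out)
    n_before = len(out)
    out = dedup_same_day(out)
    log.n_dedup_removed = n_before - len(out)
    log.n_final = len(out)
    return out, log
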