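"""Patient-level antibiotic exposure classification and its sensitivity/specificity.

Dispensing records serve as the reference standard for whether a patient was
ever exposed to an antibiotic; prescribing records are the test.  Each
patient falls into exactly one cell:

* TP — at least one prescribing and at least one dispensing record
* TN — no prescribing and no dispensing record
* FN — no prescribing record but at least one dispensing record
  (exposed, but the EHR alone would call them unexposed)
* FP — at least one prescribing record but no dispensing record

Sensitivity = TP/(TP+FN); specificity = TN/(TN+FP).  In open (non-integrated)
delivery systems dispensing capture is incomplete, so an FP there may simply
be an unfilled capture gap rather than a true non-exposure — specificity is
therefore suppressed for such strata (``report_specificity=False``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import round_half_up

__all__ = ["ClassificationSummary", "classify_patients", "summarize",
           "DAYS_PER_MONTH", "age_months"]

#: Mean calendar-month length used to convert day offsets to age in months.
DAYS_PER_MONTH = 30.4375


def age_months(day) -> np.ndarray:
    """Age in whole months for a day offset from birth."""
    return (np.asarray(day) // DAYS_PER_MONTH).astype(int)


@dataclass
class ClassificationSummary:
    n_tp: int
    n_tn: int
    n_fn: int
    n_fp: int
    sensitivity: float
    specificity: float | None  # None = not reported

    @property
    def n(self) -> int:
        return self.n_tp + self.n_tn + self.n_fn + self.n_fp

    def cell_percent(self, cell: str) -> float:
        count = {"TP": self.n_tp, "TN": self.n_tn,
                 "FN": self.n_fn, "FP": self.n_fp}[cell]
        return round_half_up(100.0 * count / self.n, 1)


def classify_patients(rx: pd.DataFrame, disp: pd.DataFrame,
                      patients: pd.DataFrame, *,
                      age_min_months: int = 0,
                      age_max_months: int = 132) -> pd.DataFrame:
    """Assign every patient a TP/TN/FN/FP cell from their record presence.

    Records outside the [age_min_months, age_max_months] window are ignored.
    Returns one row per patient: patid, has_rx, has_disp, cell.
    """
    def _exposed(records: pd.DataFrame) -> pd.Series:
        if records.empty:
            return pd.Series(False, index=patients["patid"])
        months = age_months(records["day"])
        in_window = (months >= age_min_months) & (months <= age_max_months)
        pats = records.loc[in_window, "patid"].unique()
        return pd.Series(patients["patid"].isin(pats).values, index=patients["patid"])

    has_rx = _exposed(rx)
    has_disp = _exposed(disp)
    cell = np.select(
        [has_rx & has_disp, ~has_rx & ~has_disp, ~has_rx & has_disp],
        ["TP", "TN", "FN"], default="FP")
    return pd.DataFrame({"patid": patients["patid"].values,
                         "has_rx": has_rx.values, "has_disp": has_disp.values,
                         "cell": cell})


def summarize(classifications: pd.DataFrame,
              report_specificity: bool = True) -> ClassificationSummary:
    """Cell counts plus sensitivity/specificity at one-decimal precision.

    Raises when the denominators are empty: sensitivity needs at least one
    reference-exposed patient (TP+FN > 0); specificity, when requested,
    needs at least one reference-unexposed patient (TN+FP > 0).
    """
    if classifications.empty:
        raise ValueError("empty classification list")
    counts = classifications["cell"].value_counts()
    tp, tn = int(counts.get("TP", 0)), int(counts.get("TN", 0))
    fn, fp = int(counts.get("FN", 0)), int(counts.get("FP", 0))
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: no reference-exposed patients (TP+FN=0)")
    sens = round_half_up(100.0 * tp / (tp + fn), 1)
    spec = None
    if report_specificity:
        if tn + fp == 0:
            raise ValueError("specificity undefined: no reference-negative patients (TN+FP=0)")
        spec = round_half_up(100.0 * tn / (tn + fp), 1)
    return ClassificationSummary(n_tp=tp, n_tn=tn, n_fn=fn, n_fp=fp,
                                 sensitivity=sens, specificity=spec)
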