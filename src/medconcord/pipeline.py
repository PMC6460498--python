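"""End-to-end concordance pipeline: clean, match, summarize, model, report.

One call runs the full analysis on a five-table cohort, stratified by
delivery-system type (or any other patient-level column), and emits three
report tables per stratum:

* ``table1`` — record volumes, per-patient medians/IQRs, directional match
  rates and the weighted kappa on binned per-patient counts;
* ``table2`` — odds ratios for a dispensing record lacking a matching
  prescription (record-level missingness model);
* ``table3`` — patient-level exposure classification counts, sensitivity,
  specificity (suppressed where dispensing capture is unreliable) and the
  false-negative model odds ratios.

Every row dropped at any stage appears in the audit log, so the printed
counts reconcile exactly with the inputs.  Reports are deterministic given
the input tables and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cdm import CohortTables
from .concordance import (match_rate, per_patient_contingency, round_half_up,
                          weighted_kappa)
from .exposure import classify_patients, summarize
from .lexicon import Lexicon
from .matching import match_directional
from .models import (build_patient_design, build_record_design,
                     fit_clustered_logit, fit_patient_fn_model)
from .prepare import prepare_stream

__all__ = ["PipelineConfig", "StratumReport", "ReportBundle", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs besides the tables themselves."""

    window_days: int = 7
    apply_enc_filter: bool = True          # drop inpatient/ED records pre-matching
    kappa_weight_scheme: str = "linear"
    age_min_months: int = 0
    age_max_months: int = 132
    stratify_by: str = "institution_type"
    # strata where false positives (and hence specificity) are unreliable
    suppress_specificity_for: tuple = ("non_cIDS",)
    model_method: str = "cluster_robust"
    quartile_mode: str = "data"

    def __post_init__(self):
        if self.window_days < 0:
            raise ValueError("window_days must be >= 0")
        if self.kappa_weight_scheme not in ("linear", "quadratic"):
            raise ValueError("kappa_weight_scheme must be 'linear' or 'quadratic'")


@dataclass
class StratumReport:
    stratum: str
    table1: pd.DataFrame
    table2: pd.DataFrame | None
    table3: pd.DataFrame | None
    log: dict = field(default_factory=dict)


@dataclass
class ReportBundle:
    strata: dict[str, StratumReport]
    config: PipelineConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, rep in sorted(self.strata.items()):
            rep.table1.to_csv(out / f"table1_{name}.csv", index=False)
            if rep.table2 is not None:
                rep.table2.to_csv(out / f"table2_{name}.csv", index=False)
            if rep.table3 is not None:
                rep.table3.to_csv(out / f"table3_{name}.csv", index=False)
            pd.Series(rep.log).rename("value").rename_axis("key").to_csv(
                out / f"audit_{name}.csv")


def _median_iqr(counts: pd.Series) -> str:
    med = counts.median()
    q1, q3 = counts.quantile([0.25, 0.75])
    return f"{med:g} ({q1:g}-{q3:g})"


def _or_table(fit) -> pd.DataFrame:
    t = fit.table.copy()
    t["or_"] = t["or_"].map(lambda v: round_half_up(v, 2))
    t["ci_low"] = t["ci_low"].map(lambda v: round_half_up(v, 2))
    t["ci_high"] = t["ci_high"].map(lambda v: round_half_up(v, 2))
    t["method"] = fit.method
    return t


def run_pipeline(tables: CohortTables, config: PipelineConfig | None = None,
                 lexicon: Lexicon | None = None) -> ReportBundle:
    """Run the complete concordance analysis, stratified.

    Model-stage failures (e.g. a one-level outcome on a tiny stratum) do not
    abort the run: the affected table is ``None`` and the reason is logged.
    """
    config = config or PipelineConfig()
    lexicon = lexicon or Lexicon.default()
    strata = {}
    groups = tables.demographic.groupby(config.stratify_by)
    for stratum, patients in groups:
        strata[str(stratum)] = _run_stratum(str(stratum), patients, tables,
                                            config, lexicon)
    return ReportBundle(strata=strata, config=config)


def _run_stratum(name: str, patients: pd.DataFrame, tables: CohortTables,
                 config: PipelineConfig, lexicon: Lexicon) -> StratumReport:
    pats = set(patients["patid"])
    rx_raw = tables.prescribing[tables.prescribing["patid"].isin(pats)]
    dp_raw = tables.dispensing[tables.dispensing["patid"].isin(pats)]
    enc = tables.encounter[tables.encounter["patid"].isin(pats)]
    dx = tables.diagnosis[tables.diagnosis["patid"].isin(pats)]

    rx, rx_log = prepare_stream(rx_raw, enc, dx, lexicon,
                                apply_enc_filter=config.apply_enc_filter)
    dp, dp_log = prepare_stream(dp_raw, enc, dx, lexicon,
                                apply_enc_filter=config.apply_enc_filter)

    fwd = match_directional(rx, dp, "rx_to_disp", config.window_days)
    rev = match_directional(dp, rx, "disp_to_rx", config.window_days)

    log = {f"prescribing_{k}": v for k, v in rx_log.as_dict().items()}
    log.update({f"dispensing_{k}": v for k, v in dp_log.as_dict().items()})
    log.update({
        "n_patients": len(patients),
        "pairs_rx_to_disp": fwd.n_pairs,
        "pairs_disp_to_rx": rev.n_pairs,
    })

    # --- table 1 ---
    rx_counts = rx.groupby("patid").size().reindex(patients["patid"], fill_value=0)
    dp_counts = dp.groupby("patid").size().reindex(patients["patid"], fill_value=0)
    rows = [
        ("total_patients", len(patients), ""),
        ("total_prescribing_records", len(rx), ""),
        ("prescribing_per_patient_median_iqr", np.nan, _median_iqr(rx_counts)),
        ("prescribing_matched_n", fwd.n_pairs, ""),
        ("prescribing_matched_pct",
         match_rate(fwd.n_pairs, len(rx)) if len(rx) else 0.0, ""),
        ("total_dispensing_records", len(dp), ""),
        ("dispensing_per_patient_median_iqr", np.nan, _median_iqr(dp_counts)),
        ("dispensing_matched_n", rev.n_pairs, ""),
        ("dispensing_matched_pct",
         match_rate(rev.n_pairs, len(dp)) if len(dp) else 0.0, ""),
    ]
    try:
        cont = per_patient_contingency(rx, dp, patients)
        kap = weighted_kappa(cont, config.kappa_weight_scheme)
        rows.append(("weighted_kappa", round_half_up(kap.kappa, 2), str(kap)))
    except ValueError as err:
        log["kappa_skipped"] = str(err)
    table1 = pd.DataFrame(rows, columns=["metric", "value", "display"])

    # --- table 2: record-level missingness model ---
    table2 = None
    if len(dp):
        design = build_record_design(dp, rev.source_flags, patients)
        try:
            fit = fit_clustered_logit(design, method=config.model_method)
            table2 = _or_table(fit)
            log["record_model_n"] = fit.n_obs
        except ValueError as err:
            log["table2_skipped"] = str(err)
    else:
        log["table2_skipped"] = "no dispensing records"

    # --- table 3: patient-level classification + FN model ---
    table3 = None
    cls = classify_patients(rx, dp, patients,
                            age_min_months=config.age_min_months,
                            age_max_months=config.age_max_months)
    report_spec = name not in config.suppress_specificity_for
    try:
        summ = summarize(cls, report_specificity=report_spec)
        rows3 = [
            ("total_patients", summ.n, ""),
            ("true_positives", summ.n_tp, f"{summ.cell_percent('TP'):.1f}%"),
            ("true_negatives", summ.n_tn, f"{summ.cell_percent('TN'):.1f}%"),
            ("false_negatives", summ.n_fn, f"{summ.cell_percent('FN'):.1f}%"),
            ("sensitivity_pct", summ.sensitivity, f"{summ.sensitivity:.1f}%"),
            ("specificity_pct",
             summ.specificity if summ.specificity is not None else np.nan,
             f"{summ.specificity:.1f}%" if summ.specificity is not None else "—"),
        ]
        table3 = pd.DataFrame(rows3, columns=["metric", "value", "display"])
        pdesign = build_patient_design(cls, patients,
                                       quartile_mode=config.quartile_mode)
        try:
            pfit = fit_patient_fn_model(pdesign, method=config.model_method)
            ortab = _or_table(pfit)
            ortab.insert(0, "metric", "fn_model_or")
            table3 = pd.concat(
                [table3, ortab.rename(columns={"or_": "value"})],
                ignore_index=True)
        except ValueError as err:
            log["fn_model_skipped"] = str(err)
    except ValueError as err:
        log["table3_skipped"] = str(err)

    return StratumReport(stratum=name, table1=table1, table2=table2,
                         table3=table3, log=log)
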