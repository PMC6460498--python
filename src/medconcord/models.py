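"""Clustered logistic models of missing medication records, plus VIF diagnostics.

Two outcomes are modeled:

* record level — a dispensing record has no matching prescribing record
  (adjusting for race, ethnicity, sex, age band, same-day encounter type,
  infection tier and antibiotic spectrum, with repeated records per patient
  and patients clustered in institutions);
* patient level — a patient is a false negative, i.e. has dispensing but no
  prescribing records (adjusting for sex, race, ethnicity, health status and
  health-care utilization, clustered by institution).

Estimation defaults to maximum-likelihood logistic regression with
cluster-robust (sandwich) standard errors on the institution id, which is
deterministic and the terminal member of the usual fallback chain for
clustered binary outcomes.  An exchangeable-correlation GEE (grouped by
patient) and a variational random-intercept fit are available through
``method=``.  Effects are reported as odds ratios with Wald 95% CIs;
two-sided p < 0.05 marks significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exposure import age_months

__all__ = [
    "AGE_BANDS",
    "ModelFit",
    "build_record_design",
    "build_patient_design",
    "fit_clustered_logit",
    "fit_patient_fn_model",
    "vif_diagnostic",
]

#: Age bands in months (left-closed), labels as printed in pediatric tables.
AGE_BANDS = [(0, 6, "0-<6"), (6, 12, "6-<12"), (12, 24, "12-<24"),
             (24, 60, "24-<60"), (60, 133, "60-<=132")]

# (column, reference level) — record-level model, reference levels chosen to
# reproduce the conventional contrasts (vs White, vs male, vs 24-<60 months,
# vs ambulatory visit, vs Tier 1, vs broad spectrum).
RECORD_COVARIATES = [
    ("race", "White"),
    ("hispanic", "no_unknown"),
    ("sex", "male"),
    ("age_band", "24-<60"),
    ("same_day_enc", "AV"),
    ("tier", "1"),
    ("spectrum", "broad"),
]

# Patient-level false-negative model: note sex is contrasted male vs female.
PATIENT_COVARIATES = [
    ("sex", "female"),
    ("race", "White"),
    ("hispanic", "no_unknown"),
    ("chronic_condition", False),
    ("preterm", False),
    ("asthma", False),
    ("enc_quartile", "Q1"),
]


@dataclass
class ModelFit:
    """Per-term odds ratios with Wald CIs, plus fit diagnostics."""

    table: pd.DataFrame  # term, or_, ci_low, ci_high, pvalue, significant
    converged: bool
    method: str          # estimation/robust-SE tag
    n_obs: int
    n_clusters: int
    llf: float | None = None
    notes: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        hit = self.table[self.table["term"] == name]
        if hit.empty:
            raise KeyError(f"no term {name!r}; have {list(self.table['term'])}")
        return hit.iloc[0]


def assign_age_band(day) -> pd.Series:
    months = pd.Series(age_months(day))
    out = pd.Series("60-<=132", index=months.index)
    for lo, hi, label in AGE_BANDS:
        out[(months >= lo) & (months < hi)] = label
    return out


def build_record_design(dispensings: pd.DataFrame, flags: pd.Series,
                        patients: pd.DataFrame) -> pd.DataFrame:
    """One row per prepared dispensing record; outcome = no matching prescription.

    ``flags`` maps dispensing record_id -> matched (from the disp_to_rx
    direction).  Patient covariates are joined on patid; records keep an
    explicit ``Unknown`` level rather than being dropped when a covariate is
    missing.
    """
    df = dispensings.copy()
    df["outcome"] = ~df["record_id"].map(flags).fillna(False).astype(bool)
    df["age_band"] = assign_age_band(df["day"]).values
    cov = patients.set_index("patid")[
        [c for c in ("sex", "race", "hispanic", "institution_id") if c in patients.columns]]
    df = df.join(cov, on="patid", rsuffix="_pat")
    if "institution_id_pat" in df.columns:
        inst = df["institution_id"].replace("", np.nan)
        df["institution_id"] = inst.fillna(df["institution_id_pat"])
        df = df.drop(columns="institution_id_pat")
    for col in ("sex", "race", "hispanic"):
        df[col] = df[col].fillna("Unknown")
    keep = ["record_id", "patid", "institution_id", "outcome",
            "race", "hispanic", "sex", "age_band", "same_day_enc", "tier", "spectrum"]
    return df[keep].reset_index(drop=True)


def build_patient_design(classifications: pd.DataFrame, patients: pd.DataFrame,
                         *, quartile_mode: str = "data",
                         fixed_cuts: tuple[int, int, int] = (20, 30, 45)) -> pd.DataFrame:
    """One row per patient; outcome = false-negative classification.

    Health-care utilization enters as encounter-count quartiles.  By default
    the cuts are the stratum's own quartiles; ``quartile_mode="fixed"`` uses
    ``fixed_cuts`` as upper bounds of Q1..Q3 (Q4 open-ended).
    """
    df = patients.merge(classifications[["patid", "cell"]], on="patid", how="inner")
    df["outcome"] = df["cell"] == "FN"
    counts = df["encounter_count"]
    labels = ["Q1", "Q2", "Q3", "Q4"]
    if quartile_mode == "fixed":
        bins = [-np.inf, *fixed_cuts, np.inf]
        df["enc_quartile"] = pd.cut(counts, bins=bins, labels=labels)
    elif quartile_mode == "data":
        try:
            df["enc_quartile"] = pd.qcut(counts, 4, labels=labels, duplicates="raise")
        except ValueError:
            ranks = counts.rank(method="first")
            df["enc_quartile"] = pd.qcut(ranks, 4, labels=labels)
    else:
        raise ValueError("quartile_mode must be 'data' or 'fixed'")
    df["enc_quartile"] = df["enc_quartile"].astype(str)
    keep = ["patid", "institution_id", "outcome", "sex", "race", "hispanic",
            "chronic_condition", "preterm", "asthma", "enc_quartile"]
    return df[keep].reset_index(drop=True)


def _formula(design: pd.DataFrame, covariates) -> str:
    terms = []
    for col, ref in covariates:
        if col not in design.columns:
            continue
        if design[col].nunique() < 2:
            continue  # constant columns carry no contrast
        if design[col].dtype == bool:
            terms.append(f"C({col}, Treatment(False))")
        else:
            terms.append(f"C({col}, Treatment('{ref}'))")
    if not terms:
        raise ValueError("no usable covariates in design")
    return "outcome_num ~ " + " + ".join(terms)


def _pretty_terms(names) -> list[str]:
    out = []
    for name in names:
        if name == "Intercept":
            out.append("intercept")
            continue
        # C(race, Treatment('White'))[T.Black]  ->  race[Black]
        col = name.split("(")[1].split(",")[0]
        level = name.split("[T.")[-1].rstrip("]")
        out.append(f"{col}[{level}]")
    return out


def fit_clustered_logit(design: pd.DataFrame, *, covariates=RECORD_COVARIATES,
                        cluster_col: str = "institution_id",
                        method: str = "cluster_robust",
                        alpha: float = 0.05) -> ModelFit:
    """Logistic regression of a binary outcome with clustered data.

    Parameters
    ----------
    design
        Frame with an ``outcome`` boolean plus covariate columns (from
        :func:`build_record_design` / :func:`build_patient_design`).
    covariates
        Sequence of (column, reference level) pairs; constant columns are
        skipped automatically.
    cluster_col
        Cluster identifier for robust errors (institution id).  With a
        single cluster the fit falls back to a plain MLE with a warning.
    method
        ``"cluster_robust"`` (default) — ML logit, sandwich SEs on
        ``cluster_col``; ``"gee"`` — exchangeable GEE grouped by ``patid``
        (records repeated within patient); ``"mixed"`` — variational
        Bayes random intercept on ``cluster_col``.
    """
    design = design.copy()
    if design["outcome"].nunique() < 2:
        raise ValueError("outcome has one level; model not identifiable")
    design["outcome_num"] = design["outcome"].astype(int)
    formula = _formula(design, covariates)
    n_clusters = int(design[cluster_col].nunique()) if cluster_col in design else 1

    notes: list[str] = []
    try:
        if method == "cluster_robust":
            model = smf.logit(formula, data=design)
            if n_clusters >= 2:
                res = model.fit(disp=0, maxiter=200, cov_type="cluster",
                                cov_kwds={"groups": design[cluster_col]})
                tag = "logit+cluster_robust"
            else:
                warnings.warn("single cluster: falling back to plain ML logit",
                              stacklevel=2)
                notes.append("single cluster; plain MLE SEs")
                res = model.fit(disp=0, maxiter=200)
                tag = "logit"
            params, se, pvals = res.params, res.bse, res.pvalues
            converged = bool(res.mle_retvals.get("converged", True))
            llf = float(res.llf)
        elif method == "gee":
            groups = design["patid"] if "patid" in design else design[cluster_col]
            model = smf.gee(formula, groups=groups, data=design,
                            family=sm.families.Binomial(),
                            cov_struct=sm.cov_struct.Exchangeable())
            res = model.fit()
            params, se, pvals = res.params, res.bse, res.pvalues
            tag = "gee_exchangeable"
            converged, llf = True, None
        elif method == "mixed":
            from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
            vc = {"cluster": f"0 + C({cluster_col})"}
            model = BinomialBayesMixedGLM.from_formula(formula, vc, design)
            res = model.fit_vb()
            k = len(res.fe_mean)
            params = pd.Series(res.fe_mean, index=model.exog_names[:k])
            se = pd.Series(res.fe_sd[:k], index=params.index)
            from scipy import stats
            pvals = pd.Series(2 * stats.norm.sf(np.abs(params / se)), index=params.index)
            tag = "vb_mixed_random_intercept"
            converged, llf = True, None
        else:
            raise ValueError(f"unknown method {method!r}")
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise ValueError(f"model could not be fit (separation/collinearity): {err}") from err

    from scipy import stats as _st
    zcrit = _st.norm.ppf(1 - alpha / 2)
    table = pd.DataFrame({
        "term": _pretty_terms(params.index),
        "or_": np.exp(params.values),
        "ci_low": np.exp(params.values - zcrit * se.values),
        "ci_high": np.exp(params.values + zcrit * se.values),
        "pvalue": np.asarray(pvals),
    })
    table["significant"] = table["pvalue"] < alpha
    table = table[table["term"] != "intercept"].reset_index(drop=True)
    return ModelFit(table=table, converged=converged, method=tag,
                    n_obs=len(design), n_clusters=n_clusters, llf=llf, notes=notes)


def fit_patient_fn_model(design: pd.DataFrame, **kwargs) -> ModelFit:
    """False-negative model: institution-clustered logit on patient rows."""
    kwargs.setdefault("covariates", PATIENT_COVARIATES)
    return fit_clustered_logit(design, **kwargs)


def vif_diagnostic(design: pd.DataFrame, covariates=None) -> pd.Series:
    """Variance inflation factors on the expanded (dummy-coded) design.

    VIF_j = 1/(1-R^2_j) from regressing column j on the others; a perfectly
    collinear column reports ``inf`` rather than raising.
    """
    cols = [c for c, _ in covariates] if covariates else [
        c for c in design.columns
        if c not in ("outcome", "outcome_num", "record_id", "patid", "institution_id")]
    X = pd.get_dummies(design[cols], drop_first=True).astype(float)
    X = sm.add_constant(X, has_constant="add")
    vifs = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, name in enumerate(X.columns):
            if name == "const":
                continue
            try:
                v = variance_inflation_factor(X.values, i)
            except (ZeroDivisionError, np.linalg.LinAlgError):
                v = np.inf
            vifs[name] = float(v) if np.isfinite(v) else np.inf
    return pd.Series(vifs, name="vif")
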