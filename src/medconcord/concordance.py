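"""Record-level agreement statistics: match rates, count contingency, weighted kappa.

Agreement between the prescribing and dispensing streams is summarized three
ways:

* the percentage of records in one stream with a match in the other;
* a 5x5 contingency table of per-patient record counts, binned 0/1/2/3/4+;
* a weighted Cohen's kappa on that table, with its asymptotic 95% CI and the
  Landis–Koch qualitative label.

Weighted kappa is ``1 - sum(w*O)/sum(w*E)`` with disagreement weights
``w_ij = |i-j|/(k-1)`` (linear, the default) or its square (quadratic), and
expected counts from the marginal products.  The computation is delegated to
``statsmodels.stats.inter_rater.cohens_kappa``, whose variance is the
Fleiss–Cohen–Everitt large-sample form.

Printed precision follows epidemiological reporting convention: percentages
to one decimal, kappa to two, half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import cohens_kappa

__all__ = [
    "COUNT_BINS",
    "CountContingency",
    "KappaEstimate",
    "round_half_up",
    "match_rate",
    "per_patient_contingency",
    "weighted_kappa",
    "landis_koch_label",
]

#: Ordered per-patient count bins.
COUNT_BINS = ("0", "1", "2", "3", "4+")

# Landis–Koch cut-points, upper-inclusive: the published bands leave
# (0.20, 0.21) undefined, so each band is the half-open interval ending at
# its printed upper bound.
_LANDIS_KOCH = [(0.20, "poor"), (0.40, "fair"), (0.60, "moderate"),
                (0.80, "good"), (1.00, "very_good")]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (matching printed-table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CountContingency:
    """5x5 patient-count table: rows = prescribing bin, cols = dispensing bin."""

    table: np.ndarray
    bins: tuple[str, ...] = COUNT_BINS

    def __post_init__(self):
        self.table = np.asarray(self.table)
        k = len(self.bins)
        if self.table.shape != (k, k):
            raise ValueError(f"table must be {k}x{k}, got {self.table.shape}")
        if (self.table < 0).any():
            raise ValueError("table entries must be non-negative")

    @property
    def n(self) -> int:
        return int(self.table.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.table, index=list(self.bins), columns=list(self.bins))


@dataclass
class KappaEstimate:
    kappa: float
    ci_low: float
    ci_high: float
    weight_scheme: str
    label: str

    def __str__(self):
        return (f"{round_half_up(self.kappa, 2):.2f} "
                f"({round_half_up(self.ci_low, 2):.2f}-"
                f"{round_half_up(self.ci_high, 2):.2f}), {self.label}")


def match_rate(n_matched: int, n_total: int) -> float:
    """Percent of records with a match, half-up rounded to one decimal."""
    if n_total <= 0:
        raise ValueError("match rate undefined for n_total = 0")
    if not 0 <= n_matched <= n_total:
        raise ValueError(f"need 0 <= n_matched <= n_total, got {n_matched}/{n_total}")
    return round_half_up(100.0 * n_matched / n_total, 1)


def _bin_counts(counts: pd.Series) -> pd.Series:
    binned = counts.clip(upper=4).astype(int).astype(str)
    return binned.replace("4", "4+")


def per_patient_contingency(rx: pd.DataFrame, disp: pd.DataFrame,
                            patients: pd.DataFrame) -> CountContingency:
    """Cross-tabulate per-patient prescribing vs dispensing record counts.

    Every patient in ``patients`` contributes exactly one cell; patients with
    no records land in (0, 0).  Counts of 4 or more collapse into the 4+ bin.
    """
    universe = patients["patid"]
    rx_counts = rx.groupby("patid").size().reindex(universe, fill_value=0)
    disp_counts = disp.groupby("patid").size().reindex(universe, fill_value=0)
    rx_bin = pd.Categorical(_bin_counts(rx_counts), categories=COUNT_BINS)
    disp_bin = pd.Categorical(_bin_counts(disp_counts), categories=COUNT_BINS)
    table = pd.crosstab(rx_bin, disp_bin, dropna=False)
    table = table.reindex(index=COUNT_BINS, columns=COUNT_BINS, fill_value=0)
    return CountContingency(table.to_numpy())


def weighted_kappa(table: CountContingency | np.ndarray,
                   weight_scheme: str = "linear") -> KappaEstimate:
    """Weighted Cohen's kappa with an asymptotic 95% CI and Landis–Koch label.

    Raises for a degenerate table (all mass in a single row and column),
    where chance agreement is 1 and kappa is undefined.
    """
    if isinstance(table, CountContingency):
        arr = table.table
    else:
        arr = np.asarray(table)
    if weight_scheme not in ("linear", "quadratic"):
        raise ValueError("weight_scheme must be 'linear' or 'quadratic'")
    if arr.sum() <= 0:
        raise ValueError("empty table")
    row_nonzero = (arr.sum(axis=1) > 0).sum()
    col_nonzero = (arr.sum(axis=0) > 0).sum()
    if row_nonzero <= 1 and col_nonzero <= 1:
        raise ValueError("kappa undefined: all mass in a single category")

    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = cohens_kappa(arr, wt=weight_scheme)
    kappa = float(res.kappa)
    if np.isfinite(res.kappa_low) and np.isfinite(res.kappa_upp):
        ci_low = float(max(res.kappa_low, -1.0))
        ci_high = float(min(res.kappa_upp, 1.0))
    else:
        # degenerate variance (e.g. an empty marginal): CI collapses to the point
        ci_low = ci_high = kappa
    return KappaEstimate(kappa=kappa, ci_low=ci_low, ci_high=ci_high,
                         weight_scheme=weight_scheme,
                         label=landis_koch_label(kappa))


def landis_koch_label(kappa: float) -> str:
    """Qualitative agreement band for a kappa value in [-1, 1]."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must be in [-1, 1], got {kappa}")
    for upper, label in _LANDIS_KOCH:
        if kappa <= upper + 1e-12:
            return label
    return "very_good"
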