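"""Clinical-performance statistics of the screening programme.

Confusion-table metrics (sensitivity, specificity, PPV, NPV) with Wilson
score confidence intervals, exact (Poisson / chi-squared) incidence
intervals, stratified referral rates, the post hoc referral cut-off sweep,
and term/preterm percentile equivalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ProportionCI:
    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "wilson"

    def __post_init__(self) -> None:
        if not self.lower <= self.estimate <= self.upper:
            raise ValueError("CI bounds must bracket the estimate")

    def as_percent(self, ndigits: int = 2) -> tuple[float, float, float]:
        return tuple(round(100 * v, ndigits) for v in (self.estimate, self.lower, self.upper))


def wilson_ci(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion k/n."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    lower, upper = proportion_confint(k, n, alpha=1 - level, method="wilson")
    # guard against floating-point spill just outside [k/n] or [0, 1]
    lower = min(max(float(lower), 0.0), k / n)
    upper = max(min(float(upper), 1.0), k / n)
    return ProportionCI(k / n, lower, upper, level, "wilson")


@dataclass(frozen=True)
class IncidenceEstimate:
    """Incidence as '1 in N' with exact-method confidence bounds."""

    cases: int
    denominator: int
    rate: float
    rate_lower: float
    rate_upper: float
    level: float = 0.95

    @property
    def one_in(self) -> float:
        return self.denominator / self.cases if self.cases else math.inf

    @property
    def one_in_lower(self) -> float:
        """The '1 in N' bound at the lower rate (the larger N)."""
        return math.inf if self.rate_lower == 0 else 1.0 / self.rate_lower

    @property
    def one_in_upper(self) -> float:
        return 1.0 / self.rate_upper


def exact_poisson_ci(cases: int, denominator: int, level: float = 0.95) -> IncidenceEstimate:
    """Exact Poisson confidence interval for an incidence rate.

    Bounds from the chi-squared relation for a Poisson count k:
    rate in [chi2.ppf(a/2, 2k)/2, chi2.ppf(1-a/2, 2k+2)/2] / denominator.
    """
    if cases < 0 or denominator <= 0:
        raise ValueError("need cases >= 0 and denominator > 0")
    alpha = 1 - level
    lo = 0.0 if cases == 0 else chi2.ppf(alpha / 2, 2 * cases) / 2.0
    hi = chi2.ppf(1 - alpha / 2, 2 * cases + 2) / 2.0
    return IncidenceEstimate(
        cases, denominator, cases / denominator,
        lo / denominator, hi / denominator, level,
    )


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/TN/FN counts for one outcome definition."""

    outcome_def: str  # "SCID" or "T_cell_lymphopenia"
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def referred(self) -> int:
        return self.tp + self.fp


def confusion_metrics(table: ConfusionTable, level: float = 0.95) -> dict[str, ProportionCI | None]:
    """Sensitivity, specificity, PPV and NPV, each with a Wilson interval.

    A metric whose denominator is zero is reported as None (undefined).
    """
    def metric(k: int, n: int) -> ProportionCI | None:
        return wilson_ci(k, n, level) if n > 0 else None

    return {
        "sensitivity": metric(table.tp, table.tp + table.fn),
        "specificity": metric(table.tn, table.tn + table.fp),
        "ppv": metric(table.tp, table.tp + table.fp),
        "npv": metric(table.tn, table.tn + table.fn),
    }


def rate(k: int, n: int) -> float:
    """Simple proportion; NaN on an empty stratum."""
    return k / n if n > 0 else math.nan


def referral_rates(
    outcomes: pd.DataFrame,
    cohort_children: pd.DataFrame,
    undetectable_below: float = 1.0,
) -> pd.DataFrame:
    """Referral rates overall and by stratum (term / preterm / non-newborn).

    ``cohort_children`` is one row per child with columns ga_weeks and
    is_newborn (see :func:`trecscreen.cohort.per_child_means`).  Also reports
    the rate of referred samples with undetectable TREC (mean < 1 copy/well).
    """
    joined = outcomes.merge(
        cohort_children[["child_id", "ga_weeks", "is_newborn"]], on="child_id"
    )
    referred = joined["status"] == "positive_referral"
    term = joined["is_newborn"] & (joined["ga_weeks"] >= 37)
    preterm = joined["is_newborn"] & (joined["ga_weeks"] < 37)
    non_newborn = ~joined["is_newborn"]
    undetectable = referred & (joined["mean_trec"] < undetectable_below)

    rows = []
    for name, in_stratum, numerator in [
        ("overall", np.ones(len(joined), bool), referred),
        ("term", term.to_numpy(), referred & term),
        ("preterm", preterm.to_numpy(), referred & preterm),
        ("non_newborn", non_newborn.to_numpy(), referred & non_newborn),
        ("undetectable_trec", np.ones(len(joined), bool), undetectable),
    ]:
        n = int(np.sum(in_stratum))
        k = int(np.sum(numerator))
        rows.append({"stratum": name, "referred": k, "n": n, "rate": rate(k, n)})
    return pd.DataFrame(rows)


def cutoff_sweep(
    referred: pd.DataFrame,
    cutoffs: list[float],
    n_scid_total: int | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Post hoc referral cut-off sweep over the referred children.

    ``referred`` needs columns mean_trec, stratum (term / preterm /
    non_newborn), lymphopenia (bool) and scid (bool).  For each candidate
    cut-off c the children with mean TREC <= c remain referred; PPVs are
    recomputed with Wilson intervals, and SCID sensitivity is evaluated
    against ``n_scid_total`` (defaults to the SCID cases in the table).
    """
    n_scid = int(referred["scid"].sum()) if n_scid_total is None else n_scid_total
    rows = []
    for c in cutoffs:
        kept = referred[referred["mean_trec"] <= c]
        n_ref = len(kept)
        tp_scid = int(kept["scid"].sum())
        tp_lym = int(kept["lymphopenia"].sum())
        ppv_scid = wilson_ci(tp_scid, n_ref, level) if n_ref else None
        ppv_lym = wilson_ci(tp_lym, n_ref, level) if n_ref else None
        rows.append(
            {
                "cutoff": c,
                "referred_total": n_ref,
                "referred_term": int((kept["stratum"] == "term").sum()),
                "referred_preterm": int((kept["stratum"] == "preterm").sum()),
                "tp_scid": tp_scid,
                "tp_lymphopenia": tp_lym,
                "ppv_scid": ppv_scid.estimate if ppv_scid else math.nan,
                "ppv_scid_lo": ppv_scid.lower if ppv_scid else math.nan,
                "ppv_scid_hi": ppv_scid.upper if ppv_scid else math.nan,
                "ppv_lymphopenia": ppv_lym.estimate if ppv_lym else math.nan,
                "ppv_lymphopenia_lo": ppv_lym.lower if ppv_lym else math.nan,
                "ppv_lymphopenia_hi": ppv_lym.upper if ppv_lym else math.nan,
                "sensitivity_scid": rate(tp_scid, n_scid),
            }
        )
    return pd.DataFrame(rows)


def percentile_equivalence(
    term_trecs: np.ndarray | list[float],
    preterm_trecs: np.ndarray | list[float],
    term_cutoff: float,
) -> float:
    """Preterm cut-off at the term distribution's percentile of ``term_cutoff``.

    Returns the preterm-distribution quantile at the cumulative probability
    the term cut-off attains among term children; a result of 0 means the
    matched preterm policy would refer only children with no detectable TREC.
    """
    term = np.asarray(term_trecs, dtype=float)
    pre = np.asarray(preterm_trecs, dtype=float)
    if term.size == 0 or pre.size == 0:
        raise ValueError("both samples must be nonempty")
    p = float(np.mean(term <= term_cutoff))
    return float(np.quantile(pre, p))


def summarise_distribution(
    values: np.ndarray | list[float], display_cap: float = 400.0
) -> dict[str, float]:
    """Median, IQR, 95th percentile and share above the display cap."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    q1, med, q3, p95 = np.percentile(v, [25, 50, 75, 95])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "p95": float(p95),
        "share_above_cap": float(np.mean(v > display_cap)),
        "n": int(v.size),
    }
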