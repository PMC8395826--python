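"""Synthetic cohort of screened children.

Generates a newborn (plus non-newborn) population whose TREC/KREC
copies-per-well distributions match the reference screening year: per
gestational-age stratum the analytes follow lognormal laws calibrated to the
published median and interquartile range, the stratum mixture follows the
published composition, and rare conditions (SCID, non-SCID T cell
lymphopenia, low-TREC false positives, technical card failures) are injected
at configurable rates.

The lognormal family is used because the observed copies/well distributions
are strictly positive and right-skewed; only the median and IQR are
published, which identify a lognormal exactly:

    mu = ln(median),  sigma = ln(q3/q1) / (2 * z_0.75)

with z_0.75 = 0.674490 the 75th standard-normal percentile.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .published import REFERENCE_COUNTS, REFERENCE_STRATA, ReferenceStratum

GAStratum = ReferenceStratum

Z75 = 0.6744897501960817  # standard normal 75th percentile

#: Non-newborns (1 month - 2 years) have right-shifted KREC and slightly
#: higher, wider TREC distributions than term newborns.
NON_NEWBORN_TREC = (104.0, 64.0, 151.0)  # median, q1, q3 copies/well
NON_NEWBORN_KREC = (180.0, 126.0, 258.0)

#: Programme year over which cards arrive (sets the policy epoch per card).
PROGRAMME_START = date(2019, 8, 5)
PROGRAMME_END = date(2020, 8, 4)

#: Lymphopenia definition: CD3+ T cells below this (1e9 cells/L).
CD3_LYMPHOPENIA = 2.0


class Condition(str, enum.Enum):
    """Ground-truth condition of a screened child."""

    HEALTHY = "healthy"
    SCID = "SCID"
    LYMPHOPENIA_NON_SCID = "lymphopenia_non_SCID"
    FP_LOW_TREC = "FP_low_trec"
    TECHNICAL_FAILURE = "technical_failure"


def lognormal_from_median_iqr(
    median: float, q1: float, q3: float
) -> tuple[float, float]:
    """Lognormal (mu, sigma) with the given median and interquartile range.

    Parameters are on the natural-log scale.  The returned distribution has
    exact median ``median`` and quartiles ``q1``/``q3`` up to the symmetric
    IQR approximation (only the ratio q3/q1 is used for sigma).

    Raises
    ------
    ValueError
        If the quantiles are non-positive or mis-ordered.
    """
    if not (0 < q1 <= median <= q3):
        raise ValueError(
            f"need 0 < q1 <= median <= q3, got ({median}, {q1}, {q3})"
        )
    mu = math.log(median)
    sigma = math.log(q3 / q1) / (2.0 * Z75)
    return mu, sigma


def _default_mixture() -> list[tuple[GAStratum, float]]:
    total = sum(s.n_reference for s in REFERENCE_STRATA)
    return [(s, s.n_reference / total) for s in REFERENCE_STRATA]


def _default_case_rates() -> dict[Condition, float]:
    c = REFERENCE_COUNTS
    return {
        Condition.SCID: c.tp_scid / c.n_newborns,
        Condition.LYMPHOPENIA_NON_SCID: (c.tp_lymphopenia - c.tp_scid) / c.n_newborns,
        Condition.FP_LOW_TREC: c.fp_lymphopenia / c.n_total,
    }


@dataclass
class CohortConfig:
    """Configuration of a simulated screening cohort.

    Defaults reproduce the reference screening year: stratum mixture and
    analyte distributions from the published per-gestational-age table, case
    rates from the published referral outcomes, technical-failure rate from
    the published repeat-card rate, and sampling age lognormal with median
    57.1 h and IQR (49.9, 73.0) truncated at 24 h.
    """

    n_newborns: int = REFERENCE_COUNTS.n_newborns
    n_non_newborns: int = REFERENCE_COUNTS.n_non_newborns
    ga_mixture: list[tuple[GAStratum, float]] = field(default_factory=_default_mixture)
    case_rates: dict[Condition, float] = field(default_factory=_default_case_rates)
    tech_failure_rate: float = (
        REFERENCE_COUNTS.n_inconclusive_repeat / REFERENCE_COUNTS.n_total
    )
    unknown_ga_rate: float = REFERENCE_COUNTS.n_unknown_ga / REFERENCE_COUNTS.n_newborns
    seed: int = 0
    sampling_age_model: tuple[float, tuple[float, float]] = (57.1, (49.9, 73.0))
    spot_cv: float = 0.10  # intra-card replicate CV (stand-in; not published)
    n_spots: int = 4

    def validate(self) -> None:
        total = sum(p for _, p in self.ga_mixture)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ga_mixture proportions sum to {total}, not 1")
        rates = list(self.case_rates.values()) + [
            self.tech_failure_rate,
            self.unknown_ga_rate,
        ]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.n_newborns < 0 or self.n_non_newborns < 0:
            raise ValueError("cohort sizes must be >= 0")
        if not 1 <= self.n_spots <= 4:
            raise ValueError("cards carry 1-4 blood spots")


@dataclass
class ScreenedChild:
    """One screened child: demographics, condition truth, per-spot analytes."""

    child_id: str
    sex: str  # F / M / unknown
    ga_weeks: int | None
    is_newborn: bool
    sampling_age_h: float
    condition: Condition
    true_trec: np.ndarray  # copies/well, one entry per blood spot
    true_krec: np.ndarray
    true_actb: np.ndarray
    diagnosis_cd3: float | None = None  # 1e9 cells/L
    arrival_date: date = PROGRAMME_START

    def __post_init__(self) -> None:
        for arr in (self.true_trec, self.true_krec, self.true_actb):
            a = np.asarray(arr, dtype=float)
            if a.ndim != 1 or not 1 <= a.size <= 4:
                raise ValueError("cards carry 1-4 spots")
            if (a < 0).any():
                raise ValueError("analyte truths must be >= 0")


COHORT_COLUMNS = [
    "child_id", "sex", "ga_weeks", "is_newborn", "sampling_age_h",
    "arrival_date", "condition", "spot", "trec", "krec", "actb", "cd3",
]


def _spot_noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    """Multiplicative intra-card noise, lognormal with unit median."""
    if cv <= 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(0.0, sigma, shape)


def _case_analytes(
    condition: Condition,
    n: int,
    n_spots: int,
    rng: np.random.Generator,
    cv: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray]:
    """Draw (trec[n,spots], krec[n,spots] or None, actb or None, cd3[n]).

    Returns None for an analyte the condition does not override.
    """
    shape = (n, n_spots)
    if condition is Condition.SCID:
        # every spot strictly below 1 copy/well; KREC depends on genotype:
        # ADA-like cases lose B cells too (KREC ~ 1), JAK3-like keep them.
        trec = rng.uniform(0.0, 0.95, (n, 1)) * _spot_noise(rng, shape, cv)
        trec = np.minimum(trec, 0.999)
        ada_like = rng.random(n) < 1.0 / 3.0
        krec_base = np.where(
            ada_like,
            rng.uniform(0.0, 2.0, n),
            rng.lognormal(math.log(130.0), 0.3, n),
        )
        krec = krec_base[:, None] * _spot_noise(rng, shape, cv)
        cd3 = rng.uniform(0.0, 0.15, n)
        return trec, krec, None, cd3
    if condition is Condition.LYMPHOPENIA_NON_SCID:
        trec = rng.uniform(0.0, 6.0, (n, 1)) * _spot_noise(rng, shape, cv)
        cd3 = rng.uniform(0.05, CD3_LYMPHOPENIA - 0.05, n)
        return trec, None, None, cd3
    if condition is Condition.FP_LOW_TREC:
        # transiently low TREC, clinically normal CD3
        trec = rng.uniform(0.0, 6.4, (n, 1)) * _spot_noise(rng, shape, cv)
        cd3 = rng.uniform(CD3_LYMPHOPENIA, 5.0, n)
        return trec, None, None, cd3
    if condition is Condition.TECHNICAL_FAILURE:
        # global amplification failure: everything scales down, ACTB < 1000
        trec = rng.uniform(0.0, 5.0, shape)
        krec = rng.uniform(0.0, 5.0, shape)
        actb = rng.uniform(50.0, 950.0, shape)
        return trec, krec, actb, np.full(n, np.nan)
    raise ValueError(f"unknown condition: {condition!r}")


def inject_case(
    child: ScreenedChild,
    condition: Condition | str,
    rng: np.random.Generator | None = None,
    spot_cv: float = 0.10,
) -> ScreenedChild:
    """Return a copy of ``child`` carrying ``condition``'s analyte profile."""
    condition = Condition(condition)
    if rng is None:
        rng = np.random.default_rng(abs(hash(child.child_id)) % 2**31)
    n_spots = child.true_trec.size
    trec, krec, actb, cd3 = _case_analytes(condition, 1, n_spots, rng, spot_cv)
    return replace(
        child,
        condition=condition,
        true_trec=trec[0],
        true_krec=child.true_krec if krec is None else krec[0],
        true_actb=child.true_actb if actb is None else actb[0],
        diagnosis_cd3=None if np.isnan(cd3[0]) else float(cd3[0]),
    )


def _sampling_age(
    rng: np.random.Generator, n: int, model: tuple[float, tuple[float, float]]
) -> np.ndarray:
    median, (q1, q3) = model
    mu, sigma = lognormal_from_median_iqr(median, q1, q3)
    ages = rng.lognormal(mu, sigma, n)
    return np.maximum(ages, 24.0)  # cards are sampled after 24 h of age


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a screened cohort; long format, one row per card spot.

    Deterministic given ``config.seed``.  Healthy children draw their card
    truth from their stratum's calibrated lognormals; spots vary around the
    card truth with multiplicative CV ``spot_cv``.  Non-failure children have
    ACTB >= 1000 copies/well on every spot.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_nb, n_nn = config.n_newborns, config.n_non_newborns
    n = n_nb + n_nn
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    is_newborn = np.zeros(n, dtype=bool)
    is_newborn[:n_nb] = True

    sex = rng.choice(["F", "M"], size=n, p=[0.4818 / 0.9999, 0.5181 / 0.9999])
    sex[rng.random(n) < 14 / 115786] = "unknown"

    # gestational-age strata for newborns
    strata = config.ga_mixture
    props = np.array([p for _, p in strata])
    stratum_idx = rng.choice(len(strata), size=n, p=props / props.sum())
    ga_weeks = np.empty(n, dtype=float)
    for i, (s, _) in enumerate(strata):
        m = stratum_idx == i
        ga_weeks[m] = rng.integers(s.week_lo, s.week_hi + 1, m.sum())
    ga_weeks[~is_newborn] = np.nan
    unknown = is_newborn & (rng.random(n) < config.unknown_ga_rate)
    ga_weeks[unknown] = np.nan

    sampling_age = _sampling_age(rng, n, config.sampling_age_model)
    # non-newborns: 1 month - 2 years old (in hours)
    sampling_age[~is_newborn] = rng.uniform(28 * 24, 730 * 24, (~is_newborn).sum())

    span = (PROGRAMME_END - PROGRAMME_START).days
    arrival = np.array(
        [PROGRAMME_START + timedelta(days=int(d))
         for d in rng.integers(0, span + 1, n)],
        dtype=object,
    )

    # healthy analyte truths: card-level lognormal, then per-spot noise
    n_spots = config.n_spots
    trec = np.empty((n, n_spots))
    krec = np.empty((n, n_spots))
    for i, (s, _) in enumerate(strata):
        m = stratum_idx == i
        k = int(m.sum())
        if k == 0:
            continue
        mu_t, sg_t = lognormal_from_median_iqr(s.trec_median, s.trec_q1, s.trec_q3)
        mu_k, sg_k = lognormal_from_median_iqr(s.krec_median, s.krec_q1, s.krec_q3)
        trec[m] = rng.lognormal(mu_t, sg_t, (k, 1)) * _spot_noise(
            rng, (k, n_spots), config.spot_cv
        )
        krec[m] = rng.lognormal(mu_k, sg_k, (k, 1)) * _spot_noise(
            rng, (k, n_spots), config.spot_cv
        )
    nn = ~is_newborn
    if nn.any():
        k = int(nn.sum())
        mu_t, sg_t = lognormal_from_median_iqr(*NON_NEWBORN_TREC)
        mu_k, sg_k = lognormal_from_median_iqr(*NON_NEWBORN_KREC)
        trec[nn] = rng.lognormal(mu_t, sg_t, (k, 1)) * _spot_noise(
            rng, (k, n_spots), config.spot_cv
        )
        krec[nn] = rng.lognormal(mu_k, sg_k, (k, 1)) * _spot_noise(
            rng, (k, n_spots), config.spot_cv
        )

    actb = rng.lognormal(math.log(30_000.0), 0.5, (n, n_spots))
    actb = np.maximum(actb, 1000.0)  # non-failure cards have sufficient DNA
    cd3 = rng.uniform(CD3_LYMPHOPENIA, 6.0, n)

    # condition assignment
    condition = np.full(n, Condition.HEALTHY.value, dtype=object)
    u = rng.random(n)
    edges = np.zeros(n)
    newborn_only = {Condition.SCID, Condition.LYMPHOPENIA_NON_SCID}
    order = [
        Condition.SCID,
        Condition.LYMPHOPENIA_NON_SCID,
        Condition.FP_LOW_TREC,
        Condition.TECHNICAL_FAILURE,
    ]
    rates = dict(config.case_rates)
    rates[Condition.TECHNICAL_FAILURE] = config.tech_failure_rate
    for cond in order:
        r = rates.get(cond, 0.0)
        eligible = is_newborn if cond in newborn_only else np.ones(n, dtype=bool)
        hit = eligible & (u >= edges) & (u < edges + r)
        condition[hit] = cond.value
        edges = edges + r

    for cond in order:
        m = condition == cond.value
        k = int(m.sum())
        if k == 0:
            continue
        t, kr, ab, c3 = _case_analytes(cond, k, n_spots, rng, config.spot_cv)
        trec[m] = t
        if kr is not None:
            krec[m] = kr
        if ab is not None:
            actb[m] = ab
        cd3[m] = c3

    child_id = np.array([f"C{i:06d}" for i in range(n)])
    spot = np.arange(1, n_spots + 1)
    df = pd.DataFrame(
        {
            "child_id": np.repeat(child_id, n_spots),
            "sex": np.repeat(sex, n_spots),
            "ga_weeks": np.repeat(ga_weeks, n_spots),
            "is_newborn": np.repeat(is_newborn, n_spots),
            "sampling_age_h": np.repeat(sampling_age, n_spots),
            "arrival_date": np.repeat(arrival, n_spots),
            "condition": np.repeat(condition, n_spots),
            "spot": np.tile(spot, n),
            "trec": trec.ravel(),
            "krec": krec.ravel(),
            "actb": actb.ravel(),
            "cd3": np.repeat(cd3, n_spots),
        }
    )
    return df


def children_from_frame(df: pd.DataFrame) -> list[ScreenedChild]:
    """Materialise :class:`ScreenedChild` objects from a long cohort frame."""
    out: list[ScreenedChild] = []
    for cid, g in df.groupby("child_id", sort=True):
        g = g.sort_values("spot")
        first = g.iloc[0]
        ga = first["ga_weeks"]
        cd3 = first["cd3"]
        arr = first["arrival_date"]
        if isinstance(arr, pd.Timestamp):
            arr = arr.date()
        out.append(
            ScreenedChild(
                child_id=str(cid),
                sex=str(first["sex"]),
                ga_weeks=None if pd.isna(ga) else int(ga),
                is_newborn=bool(first["is_newborn"]),
                sampling_age_h=float(first["sampling_age_h"]),
                condition=Condition(first["condition"]),
                true_trec=g["trec"].to_numpy(float),
                true_krec=g["krec"].to_numpy(float),
                true_actb=g["actb"].to_numpy(float),
                diagnosis_cd3=None if pd.isna(cd3) else float(cd3),
                arrival_date=arr,
            )
        )
    return out


def per_child_means(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long cohort frame to one row per child (spot means)."""
    agg = df.groupby("child_id", sort=False).agg(
        trec=("trec", "mean"),
        krec=("krec", "mean"),
        actb=("actb", "mean"),
        ga_weeks=("ga_weeks", "first"),
        is_newborn=("is_newborn", "first"),
        condition=("condition", "first"),
        cd3=("cd3", "first"),
        arrival_date=("arrival_date", "first"),
    )
    return agg.reset_index()
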