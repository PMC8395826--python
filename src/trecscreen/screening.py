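"""Screening decision algorithm.

Per card: an initial TREC/ACTB measurement from one punch passes a quality
gate (expected amplification profile and ACTB >= 1000 copies/well).  A TREC
result above the epoch's reanalysis cut-off (15 copies/well; lowered to 10 on
2020-04-01) is directly negative.  Between the referral cut-off (TREC <= 6,
inclusive) and the reanalysis cut-off, the card is reanalysed in duplicate
from new punches; at or below the referral cut-off, in quadruplicate (or from
all available spots).  The verdict uses the mean over all PCRs of the card,
after an outlier rule that may drop a single extremely-low replicate: SCID
cards yield uniformly low TREC, so one aberrant low value among otherwise
normal replicates indicates a technical artefact, never disease.  Cards whose
replicates are all below the referral cut-off with ACTB < 1000 throughout are
inconclusive (amplification failure) and a new card is requested.
KREC is quantified and reported but never enters the referral decision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .cohort import Condition, per_child_means


class Action(str, enum.Enum):
    NEGATIVE = "negative"
    REANALYSE_DUPLICATE = "reanalyse_duplicate"
    REANALYSE_QUADRUPLICATE = "reanalyse_quadruplicate"
    QUALITY_FAIL = "quality_fail"


class Status(str, enum.Enum):
    NEGATIVE = "negative"
    NEGATIVE_AFTER_REANALYSIS = "negative_after_reanalysis"
    POSITIVE_REFERRAL = "positive_referral"
    INCONCLUSIVE_NEW_CARD = "inconclusive_new_card"
    LOST_TO_FOLLOWUP = "lost_to_followup"


@dataclass(frozen=True)
class ScreeningPolicy:
    """Cut-offs and rules of the screening programme (copies/well)."""

    reanalysis_cutoff_epoch1: float = 15.0
    reanalysis_cutoff_epoch2: float = 10.0
    referral_cutoff: float = 6.0
    actb_min: float = 1000.0
    epoch_switch_date: date = date(2020, 4, 1)
    outlier_ratio: float = 10.0   # max/min ratio that flags extreme variability
    borderline_delta: float = 0.0  # discretionary referral band above cut-off
    repeat_card_response_rate: float = 20 / 27

    def __post_init__(self) -> None:
        if self.referral_cutoff > min(
            self.reanalysis_cutoff_epoch1, self.reanalysis_cutoff_epoch2
        ):
            raise ValueError("referral cut-off must not exceed reanalysis cut-offs")
        if self.actb_min <= 0:
            raise ValueError("actb_min must be > 0")

    def epoch(self, when: date) -> int:
        return 2 if when >= self.epoch_switch_date else 1

    def reanalysis_cutoff(self, when: date) -> float:
        return (
            self.reanalysis_cutoff_epoch2
            if self.epoch(when) == 2
            else self.reanalysis_cutoff_epoch1
        )


@dataclass
class ScreeningOutcome:
    """Terminal verdict for one child's screening trajectory."""

    child_id: str
    status: Status
    mean_trec: float
    mean_krec: float
    replicates_used: int
    replicates_excluded: int
    epoch: int


def classify_initial(
    trec: float,
    actb: float,
    amplification_ok: bool,
    policy: ScreeningPolicy,
    when: date,
) -> Action:
    """Triage the first PCR of a card."""
    if trec < 0 or actb < 0:
        raise ValueError("analyte values must be >= 0")
    if not amplification_ok or actb < policy.actb_min:
        return Action.QUALITY_FAIL
    if trec > policy.reanalysis_cutoff(when):
        return Action.NEGATIVE
    if trec > policy.referral_cutoff:
        return Action.REANALYSE_DUPLICATE
    return Action.REANALYSE_QUADRUPLICATE


def replicate_consensus(
    replicate_trecs: list[float] | np.ndarray,
    policy: ScreeningPolicy = ScreeningPolicy(),
) -> tuple[float, list[int]]:
    """Mean TREC over replicates after the extreme-variability rule.

    A replicate is dropped iff it is the current minimum, the retained
    max/min ratio exceeds ``policy.outlier_ratio``, and the mean of the
    remaining replicates exceeds the referral cut-off (so the exclusion can
    never convert a uniformly-low SCID-like card into a negative).  The rule
    is applied iteratively but always keeps at least one replicate.
    """
    values = np.asarray(replicate_trecs, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one replicate")
    if (values < 0).any():
        raise ValueError("replicate TRECs must be >= 0")
    keep = list(range(values.size))
    excluded: list[int] = []
    while len(keep) > 1:
        sub = values[keep]
        lo, hi = float(sub.min()), float(sub.max())
        extreme = lo < hi and hi > lo * policy.outlier_ratio
        if not extreme:
            break
        i_min = keep[int(np.argmin(sub))]
        rest = [i for i in keep if i != i_min]
        if float(values[rest].mean()) <= policy.referral_cutoff:
            break
        excluded.append(i_min)
        keep = rest
    return float(values[keep].mean()), excluded


@dataclass
class SpotResult:
    """Quantified PCR result of one punch."""

    trec: float
    krec: float
    actb: float
    amplification_ok: bool = True


def screen_child(
    child_id: str,
    spots: list[SpotResult],
    policy: ScreeningPolicy,
    when: date,
) -> ScreeningOutcome:
    """Run the per-card decision algorithm over quantified punch results.

    ``spots`` are the card's available punches in analysis order; the first
    is the initial screening PCR.  Duplicate reanalysis uses the next two
    punches, quadruplicate all punches; the consensus mean covers every PCR
    performed on the card.
    """
    if not spots:
        return ScreeningOutcome(
            child_id, Status.INCONCLUSIVE_NEW_CARD, float("nan"), float("nan"),
            0, 0, policy.epoch(when),
        )
    epoch = policy.epoch(when)
    first = spots[0]
    action = classify_initial(first.trec, first.actb, first.amplification_ok,
                              policy, when)
    if action is Action.NEGATIVE:
        return ScreeningOutcome(
            child_id, Status.NEGATIVE, first.trec, first.krec, 1, 0, epoch
        )
    if action is Action.REANALYSE_DUPLICATE:
        used = spots[: min(3, len(spots))]
    else:  # quadruplicate or quality failure: all available punches
        used = spots
    trecs = [s.trec for s in used]
    mean_trec, excluded = replicate_consensus(trecs, policy)
    kept = [s for i, s in enumerate(used) if i not in excluded]
    mean_krec = float(np.mean([s.krec for s in kept]))
    all_low_quality = all(
        s.actb < policy.actb_min or not s.amplification_ok for s in used
    )
    all_below_referral = all(s.trec < policy.referral_cutoff for s in used)
    if all_low_quality and all_below_referral:
        status = Status.INCONCLUSIVE_NEW_CARD
    elif mean_trec <= policy.referral_cutoff:
        status = Status.POSITIVE_REFERRAL
    elif mean_trec <= policy.referral_cutoff + policy.borderline_delta:
        status = Status.POSITIVE_REFERRAL  # discretionary borderline referral
    else:
        status = Status.NEGATIVE_AFTER_REANALYSIS
    return ScreeningOutcome(
        child_id, status, mean_trec, mean_krec, len(used), len(excluded), epoch
    )


OUTCOME_COLUMNS = [
    "child_id", "status", "mean_trec", "mean_krec",
    "replicates_used", "replicates_excluded", "epoch",
]


def run_programme(
    cohort: pd.DataFrame,
    policy: ScreeningPolicy = ScreeningPolicy(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Screen every child in a long-format cohort frame.

    Measured copies/well equal the card truths (the zero-noise quantification
    round-trip is the identity); route the cohort through
    :func:`trecscreen.qpcr.simulate_plate` first to add Ct noise and
    near-detection-limit dropout.  ``seed`` drives only the second-card
    response of inconclusive children.  Returns (outcomes frame, programme
    log with aggregate counters).
    """
    rng = np.random.default_rng(seed)
    if cohort.empty:
        return pd.DataFrame(columns=OUTCOME_COLUMNS), {
            "n_children": 0, "n_reanalysed": 0, "n_referred": 0,
            "n_inconclusive": 0, "n_lost_to_followup": 0,
            "reanalysis_rate_by_epoch": {},
        }

    wide = cohort.pivot_table(
        index="child_id", columns="spot", values=["trec", "krec", "actb"],
        sort=False,
    )
    meta = cohort.drop_duplicates("child_id").set_index("child_id")
    order = meta.index
    trec = wide["trec"].loc[order].to_numpy(float)
    krec = wide["krec"].loc[order].to_numpy(float)
    actb = wide["actb"].loc[order].to_numpy(float)
    when = pd.to_datetime(meta["arrival_date"]).dt.date.to_numpy()
    epochs = np.array([policy.epoch(d) for d in when])
    rean_cut = np.where(
        epochs == 2, policy.reanalysis_cutoff_epoch2, policy.reanalysis_cutoff_epoch1
    )

    quality_ok = actb[:, 0] >= policy.actb_min
    direct_negative = quality_ok & (trec[:, 0] > rean_cut)

    n = len(order)
    statuses = np.empty(n, dtype=object)
    mean_trec = np.full(n, np.nan)
    mean_krec = np.full(n, np.nan)
    used = np.zeros(n, dtype=int)
    excl = np.zeros(n, dtype=int)

    statuses[direct_negative] = Status.NEGATIVE.value
    mean_trec[direct_negative] = trec[direct_negative, 0]
    mean_krec[direct_negative] = krec[direct_negative, 0]
    used[direct_negative] = 1

    n_inconclusive = 0
    n_lost = 0
    flagged = np.flatnonzero(~direct_negative)
    for i in flagged:
        spots = [
            SpotResult(trec[i, j], krec[i, j], actb[i, j], True)
            for j in range(trec.shape[1])
            if not np.isnan(trec[i, j])
        ]
        out = screen_child(str(order[i]), spots, policy, when[i])
        if out.status is Status.INCONCLUSIVE_NEW_CARD:
            n_inconclusive += 1
            # one repeat card is requested; responders screen negative on a
            # fresh card (failures are card artefacts, not disease)
            if rng.random() < policy.repeat_card_response_rate:
                out.status = Status.NEGATIVE
            else:
                out.status = Status.LOST_TO_FOLLOWUP
                n_lost += 1
        statuses[i] = out.status.value
        mean_trec[i] = out.mean_trec
        mean_krec[i] = out.mean_krec
        used[i] = out.replicates_used
        excl[i] = out.replicates_excluded

    outcomes = pd.DataFrame(
        {
            "child_id": order,
            "status": statuses,
            "mean_trec": mean_trec,
            "mean_krec": mean_krec,
            "replicates_used": used,
            "replicates_excluded": excl,
            "epoch": epochs,
        }
    ).reset_index(drop=True)

    reanalysed = ~direct_negative
    log = {
        "n_children": int(n),
        "n_reanalysed": int(reanalysed.sum()),
        "reanalysis_rate": float(reanalysed.mean()),
        "reanalysis_rate_by_epoch": {
            int(e): float(reanalysed[epochs == e].mean())
            for e in np.unique(epochs)
        },
        "n_referred": int((outcomes["status"] == Status.POSITIVE_REFERRAL.value).sum()),
        "n_inconclusive": int(n_inconclusive),
        "n_lost_to_followup": int(n_lost),
        "policy": {
            "reanalysis_cutoff_epoch1": policy.reanalysis_cutoff_epoch1,
            "reanalysis_cutoff_epoch2": policy.reanalysis_cutoff_epoch2,
            "referral_cutoff": policy.referral_cutoff,
            "actb_min": policy.actb_min,
        },
    }
    return outcomes, log
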