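"""End-to-end pipeline: typed configuration, reference mode, simulation mode.

Two entry points:

* :func:`reference_report` — pure arithmetic on the published aggregate
  counts of the reference screening year (no simulation, no randomness):
  confusion-table metrics for both outcome definitions, stratified referral
  rates, the SCID incidence estimate, and the post hoc cut-off sweep over the
  reconstructed referred-children table.

* :func:`run_all` — simulate a cohort, screen it, and evaluate the same
  statistics on the simulated programme.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import published
from .cohort import CohortConfig, Condition, per_child_means, simulate_cohort
from .performance import (
    ConfusionTable,
    confusion_metrics,
    cutoff_sweep,
    exact_poisson_ci,
    percentile_equivalence,
    rate,
    referral_rates,
    summarise_distribution,
)
from .screening import ScreeningPolicy, Status, run_programme

DEFAULT_SWEEP_CUTOFFS = [6.0, 5.0, 4.0, 3.0, 2.0, 1.0, 0.0]


class CohortSettings(BaseModel):
    n_newborns: int = 50_000
    n_non_newborns: int = 250
    spot_cv: float = 0.10
    n_spots: int = 4
    case_rates: dict[str, float] | None = None  # None: reference-year rates
    tech_failure_rate: float | None = None

    def to_config(self, seed: int) -> CohortConfig:
        cfg = CohortConfig(
            n_newborns=self.n_newborns,
            n_non_newborns=self.n_non_newborns,
            spot_cv=self.spot_cv,
            n_spots=self.n_spots,
            seed=seed,
        )
        if self.case_rates is not None:
            cfg.case_rates = {Condition(k): v for k, v in self.case_rates.items()}
        if self.tech_failure_rate is not None:
            cfg.tech_failure_rate = self.tech_failure_rate
        return cfg


class PolicySettings(BaseModel):
    reanalysis_cutoff_epoch1: float = 15.0
    reanalysis_cutoff_epoch2: float = 10.0
    referral_cutoff: float = 6.0
    actb_min: float = 1000.0
    epoch_switch_date: date = date(2020, 4, 1)
    outlier_ratio: float = 10.0
    borderline_delta: float = 0.0

    def to_policy(self) -> ScreeningPolicy:
        return ScreeningPolicy(**self.model_dump())


class EvalSettings(BaseModel):
    ci_level: float = 0.95
    sweep_cutoffs: list[float] = Field(default_factory=lambda: list(DEFAULT_SWEEP_CUTOFFS))
    term_cutoff_for_equivalence: float = 4.0


class PipelineConfig(BaseModel):
    """Typed configuration for the whole pipeline (YAML/JSON round-trip)."""

    seed: int = 0
    cohort: CohortSettings = Field(default_factory=CohortSettings)
    policy: PolicySettings = Field(default_factory=PolicySettings)
    eval: EvalSettings = Field(default_factory=EvalSettings)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = json.loads(self.model_dump_json())
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))


def _ci_dict(ci) -> dict | None:
    if ci is None:
        return None
    return {
        "estimate": ci.estimate, "lower": ci.lower, "upper": ci.upper,
        "percent": ci.as_percent(),
    }


def _metrics_dict(table: ConfusionTable, level: float = 0.95) -> dict:
    m = confusion_metrics(table, level)
    return {
        "counts": {"tp": table.tp, "fp": table.fp, "tn": table.tn, "fn": table.fn},
        **{name: _ci_dict(ci) for name, ci in m.items()},
    }


def reference_report(level: float = 0.95, sweep_cutoffs: list[float] | None = None) -> dict:
    """Recompute the screening year's performance from the published counts.

    Pure arithmetic: consumes no random numbers.  Screening-negative children
    without a final outcome (lost to follow-up and opt-outs) are excluded
    from the true-negative count, which the published negative count already
    reflects.
    """
    c = published.REFERENCE_COUNTS
    scid = ConfusionTable("SCID", c.tp_scid, c.fp_scid, c.n_screening_negative, c.fn_scid)
    lym = ConfusionTable(
        "T_cell_lymphopenia", c.tp_lymphopenia, c.fp_lymphopenia,
        c.n_screening_negative, c.fn_lymphopenia,
    )
    incidence = exact_poisson_ci(c.tp_scid, c.n_newborns, level)
    referred = published.referred_children()
    sweep = cutoff_sweep(referred, sweep_cutoffs or DEFAULT_SWEEP_CUTOFFS,
                         n_scid_total=c.tp_scid, level=level)
    return {
        "mode": "reference-counts",
        "confusion": {
            "SCID": _metrics_dict(scid, level),
            "T_cell_lymphopenia": _metrics_dict(lym, level),
        },
        "referral_rates": {
            "overall": {"k": c.n_referred, "n": c.n_total, "rate": rate(c.n_referred, c.n_total)},
            "term": {"k": c.n_referred_term, "n": c.n_term, "rate": rate(c.n_referred_term, c.n_term)},
            "preterm": {"k": c.n_referred_preterm, "n": c.n_preterm, "rate": rate(c.n_referred_preterm, c.n_preterm)},
            "non_newborn": {"k": c.n_referred_non_newborn, "n": c.n_non_newborns, "rate": rate(c.n_referred_non_newborn, c.n_non_newborns)},
            "undetectable_trec": {"k": c.n_undetectable_trec, "n": c.n_total, "rate": rate(c.n_undetectable_trec, c.n_total)},
            "repeat_card": {"k": c.n_inconclusive_repeat, "n": c.n_total, "rate": rate(c.n_inconclusive_repeat, c.n_total)},
        },
        "incidence": {
            "cases": incidence.cases,
            "denominator": incidence.denominator,
            "one_in": incidence.one_in,
            "one_in_lower": incidence.one_in_lower,
            "one_in_upper": incidence.one_in_upper,
        },
        "cutoff_sweep": sweep.to_dict(orient="records"),
    }


def _simulated_confusion(children: pd.DataFrame, outcomes: pd.DataFrame) -> dict[str, ConfusionTable]:
    """Confusion tables against the simulation's ground-truth labels.

    Children lost to follow-up have no final outcome and are excluded.
    """
    j = outcomes.merge(children[["child_id", "condition"]], on="child_id")
    j = j[j["status"] != Status.LOST_TO_FOLLOWUP.value]
    referred = j["status"] == Status.POSITIVE_REFERRAL.value
    tables = {}
    for name, positive in [
        ("SCID", j["condition"] == Condition.SCID.value),
        ("T_cell_lymphopenia", j["condition"].isin(
            [Condition.SCID.value, Condition.LYMPHOPENIA_NON_SCID.value])),
    ]:
        tables[name] = ConfusionTable(
            name,
            tp=int((referred & positive).sum()),
            fp=int((referred & ~positive).sum()),
            tn=int((~referred & ~positive).sum()),
            fn=int((~referred & positive).sum()),
        )
    return tables


def run_all(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate, screen and evaluate one cohort; optionally write artefacts."""
    cohort = simulate_cohort(config.cohort.to_config(config.seed))
    children = per_child_means(cohort)
    policy = config.policy.to_policy()
    outcomes, log = run_programme(cohort, policy, seed=config.seed)

    tables = _simulated_confusion(children, outcomes)
    rates = referral_rates(outcomes, children)

    referred = outcomes[outcomes["status"] == Status.POSITIVE_REFERRAL.value].merge(
        children[["child_id", "ga_weeks", "is_newborn", "condition"]], on="child_id"
    )
    referred["stratum"] = np.where(
        ~referred["is_newborn"], "non_newborn",
        np.where(referred["ga_weeks"] >= 37, "term", "preterm"),
    )
    referred["scid"] = referred["condition"] == Condition.SCID.value
    referred["lymphopenia"] = referred["condition"].isin(
        [Condition.SCID.value, Condition.LYMPHOPENIA_NON_SCID.value]
    )
    sweep = cutoff_sweep(referred, config.eval.sweep_cutoffs, level=config.eval.ci_level)

    newborns = children[children["is_newborn"]]
    scid_cases = int(
        (referred["scid"] & referred["is_newborn"]).sum()
    )
    incidence = exact_poisson_ci(scid_cases, max(len(newborns), 1), config.eval.ci_level)

    term_trec = newborns.loc[newborns["ga_weeks"] >= 37, "trec"].to_numpy()
    pre_trec = newborns.loc[newborns["ga_weeks"] < 37, "trec"].to_numpy()
    equivalence = (
        percentile_equivalence(term_trec, pre_trec, config.eval.term_cutoff_for_equivalence)
        if term_trec.size and pre_trec.size
        else float("nan")
    )

    report = {
        "mode": "simulation",
        "seed": config.seed,
        "n_children": int(len(children)),
        "programme_log": log,
        "confusion": {k: _metrics_dict(t, config.eval.ci_level) for k, t in tables.items()},
        "referral_rates": rates.to_dict(orient="records"),
        "incidence": {
            "cases": incidence.cases,
            "denominator": incidence.denominator,
            "one_in": incidence.one_in,
            "one_in_lower": incidence.one_in_lower,
            "one_in_upper": incidence.one_in_upper,
        },
        "trec_distribution": summarise_distribution(newborns["trec"].to_numpy()),
        "cutoff_sweep": sweep.to_dict(orient="records"),
        "preterm_cutoff_at_term_percentile": equivalence,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        outcomes.to_csv(out / "outcomes.csv", index=False)
        sweep.to_csv(out / "cutoff_sweep.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
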