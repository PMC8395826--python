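"""96-well multiplex qPCR model: standard curves, quantification, plates.

The assay quantifies TREC, KREC and ACTB copies/well from dried-blood-spot
punches against 5-point plasmid standard curves (TREC/KREC 10-100,000
copies/well, ACTB 100-1,000,000).  A fitted curve is the least-squares line
of Ct on log10(copies); quantification inverts it.  The forward model
(``simulate_plate``) adds Gaussian Ct noise and a stochastic detection step
near the assay's limit of blank / limit of detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ANALYTES = ("TREC", "KREC", "ACTB")

#: Standard-curve spans, copies/well.
CURVE_RANGE = {
    "TREC": (10.0, 100_000.0),
    "KREC": (10.0, 100_000.0),
    "ACTB": (100.0, 1_000_000.0),
}


@dataclass(frozen=True)
class AnalyticalLimits:
    """Manufacturer analytical limits of the assay, copies/well."""

    lod_trec: float = 3.41
    lod_krec: float = 3.13
    lob_trec: float = 0.32
    lob_krec: float = 0.38

    def __post_init__(self) -> None:
        if self.lob_trec >= self.lod_trec or self.lob_krec >= self.lod_krec:
            raise ValueError("limit of blank must be below limit of detection")

    def lob(self, analyte: str) -> float:
        return {"TREC": self.lob_trec, "KREC": self.lob_krec}.get(analyte, 0.0)

    def lod(self, analyte: str) -> float:
        return {"TREC": self.lod_trec, "KREC": self.lod_krec}.get(analyte, 0.0)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted standard curve: Ct = intercept + slope * log10(copies)."""

    analyte: str
    points: tuple[tuple[float, float], ...]  # (nominal copies/well, Ct)
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 1.0 = perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


class InvalidCurveError(ValueError):
    pass


def fit_standard_curve(
    points: list[tuple[float, float]], analyte: str = "TREC"
) -> StandardCurve:
    """Least-squares fit of Ct on log10(copies/well).

    Raises :class:`InvalidCurveError` for fewer than two distinct
    concentrations or non-positive concentrations.
    """
    conc = np.array([c for c, _ in points], dtype=float)
    cts = np.array([ct for _, ct in points], dtype=float)
    if (conc <= 0).any():
        raise InvalidCurveError("standard concentrations must be > 0")
    if np.unique(conc).size < 2:
        raise InvalidCurveError("need >= 2 distinct standard concentrations")
    x = np.log10(conc)
    slope, intercept = np.polyfit(x, cts, 1)
    pred = intercept + slope * x
    ss_res = float(np.sum((cts - pred) ** 2))
    ss_tot = float(np.sum((cts - cts.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return StandardCurve(
        analyte=analyte,
        points=tuple((float(c), float(t)) for c, t in points),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
    )


def ideal_curve(analyte: str, intercept: float = 40.0) -> StandardCurve:
    """A perfect 100%-efficiency curve over the kit's standard span."""
    lo, hi = CURVE_RANGE[analyte]
    slope = -1.0 / math.log10(2.0)  # -3.321928: one Ct per doubling
    concs = np.geomspace(lo, hi, 5)
    pts = [(float(c), intercept + slope * math.log10(c)) for c in concs]
    return fit_standard_curve(pts, analyte)


def default_curves(intercept: float = 40.0) -> dict[str, StandardCurve]:
    return {a: ideal_curve(a, intercept) for a in ANALYTES}


def quantify(ct: float | None, curve: StandardCurve) -> float:
    """Copies/well from a Ct value; no amplification (None/NaN) is 0 copies."""
    if ct is None or (isinstance(ct, float) and math.isnan(ct)):
        return 0.0
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def in_curve_range(copies: float, curve: StandardCurve) -> bool:
    lo, hi = CURVE_RANGE[curve.analyte]
    return lo <= copies <= hi


@dataclass
class WellMeasurement:
    """One well: per-analyte Ct (NaN = no amplification) and QC flag."""

    well_id: str
    sample_ref: str
    cts: dict[str, float]
    amplification_ok: dict[str, bool] = field(default_factory=dict)

    def quantified(self, curves: dict[str, StandardCurve]) -> dict[str, float]:
        return {a: quantify(self.cts.get(a, math.nan), curves[a]) for a in curves}


#: Internal dried-blood-spot control patterns: expected (TREC, KREC) truth in
#: copies/well.  "Low" sits below the referral region, "high" well above the
#: reanalysis region.
CONTROL_TRUTHS = {
    "low-TREC/high-KREC": {"TREC": 2.0, "KREC": 100.0, "ACTB": 30_000.0},
    "low-KREC/high-TREC": {"TREC": 100.0, "KREC": 2.0, "ACTB": 30_000.0},
    "low-TREC/low-KREC": {"TREC": 2.0, "KREC": 2.0, "ACTB": 30_000.0},
}

PLATE_CAPACITY = 92  # 96 wells minus three DBS controls and one blank


@dataclass
class PlateRecord:
    """One 96-well run: curves, sample wells, three controls, one blank."""

    plate_id: str
    curves: dict[str, StandardCurve]
    wells: list[WellMeasurement]
    controls: dict[str, WellMeasurement]
    blank: WellMeasurement

    def __post_init__(self) -> None:
        if set(self.controls) != set(CONTROL_TRUTHS):
            raise ValueError("a plate carries exactly the three DBS controls")


class PlateCapacityError(ValueError):
    pass


def _simulate_ct(
    truth: float,
    analyte: str,
    curve: StandardCurve,
    noise_sd: float,
    rng: np.random.Generator,
    limits: AnalyticalLimits,
    near_lod_detection_p: float = 0.5,
) -> float:
    """Forward model: Ct from a true copy number; NaN = no amplification."""
    lob, lod = limits.lob(analyte), limits.lod(analyte)
    if truth <= 0 or truth < lob:
        return math.nan
    if truth < lod and rng.random() >= near_lod_detection_p:
        return math.nan
    ct = curve.intercept + curve.slope * math.log10(truth)
    if noise_sd > 0:
        ct += rng.normal(0.0, noise_sd)
    return ct


def simulate_plate(
    samples: list[tuple[str, dict[str, float]]],
    curves: dict[str, StandardCurve] | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    limits: AnalyticalLimits = AnalyticalLimits(),
    plate_id: str = "P1",
    near_lod_detection_p: float = 0.5,
) -> PlateRecord:
    """Simulate a plate from (sample_ref, {analyte: true copies/well}) pairs.

    At most 92 samples fit beside the three internal controls and the blank.
    Truths below the limit of blank never amplify; truths between LoB and LoD
    amplify with probability ``near_lod_detection_p``.
    """
    if len(samples) > PLATE_CAPACITY:
        raise PlateCapacityError(
            f"{len(samples)} samples exceed plate capacity {PLATE_CAPACITY}"
        )
    curves = curves or default_curves()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def make_well(well_id: str, ref: str, truths: dict[str, float]) -> WellMeasurement:
        cts = {
            a: _simulate_ct(
                truths.get(a, 0.0), a, curves[a], noise_sd, rng, limits,
                near_lod_detection_p,
            )
            for a in curves
        }
        ok = {a: not math.isnan(cts[a]) for a in cts}
        return WellMeasurement(well_id=well_id, sample_ref=ref, cts=cts,
                               amplification_ok=ok)

    wells = [
        make_well(f"{plate_id}-S{i + 1:02d}", ref, truths)
        for i, (ref, truths) in enumerate(samples)
    ]
    controls = {
        name: make_well(f"{plate_id}-CTRL-{name}", name, truths)
        for name, truths in CONTROL_TRUTHS.items()
    }
    blank = make_well(f"{plate_id}-BLANK", "blank", {a: 0.0 for a in curves})
    return PlateRecord(plate_id, curves, wells, controls, blank)


@dataclass(frozen=True)
class PlateVerdict:
    accepted: bool
    reasons: tuple[str, ...] = ()


def accept_plate(
    plate: PlateRecord,
    min_r2: float = 0.98,
    efficiency_range: tuple[float, float] = (0.9, 1.1),
    control_low_max: float = 6.0,
    control_high_min: float = 15.0,
) -> PlateVerdict:
    """Plate QC: curve quality, control patterns, blank purity.

    Accepted iff every curve has r^2 >= ``min_r2`` and efficiency within
    ``efficiency_range``, every internal control reproduces its expected
    low/high TREC-KREC pattern (low below the referral region, high above the
    reanalysis region), and the blank shows no amplification in any analyte.
    """
    reasons: list[str] = []
    for a, curve in plate.curves.items():
        if curve.r_squared < min_r2:
            reasons.append(f"curve {a}: r2 {curve.r_squared:.4f} < {min_r2}")
        lo, hi = efficiency_range
        if not lo <= curve.efficiency <= hi:
            reasons.append(f"curve {a}: efficiency {curve.efficiency:.3f} outside [{lo}, {hi}]")
    for name, well in plate.controls.items():
        q = well.quantified(plate.curves)
        for analyte in ("TREC", "KREC"):
            expected_low = CONTROL_TRUTHS[name][analyte] <= control_low_max
            if expected_low and q[analyte] > control_low_max:
                reasons.append(f"control pattern: {name} {analyte} high ({q[analyte]:.1f})")
            if not expected_low and q[analyte] < control_high_min:
                reasons.append(f"control pattern: {name} {analyte} low ({q[analyte]:.1f})")
    if any(not math.isnan(ct) for ct in plate.blank.cts.values()):
        reasons.append("blank contamination")
    return PlateVerdict(accepted=not reasons, reasons=tuple(reasons))


def plate_to_frame(plate: PlateRecord):
    """Plate export: one row per well x analyte (round-trippable CSV dialect)."""
    import pandas as pd

    rows = []
    all_wells = (
        list(plate.wells) + list(plate.controls.values()) + [plate.blank]
    )
    for w in all_wells:
        for a, ct in w.cts.items():
            rows.append(
                {
                    "plate_id": plate.plate_id,
                    "well": w.well_id,
                    "sample_ref": w.sample_ref,
                    "analyte": a,
                    "ct": ct,
                    "amplification_ok": w.amplification_ok.get(a, False),
                }
            )
    return pd.DataFrame(rows)
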