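"""Preclinical tumor-response quantification.

Caliper measurements are converted to volume with the modified ellipsoid
formula V = length × width² / 2.  Each mouse's growth curve is classified
into one of four response classes relative to its treatment-start
baseline: CR (complete response: final volume at or below a detection
threshold, default 0 mm³ = no palpable tumor), DR (durable response:
final volume below baseline), SR (short response: a real dip below
baseline — nadir under ``response_fraction`` × baseline — followed by
progression past baseline), and NR (no response).  Arm-level summaries,
Kaplan–Meier survival with a log-rank (Mantel–Cox) comparison, and
ΔΔCt-based qPCR log2 fold changes (housekeeping gene Tbp) round out the
analysis layer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger(__name__)

RESPONSE_CLASSES = ("CR", "DR", "SR", "NR")


def tumor_volume(length: float, width: float) -> float:
    """Modified ellipsoid volume (mm³) from caliper length and width (mm)."""
    if length < 0 or width < 0:
        raise ValueError("caliper dimensions must be non-negative")
    return length * width**2 / 2.0


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for reported percents)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class GrowthMeasurement:
    """One caliper reading; width > length is swapped with a warning."""

    mouse_id: str
    day: int
    length: float
    width: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("measurement day must be >= 0")
        if self.width > self.length:
            logger.warning(
                "measurement %s day %d: width %.1f > length %.1f, swapping",
                self.mouse_id, self.day, self.width, self.length,
            )
            self.length, self.width = self.width, self.length

    @property
    def volume(self) -> float:
        return tumor_volume(self.length, self.width)


@dataclass
class GrowthCurve:
    """Time-ordered caliper series for one mouse."""

    mouse_id: str
    arm: str
    measurements: list[GrowthMeasurement]
    treatment_start: int = 0

    def __post_init__(self) -> None:
        days = [m.day for m in self.measurements]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"mouse {self.mouse_id}: days must be strictly increasing")

    @property
    def days(self) -> np.ndarray:
        return np.array([m.day for m in self.measurements])

    @property
    def volumes(self) -> np.ndarray:
        return np.array([m.volume for m in self.measurements])


@dataclass
class ResponseCall:
    mouse_id: str
    response: str  # CR | DR | SR | NR
    baseline: float
    nadir: float
    final: float


@dataclass
class SurvivalRecord:
    mouse_id: str
    time: float  # days
    event: int  # 1 = endpoint reached, 0 = censored
    arm: str = ""

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (endpoint)")


@dataclass
class QpcrRecord:
    """Per-sample Ct values for a target gene and the Tbp housekeeping gene."""

    sample_id: str
    condition: str
    gene: str
    ct: float
    tbp_ct: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ct) and np.isfinite(self.tbp_ct)):
            raise ValueError("Ct values must be finite")
        if self.ct <= 0 or self.tbp_ct <= 0:
            raise ValueError("Ct values must be > 0")


def percent_inhibition(
    treated_final: Sequence[float],
    control_final: Sequence[float],
    treated_baseline: Sequence[float] | None = None,
    control_baseline: Sequence[float] | None = None,
    mode: str = "final",
) -> float:
    """Tumor-volume inhibition of a treated arm versus control, in percent.

    Default ``mode="final"``: 100 × (1 − mean(treated)/mean(control)) on
    final volumes, reported to the nearest integer percent.  ``mode="delta"``
    uses mean volume change from baseline instead (requires baselines).
    """
    t = np.asarray(treated_final, dtype=float)
    c = np.asarray(control_final, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both volume lists must be non-empty")
    if mode == "delta":
        if treated_baseline is None or control_baseline is None:
            raise ValueError("delta mode requires baseline volumes")
        t = t - np.asarray(treated_baseline, dtype=float)
        c = c - np.asarray(control_baseline, dtype=float)
    elif mode != "final":
        raise ValueError(f"unknown percent_inhibition mode {mode!r}")
    if c.mean() == 0:
        raise ValueError("mean control volume is zero")
    return round_half_away(100.0 * (1.0 - t.mean() / c.mean()))


def percent_shrinkage(baseline: float, final: float) -> float:
    """Percent volume change from the starting size (negative = growth)."""
    if baseline <= 0:
        raise ValueError("baseline volume must be > 0")
    return 100.0 * (baseline - final) / baseline


def classify_response(
    curve: GrowthCurve,
    cr_threshold: float = 0.0,
    response_fraction: float = 0.8,
) -> ResponseCall:
    """Classify one growth curve as CR, DR, SR or NR.

    Rules applied to the on-treatment portion of the curve (from
    ``treatment_start``): CR if final ≤ ``cr_threshold``; else DR if final
    < baseline; else SR if the nadir dipped under ``response_fraction`` ×
    baseline before final progression past baseline; else NR.
    """
    on_treatment = [m for m in curve.measurements if m.day >= curve.treatment_start]
    if len(on_treatment) < 2:
        raise ValueError(f"mouse {curve.mouse_id}: need >= 2 on-treatment time points")
    volumes = np.array([m.volume for m in on_treatment])
    baseline = volumes[0]
    if baseline <= 0:
        raise ValueError(f"mouse {curve.mouse_id}: baseline volume must be > 0")
    nadir = float(volumes[1:].min())
    final = float(volumes[-1])
    if final <= cr_threshold:
        response = "CR"
    elif final < baseline:
        response = "DR"
    elif nadir < response_fraction * baseline:
        response = "SR"
    else:
        response = "NR"
    return ResponseCall(curve.mouse_id, response, float(baseline), nadir, final)


def summarize_responses(calls: Iterable[ResponseCall]) -> pd.DataFrame:
    """Per-class counts with integer and one-decimal percent renderings."""
    calls = list(calls)
    if not calls:
        raise ValueError("no response calls to summarize")
    total = len(calls)
    counts = {cls: sum(c.response == cls for c in calls) for cls in RESPONSE_CLASSES}
    out = pd.DataFrame(
        {
            "response": RESPONSE_CLASSES,
            "count": [counts[c] for c in RESPONSE_CLASSES],
            "total": total,
        }
    )
    out["percent"] = 100.0 * out["count"] / total
    out["percent_int"] = [round_half_away(p) for p in out["percent"]]
    out["percent_1dp"] = [round_half_away(p, 1) for p in out["percent"]]
    return out.set_index("response")


def km_estimator(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate as a (time, survival) step table.

    Right-censoring is handled; the table starts at S(0) = 1 and has one
    row per distinct observed time.
    """
    if not records:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit([r.time for r in records], [r.event for r in records])
    sf = kmf.survival_function_
    out = sf.reset_index()
    out.columns = ["time", "survival"]
    if out.loc[0, "time"] != 0.0:
        out = pd.concat(
            [pd.DataFrame({"time": [0.0], "survival": [1.0]}), out], ignore_index=True
        )
    return out


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """One-degree-of-freedom log-rank (Mantel–Cox) test: (chi², p).

    By convention, two groups with no events at all give (0, 1).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in group_a) and not any(r.event for r in group_b):
        return 0.0, 1.0
    res = _ll_logrank(
        [r.time for r in group_a],
        [r.time for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return float(res.test_statistic), float(res.p_value)


def ddct_log2fc(sample: QpcrRecord, reference: QpcrRecord) -> float:
    """qPCR log2 fold change of sample vs reference after Tbp normalization.

    ΔCt = Ct(target) − Ct(Tbp) per sample; the returned value is
    −ΔΔCt = −(ΔCt_sample − ΔCt_reference), i.e. the log2 fold change.
    """
    d_sample = sample.ct - sample.tbp_ct
    d_reference = reference.ct - reference.tbp_ct
    return -(d_sample - d_reference)


# ---------------------------------------------------------------------------
# file I/O


def read_growth_log(path: str | Path) -> list[GrowthCurve]:
    """Growth log CSV (mouse_id, arm, day, length_mm, width_mm) → curves."""
    df = pd.read_csv(path, dtype={"mouse_id": str, "arm": str})
    required = {"mouse_id", "arm", "day", "length_mm", "width_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth log {path} lacks columns {sorted(missing)}")
    curves = []
    for (mouse, arm), sub in df.sort_values("day").groupby(["mouse_id", "arm"], sort=True):
        measurements = [
            GrowthMeasurement(mouse, int(r.day), float(r.length_mm), float(r.width_mm))
            for r in sub.itertuples()
        ]
        curves.append(GrowthCurve(mouse, arm, measurements))
    return curves


def write_growth_log(curves: Sequence[GrowthCurve], path: str | Path) -> None:
    rows = [
        {
            "mouse_id": c.mouse_id,
            "arm": c.arm,
            "day": m.day,
            "length_mm": m.length,
            "width_mm": m.width,
        }
        for c in curves
        for m in c.measurements
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Survival CSV (mouse_id, arm, time_days, event) → records."""
    df = pd.read_csv(path, dtype={"mouse_id": str, "arm": str})
    required = {"mouse_id", "arm", "time_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival file {path} lacks columns {sorted(missing)}")
    return [
        SurvivalRecord(r.mouse_id, float(r.time_days), int(r.event), r.arm)
        for r in df.itertuples()
    ]


def write_survival(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "mouse_id": [r.mouse_id for r in records],
            "arm": [r.arm for r in records],
            "time_days": [r.time for r in records],
            "event": [r.event for r in records],
        }
    ).to_csv(path, index=False)


def read_qpcr(path: str | Path) -> list[QpcrRecord]:
    """qPCR CSV (sample, condition, gene, ct, tbp_ct) → records."""
    df = pd.read_csv(path, dtype={"sample": str, "condition": str, "gene": str})
    required = {"sample", "condition", "gene", "ct", "tbp_ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR file {path} lacks columns {sorted(missing)}")
    return [
        QpcrRecord(r.sample, r.condition, r.gene, float(r.ct), float(r.tbp_ct))
        for r in df.itertuples()
    ]
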