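"""Calibration, single-marker (QAMS) quantitation, and method validation.

The single-marker workflow quantifies several analytes against one
reference standard.  Each analyte k gets a relative correction factor
f = F_s / F_k, the ratio of the reference calibration slope to its own
slope; content is then computed from the reference curve alone.  Peaks for
analytes without standards are located by relative retention time (RRT).

Validation helpers compute spike recoveries, relative standard deviations
(RSD, sample standard deviation over mean), and durability summaries of
correction factors and RRTs across instrument conditions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "RCFTable",
    "SamplePrep",
    "PeakMeasurement",
    "BatchQuantResult",
    "ValidationReport",
    "serial_dilution_levels",
    "fit_calibration",
    "fit_calibration_table",
    "compute_rcf",
    "compute_rcf_table",
    "locate_by_rrt",
    "esm_content",
    "qams_content",
    "relative_error",
    "recovery",
    "rsd",
    "validation_summary",
    "quantify_batches",
]


class RangeWarning(UserWarning):
    """Concentration outside the validated linear range."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted line ``area = slope * conc + intercept`` for one analyte."""

    analyte: str
    slope: float
    intercept: float
    r2: float
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"{self.analyte}: slope must be positive")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"{self.analyte}: r2 must lie in [0, 1]")
        if self.range_low >= self.range_high:
            raise ValueError(f"{self.analyte}: empty linear range")

    def concentration(self, area: float) -> float:
        """Invert the line: concentration (ug/ml) from a peak area."""
        return (area - self.intercept) / self.slope


@dataclass
class RCFTable:
    """Relative correction factors and RRTs against a reference analyte."""

    reference: str
    factors: dict[str, float]
    rrts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.factors.setdefault(self.reference, 1.0)
        if not math.isclose(self.factors[self.reference], 1.0):
            raise ValueError("reference correction factor must be 1")
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("correction factors must be positive")
        if any(r <= 0 for r in self.rrts.values()):
            raise ValueError("relative retention times must be positive")


@dataclass(frozen=True)
class SamplePrep:
    """Sample preparation parameters: weighed mass, final volume, dilution."""

    mass: float  # g
    volume: float  # ml
    dilution: float = 1.0
    purity: float = 1.0  # mass fraction of standard, applied only on request

    def __post_init__(self) -> None:
        if min(self.mass, self.volume, self.dilution) <= 0:
            raise ValueError("mass, volume and dilution must be positive")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must lie in (0, 1]")


@dataclass(frozen=True)
class PeakMeasurement:
    analyte: str
    rt: float  # minutes
    area: float

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError("retention time must be positive")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


@dataclass
class BatchQuantResult:
    """Per-batch contents by external standard and single-marker methods."""

    batch_id: str
    w_esm: dict[str, float]
    w_qams: dict[str, float]
    re_pct: dict[str, float]


@dataclass
class ValidationReport:
    precision_rsd: dict[str, float]
    repeatability_rsd: dict[str, float]
    stability_rsd: dict[str, float]
    recovery_rows: dict[str, list[tuple[float, float, float, float]]]
    recovery_mean: dict[str, float]
    recovery_rsd: dict[str, float]
    durability: dict[str, dict[str, dict[str, float]]]


def serial_dilution_levels(top: float, factor: float, n: int) -> list[float]:
    """Descending geometric dilution series: ``top / factor**i`` for i < n."""
    if top <= 0:
        raise ValueError("top concentration must be positive")
    if factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if n < 1:
        raise ValueError("need at least one level")
    return [top / factor**i for i in range(n)]


def fit_calibration(
    points: Iterable[tuple[float, float]],
    analyte: str = "",
) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, area) points.

    r2 is the squared Pearson correlation; the linear range is the span of
    the supplied concentrations.
    """
    pts = list(points)
    conc = np.asarray([p[0] for p in pts], dtype=float)
    area = np.asarray([p[1] for p in pts], dtype=float)
    if len(pts) < 2 or np.ptp(conc) == 0:
        raise ValueError("need at least two distinct concentration levels")
    res = stats.linregress(conc, area)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        range_low=float(conc.min()),
        range_high=float(conc.max()),
    )


def fit_calibration_table(table: pd.DataFrame) -> dict[str, CalibrationCurve]:
    """Fit one curve per analyte from a long table.

    Expects columns ``analyte, conc_ug_ml, area``.
    """
    required = {"analyte", "conc_ug_ml", "area"}
    if not required <= set(table.columns):
        raise ValueError(f"calibration table needs columns {sorted(required)}")
    return {
        str(analyte): fit_calibration(
            zip(group["conc_ug_ml"], group["area"]), analyte=str(analyte)
        )
        for analyte, group in table.groupby("analyte", sort=False)
    }


def compute_rcf(reference: CalibrationCurve, analyte: CalibrationCurve) -> float:
    """Relative correction factor f = F_s / F_k (slope-ratio method)."""
    if reference.slope <= 0 or analyte.slope <= 0:
        raise ValueError("calibration slopes must be positive")
    return reference.slope / analyte.slope


def compute_rcf_table(
    curves: Mapping[str, CalibrationCurve],
    reference: str,
    rrts: Mapping[str, float] | None = None,
) -> RCFTable:
    """Correction factors for every analyte against the chosen reference."""
    if reference not in curves:
        raise ValueError(f"reference analyte {reference!r} has no calibration curve")
    ref = curves[reference]
    factors = {name: compute_rcf(ref, curve) for name, curve in curves.items()}
    return RCFTable(reference=reference, factors=factors, rrts=dict(rrts or {}))


def locate_by_rrt(
    peaks: Sequence[PeakMeasurement],
    reference_rt: float,
    expected_rrt: float,
    tol_pct: float = 3.0,
) -> PeakMeasurement:
    """Pick the peak whose rt / reference_rt best matches ``expected_rrt``.

    Only peaks within ``tol_pct`` percent of the expected ratio qualify;
    exact ties are broken by earlier retention time.
    """
    if reference_rt <= 0:
        raise ValueError("reference retention time must be positive")
    if tol_pct <= 0:
        raise ValueError("tolerance must be positive")
    best: PeakMeasurement | None = None
    best_dev = float("inf")
    for peak in sorted(peaks, key=lambda p: p.rt):
        ratio = peak.rt / reference_rt
        dev_pct = abs(ratio - expected_rrt) / expected_rrt * 100.0
        if dev_pct <= tol_pct and dev_pct < best_dev:
            best_dev = dev_pct
            best = peak
    if best is None:
        raise ValueError(
            f"no peak within {tol_pct}% of expected RRT {expected_rrt}"
        )
    return best


def _content_from_conc(conc: float, prep: SamplePrep, apply_purity: bool) -> float:
    """Convert a solution concentration (ug/ml) into a w/w percentage."""
    w = conc * prep.volume * prep.dilution / (prep.mass * 1e6) * 100.0
    if apply_purity:
        w /= prep.purity
    return w


def esm_content(
    area: float,
    curve: CalibrationCurve,
    prep: SamplePrep,
    apply_purity: bool = False,
) -> float:
    """External-standard content (w/w %) from a peak area.

    The area is inverted through the analyte's own calibration line.
    Concentrations outside the validated linear range emit a
    :class:`RangeWarning`; negative back-calculated concentrations raise.
    """
    if area < 0:
        raise ValueError("peak area must be non-negative")
    conc = curve.concentration(area)
    if conc < 0:
        raise ValueError(
            f"{curve.analyte}: back-calculated concentration is negative"
        )
    if not curve.range_low <= conc <= curve.range_high:
        warnings.warn(
            f"{curve.analyte}: concentration {conc:.4g} ug/ml outside linear "
            f"range [{curve.range_low:.4g}, {curve.range_high:.4g}]",
            RangeWarning,
            stacklevel=2,
        )
    return _content_from_conc(conc, prep, apply_purity)


def qams_content(
    area: float,
    f: float,
    reference_curve: CalibrationCurve,
    prep: SamplePrep,
    apply_purity: bool = False,
    subtract_intercept: bool = False,
) -> float:
    """Single-marker content (w/w %) using the reference curve only.

    The default is the pure slope formula ``C = f * area / F_s``;
    ``subtract_intercept=True`` removes the reference intercept first
    (sensitivity-analysis option).
    """
    if f <= 0:
        raise ValueError("correction factor must be positive")
    if area < 0:
        raise ValueError("peak area must be non-negative")
    effective = area - reference_curve.intercept if subtract_intercept else area
    conc = f * effective / reference_curve.slope
    if conc < 0:
        raise ValueError("back-calculated concentration is negative")
    return _content_from_conc(conc, prep, apply_purity)


def relative_error(w_esm: float, w_qams: float) -> float:
    """Relative error (%) of the external-standard vs single-marker result."""
    if w_qams == 0:
        raise ValueError("single-marker content is zero")
    return (w_esm - w_qams) / w_qams * 100.0


def recovery(sample_amt: float, spiked_amt: float, found_amt: float) -> float:
    """Spike recovery (%): (found - sample) / spiked * 100."""
    if spiked_amt <= 0:
        raise ValueError("spiked amount must be positive")
    return (found_amt - sample_amt) / spiked_amt * 100.0


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation (%): sample SD (n-1) over mean, x100."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("RSD needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(arr.std(ddof=1) / mean * 100.0)


def validation_summary(
    precision_runs: Mapping[str, Sequence[float]],
    repeatability_runs: Mapping[str, Sequence[float]],
    stability_runs: Mapping[str, Sequence[float]],
    recovery_rows: Mapping[str, Sequence[tuple[float, float, float]]],
    durability_sets: Mapping[str, Mapping[str, Mapping[str, Sequence[float]]]]
    | None = None,
) -> ValidationReport:
    """Aggregate validation statistics.

    ``precision_runs``/``repeatability_runs``/``stability_runs`` map analyte
    to repeated peak areas.  ``recovery_rows`` maps analyte to
    ``(sample_mg, spiked_mg, found_mg)`` triples.  ``durability_sets`` maps a
    condition-set name (e.g. instruments) to per-analyte ``{"rcf": [...],
    "rrt": [...]}`` series; the report carries their mean and RSD.
    """
    for label, runs in (
        ("precision", precision_runs),
        ("repeatability", repeatability_runs),
        ("stability", stability_runs),
    ):
        if not runs or any(len(v) == 0 for v in runs.values()):
            raise ValueError(f"empty {label} run list")
    rec_rows: dict[str, list[tuple[float, float, float, float]]] = {}
    rec_mean: dict[str, float] = {}
    rec_rsd: dict[str, float] = {}
    for analyte, rows in recovery_rows.items():
        if not rows:
            raise ValueError(f"no recovery rows for {analyte}")
        recs = [recovery(*row) for row in rows]
        rec_rows[analyte] = [(*row, r) for row, r in zip(rows, recs)]
        rec_mean[analyte] = float(np.mean(recs))
        rec_rsd[analyte] = rsd(recs)
    durability: dict[str, dict[str, dict[str, float]]] = {}
    for set_name, per_analyte in (durability_sets or {}).items():
        durability[set_name] = {}
        for analyte, series in per_analyte.items():
            stats_out: dict[str, float] = {}
            for quantity, values in series.items():
                stats_out[f"{quantity}_mean"] = float(np.mean(values))
                stats_out[f"{quantity}_rsd"] = rsd(values)
            durability[set_name][analyte] = stats_out
    return ValidationReport(
        precision_rsd={a: rsd(v) for a, v in precision_runs.items()},
        repeatability_rsd={a: rsd(v) for a, v in repeatability_runs.items()},
        stability_rsd={a: rsd(v) for a, v in stability_runs.items()},
        recovery_rows=rec_rows,
        recovery_mean=rec_mean,
        recovery_rsd=rec_rsd,
        durability=durability,
    )


def quantify_batches(
    peaks: pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    rcf: RCFTable,
    prep: SamplePrep,
    subtract_intercept: bool = False,
) -> list[BatchQuantResult]:
    """Quantify every batch by both methods and report relative errors.

    ``peaks`` is a long table with columns ``batch_id, analyte, rt_min,
    area``.  The reference analyte is quantified by its own curve only.
    """
    required = {"batch_id", "analyte", "area"}
    if not required <= set(peaks.columns):
        raise ValueError(f"batch table needs columns {sorted(required)}")
    results: list[BatchQuantResult] = []
    for batch_id, group in peaks.groupby("batch_id", sort=False):
        w_esm: dict[str, float] = {}
        w_qams: dict[str, float] = {}
        re_pct: dict[str, float] = {}
        for row in group.itertuples(index=False):
            analyte = str(row.analyte)
            area = float(row.area)
            if analyte in curves:
                w_esm[analyte] = esm_content(area, curves[analyte], prep)
            if analyte == rcf.reference:
                continue
            if analyte in rcf.factors:
                w_qams[analyte] = qams_content(
                    area,
                    rcf.factors[analyte],
                    curves[rcf.reference],
                    prep,
                    subtract_intercept=subtract_intercept,
                )
                if analyte in w_esm:
                    re_pct[analyte] = relative_error(w_esm[analyte], w_qams[analyte])
        results.append(
            BatchQuantResult(
                batch_id=str(batch_id), w_esm=w_esm, w_qams=w_qams, re_pct=re_pct
            )
        )
    return results


def batch_results_frame(results: Sequence[BatchQuantResult]) -> pd.DataFrame:
    """Flatten batch results into a tidy frame."""
    rows = []
    for res in results:
        for analyte in sorted(set(res.w_esm) | set(res.w_qams)):
            rows.append(
                {
                    "batch_id": res.batch_id,
                    "analyte": analyte,
                    "w_esm_pct": res.w_esm.get(analyte),
                    "w_qams_pct": res.w_qams.get(analyte),
                    "re_pct": res.re_pct.get(analyte),
                }
            )
    return pd.DataFrame(rows)
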