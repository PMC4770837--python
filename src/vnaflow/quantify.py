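"""Isotope-dilution calibration and quantitation with in-batch blank subtraction.

Quantitation follows the standard isotope-dilution scheme: the response ratio
(analyte quant-ion area / ISTD area) is regressed on the known amount ratio
(native mass / ISTD mass) over the calibration levels; unknowns are
back-calculated through the fitted line and converted to urine concentration
via the 500 pg ISTD spike and 2 mL sample volume.

Each batch carries two DCM blanks (first and last plate wells). The mean of
their calculated concentrations is subtracted from every other result in the
batch; the blanks themselves keep their raw values so run-rejection rules can
be applied to them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .core import (
    AnalytePanel,
    BatchError,
    InjectionRecord,
    MethodConstants,
    PlateBatch,
    Role,
)


class CalibrationError(Exception):
    """Calibration could not be fitted or was rejected."""


class Weighting(str, Enum):
    """Calibration weighting scheme. ``1/x^2`` (inverse-variance for
    proportional noise) is the default for curves spanning more than two
    orders of magnitude in concentration."""

    NONE = "none"
    ONE_OVER_X = "1/x"
    ONE_OVER_X2 = "1/x^2"


def _weights(x: np.ndarray, weighting: Weighting) -> np.ndarray:
    if weighting is Weighting.NONE:
        return np.ones_like(x)
    if np.any(x <= 0):
        raise CalibrationError(
            f"{weighting.value} weighting requires strictly positive amount ratios"
        )
    if weighting is Weighting.ONE_OVER_X:
        return 1.0 / x
    return 1.0 / x**2


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted response-ratio vs amount-ratio line for one analyte.

    ``level_residuals`` maps each nominal amount ratio to the relative error
    (%) of the back-calculated level mean — the standard per-level accuracy
    diagnostic for an accepted curve.
    """

    analyte: str
    slope: float
    intercept: float
    weighting: Weighting
    r_squared: float
    level_residuals: Mapping[float, float]
    n_points: int

    def back_calculate(self, response_ratio: float) -> float:
        """Invert the curve: response ratio -> amount ratio."""
        return (response_ratio - self.intercept) / self.slope


@dataclass(frozen=True)
class QuantResult:
    """Quantitation outcome for one (sample, analyte) injection."""

    sample_id: str
    well: str
    analyte: str
    injection_index: int
    role: Role
    quantifiable: bool
    response_ratio: Optional[float]
    raw_conc_pg_ml: Optional[float]
    blank_sub_conc_pg_ml: Optional[float] = None
    below_lod: bool = False


def response_ratio(record: InjectionRecord) -> Optional[float]:
    """Analyte/ISTD area ratio; ``None`` marks an unquantifiable injection
    (lost internal standard), consumed downstream by the QA engine."""
    if record.istd_area == 0:
        return None
    return record.quant_area / record.istd_area


def fit_calibration(
    records: Sequence[InjectionRecord],
    weighting: Weighting | str = Weighting.ONE_OVER_X2,
) -> CalibrationCurve:
    """Fit the weighted least-squares calibration line for one analyte.

    Requires at least three distinct calibrant levels with computable
    response ratios. The fit is plain WLS of response ratio on amount ratio;
    r-squared is reported on the weighted fit. A non-positive slope rejects
    the curve.
    """
    weighting = Weighting(weighting)
    pts = [
        (r.calibrant_amount_ratio, response_ratio(r))
        for r in records
        if r.role is Role.CALIBRANT
    ]
    pts = [(x, y) for x, y in pts if x is not None and y is not None]
    if not pts:
        raise CalibrationError("no calibrant records with valid response ratios")
    analytes = {r.analyte for r in records}
    if len(analytes) != 1:
        raise CalibrationError(f"calibrant records span multiple analytes: {sorted(analytes)}")
    (analyte,) = analytes

    x = np.asarray([p[0] for p in pts], dtype=float)
    y = np.asarray([p[1] for p in pts], dtype=float)
    levels = np.unique(x)
    if levels.size < 3:
        raise CalibrationError(
            f"{analyte}: need >= 3 distinct calibrant levels, got {levels.size}"
        )

    w = _weights(x, weighting)
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = res.params
    if slope <= 0:
        raise CalibrationError(
            f"{analyte}: rejected curve, non-positive slope {slope:.4g}"
        )

    level_residuals: dict[float, float] = {}
    for lvl in levels:
        mean_y = float(y[x == lvl].mean())
        back = (mean_y - intercept) / slope
        level_residuals[float(lvl)] = (back - lvl) / lvl * 100.0 if lvl != 0 else float("nan")

    return CalibrationCurve(
        analyte=analyte,
        slope=float(slope),
        intercept=float(intercept),
        weighting=weighting,
        r_squared=float(res.rsquared),
        level_residuals=level_residuals,
        n_points=len(pts),
    )


def quantitate(
    record: InjectionRecord,
    curve: CalibrationCurve,
    constants: MethodConstants,
) -> QuantResult:
    """Back-calculate one injection through the calibration curve.

    raw concentration (pg/mL) = (response ratio - intercept) / slope
    x ISTD mass / sample volume x dilution factor.
    """
    rr = response_ratio(record)
    if rr is None:
        return QuantResult(
            sample_id=record.sample_id,
            well=record.well,
            analyte=record.analyte,
            injection_index=record.injection_index,
            role=record.role,
            quantifiable=False,
            response_ratio=None,
            raw_conc_pg_ml=None,
        )
    amount_ratio = curve.back_calculate(rr)
    conc = constants.amount_ratio_to_conc(amount_ratio, record.dilution_factor)
    return QuantResult(
        sample_id=record.sample_id,
        well=record.well,
        analyte=record.analyte,
        injection_index=record.injection_index,
        role=record.role,
        quantifiable=True,
        response_ratio=rr,
        raw_conc_pg_ml=conc,
    )


def blank_subtract(
    results: Sequence[QuantResult],
    panel: Optional[AnalytePanel] = None,
) -> list[QuantResult]:
    """Apply in-batch DCM-blank subtraction to one batch of results.

    For each analyte the mean raw concentration of the two DCM blanks (first
    and last plate wells) is subtracted from every other result. Blanks keep
    their raw values (``blank_sub_conc = raw_conc``) so the run-rejection
    check still sees the uncorrected background. Negative corrected values
    are reported as-is and flagged below the LOD, never clamped, so batch
    statistics stay unbiased.
    """
    panel = panel or AnalytePanel.default()
    out: list[QuantResult] = []
    by_analyte: dict[str, list[QuantResult]] = {}
    for r in results:
        by_analyte.setdefault(r.analyte, []).append(r)

    for analyte, group in by_analyte.items():
        blanks = [r for r in group if r.role is Role.DCM_BLANK]
        if len(blanks) != 2:
            raise BatchError(
                f"{analyte}: batch must contain exactly 2 DCM blank results, "
                f"found {len(blanks)}; batch cannot be reported"
            )
        if any(not b.quantifiable for b in blanks):
            raise BatchError(f"{analyte}: a DCM blank is unquantifiable")
        blank_mean = float(np.mean([b.raw_conc_pg_ml for b in blanks]))
        lod = panel[analyte].lod_pg_ml if panel.get(analyte) else 0.0
        for r in group:
            if r.role is Role.DCM_BLANK:
                out.append(replace(r, blank_sub_conc_pg_ml=r.raw_conc_pg_ml))
            elif not r.quantifiable:
                out.append(r)
            else:
                corrected = r.raw_conc_pg_ml - blank_mean
                out.append(
                    replace(
                        r,
                        blank_sub_conc_pg_ml=corrected,
                        below_lod=corrected < lod,
                    )
                )
    out.sort(key=lambda r: (r.injection_index, r.analyte))
    return out


def blank_means(results: Sequence[QuantResult]) -> dict[str, float]:
    """Per-analyte mean raw concentration of the two DCM blanks."""
    means: dict[str, float] = {}
    by_analyte: dict[str, list[QuantResult]] = {}
    for r in results:
        if r.role is Role.DCM_BLANK:
            by_analyte.setdefault(r.analyte, []).append(r)
    for analyte, blanks in by_analyte.items():
        if len(blanks) != 2:
            raise BatchError(f"{analyte}: expected 2 DCM blanks, found {len(blanks)}")
        means[analyte] = float(np.mean([b.raw_conc_pg_ml for b in blanks]))
    return means


def quantify_batch(
    batch: PlateBatch,
    panel: Optional[AnalytePanel] = None,
    constants: Optional[MethodConstants] = None,
    weighting: Weighting | str = Weighting.ONE_OVER_X2,
) -> tuple[dict[str, CalibrationCurve], list[QuantResult]]:
    """Fit per-analyte curves from the batch's calibrant records, quantitate
    every non-calibrant injection, and blank-subtract.

    Returns ``(curves, results)`` with results ordered by injection index.
    """
    panel = panel or AnalytePanel.default()
    constants = constants or MethodConstants()
    curves: dict[str, CalibrationCurve] = {}
    results: list[QuantResult] = []
    for analyte in panel.names:
        recs = batch.records_for(analyte)
        cal = [r for r in recs if r.role is Role.CALIBRANT]
        curves[analyte] = fit_calibration(cal, weighting)
        for rec in recs:
            if rec.role is Role.CALIBRANT:
                continue
            results.append(quantitate(rec, curves[analyte], constants))
    results = blank_subtract(results, panel)
    return curves, results
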