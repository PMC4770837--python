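"""Method-validation statistics: detection limits, precision, accuracy.

Two detection-limit estimators are provided, matching how such panels are
characterized in practice:

* **3S0** — for analytes with positive blank detections. Per-pool SDs from a
  multi-run study of spiked pools (0/2.5/5/7.5 pg/mL by default) are
  regressed on nominal concentration by ordinary least squares; ``S0`` is
  the intercept (the SD extrapolated to zero concentration) and
  ``LOD = 3 * S0``.
* **CLSI (EP17-style, parametric)** — for analytes with clean blanks.
  ``LoB = mean(blank) + 1.645 * SD(blank)`` and
  ``LoD = LoB + 1.645 * SD(low pools)``.

Precision follows the 6-replicates-x-5-runs design: intra-run CV per run,
inter-run CV as the CV of the run means (n = number of runs). Accuracy is
spike recovery against the mean unspiked baseline, and a second-source
check back-calculates fresh calibrators through the working curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import MethodConstants, VnaflowError
from .quantify import CalibrationCurve


class ValidationError(VnaflowError):
    """Validation computation could not be carried out on the data given."""


def c4_correction(n: int) -> float:
    """Finite-sample unbiasing constant for the sample SD of a normal sample:
    ``E[s] = c4(n) * sigma``. Dividing sample SDs by ``c4(n)`` removes the
    downward bias (about 0.4 % at n = 60) before extrapolating."""
    if n < 2:
        raise ValidationError("c4 requires n >= 2")
    return math.sqrt(2.0 / (n - 1)) * math.exp(
        math.lgamma(n / 2.0) - math.lgamma((n - 1) / 2.0)
    )


@dataclass(frozen=True)
class LODEstimate:
    analyte: str
    method: str  # "three_s0" | "clsi"
    lod: float
    s0: Optional[float] = None
    lob: Optional[float] = None
    n_runs: int = 0

    def __post_init__(self) -> None:
        if not self.lod > 0:
            raise ValidationError(f"{self.analyte}: LOD must be > 0, got {self.lod}")


@dataclass(frozen=True)
class ValidationDesign:
    """Shape of the detection-limit study."""

    pool_concs: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5)
    runs: int = 60
    replicates_per_run: int = 1

    def __post_init__(self) -> None:
        if self.pool_concs[0] != 0.0 or list(self.pool_concs) != sorted(
            set(self.pool_concs)
        ):
            raise ValidationError(
                "pool_concs must be strictly increasing and start at 0"
            )


def lod_3s0_from_sds(
    pool_concs: Sequence[float],
    pool_sds: Sequence[float],
    analyte: str = "",
    n_runs: int = 0,
) -> LODEstimate:
    """3S0 estimate from per-pool SDs taken as given (no resampling, no bias
    correction): OLS of SD on concentration, ``LOD = 3 x intercept``."""
    x = np.asarray(pool_concs, dtype=float)
    y = np.asarray(pool_sds, dtype=float)
    if x.size < 3:
        raise ValidationError("need >= 3 pools for the SD-vs-concentration line")
    coeffs = np.polynomial.polynomial.polyfit(x, y, 1)
    s0 = float(coeffs[0])
    if s0 <= 0:
        raise ValidationError(
            f"{analyte or 'analyte'}: extrapolated S0 is non-positive ({s0:.4g}); "
            "use the CLSI estimator instead"
        )
    return LODEstimate(analyte=analyte, method="three_s0", lod=3.0 * s0, s0=s0, n_runs=n_runs)


def estimate_lod_3s0(
    pool_results: Mapping[float, Sequence[float]],
    analyte: str = "",
    bias_correct: bool = True,
) -> LODEstimate:
    """3S0 detection limit from raw pool measurements.

    ``pool_results`` maps nominal pool concentration (pg/mL) to the measured
    concentrations across runs; at least 3 pools with at least 2 values each
    are required. Per-pool sample SDs are divided by ``c4(n)`` by default so
    the extrapolated intercept is unbiased. A non-positive intercept aborts
    with advice to use the CLSI estimator.
    """
    concs = sorted(pool_results)
    if len(concs) < 3:
        raise ValidationError(f"need >= 3 pools, got {len(concs)}")
    sds = []
    n_min = None
    for c in concs:
        vals = np.asarray(pool_results[c], dtype=float)
        if vals.size < 2:
            raise ValidationError(f"pool {c} pg/mL: need >= 2 values, got {vals.size}")
        sd = float(vals.std(ddof=1))
        if bias_correct:
            sd /= c4_correction(vals.size)
        sds.append(sd)
        n_min = vals.size if n_min is None else min(n_min, vals.size)
    return lod_3s0_from_sds(concs, sds, analyte=analyte, n_runs=int(n_min))


def estimate_lod_clsi(
    blank_values: Sequence[float],
    low_pool_values: Sequence[float] | Mapping[float, Sequence[float]],
    analyte: str = "",
    beta_quantile: float = 1.645,
) -> LODEstimate:
    """Parametric CLSI-style LoB/LoD.

    ``LoB = mean(blanks) + q * SD(blanks)``;
    ``LoD = LoB + q * SD_pooled(low pools)`` with ``q`` the one-sided normal
    quantile (1.645 for 5 % alpha/beta). ``low_pool_values`` may be a flat
    sequence or a mapping pool -> values, in which case the pool SDs are
    pooled by degrees of freedom.
    """
    blanks = np.asarray(blank_values, dtype=float)
    if blanks.size < 2:
        raise ValidationError("need >= 2 blank values")
    if isinstance(low_pool_values, Mapping):
        groups = [np.asarray(v, dtype=float) for v in low_pool_values.values()]
    else:
        groups = [np.asarray(low_pool_values, dtype=float)]
    if any(g.size < 2 for g in groups) or not groups:
        raise ValidationError("need >= 2 values in each low pool")
    dof = sum(g.size - 1 for g in groups)
    pooled_var = sum(g.var(ddof=1) * (g.size - 1) for g in groups) / dof
    sd_low = math.sqrt(pooled_var)

    lob = float(blanks.mean() + beta_quantile * blanks.std(ddof=1))
    lod = lob + beta_quantile * sd_low
    return LODEstimate(
        analyte=analyte,
        method="clsi",
        lod=float(lod),
        lob=float(lob),
        n_runs=int(blanks.size),
    )


@dataclass(frozen=True)
class PrecisionSummary:
    analyte: str
    pool: str
    intra_run_cv_pct: tuple[float, ...]  # one per run
    inter_run_cv_pct: float
    run_means: tuple[float, ...]

    @property
    def mean_intra_run_cv_pct(self) -> float:
        return float(np.mean(self.intra_run_cv_pct))


def _cv_pct(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        raise ValidationError("CV undefined: zero mean")
    return float(values.std(ddof=1) / mean * 100.0)


def precision_summary(
    runs: Mapping[int, Sequence[float]] | pd.DataFrame,
    analyte: str = "",
    pool: str = "",
) -> PrecisionSummary:
    """Intra-run CVs (one per run) and the inter-run CV of the run means.

    Accepts either a mapping run -> replicate values or a DataFrame with
    ``run`` and ``measured_conc_pg_ml`` columns. Needs >= 2 replicates per
    run and >= 2 runs.
    """
    if isinstance(runs, pd.DataFrame):
        runs = {
            int(run): grp["measured_conc_pg_ml"].to_numpy()
            for run, grp in runs.groupby("run")
        }
    if len(runs) < 2:
        raise ValidationError(f"need >= 2 runs, got {len(runs)}")
    intra = []
    means = []
    for run in sorted(runs):
        vals = np.asarray(runs[run], dtype=float)
        if vals.size < 2:
            raise ValidationError(f"run {run}: need >= 2 replicates, got {vals.size}")
        intra.append(_cv_pct(vals))
        means.append(float(vals.mean()))
    inter = _cv_pct(np.asarray(means))
    return PrecisionSummary(
        analyte=analyte,
        pool=pool,
        intra_run_cv_pct=tuple(intra),
        inter_run_cv_pct=inter,
        run_means=tuple(means),
    )


@dataclass(frozen=True)
class AccuracyLevel:
    nominal_spike_pg_ml: float
    mean_recovery_pct: float
    cv_pct: float
    n: int


def accuracy_summary(
    spiked: Mapping[float, Sequence[float]],
    baseline: Sequence[float],
    analyte: str = "",
) -> dict[float, AccuracyLevel]:
    """Spike-recovery accuracy per level.

    Recovery of each spiked measurement is
    ``(measured - mean(baseline)) / nominal x 100``; the summary reports the
    mean and CV of the recoveries at each level (n = 9 in the standard
    triplicate-x-3-day design).
    """
    base = float(np.mean(np.asarray(baseline, dtype=float))) if len(baseline) else 0.0
    out: dict[float, AccuracyLevel] = {}
    for nominal in sorted(spiked):
        if nominal == 0:
            raise ValidationError("nominal spike must be non-zero")
        vals = np.asarray(spiked[nominal], dtype=float)
        if vals.size < 2:
            raise ValidationError(f"level {nominal}: need >= 2 values, got {vals.size}")
        recoveries = (vals - base) / nominal * 100.0
        out[float(nominal)] = AccuracyLevel(
            nominal_spike_pg_ml=float(nominal),
            mean_recovery_pct=float(recoveries.mean()),
            cv_pct=float(recoveries.std(ddof=1) / recoveries.mean() * 100.0),
            n=int(vals.size),
        )
    return out


@dataclass(frozen=True)
class SolutionAccuracyLevel:
    nominal_amount_ratio: float
    accuracy_pct: float
    passed: bool
    n: int


def solution_accuracy_check(
    measurements: Mapping[float, Sequence[float]],
    curve: CalibrationCurve,
    floor_pct: float = 90.0,
) -> dict[float, SolutionAccuracyLevel]:
    """Second-source calibrator verification.

    ``measurements`` maps nominal amount ratio (the 0.5 %/25 %/50 %-of-top
    levels in the standard design) to replicate response ratios of the new
    standards. Each replicate is back-calculated through the working curve;
    accuracy is the mean back-calculated/nominal x 100 per level, checked
    against a configurable floor. Levels with no replicates are an error.
    """
    out: dict[float, SolutionAccuracyLevel] = {}
    if not measurements:
        raise ValidationError("no calibrator levels supplied")
    for nominal in sorted(measurements):
        ratios = list(measurements[nominal])
        if not ratios:
            raise ValidationError(f"level {nominal}: no replicate measurements")
        if nominal <= 0:
            raise ValidationError("nominal amount ratio must be > 0")
        accs = [curve.back_calculate(r) / nominal * 100.0 for r in ratios]
        mean_acc = float(np.mean(accs))
        out[float(nominal)] = SolutionAccuracyLevel(
            nominal_amount_ratio=float(nominal),
            accuracy_pct=mean_acc,
            passed=mean_acc >= floor_pct,
            n=len(ratios),
        )
    return out
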