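"""End-to-end batch orchestration: quantify -> QA -> Westgard QC -> LIMS export.

:func:`run_pipeline` is a pure function of (configuration, inputs, seed):
given a plate map and either a measured peak table or the synthetic-data
generator, it fits the calibration, quantitates and blank-subtracts every
injection, applies the QA rule list and the run-blank rejection, evaluates
batch QCs against the Westgard rule set, and assembles the LIMS import
table. Repeated runs with the same inputs produce identical output bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import io as vio
from .config import MethodConfig
from .core import BatchError, PlateBatch, Role, validate_batch
from .qa import BatchQAReport, evaluate_batch_qa
from .quantify import CalibrationCurve, QuantResult, quantify_batch
from .simulate import batch_truth, default_calibrant_amount_ratios, generate_batch
from .westgard import QCStatus, QCVerdict, evaluate_batch_qc

PathLike = Union[str, Path]


@dataclass(frozen=True)
class PipelineResult:
    """Everything one batch produces."""

    batch: PlateBatch
    curves: Mapping[str, CalibrationCurve]
    results: tuple[QuantResult, ...]
    qa_report: BatchQAReport
    qc_verdicts: Mapping[str, QCVerdict]
    lims: pd.DataFrame
    truth: Optional[pd.DataFrame] = None

    @property
    def accepted(self) -> bool:
        return bool(
            self.qa_report.blank_verdict.accepted
            and all(v.status is not QCStatus.REJECT for v in self.qc_verdicts.values())
        )

    def results_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": r.sample_id,
                "well": r.well,
                "analyte": r.analyte,
                "injection_index": r.injection_index,
                "role": r.role.value,
                "response_ratio": r.response_ratio,
                "raw_conc_pg_ml": r.raw_conc_pg_ml,
                "blank_sub_conc_pg_ml": r.blank_sub_conc_pg_ml,
                "below_lod": r.below_lod,
                "quantifiable": r.quantifiable,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def qa_frame(self) -> pd.DataFrame:
        rows = []
        for rep in self.qa_report.sample_reports:
            for flag in rep.flags:
                rows.append(
                    {
                        "sample_id": rep.sample_id,
                        "analyte": rep.analyte,
                        "rule_id": flag.rule_id.value,
                        "passed": flag.passed,
                        "detail": flag.detail,
                    }
                )
        return pd.DataFrame(rows)

    def qc_frame(self) -> pd.DataFrame:
        rows = []
        for analyte, verdict in self.qc_verdicts.items():
            rows.append(
                {
                    "analyte": analyte,
                    "status": verdict.status.value,
                    "z_qc_low": verdict.z_current.get("qc_low"),
                    "z_qc_high": verdict.z_current.get("qc_high"),
                    "violations": "; ".join(
                        f"{v.rule.value}[{','.join(v.pools)}]" for v in verdict.violations
                    ),
                }
            )
        return pd.DataFrame(rows)

    def recovery_frame(self) -> Optional[pd.DataFrame]:
        """Per-(unknown, analyte) recovery against simulation truth."""
        if self.truth is None:
            return None
        res = self.results_frame()
        merged = res.merge(self.truth, on=["sample_id", "well", "analyte"], how="inner")
        merged = merged[(merged["role_x"] == "unknown") & (merged["true_conc_pg_ml"] > 0)]
        merged = merged.assign(
            recovery_pct=merged["blank_sub_conc_pg_ml"] / merged["true_conc_pg_ml"] * 100.0
        )
        return merged[
            ["sample_id", "well", "analyte", "true_conc_pg_ml",
             "blank_sub_conc_pg_ml", "recovery_pct"]
        ].reset_index(drop=True)


def _qc_values(results: Sequence[QuantResult], analyte: str) -> dict[str, float]:
    values: dict[str, float] = {}
    for pool, role in (("qc_low", Role.QC_LOW), ("qc_high", Role.QC_HIGH)):
        concs = [
            r.blank_sub_conc_pg_ml
            for r in results
            if r.analyte == analyte and r.role is role and r.blank_sub_conc_pg_ml is not None
        ]
        if concs:
            values[pool] = float(np.mean(concs))
    return values


def run_pipeline(
    config: MethodConfig,
    worklist: Union[PathLike, PlateBatch],
    peak_table: Optional[PathLike] = None,
    simulate: bool = False,
    seed: Optional[int] = None,
    outdir: Optional[PathLike] = None,
    qc_history: Optional[Mapping[str, Mapping[str, Sequence[float]]]] = None,
) -> PipelineResult:
    """Run one batch end to end.

    Exactly one of ``peak_table`` (a measured per-injection CSV) or
    ``simulate`` must be supplied; with ``simulate`` the synthetic generator
    provides the peak data (``seed`` overrides the configured simulation
    seed) and the truth table is attached for recovery reporting. With
    ``outdir`` set, the full CSV bundle (sequence, results, QA flags, QC
    verdicts, LIMS import, and truth/recovery when simulated) is written.
    """
    batch = worklist if isinstance(worklist, PlateBatch) else vio.read_worklist(worklist)
    violations = validate_batch(batch, config.panel)
    if violations:
        raise BatchError("worklist: " + "; ".join(violations))

    truth = None
    if simulate:
        if peak_table is not None:
            raise BatchError("give either a peak table or --simulate, not both")
        sim = config.simulation
        if seed is not None:
            sim = replace(sim, seed=seed)
        batch = generate_batch(sim, batch, config.panel, config.constants)
        truth = batch_truth(sim, batch, config.panel)
    else:
        if peak_table is None:
            raise BatchError("a peak table is required unless simulating")
        batch = batch.with_records(vio.read_peak_table(peak_table))

    curves, results = quantify_batch(batch, config.panel, config.constants)
    qa_report = evaluate_batch_qa(
        batch.batch_id, batch.records, results, config.panel,
        config.qa_rules, config.constants,
    )

    qc_verdicts: dict[str, QCVerdict] = {}
    for analyte in config.panel.names:
        values = _qc_values(results, analyte)
        if not values:
            continue
        chars = config.qc_characterizations.get(analyte, {})
        history = (qc_history or {}).get(analyte)
        qc_verdicts[analyte] = evaluate_batch_qc(
            values, chars, config.westgard_rules, history
        )

    lims = vio.export_lims(batch, results, qa_report, qc_verdicts)
    result = PipelineResult(
        batch=batch,
        curves=curves,
        results=tuple(results),
        qa_report=qa_report,
        qc_verdicts=qc_verdicts,
        lims=lims,
        truth=truth,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        entries = vio.worklist_to_sequence(
            batch, default_calibrant_amount_ratios(config.constants)
        )
        vio.write_sequence(entries, outdir / "sequence.csv")
        result.results_frame().to_csv(outdir / "results.csv", index=False)
        result.qa_frame().to_csv(outdir / "qa_flags.csv", index=False)
        result.qc_frame().to_csv(outdir / "qc_verdicts.csv", index=False)
        vio.write_lims(lims, outdir / "lims_import.csv")
        if truth is not None:
            vio.write_truth(truth, outdir / "truth.csv")
            rec = result.recovery_frame()
            if rec is not None:
                rec.to_csv(outdir / "recovery.csv", index=False)
    return result
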