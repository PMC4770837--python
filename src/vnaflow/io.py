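"""File-level plumbing of the batch data flow.

Everything is plain CSV with documented headers: the plate-map worklist
(in), the per-injection peak table (in), the instrument sequence (out), the
quantitation results and QA/QC verdicts (out), and the LIMS import file
(out). Concentrations in the LIMS file are formatted to 3 decimal places so
an export/re-import round trip is bit-exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    BatchError,
    InjectionRecord,
    MethodConstants,
    PlateBatch,
    Role,
    VnaflowError,
    WellAssignment,
)
from .qa import BatchQAReport, Disposition
from .quantify import QuantResult
from .westgard import QCVerdict, QCStatus

PathLike = Union[str, Path]


class WorklistError(VnaflowError):
    """Malformed plate-map worklist; message carries offending line numbers."""


class PeakTableError(VnaflowError):
    """Malformed peak table."""


class SequencingError(VnaflowError):
    """Pipeline stages invoked out of order (e.g. export before QC)."""


WORKLIST_COLUMNS = ("batch_id", "well", "sample_id", "role")

PEAK_TABLE_COLUMNS = (
    "sample_id",
    "well",
    "injection_index",
    "role",
    "analyte",
    "quant_area",
    "confirm_area",
    "istd_area",
    "rt_quant_min",
    "rt_istd_min",
    "calibrant_amount_ratio",
    "dilution_factor",
)

LIMS_COLUMNS = (
    "batch_id",
    "sample_id",
    "well",
    "analyte",
    "conc_pg_ml",
    "below_lod",
    "disposition",
    "reportable",
    "batch_verdict",
    "reject_reason",
)


def read_worklist(path: PathLike) -> PlateBatch:
    """Parse a plate-map CSV into a batch skeleton (no records).

    The file must have columns ``batch_id, well, sample_id, role`` and
    exactly 48 rows for one batch; duplicate wells and unknown role tokens
    are reported with their line numbers.
    """
    path = Path(path)
    errors: list[str] = []
    wells: dict[str, WellAssignment] = {}
    batch_ids: set[str] = set()
    allowed_roles = {r.value for r in Role}

    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(WORKLIST_COLUMNS) - set(reader.fieldnames):
            missing = sorted(set(WORKLIST_COLUMNS) - set(reader.fieldnames or []))
            raise WorklistError(f"{path.name}: missing columns: {', '.join(missing)}")
        n_rows = 0
        for lineno, row in enumerate(reader, start=2):
            n_rows += 1
            well = row["well"].strip()
            role_token = row["role"].strip()
            batch_ids.add(row["batch_id"].strip())
            if role_token not in allowed_roles:
                errors.append(
                    f"line {lineno}: unknown role {role_token!r} "
                    f"(allowed: {', '.join(sorted(allowed_roles))})"
                )
                continue
            if well in wells:
                errors.append(f"line {lineno}: duplicate well {well}")
                continue
            wells[well] = WellAssignment(row["sample_id"].strip(), Role(role_token))
    if n_rows != 48:
        errors.append(f"expected 48 wells, found {n_rows} rows")
    if len(batch_ids) > 1:
        errors.append(f"multiple batch_ids in one worklist: {sorted(batch_ids)}")
    if errors:
        raise WorklistError(f"{path.name}: " + "; ".join(errors))
    return PlateBatch(batch_id=batch_ids.pop(), wells=wells)


def write_worklist(batch: PlateBatch, path: PathLike) -> None:
    rows = [
        {
            "batch_id": batch.batch_id,
            "well": well,
            "sample_id": batch.wells[well].sample_id,
            "role": batch.wells[well].role.value,
        }
        for well in batch.processing_order()
    ]
    pd.DataFrame(rows, columns=list(WORKLIST_COLUMNS)).to_csv(path, index=False)


@dataclass(frozen=True)
class SequenceEntry:
    """One line of the instrument injection sequence."""

    injection_index: int
    vial: str
    sample_id: str
    sample_type: str  # blank | calibrant | qc | unknown
    dilution: float = 1.0
    calibrant_amount_ratio: Optional[float] = None


def worklist_to_sequence(
    batch: PlateBatch,
    calibrant_amount_ratios: Sequence[float],
) -> list[SequenceEntry]:
    """Expand a plate map into the injection sequence.

    Layout: one leading ACN solvent blank, the calibrants in ascending
    order, three ACN purge blanks immediately after the top standard (the
    carryover-prone analytes need them), then the 48 plate wells in
    processing order. Injection indices are contiguous from 1 and sample IDs
    pass through verbatim.
    """
    if not calibrant_amount_ratios:
        raise BatchError("a calibration curve is required: no calibrant levels given")
    levels = sorted(float(x) for x in calibrant_amount_ratios)
    entries: list[SequenceEntry] = []
    idx = 1
    entries.append(SequenceEntry(idx, "ACN1", "ACN_BLANK_LEAD", "blank"))
    idx += 1
    for i, level in enumerate(levels, start=1):
        entries.append(
            SequenceEntry(idx, f"CAL{i}", f"CAL{i}", "calibrant",
                          calibrant_amount_ratio=level)
        )
        idx += 1
    for i in range(1, 4):
        entries.append(SequenceEntry(idx, f"ACN{i + 1}", f"ACN_BLANK_PURGE_{i}", "blank"))
        idx += 1
    type_map = {
        Role.DCM_BLANK: "blank",
        Role.QC_LOW: "qc",
        Role.QC_HIGH: "qc",
        Role.UNKNOWN: "unknown",
    }
    for well in batch.processing_order():
        asg = batch.wells[well]
        entries.append(
            SequenceEntry(idx, well, asg.sample_id, type_map.get(asg.role, "unknown"))
        )
        idx += 1
    return entries


def write_sequence(entries: Sequence[SequenceEntry], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "injection_index": e.injection_index,
                "vial": e.vial,
                "sample_id": e.sample_id,
                "sample_type": e.sample_type,
                "dilution": e.dilution,
                "calibrant_amount_ratio": (
                    "" if e.calibrant_amount_ratio is None else e.calibrant_amount_ratio
                ),
            }
            for e in entries
        ]
    ).to_csv(path, index=False)


def write_peak_table(records: Sequence[InjectionRecord], path: PathLike) -> None:
    rows = []
    for r in sorted(records, key=lambda r: (r.injection_index, r.analyte)):
        rows.append(
            {
                "sample_id": r.sample_id,
                "well": r.well,
                "injection_index": r.injection_index,
                "role": r.role.value,
                "analyte": r.analyte,
                "quant_area": repr(r.quant_area),
                "confirm_area": repr(r.confirm_area),
                "istd_area": repr(r.istd_area),
                "rt_quant_min": repr(r.rt_quant_min),
                "rt_istd_min": repr(r.rt_istd_min),
                "calibrant_amount_ratio": (
                    "" if r.calibrant_amount_ratio is None else repr(r.calibrant_amount_ratio)
                ),
                "dilution_factor": repr(r.dilution_factor),
            }
        )
    pd.DataFrame(rows, columns=list(PEAK_TABLE_COLUMNS)).to_csv(path, index=False)


def read_peak_table(path: PathLike) -> list[InjectionRecord]:
    """Read a per-injection peak table CSV into records; a missing column is
    reported by name."""
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "well": str, "analyte": str},
        float_precision="round_trip",
    )
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableError(f"{path.name}: missing column(s): {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        ratio = getattr(row, "calibrant_amount_ratio")
        ratio = None if pd.isna(ratio) else float(ratio)
        records.append(
            InjectionRecord(
                sample_id=str(row.sample_id),
                well=str(row.well),
                injection_index=int(row.injection_index),
                role=Role(row.role),
                analyte=str(row.analyte),
                quant_area=float(row.quant_area),
                confirm_area=float(row.confirm_area),
                istd_area=float(row.istd_area),
                rt_quant_min=float(row.rt_quant_min),
                rt_istd_min=float(row.rt_istd_min),
                calibrant_amount_ratio=ratio,
                dilution_factor=float(row.dilution_factor),
            )
        )
    return records


def write_truth(truth: pd.DataFrame, path: PathLike) -> None:
    truth.to_csv(path, index=False)


def export_lims(
    batch: PlateBatch,
    results: Sequence[QuantResult],
    qa_report: BatchQAReport,
    qc_verdicts: Optional[dict[str, QCVerdict]],
) -> pd.DataFrame:
    """Build the LIMS import table: one row per unknown (sample, analyte).

    Requires QC evaluation to have run (pass ``qc_verdicts``, possibly empty
    only for a batch already rejected on blanks). A batch rejected by the
    run-blank rule or by Westgard QC exports its rows with the reject marker
    and no reportable concentrations.
    """
    if qc_verdicts is None:
        raise SequencingError("LIMS export requires QC evaluation (run QC first)")

    blank_rejected = not qa_report.blank_verdict.accepted
    qc_rejected = any(v.status is QCStatus.REJECT for v in qc_verdicts.values())
    batch_rejected = blank_rejected or qc_rejected
    if blank_rejected:
        verdict, reason = "reject", qa_report.blank_verdict.reason
    elif qc_rejected:
        rejected = sorted(
            a for a, v in qc_verdicts.items() if v.status is QCStatus.REJECT
        )
        verdict, reason = "reject", "westgard QC rejection: " + ", ".join(rejected)
    else:
        verdict, reason = "accept", ""

    report_by_key = {(r.sample_id, r.analyte): r for r in qa_report.sample_reports}
    rows = []
    for res in sorted(results, key=lambda r: (r.injection_index, r.analyte)):
        if res.role is not Role.UNKNOWN:
            continue
        rep = report_by_key.get((res.sample_id, res.analyte))
        disposition = rep.disposition.value if rep else Disposition.REJECT.value
        reportable = (not batch_rejected) and rep is not None and rep.reportable
        conc = (
            f"{res.blank_sub_conc_pg_ml:.3f}"
            if (reportable and res.blank_sub_conc_pg_ml is not None)
            else ""
        )
        rows.append(
            {
                "batch_id": batch.batch_id,
                "sample_id": res.sample_id,
                "well": res.well,
                "analyte": res.analyte,
                "conc_pg_ml": conc,
                "below_lod": res.below_lod,
                "disposition": disposition,
                "reportable": reportable,
                "batch_verdict": verdict,
                "reject_reason": reason,
            }
        )
    return pd.DataFrame(rows, columns=list(LIMS_COLUMNS))


def write_lims(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False)


def read_lims(path: PathLike) -> pd.DataFrame:
    """Read a LIMS import file back, preserving the fixed-decimal formatting
    (concentrations stay strings so a re-export is bit-exact)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["below_lod"] = df["below_lod"].map({"True": True, "False": False})
    df["reportable"] = df["reportable"].map({"True": True, "False": False})
    return df[list(LIMS_COLUMNS)]
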