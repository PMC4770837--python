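"""Core domain types for urinary volatile-nitrosamine (VNA) batch quantitation.

The laboratory workflow this package models measures six VNAs in urine by
isotope-dilution GC-MS/MS: each 2 mL urine aliquot is spiked with 500 pg of a
deuterated internal standard (ISTD) per analyte, extracted, and injected.
Samples are prepared on 48-well plates (rows A-F x columns 1-8, processed
row-major) whose first and last wells contain dichloromethane (DCM) processed
as samples — the system blanks used for in-batch blank subtraction.

This module holds the panel definition (:class:`Analyte`,
:class:`AnalytePanel`), the method constants, the per-injection measurement
record, and the plate/batch container with its structural validator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence


class VnaflowError(Exception):
    """Base class for all package errors."""


class ConfigError(VnaflowError):
    """Invalid or inconsistent configuration."""


class BatchError(VnaflowError):
    """A batch violates a structural precondition (e.g. missing DCM blank)."""


class OrderingError(VnaflowError):
    """Records were supplied out of injection order where order matters."""


#: Panel analyte names, in elution order.
ANALYTE_NAMES = ("NDMA", "NMEA", "NDEA", "NPIP", "NPYR", "NMOR")

#: Analytes for which small carryover is seen after the top calibration
#: standard; these get carryover in simulation and drive the purge-blank rule.
CARRYOVER_PRONE = frozenset({"NDMA", "NMEA", "NDEA"})

PLATE_ROWS = "ABCDEF"
PLATE_COLUMNS = tuple(range(1, 9))

#: The 48 plate coordinates in processing (row-major) order: A1..A8, B1..B8, ...
PLATE_WELLS = tuple(f"{row}{col}" for row in PLATE_ROWS for col in PLATE_COLUMNS)


class Role(str, Enum):
    """What a vial or well contains."""

    DCM_BLANK = "dcm_blank"
    ACN_BLANK = "acn_blank"
    CALIBRANT = "calibrant"
    QC_LOW = "qc_low"
    QC_HIGH = "qc_high"
    UNKNOWN = "unknown"


#: Roles that occupy physical plate wells (everything except solvent blanks
#: and calibrants, which are injected from separate vials).
PLATE_ROLES = frozenset({Role.DCM_BLANK, Role.QC_LOW, Role.QC_HIGH, Role.UNKNOWN})


@dataclass(frozen=True)
class Analyte:
    """One panel analyte and the per-analyte acceptance settings.

    ``expected_rt_min`` / ``expected_ion_ratio`` are method-configuration
    values (they depend on column and tune state and are re-established per
    instrument); the shipped defaults are plausible placeholders. The
    ``blank_limit_pg_ml`` is the run-rejection ceiling for DCM blanks,
    characterized in routine use from historical blank runs.
    """

    name: str
    istd_name: str
    expected_rt_min: float
    expected_ion_ratio: float
    blank_limit_pg_ml: float
    lod_pg_ml: float
    carryover_prone: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("analyte name must be non-empty")
        if not self.istd_name:
            raise ConfigError(f"analyte {self.name}: missing internal-standard pairing")
        if not self.expected_ion_ratio > 0:
            raise ConfigError(f"analyte {self.name}: expected_ion_ratio must be > 0")
        if not self.blank_limit_pg_ml > 0:
            raise ConfigError(f"analyte {self.name}: blank_limit_pg_ml must be > 0")
        if not self.lod_pg_ml > 0:
            raise ConfigError(f"analyte {self.name}: lod_pg_ml must be > 0")
        if not self.expected_rt_min > 0:
            raise ConfigError(f"analyte {self.name}: expected_rt_min must be > 0")

    @property
    def expected_rt_istd_min(self) -> float:
        """Expected ISTD retention time; deuterated analogues elute slightly early."""
        return self.expected_rt_min - 0.03


# Shipped default panel. LODs are the method's characterized detection limits;
# blank limits default to 2x LOD (placeholder pending local blank
# characterization). RTs and ion ratios are instrument-dependent placeholders.
_DEFAULT_PANEL_ROWS = (
    # name,   istd,        rt,   ion_ratio, lod
    ("NDMA", "NDMA-d6", 5.82, 0.45, 6.54),
    ("NMEA", "NMEA-d3", 6.41, 0.52, 3.64),
    ("NDEA", "NDEA-d10", 6.93, 0.48, 5.02),
    ("NPIP", "NPIP-d10", 8.61, 0.55, 5.08),
    ("NPYR", "NPYR-d8", 9.18, 0.50, 8.15),
    ("NMOR", "NMOR-d8", 9.84, 0.47, 7.84),
)


@dataclass(frozen=True)
class AnalytePanel:
    """The ordered set of analytes measured in every injection."""

    analytes: tuple[Analyte, ...]

    def __post_init__(self) -> None:
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate analyte names in panel")

    def __iter__(self):
        return iter(self.analytes)

    def __len__(self) -> int:
        return len(self.analytes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.analytes)

    def __getitem__(self, name: str) -> Analyte:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(name)

    def get(self, name: str) -> Optional[Analyte]:
        try:
            return self[name]
        except KeyError:
            return None

    @classmethod
    def default(cls) -> "AnalytePanel":
        return cls(
            tuple(
                Analyte(
                    name=name,
                    istd_name=istd,
                    expected_rt_min=rt,
                    expected_ion_ratio=ratio,
                    blank_limit_pg_ml=2.0 * lod,
                    lod_pg_ml=lod,
                    carryover_prone=name in CARRYOVER_PRONE,
                )
                for name, istd, rt, ratio, lod in _DEFAULT_PANEL_ROWS
            )
        )


@dataclass(frozen=True)
class MethodConstants:
    """Fixed method parameters.

    * 2 mL urine aliquots carry 500 pg ISTD per analyte, so an amount ratio of
      ``r`` corresponds to ``r * 500 / 2`` pg/mL in urine.
    * The top calibration standard is 400 ng/mL (solution phase); the nominal
      20x extract concentration (2 mL urine evaporated to ~100 uL) maps
      solution calibrant concentrations onto the urine scale.
    * Samples immediately following an injection above 200 pg/mL are flagged
      for reinjection; duplicate injections must agree within 20 % below
      50 pg/mL and within 10 % at or above it.
    """

    istd_mass_pg: float = 500.0
    sample_volume_ml: float = 2.0
    top_standard_ng_ml: float = 400.0
    extract_concentration_factor: float = 20.0
    carryover_flag_threshold_pg_ml: float = 200.0
    repeatability_low_pct: float = 20.0
    repeatability_high_pct: float = 10.0
    repeatability_cut_pg_ml: float = 50.0

    def __post_init__(self) -> None:
        for name in (
            "istd_mass_pg",
            "sample_volume_ml",
            "top_standard_ng_ml",
            "extract_concentration_factor",
            "carryover_flag_threshold_pg_ml",
            "repeatability_low_pct",
            "repeatability_high_pct",
            "repeatability_cut_pg_ml",
        ):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not self.repeatability_high_pct < self.repeatability_low_pct:
            raise ConfigError(
                "repeatability_high_pct must be below repeatability_low_pct "
                f"(got {self.repeatability_high_pct} >= {self.repeatability_low_pct})"
            )

    @property
    def conc_per_amount_ratio(self) -> float:
        """pg/mL of urine per unit analyte/ISTD amount ratio (default 250)."""
        return self.istd_mass_pg / self.sample_volume_ml

    @property
    def top_standard_amount_ratio(self) -> float:
        """Amount ratio of the top calibration standard.

        The 400 ng/mL solution standard is equivalent, through the nominal
        extract concentration factor, to ``400e3 / 20 = 20000`` pg/mL on the
        urine scale, i.e. an amount ratio of 80 with the default constants.
        """
        urine_equiv_pg_ml = (
            self.top_standard_ng_ml * 1000.0 / self.extract_concentration_factor
        )
        return urine_equiv_pg_ml / self.conc_per_amount_ratio

    def amount_ratio_to_conc(self, amount_ratio: float, dilution: float = 1.0) -> float:
        return amount_ratio * self.conc_per_amount_ratio * dilution

    def conc_to_amount_ratio(self, conc_pg_ml: float) -> float:
        return conc_pg_ml / self.conc_per_amount_ratio


@dataclass(frozen=True)
class InjectionRecord:
    """Measured peak quantities for one analyte in one injection.

    All six analytes of a physical injection share the same
    ``injection_index``; the index is unique per analyte within a batch.
    ``calibrant_amount_ratio`` is the known analyte/ISTD amount ratio and is
    present exactly for calibrant injections.
    """

    sample_id: str
    well: str
    injection_index: int
    role: Role
    analyte: str
    quant_area: float
    confirm_area: float
    istd_area: float
    rt_quant_min: float
    rt_istd_min: float
    calibrant_amount_ratio: Optional[float] = None
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for attr in ("quant_area", "confirm_area", "istd_area"):
            v = getattr(self, attr)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{attr} must be finite and non-negative, got {v!r}")
        if self.injection_index < 1:
            raise ValueError("injection_index is 1-based")
        if (self.role is Role.CALIBRANT) != (self.calibrant_amount_ratio is not None):
            raise ValueError(
                "calibrant_amount_ratio must be present iff role is calibrant "
                f"(sample {self.sample_id}, role {self.role.value})"
            )
        if self.dilution_factor < 1.0:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class WellAssignment:
    sample_id: str
    role: Role


@dataclass(frozen=True)
class PlateBatch:
    """A 48-well plate plus the injection records acquired for it.

    ``wells`` maps plate coordinates to their contents; a structurally valid
    batch has exactly the 48 coordinates of :data:`PLATE_WELLS` with DCM
    blanks in the first and last processing positions. ``records`` may also
    contain calibrant and ACN solvent-blank injections, which live in
    sequence vials (pseudo-wells such as ``CAL1`` or ``ACN1``) rather than
    plate wells.
    """

    batch_id: str
    wells: Mapping[str, WellAssignment]
    records: tuple[InjectionRecord, ...] = ()

    def processing_order(self) -> list[str]:
        """Plate wells in robotic processing (row-major) order."""
        return [w for w in PLATE_WELLS if w in self.wells]

    def records_for(self, analyte: str) -> list[InjectionRecord]:
        recs = [r for r in self.records if r.analyte == analyte]
        recs.sort(key=lambda r: r.injection_index)
        return recs

    def with_records(self, records: Iterable[InjectionRecord]) -> "PlateBatch":
        return PlateBatch(self.batch_id, dict(self.wells), tuple(records))

    def sample_ids(self, role: Optional[Role] = None) -> list[str]:
        order = self.processing_order()
        out = []
        for w in order:
            asg = self.wells[w]
            if role is None or asg.role is role:
                out.append(asg.sample_id)
        return out


def validate_batch(
    batch: PlateBatch, panel: Optional[AnalytePanel] = None
) -> list[str]:
    """Return structural violations of a batch; empty list means well-formed.

    Pure: never raises, never mutates. Checks well count and coordinates,
    DCM-blank placement in the first and last processing positions, that
    plate-role records reference known wells and panel analytes, and that
    injection indices are unique per analyte.
    """
    violations: list[str] = []
    wells = batch.wells
    if len(wells) != 48:
        violations.append(f"expected 48 wells, found {len(wells)}")
    unknown_coords = sorted(set(wells) - set(PLATE_WELLS))
    if unknown_coords:
        violations.append(f"unknown well coordinates: {', '.join(unknown_coords)}")

    order = batch.processing_order()
    if order:
        first, last = order[0], order[-1]
        if wells[first].role is not Role.DCM_BLANK:
            violations.append(
                f"first processing well {first} must be a DCM blank, "
                f"found role {wells[first].role.value}"
            )
        if last != first and wells[last].role is not Role.DCM_BLANK:
            violations.append(
                f"last processing well {last} must be a DCM blank, "
                f"found role {wells[last].role.value}"
            )

    known_analytes = set((panel or AnalytePanel.default()).names)
    seen_index: dict[str, set[int]] = {}
    for rec in batch.records:
        if rec.analyte not in known_analytes:
            violations.append(
                f"record for sample {rec.sample_id} references unknown analyte {rec.analyte}"
            )
        if rec.role in PLATE_ROLES and rec.well not in wells:
            violations.append(
                f"record for sample {rec.sample_id} references unknown well {rec.well}"
            )
        idx = seen_index.setdefault(rec.analyte, set())
        if rec.injection_index in idx:
            violations.append(
                f"duplicate injection_index {rec.injection_index} for analyte {rec.analyte}"
            )
        idx.add(rec.injection_index)
    return violations


def default_layout(
    batch_id: str = "BATCH01", unknown_prefix: str = "U"
) -> PlateBatch:
    """Standard plate skeleton: DCM blanks in A1/F8, the low QC pool early
    (A2), the high QC pool late (F7, so the 200 pg/mL pool never immediately
    precedes an unknown), 44 unknowns in the remaining wells."""
    wells: dict[str, WellAssignment] = {}
    unknown_no = 0
    for i, well in enumerate(PLATE_WELLS):
        if i == 0:
            wells[well] = WellAssignment("DCM_BLANK_1", Role.DCM_BLANK)
        elif i == len(PLATE_WELLS) - 1:
            wells[well] = WellAssignment("DCM_BLANK_2", Role.DCM_BLANK)
        elif i == 1:
            wells[well] = WellAssignment("QC_LOW", Role.QC_LOW)
        elif i == len(PLATE_WELLS) - 2:
            wells[well] = WellAssignment("QC_HIGH", Role.QC_HIGH)
        else:
            unknown_no += 1
            wells[well] = WellAssignment(f"{unknown_prefix}{unknown_no:03d}", Role.UNKNOWN)
    return PlateBatch(batch_id=batch_id, wells=wells)
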