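"""Synthetic injection data with the statistical structure the pipeline assumes.

The generator emulates what the instrument hands the pipeline: per-injection
peak areas for a 48-well batch (DCM blanks first/last, QC pools at 50 and
200 pg/mL, calibrants up to the 400 ng/mL top standard, leading and purge
ACN blanks) and the three method-validation study designs.

Noise model, per injection and analyte: the quant-ion area is

    quant_area = g * x * istd_area * (1 + e_prop) + e_add,  truncated at 0,

with ``x`` the analyte/ISTD amount ratio implied by the true concentration,
``e_prop ~ N(0, proportional_cv)`` and ``e_add ~ N(0, additive_sd_area)``.
The proportional term reproduces the concentration-independent CVs the
method reports; the additive term sets the near-zero concentration noise
floor that determines the detection limit. Between-run variability is a
single per-batch factor ``~ N(1, run_factor_cv)`` applied to everything
processed through sample preparation (plate wells, not solution calibrants),
which is what makes inter-run CVs exceed intra-run CVs. DCM blank wells
carry only the process contamination signal (NDMA at roughly 1.5x its LOD
by default); small carryover after the top standard affects NDMA, NMEA and
NDEA only.

All randomness flows from one seeded Generator keyed by (seed, batch or
design id), so identical configurations reproduce byte-identical tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnalytePanel,
    BatchError,
    ConfigError,
    InjectionRecord,
    MethodConstants,
    OrderingError,
    PlateBatch,
    Role,
)
from .io import SequenceEntry, worklist_to_sequence

VALIDATION_DESIGNS = ("precision_6x5", "accuracy_matrix_3x3x3", "lod_pools_60")


def _default_true_conc() -> dict[str, float]:
    # Plausible urine levels for a mixed smoker/non-smoker population.
    return {"NDMA": 25.0, "NMEA": 8.0, "NDEA": 10.0, "NPIP": 15.0, "NPYR": 30.0, "NMOR": 20.0}


def _default_lod_s0() -> dict[str, float]:
    # Generating near-zero SDs chosen so the characterized detection limits
    # come out at the method's reported values (LOD/3 for the 3S0 analytes,
    # LOD/(2*1.645) for NPYR whose LOD is CLSI-based).
    return {
        "NDMA": 2.18,
        "NMEA": 1.213,
        "NDEA": 1.673,
        "NPIP": 1.693,
        "NPYR": 2.477,
        "NMOR": 2.613,
    }


def _default_blank_contamination() -> dict[str, float]:
    # Five of the six analytes show positive blank detections; NDMA sits at
    # ~1.5x its LOD, the others at modest levels (~0.5x LOD here). NPYR has
    # clean blanks, which is why its detection limit is CLSI-based.
    return {"NDMA": 9.81, "NMEA": 1.82, "NDEA": 2.51, "NPIP": 2.54, "NPYR": 0.0, "NMOR": 3.92}


def _default_baseline() -> dict[str, float]:
    # Endogenous non-smoker urine background: zero except small positive
    # levels for the analytes with ubiquitous environmental sources.
    return {"NDMA": 12.0, "NMEA": 0.0, "NDEA": 0.0, "NPIP": 0.0, "NPYR": 15.0, "NMOR": 10.0}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic-data generator.

    Defaults reproduce the method's documented operating conditions: 5 %
    proportional CV for prep-processed samples (solution calibrants see only
    the 1 % ISTD-corrected instrument repeatability, since they skip sample
    preparation), an integration noise floor of ~1.25 pg/mL
    (``additive_sd_area / istd_area_mean`` x 250 pg/mL per unit ratio) that
    together with calibration-transfer error yields ~2.2 pg/mL total
    near-zero imprecision, NDMA blank contamination at ~1.5x LOD, 0.2 %
    carryover for the carryover-prone analytes, and a 5 % between-run factor.
    """

    seed: int = 0
    true_conc_pg_ml: Mapping[str, float] = field(default_factory=_default_true_conc)
    proportional_cv: float = 0.05
    calibrant_proportional_cv: float = 0.01
    additive_sd_area: float = 1000.0
    istd_area_mean: float = 200_000.0
    istd_area_cv: float = 0.05
    ndma_blank_contamination_pg_ml: float = 9.81  # ~1.5x the NDMA LOD
    blank_contamination_pg_ml: Optional[Mapping[str, float]] = None  # default: see below
    carryover_fraction: float = 0.002
    rt_jitter_sd_min: float = 0.01
    ion_ratio_true: Optional[Mapping[str, float]] = None  # default: panel expectations
    ion_ratio_cv: float = 0.02
    run_factor_cv: float = 0.05
    response_factor: Optional[Mapping[str, float]] = None  # default: 1.0 everywhere
    qc_low_conc_pg_ml: float = 50.0
    qc_high_conc_pg_ml: float = 200.0
    lod_s0_pg_ml: Mapping[str, float] = field(default_factory=_default_lod_s0)
    lod_sd_slope: float = 0.02
    baseline_conc_pg_ml: Mapping[str, float] = field(default_factory=_default_baseline)
    accuracy_bias: Optional[Mapping[str, float]] = None  # recovery multiplier, default 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportional_cv < 1.0):
            raise ConfigError("proportional_cv must be in [0, 1)")
        if not (0.0 <= self.carryover_fraction < 0.05):
            raise ConfigError("carryover_fraction must be in [0, 0.05)")
        for name in ("additive_sd_area", "istd_area_cv", "rt_jitter_sd_min",
                     "ion_ratio_cv", "run_factor_cv", "lod_sd_slope"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.istd_area_mean <= 0:
            raise ConfigError("istd_area_mean must be > 0")

    def noiseless(self) -> "SimConfig":
        """Copy with every stochastic term (and carryover) switched off."""
        return replace(
            self,
            proportional_cv=0.0,
            calibrant_proportional_cv=0.0,
            additive_sd_area=0.0,
            istd_area_cv=0.0,
            rt_jitter_sd_min=0.0,
            ion_ratio_cv=0.0,
            run_factor_cv=0.0,
            carryover_fraction=0.0,
            ndma_blank_contamination_pg_ml=0.0,
            blank_contamination_pg_ml={},
            lod_s0_pg_ml={k: 0.0 for k in self.lod_s0_pg_ml},
            lod_sd_slope=0.0,
        )

    def contamination(self, analyte: str) -> float:
        """Process-contamination level seen in blanks (and hence in every
        processed sample) for an analyte. An explicit map takes precedence;
        otherwise NDMA uses ``ndma_blank_contamination_pg_ml`` and the other
        positive-blank analytes their documented defaults."""
        if self.blank_contamination_pg_ml is not None:
            return float(self.blank_contamination_pg_ml.get(analyte, 0.0))
        if analyte == "NDMA":
            return self.ndma_blank_contamination_pg_ml
        return _default_blank_contamination().get(analyte, 0.0)

    def gain(self, analyte: str) -> float:
        if self.response_factor and analyte in self.response_factor:
            return float(self.response_factor[analyte])
        return 1.0

    def bias(self, analyte: str) -> float:
        if self.accuracy_bias and analyte in self.accuracy_bias:
            return float(self.accuracy_bias[analyte])
        return 1.0

    def additive_conc_sd(self, constants: MethodConstants) -> float:
        """Additive area noise expressed on the concentration scale."""
        return (
            self.additive_sd_area / self.istd_area_mean * constants.conc_per_amount_ratio
        )


def _rng(sim: SimConfig, label: str) -> np.random.Generator:
    return np.random.default_rng([sim.seed, zlib.crc32(label.encode())])


def default_calibrant_amount_ratios(
    constants: Optional[MethodConstants] = None, n_levels: int = 8
) -> list[float]:
    """Default curve: levels log-spaced from 0.5 % to 100 % of the top
    standard, expressed as amount ratios."""
    constants = constants or MethodConstants()
    top = constants.top_standard_amount_ratio
    return [float(x) for x in np.geomspace(0.005 * top, top, n_levels)]


def _true_conc_for(sim: SimConfig, role: Role, analyte: str) -> float:
    if role is Role.ACN_BLANK:
        return 0.0
    if role is Role.DCM_BLANK:
        return sim.contamination(analyte)
    if role is Role.QC_LOW:
        return sim.qc_low_conc_pg_ml + sim.contamination(analyte)
    if role is Role.QC_HIGH:
        return sim.qc_high_conc_pg_ml + sim.contamination(analyte)
    return float(sim.true_conc_pg_ml.get(analyte, 0.0)) + sim.contamination(analyte)


def generate_batch(
    sim: SimConfig,
    layout: PlateBatch,
    panel: Optional[AnalytePanel] = None,
    constants: Optional[MethodConstants] = None,
    calibrant_amount_ratios: Optional[Sequence[float]] = None,
) -> PlateBatch:
    """Simulate the full injection sequence for a plate layout.

    The layout must be structurally valid (use :func:`core.validate_batch`
    first; violations raise :class:`BatchError` here). Produces one record
    per (injection, analyte) for the whole sequence — leading ACN blank,
    calibrants, purge blanks, then the 48 plate wells — and applies
    carryover to the carryover-prone analytes.
    """
    from .core import validate_batch

    panel = panel or AnalytePanel.default()
    constants = constants or MethodConstants()
    violations = validate_batch(layout, panel)
    if violations:
        raise BatchError("layout is not structurally valid: " + "; ".join(violations))
    levels = (
        list(calibrant_amount_ratios)
        if calibrant_amount_ratios is not None
        else default_calibrant_amount_ratios(constants)
    )
    entries = worklist_to_sequence(layout, levels)
    rng = _rng(sim, f"batch:{layout.batch_id}")
    run_factor = float(rng.normal(1.0, sim.run_factor_cv))

    role_by_entry: list[Role] = []
    for e in entries:
        if e.sample_type == "calibrant":
            role_by_entry.append(Role.CALIBRANT)
        elif e.sample_type == "blank" and e.vial in layout.wells:
            role_by_entry.append(Role.DCM_BLANK)
        elif e.sample_type == "blank":
            role_by_entry.append(Role.ACN_BLANK)
        else:
            role_by_entry.append(layout.wells[e.vial].role)

    records: list[InjectionRecord] = []
    for entry, role in zip(entries, role_by_entry):
        for analyte in panel:
            g = sim.gain(analyte.name)
            if role is Role.CALIBRANT:
                x = float(entry.calibrant_amount_ratio)
            else:
                conc = _true_conc_for(sim, role, analyte.name)
                if role in (Role.DCM_BLANK, Role.QC_LOW, Role.QC_HIGH, Role.UNKNOWN):
                    conc *= run_factor
                x = constants.conc_to_amount_ratio(conc)
            istd_area = max(
                float(rng.normal(sim.istd_area_mean, sim.istd_area_mean * sim.istd_area_cv)),
                1.0,
            )
            prop_cv = (
                sim.calibrant_proportional_cv
                if role is Role.CALIBRANT
                else sim.proportional_cv
            )
            e_prop = float(rng.normal(0.0, prop_cv))
            e_add = float(rng.normal(0.0, sim.additive_sd_area))
            quant_area = max(g * x * istd_area * (1.0 + e_prop) + e_add, 0.0)
            ratio_true = (
                float(sim.ion_ratio_true[analyte.name])
                if sim.ion_ratio_true and analyte.name in sim.ion_ratio_true
                else analyte.expected_ion_ratio
            )
            confirm_area = max(
                ratio_true * quant_area * (1.0 + float(rng.normal(0.0, sim.ion_ratio_cv))),
                0.0,
            )
            records.append(
                InjectionRecord(
                    sample_id=entry.sample_id,
                    well=entry.vial,
                    injection_index=entry.injection_index,
                    role=role,
                    analyte=analyte.name,
                    quant_area=quant_area,
                    confirm_area=confirm_area,
                    istd_area=istd_area,
                    rt_quant_min=analyte.expected_rt_min
                    + float(rng.normal(0.0, sim.rt_jitter_sd_min)),
                    rt_istd_min=analyte.expected_rt_istd_min
                    + float(rng.normal(0.0, sim.rt_jitter_sd_min)),
                    calibrant_amount_ratio=(
                        float(entry.calibrant_amount_ratio) if role is Role.CALIBRANT else None
                    ),
                )
            )
    if sim.carryover_fraction > 0:
        records = apply_carryover(records, sim, panel)
    return layout.with_records(records)


def apply_carryover(
    records: Sequence[InjectionRecord],
    sim: SimConfig,
    panel: Optional[AnalytePanel] = None,
) -> list[InjectionRecord]:
    """Add injection-to-injection carryover for the carryover-prone analytes.

    For each such analyte, injection ``i`` gains ``carryover_fraction`` times
    the as-injected quant area of injection ``i - 1`` (the first injection is
    unchanged); other analytes pass through untouched. Records must arrive
    sorted by injection index.
    """
    panel = panel or AnalytePanel.default()
    indices = [r.injection_index for r in records]
    if indices != sorted(indices):
        raise OrderingError("records must be sorted by injection_index")
    prone = {a.name for a in panel if a.carryover_prone}
    by_analyte: dict[str, list[InjectionRecord]] = {}
    for r in records:
        by_analyte.setdefault(r.analyte, []).append(r)

    updated: dict[int, InjectionRecord] = {}
    for analyte, group in by_analyte.items():
        if analyte not in prone:
            continue
        for prev, cur in zip(group, group[1:]):
            updated[id(cur)] = replace(
                cur, quant_area=cur.quant_area + sim.carryover_fraction * prev.quant_area
            )
    return [updated.get(id(r), r) for r in records]


def batch_truth(
    sim: SimConfig,
    layout: PlateBatch,
    panel: Optional[AnalytePanel] = None,
) -> pd.DataFrame:
    """True (blank-subtraction-free, pre-noise) concentrations per plate
    sample and analyte, for recovery reporting against pipeline output."""
    panel = panel or AnalytePanel.default()
    rows = []
    for well in layout.processing_order():
        asg = layout.wells[well]
        for analyte in panel.names:
            if asg.role is Role.DCM_BLANK:
                true = 0.0
            elif asg.role is Role.QC_LOW:
                true = sim.qc_low_conc_pg_ml
            elif asg.role is Role.QC_HIGH:
                true = sim.qc_high_conc_pg_ml
            else:
                true = float(sim.true_conc_pg_ml.get(analyte, 0.0))
            rows.append(
                {
                    "sample_id": asg.sample_id,
                    "well": well,
                    "role": asg.role.value,
                    "analyte": analyte,
                    "true_conc_pg_ml": true,
                }
            )
    return pd.DataFrame(rows)


def generate_validation_study(
    design: str,
    sim: SimConfig,
    panel: Optional[AnalytePanel] = None,
    constants: Optional[MethodConstants] = None,
) -> pd.DataFrame:
    """Generate one of the three method-validation datasets.

    * ``precision_6x5`` — 6 replicates x 5 runs of the 50 and 200 pg/mL QC
      pools, with a per-run factor ~ N(1, run_factor_cv).
    * ``accuracy_matrix_3x3x3`` — spikes of 100/200/300 pg/mL over the
      endogenous baseline, in triplicate on 3 days, plus unspiked baseline
      triplicates per day.
    * ``lod_pools_60`` — 60 runs of the 4 pools (0/2.5/5/7.5 pg/mL) plus a
      DCM blank per run. Pool noise is drawn directly on the concentration
      scale with the linear SD profile ``s0 + lod_sd_slope * conc`` that the
      3S0 extrapolation assumes; over 60 independent runs this SD plays the
      role of the total (intra- plus inter-run) imprecision.

    Values are final quantitated concentrations (pg/mL, blank-subtracted
    scale). Unknown designs raise ``ValueError``.
    """
    panel = panel or AnalytePanel.default()
    constants = constants or MethodConstants()
    rng = _rng(sim, f"study:{design}")
    add_sd = sim.additive_conc_sd(constants)
    rows: list[dict] = []

    if design == "precision_6x5":
        pools = (("qc_low", sim.qc_low_conc_pg_ml), ("qc_high", sim.qc_high_conc_pg_ml))
        for analyte in panel.names:
            for pool, nominal in pools:
                for run in range(1, 6):
                    rf = float(rng.normal(1.0, sim.run_factor_cv))
                    for rep in range(1, 7):
                        measured = nominal * rf * (
                            1.0 + float(rng.normal(0.0, sim.proportional_cv))
                        ) + float(rng.normal(0.0, add_sd))
                        rows.append(
                            {
                                "analyte": analyte,
                                "pool": pool,
                                "nominal_pg_ml": nominal,
                                "run": run,
                                "replicate": rep,
                                "measured_conc_pg_ml": measured,
                            }
                        )
        return pd.DataFrame(rows)

    if design == "accuracy_matrix_3x3x3":
        spikes = (100.0, 200.0, 300.0)
        for analyte in panel.names:
            base = float(sim.baseline_conc_pg_ml.get(analyte, 0.0))
            bias = sim.bias(analyte)
            for day in range(1, 4):
                rf = float(rng.normal(1.0, sim.run_factor_cv))
                for rep in range(1, 4):
                    measured = base * rf * (
                        1.0 + float(rng.normal(0.0, sim.proportional_cv))
                    ) + float(rng.normal(0.0, add_sd))
                    rows.append(
                        {
                            "analyte": analyte,
                            "day": day,
                            "spike_pg_ml": 0.0,
                            "replicate": rep,
                            "measured_conc_pg_ml": measured,
                        }
                    )
                for spike in spikes:
                    for rep in range(1, 4):
                        measured = (base + spike * bias) * rf * (
                            1.0 + float(rng.normal(0.0, sim.proportional_cv))
                        ) + float(rng.normal(0.0, add_sd))
                        rows.append(
                            {
                                "analyte": analyte,
                                "day": day,
                                "spike_pg_ml": spike,
                                "replicate": rep,
                                "measured_conc_pg_ml": measured,
                            }
                        )
        return pd.DataFrame(rows)

    if design == "lod_pools_60":
        pool_concs = (0.0, 2.5, 5.0, 7.5)
        for analyte in panel.names:
            s0 = float(sim.lod_s0_pg_ml.get(analyte, 0.0))
            for run in range(1, 61):
                for conc in pool_concs:
                    sd = s0 + sim.lod_sd_slope * conc
                    rows.append(
                        {
                            "analyte": analyte,
                            "run": run,
                            "role": "pool",
                            "pool_conc_pg_ml": conc,
                            "measured_conc_pg_ml": conc + float(rng.normal(0.0, sd)),
                        }
                    )
                rows.append(
                    {
                        "analyte": analyte,
                        "run": run,
                        "role": "dcm_blank",
                        "pool_conc_pg_ml": np.nan,
                        "measured_conc_pg_ml": sim.contamination(analyte)
                        + float(rng.normal(0.0, s0)),
                    }
                )
        return pd.DataFrame(rows)

    raise ValueError(
        f"unknown validation design {design!r}; expected one of {VALIDATION_DESIGNS}"
    )
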