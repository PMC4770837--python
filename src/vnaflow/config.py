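"""Configuration loading, validation and round-trip serialization.

One JSON or YAML file configures a deployment, with sections ``panel``,
``constants``, ``qa_rules``, ``westgard`` (rule set plus frozen QC-pool
characterizations), and ``simulation``. Absent optional fields take the
documented method defaults; structural problems (missing ISTD pairing,
non-positive thresholds, inverted repeatability tiers) raise
:class:`~vnaflow.core.ConfigError` naming the offender.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .core import (
    Analyte,
    AnalytePanel,
    CARRYOVER_PRONE,
    ConfigError,
    MethodConstants,
)
from .qa import QARuleConfig
from .westgard import (
    Action,
    QCCharacterization,
    RuleName,
    RuleSpec,
    Scope,
    WestgardRuleSet,
)
from .simulate import SimConfig

PathLike = Union[str, Path]


def _default_characterizations() -> dict[str, dict[str, QCCharacterization]]:
    # Placeholder characterization pending a local >=20-run history: nominal
    # pool means, with SDs equal to the pools' total (intra- plus inter-run
    # plus blank-subtraction) imprecision at the method's documented noise
    # levels — what a real multi-run characterization would converge to.
    out: dict[str, dict[str, QCCharacterization]] = {}
    for analyte in AnalytePanel.default().names:
        out[analyte] = {
            "qc_low": QCCharacterization(analyte, "qc_low", 50.0, 4.1, 60),
            "qc_high": QCCharacterization(analyte, "qc_high", 200.0, 14.3, 60),
        }
    return out


@dataclass(frozen=True)
class MethodConfig:
    """Validated bundle of everything the pipeline needs."""

    panel: AnalytePanel
    constants: MethodConstants
    qa_rules: QARuleConfig
    westgard_rules: WestgardRuleSet
    qc_characterizations: Mapping[str, Mapping[str, QCCharacterization]]
    simulation: SimConfig

    @classmethod
    def default(cls) -> "MethodConfig":
        return cls(
            panel=AnalytePanel.default(),
            constants=MethodConstants(),
            qa_rules=QARuleConfig(),
            westgard_rules=WestgardRuleSet.default(),
            qc_characterizations=_default_characterizations(),
            simulation=SimConfig(),
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "panel": [
                {
                    "name": a.name,
                    "istd_name": a.istd_name,
                    "expected_rt_min": a.expected_rt_min,
                    "expected_ion_ratio": a.expected_ion_ratio,
                    "blank_limit_pg_ml": a.blank_limit_pg_ml,
                    "lod_pg_ml": a.lod_pg_ml,
                    "carryover_prone": a.carryover_prone,
                }
                for a in self.panel
            ],
            "constants": asdict(self.constants),
            "qa_rules": {
                "rt_tolerance_min": self.qa_rules.rt_tolerance_min,
                "ion_ratio_tolerance_pct": self.qa_rules.ion_ratio_tolerance_pct,
                "istd_area_min": self.qa_rules.istd_area_min,
                "blank_limits": (
                    dict(self.qa_rules.blank_limits) if self.qa_rules.blank_limits else None
                ),
                "check_leading_acn": self.qa_rules.check_leading_acn,
            },
            "westgard": {
                "rules": {
                    rule.value: {"action": spec.action.value, "scope": spec.scope.value}
                    for rule, spec in self.westgard_rules.rules.items()
                },
                "characterizations": {
                    analyte: {
                        pool: {"mean": c.mean, "sd": c.sd, "n_runs": c.n_runs}
                        for pool, c in pools.items()
                    }
                    for analyte, pools in self.qc_characterizations.items()
                },
            },
            "simulation": {
                "seed": self.simulation.seed,
                "true_conc_pg_ml": dict(self.simulation.true_conc_pg_ml),
                "proportional_cv": self.simulation.proportional_cv,
                "calibrant_proportional_cv": self.simulation.calibrant_proportional_cv,
                "additive_sd_area": self.simulation.additive_sd_area,
                "istd_area_mean": self.simulation.istd_area_mean,
                "istd_area_cv": self.simulation.istd_area_cv,
                "ndma_blank_contamination_pg_ml": self.simulation.ndma_blank_contamination_pg_ml,
                "blank_contamination_pg_ml": (
                    dict(self.simulation.blank_contamination_pg_ml)
                    if self.simulation.blank_contamination_pg_ml is not None
                    else None
                ),
                "carryover_fraction": self.simulation.carryover_fraction,
                "rt_jitter_sd_min": self.simulation.rt_jitter_sd_min,
                "ion_ratio_true": (
                    dict(self.simulation.ion_ratio_true)
                    if self.simulation.ion_ratio_true
                    else None
                ),
                "ion_ratio_cv": self.simulation.ion_ratio_cv,
                "run_factor_cv": self.simulation.run_factor_cv,
                "response_factor": (
                    dict(self.simulation.response_factor)
                    if self.simulation.response_factor
                    else None
                ),
                "qc_low_conc_pg_ml": self.simulation.qc_low_conc_pg_ml,
                "qc_high_conc_pg_ml": self.simulation.qc_high_conc_pg_ml,
                "lod_s0_pg_ml": dict(self.simulation.lod_s0_pg_ml),
                "lod_sd_slope": self.simulation.lod_sd_slope,
                "baseline_conc_pg_ml": dict(self.simulation.baseline_conc_pg_ml),
                "accuracy_bias": (
                    dict(self.simulation.accuracy_bias)
                    if self.simulation.accuracy_bias
                    else None
                ),
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "MethodConfig":
        default = cls.default()

        panel = default.panel
        if "panel" in data and data["panel"] is not None:
            analytes = []
            for entry in data["panel"]:
                if "istd_name" not in entry or not entry["istd_name"]:
                    raise ConfigError(
                        f"analyte {entry.get('name', '?')}: missing internal-standard pairing"
                    )
                name = entry["name"]
                analytes.append(
                    Analyte(
                        name=name,
                        istd_name=entry["istd_name"],
                        expected_rt_min=float(entry["expected_rt_min"]),
                        expected_ion_ratio=float(entry["expected_ion_ratio"]),
                        blank_limit_pg_ml=float(entry["blank_limit_pg_ml"]),
                        lod_pg_ml=float(entry["lod_pg_ml"]),
                        carryover_prone=bool(
                            entry.get("carryover_prone", name in CARRYOVER_PRONE)
                        ),
                    )
                )
            panel = AnalytePanel(tuple(analytes))

        constants = MethodConstants(**{**asdict(default.constants), **data.get("constants", {})})

        qa_in = dict(data.get("qa_rules", {}))
        qa_rules = QARuleConfig(
            rt_tolerance_min=float(qa_in.get("rt_tolerance_min", 0.1)),
            ion_ratio_tolerance_pct=float(qa_in.get("ion_ratio_tolerance_pct", 20.0)),
            istd_area_min=float(qa_in.get("istd_area_min", 50_000.0)),
            blank_limits=qa_in.get("blank_limits"),
            check_leading_acn=bool(qa_in.get("check_leading_acn", True)),
        )

        westgard_in = data.get("westgard", {})
        if "rules" in westgard_in and westgard_in["rules"]:
            rules = {
                RuleName(rule): RuleSpec(Action(spec["action"]), Scope(spec["scope"]))
                for rule, spec in westgard_in["rules"].items()
            }
            westgard_rules = WestgardRuleSet(rules)
        else:
            westgard_rules = default.westgard_rules
        if "characterizations" in westgard_in and westgard_in["characterizations"]:
            chars = {
                analyte: {
                    pool: QCCharacterization(
                        analyte, pool, float(c["mean"]), float(c["sd"]), int(c["n_runs"])
                    )
                    for pool, c in pools.items()
                }
                for analyte, pools in westgard_in["characterizations"].items()
            }
        else:
            chars = default.qc_characterizations

        sim_in = dict(data.get("simulation", {}))
        sim_in = {k: v for k, v in sim_in.items() if v is not None or k in
                  ("ion_ratio_true", "response_factor", "accuracy_bias")}
        simulation = SimConfig(**sim_in) if sim_in else default.simulation

        return cls(panel, constants, qa_rules, westgard_rules, chars, simulation)


def load_config(path: PathLike) -> MethodConfig:
    """Load and validate a configuration file (JSON or YAML by extension)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path.name}: cannot parse: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path.name}: top level must be a mapping")
    return MethodConfig.from_dict(data)


def save_config(config: MethodConfig, path: PathLike) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")
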