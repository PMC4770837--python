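"""Westgard multirule batch-QC engine with QC-pool characterization.

Each batch carries QC pools at 50 and 200 pg/mL. Their quantitated values
are converted to z-scores against a frozen characterization (mean and SD per
pool, established from historical runs) and evaluated against a configurable
multirule family:

* ``1_2s`` — one control beyond +-2 SD (warning by default).
* ``1_3s`` — one control beyond +-3 SD.
* ``2_2s`` — two consecutive controls beyond 2 SD on the same side, either
  the two pools of the current run (across-pool) or the current and previous
  value of one pool (within-pool).
* ``R_4s`` — within the current run, one pool beyond +2 SD and another
  beyond -2 SD (range > 4 SD).
* ``4_1s`` — four consecutive controls beyond 1 SD on the same side.
* ``10_x`` — ten consecutive controls on the same side of the mean.

Every rule can be enabled/disabled, given a warn or reject action, and
scoped within-pool, across-pool, or both, so any plausible "modified"
multirule scheme is expressible in configuration. The default set rejects on
1_3s, 2_2s and R_4s and warns on 1_2s. All excursions are strict
inequalities (a value exactly at 2 SD does not trip a 2s rule).

The characterization is frozen between explicit re-characterizations:
in-flight batches never update it, so slow drift cannot mask itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import ConfigError, VnaflowError


class QCError(VnaflowError):
    """QC characterization or evaluation failure."""


POOLS = ("qc_low", "qc_high")


class RuleName(str, Enum):
    ONE_2S = "1_2s"
    ONE_3S = "1_3s"
    TWO_2S = "2_2s"
    R_4S = "R_4s"
    FOUR_1S = "4_1s"
    TEN_X = "10_x"


class Action(str, Enum):
    WARN = "warn"
    REJECT = "reject"


class Scope(str, Enum):
    WITHIN_POOL = "within_pool"
    ACROSS_POOL = "across_pool"
    BOTH = "both"


@dataclass(frozen=True)
class RuleSpec:
    action: Action = Action.REJECT
    scope: Scope = Scope.BOTH


@dataclass(frozen=True)
class WestgardRuleSet:
    """Enabled rules with their actions and scoping."""

    rules: Mapping[RuleName, RuleSpec]

    def __post_init__(self) -> None:
        if not any(spec.action is Action.REJECT for spec in self.rules.values()):
            raise ConfigError("at least one rejection rule must be enabled")

    @classmethod
    def default(cls) -> "WestgardRuleSet":
        return cls(
            {
                RuleName.ONE_2S: RuleSpec(Action.WARN, Scope.BOTH),
                RuleName.ONE_3S: RuleSpec(Action.REJECT, Scope.BOTH),
                RuleName.TWO_2S: RuleSpec(Action.REJECT, Scope.BOTH),
                RuleName.R_4S: RuleSpec(Action.REJECT, Scope.ACROSS_POOL),
            }
        )


@dataclass(frozen=True)
class QCCharacterization:
    """Frozen mean/SD of one QC pool for one analyte."""

    analyte: str
    pool: str
    mean: float
    sd: float
    n_runs: int

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise QCError(f"{self.analyte}/{self.pool}: characterization SD must be > 0")
        if self.n_runs < 2:
            raise QCError(f"{self.analyte}/{self.pool}: need >= 2 characterization runs")

    def z(self, value: float) -> float:
        return (value - self.mean) / self.sd


def characterize_qc(
    values: Sequence[float], analyte: str, pool: str
) -> QCCharacterization:
    """Sample mean/SD characterization of a QC pool from historical results.

    Fewer than 20 runs triggers a warning (the characterization is usable but
    weak); fewer than 2 values, or a zero SD, is an error since z-scores
    would be undefined.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise QCError(f"{analyte}/{pool}: need >= 2 values to characterize, got {vals.size}")
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        raise QCError(f"{analyte}/{pool}: constant values give SD 0; rules undefined")
    if vals.size < 20:
        warnings.warn(
            f"{analyte}/{pool}: characterization from only {vals.size} runs "
            "(>= 20 recommended)",
            stacklevel=2,
        )
    return QCCharacterization(analyte, pool, float(vals.mean()), sd, int(vals.size))


@dataclass(frozen=True)
class RuleViolation:
    rule: RuleName
    pools: tuple[str, ...]
    z_scores: tuple[float, ...]


class QCStatus(str, Enum):
    ACCEPT = "accept"
    WARN = "warn"
    REJECT = "reject"


@dataclass(frozen=True)
class QCVerdict:
    analyte: str
    status: QCStatus
    violations: tuple[RuleViolation, ...]
    z_current: Mapping[str, float]


def _same_side_beyond(zs: Sequence[float], limit: float) -> bool:
    return all(z > limit for z in zs) or all(z < -limit for z in zs)


def _tail(series: Sequence[float], n: int) -> Optional[list[float]]:
    if len(series) < n:
        return None
    return list(series[-n:])


def _rule_fires(
    rule: RuleName,
    spec: RuleSpec,
    series: Mapping[str, list[float]],
    current: Mapping[str, float],
) -> Optional[RuleViolation]:
    """Evaluate one rule; ``series`` holds each pool's chronological z-scores
    ending with the current batch, ``current`` just the current z per pool."""
    pools = list(current)
    cur_z = [current[p] for p in pools]
    within = spec.scope in (Scope.WITHIN_POOL, Scope.BOTH)
    across = spec.scope in (Scope.ACROSS_POOL, Scope.BOTH)

    if rule is RuleName.ONE_2S or rule is RuleName.ONE_3S:
        limit = 2.0 if rule is RuleName.ONE_2S else 3.0
        hits = [(p, z) for p, z in current.items() if abs(z) > limit]
        if hits:
            return RuleViolation(rule, tuple(p for p, _ in hits), tuple(z for _, z in hits))
        return None

    if rule is RuleName.TWO_2S:
        if across and len(pools) >= 2 and _same_side_beyond(cur_z, 2.0):
            return RuleViolation(rule, tuple(pools), tuple(cur_z))
        if within:
            for p in pools:
                tail = _tail(series[p], 2)
                if tail is not None and _same_side_beyond(tail, 2.0):
                    return RuleViolation(rule, (p, p), tuple(tail))
        return None

    if rule is RuleName.R_4S:
        # Within-run, across pools: opposite excursions beyond +-2 SD.
        if len(pools) >= 2:
            hi, lo = max(cur_z), min(cur_z)
            if hi > 2.0 and lo < -2.0:
                return RuleViolation(rule, tuple(pools), tuple(cur_z))
        return None

    if rule is RuleName.FOUR_1S:
        if within:
            for p in pools:
                tail = _tail(series[p], 4)
                if tail is not None and _same_side_beyond(tail, 1.0):
                    return RuleViolation(rule, (p,) * 4, tuple(tail))
        if across and len(pools) >= 2:
            combined: list[float] = []
            for p in pools:
                tail = _tail(series[p], 2)
                if tail is None:
                    combined = []
                    break
                combined.extend(tail)
            if combined and _same_side_beyond(combined, 1.0):
                return RuleViolation(rule, tuple(pools), tuple(combined))
        return None

    if rule is RuleName.TEN_X:
        if within:
            for p in pools:
                tail = _tail(series[p], 10)
                if tail is not None and _same_side_beyond(tail, 0.0):
                    return RuleViolation(rule, (p,) * 10, tuple(tail))
        if across and len(pools) >= 2:
            combined = []
            for p in pools:
                tail = _tail(series[p], 5)
                if tail is None:
                    combined = []
                    break
                combined.extend(tail)
            if combined and _same_side_beyond(combined, 0.0):
                return RuleViolation(rule, tuple(pools), tuple(combined))
        return None

    raise QCError(f"unknown rule {rule}")


def evaluate_batch_qc(
    current_values: Mapping[str, float],
    characterizations: Mapping[str, QCCharacterization],
    rules: Optional[WestgardRuleSet] = None,
    history: Optional[Mapping[str, Sequence[float]]] = None,
) -> QCVerdict:
    """Evaluate one analyte's batch QCs against the rule set.

    ``current_values`` maps pool name -> this batch's quantitated QC value;
    ``history`` optionally supplies each pool's recent historical values
    (oldest first, raw concentrations) consumed by the streak rules
    (2_2s within-pool, 4_1s, 10_x). A missing characterization for any pool
    present is an error.
    """
    rules = rules or WestgardRuleSet.default()
    history = history or {}
    z_current: dict[str, float] = {}
    series: dict[str, list[float]] = {}
    for pool, value in current_values.items():
        char = characterizations.get(pool)
        if char is None:
            raise QCError(f"missing QC characterization for pool {pool}")
        z_current[pool] = char.z(value)
        series[pool] = [char.z(v) for v in history.get(pool, [])] + [z_current[pool]]

    analyte = next(iter(characterizations.values())).analyte if characterizations else ""
    violations: list[RuleViolation] = []
    reject = False
    warn = False
    for rule, spec in rules.rules.items():
        v = _rule_fires(rule, spec, series, z_current)
        if v is not None:
            violations.append(v)
            if spec.action is Action.REJECT:
                reject = True
            else:
                warn = True
    status = QCStatus.REJECT if reject else (QCStatus.WARN if warn else QCStatus.ACCEPT)
    return QCVerdict(analyte, status, tuple(violations), z_current)


def levey_jennings_table(
    values: Sequence[float], characterization: QCCharacterization
):
    """Run-indexed z-scores for Levey-Jennings plotting (returned as a
    pandas DataFrame; plotting itself is left to the caller)."""
    import pandas as pd

    zs = [characterization.z(v) for v in values]
    return pd.DataFrame(
        {
            "run": np.arange(1, len(values) + 1),
            "analyte": characterization.analyte,
            "pool": characterization.pool,
            "value_pg_ml": list(values),
            "z_score": zs,
        }
    )
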