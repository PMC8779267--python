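"""Structural validation of the three event tables against their invariants."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .simulate import MIN_PARASITISM_CLUTCH
from .design import PARASITOID_EMERGENCE

__all__ = ["ValidationIssue", "validate_subjects", "validate_containers", "validate_clutches", "validate_tables"]


@dataclass
class ValidationIssue:
    table: str
    rule: str
    severity: str            # "error" | "warning"
    rows: list[int]
    message: str


def _issue(table, rule, severity, mask, message) -> ValidationIssue:
    rows = list(mask[mask].index[:50])
    return ValidationIssue(table, rule, severity, rows, message)


def validate_subjects(df: pd.DataFrame, followup_days: float | None = None) -> list[ValidationIssue]:
    issues = []
    bad = df["time_days"] <= 0
    if bad.any():
        issues.append(_issue("subjects", "positive_time", "error", bad, "time_days must be positive"))
    bad = ~df["event"].isin([0, 1])
    if bad.any():
        issues.append(_issue("subjects", "event_binary", "error", bad, "event must be 0 or 1"))
    if followup_days is not None:
        bad = df["time_days"] > followup_days
        if bad.any():
            issues.append(_issue("subjects", "followup_horizon", "error", bad, f"time_days exceeds follow-up horizon {followup_days}"))
    bad = ~df["sex"].isin(["f", "m"])
    if bad.any():
        issues.append(_issue("subjects", "sex_labels", "error", bad, "sex must be 'f' or 'm'"))
    return issues


def validate_containers(df: pd.DataFrame, max_female_days: float | None = None) -> list[ValidationIssue]:
    issues = []
    bad = df["total_eggs"] < 0
    if bad.any():
        issues.append(_issue("containers", "nonneg_eggs", "error", bad, "total_eggs must be >= 0"))
    bad = (df["total_eggs"] == 0) != (df["n_clutches"] == 0)
    if bad.any():
        issues.append(_issue("containers", "zero_iff_no_clutches", "error", bad, "total_eggs = 0 exactly when n_clutches = 0"))
    if max_female_days is not None:
        bad = df["female_days"] > max_female_days + 1e-9
        if bad.any():
            issues.append(_issue("containers", "female_days_bound", "error", bad, f"female_days exceeds {max_female_days}"))
    return issues


def validate_clutches(df: pd.DataFrame) -> list[ValidationIssue]:
    issues = []
    bad = df["n_eggs"] < 1
    if bad.any():
        issues.append(_issue("clutches", "positive_clutch", "error", bad, "n_eggs must be >= 1"))
    bad = (df["n_success"] < 0) | (df["n_success"] > df["n_eggs"])
    if bad.any():
        issues.append(_issue("clutches", "success_bounds", "error", bad, "n_success must lie in [0, n_eggs]"))
    small = (df["outcome_type"] == PARASITOID_EMERGENCE) & (df["n_eggs"] < MIN_PARASITISM_CLUTCH)
    if small.any():
        issues.append(
            _issue(
                "clutches", "min_parasitism_clutch", "warning", small,
                f"parasitoid-exposed clutches should have at least {MIN_PARASITISM_CLUTCH} eggs",
            )
        )
    return issues


def validate_tables(
    subjects: pd.DataFrame | str | Path | None = None,
    containers: pd.DataFrame | str | Path | None = None,
    clutches: pd.DataFrame | str | Path | None = None,
    followup_days: float | None = None,
    max_female_days: float | None = None,
) -> pd.DataFrame:
    """Run every table's invariant checks; returns a tidy issue report."""
    from . import io

    issues: list[ValidationIssue] = []
    if subjects is not None:
        df = subjects if isinstance(subjects, pd.DataFrame) else io.read_subjects(subjects)
        issues += validate_subjects(df, followup_days)
    if containers is not None:
        df = containers if isinstance(containers, pd.DataFrame) else io.read_containers(containers)
        issues += validate_containers(df, max_female_days)
    if clutches is not None:
        df = clutches if isinstance(clutches, pd.DataFrame) else io.read_clutches(clutches)
        issues += validate_clutches(df)
    return pd.DataFrame(
        [
            {"table": i.table, "rule": i.rule, "severity": i.severity,
             "rows": ";".join(map(str, i.rows)), "message": i.message}
            for i in issues
        ],
        columns=["table", "rule", "severity", "rows", "message"],
    )
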