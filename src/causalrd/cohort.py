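"""Cohort ingestion, variable coding, and design-matrix construction.

The analysis cohort is a per-participant table with a binary self-rated
health outcome (1 = poor), a binary labour-market exposure (1 = unemployed),
and categorical confounders coded against an explicit codebook.  All
regressions use reference (treatment-contrast) coding so that coefficient
signs read as effects relative to the declared reference group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CodingError,
    DimensionError,
    DomainError,
    SchemaError,
)

__all__ = [
    "ThresholdRule",
    "Variable",
    "VariableCodebook",
    "CohortTable",
    "DesignMatrix",
    "default_codebook",
    "CONFOUNDER_ORDER",
    "load_cohort",
    "code_bmi",
    "code_thresholded",
    "build_design",
]


@dataclass(frozen=True)
class ThresholdRule:
    """Map a continuous score to an ordered set of levels.

    ``breaks`` are the interior cut points; ``interval_levels`` has one more
    entry than ``breaks`` and names the level of each interval in ascending
    order.  When ``right`` is true a boundary value belongs to the lower
    interval (intervals closed on the right), otherwise to the upper one.
    """

    breaks: tuple[float, ...]
    interval_levels: tuple[str, ...]
    right: bool = False

    def __post_init__(self):
        if len(self.interval_levels) != len(self.breaks) + 1:
            raise SchemaError("threshold rule needs len(breaks)+1 levels")
        if list(self.breaks) != sorted(self.breaks):
            raise SchemaError("threshold breaks must be increasing")

    def apply(self, value: float) -> str:
        idx = 0
        for b in self.breaks:
            if (value > b) if self.right else (value >= b):
                idx += 1
            else:
                break
        return self.interval_levels[idx]


@dataclass(frozen=True)
class Variable:
    """One codebook entry: a categorical study variable."""

    name: str
    levels: tuple[str, ...]
    reference: str
    threshold: ThresholdRule | None = None

    def __post_init__(self):
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"{self.name}: duplicate level labels")
        if self.reference not in self.levels:
            raise SchemaError(f"{self.name}: reference {self.reference!r} not a level")
        if self.threshold is not None:
            unknown = set(self.threshold.interval_levels) - set(self.levels)
            if unknown:
                raise SchemaError(f"{self.name}: threshold levels {unknown} undeclared")

    @property
    def non_reference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)


@dataclass(frozen=True)
class VariableCodebook:
    """Ordered collection of :class:`Variable` entries."""

    variables: tuple[Variable, ...]

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in codebook")

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise SchemaError(f"variable {name!r} not in codebook")

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VariableCodebook":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        variables = []
        for entry in raw["variables"]:
            thr = None
            if "threshold" in entry:
                t = entry["threshold"]
                thr = ThresholdRule(
                    breaks=tuple(float(b) for b in t["breaks"]),
                    interval_levels=tuple(t["levels"]),
                    right=bool(t.get("right", False)),
                )
            variables.append(
                Variable(
                    name=entry["name"],
                    levels=tuple(entry["levels"]),
                    reference=entry["reference"],
                    threshold=thr,
                )
            )
        return cls(tuple(variables))

    def to_yaml(self, path: str | Path) -> None:
        out = {"variables": []}
        for v in self.variables:
            entry: dict = {
                "name": v.name,
                "levels": list(v.levels),
                "reference": v.reference,
            }
            if v.threshold is not None:
                entry["threshold"] = {
                    "breaks": list(v.threshold.breaks),
                    "levels": list(v.threshold.interval_levels),
                    "right": v.threshold.right,
                }
            out["variables"].append(entry)
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=False)


# Confounder declaration order: the order in which the full adjustment set
# is listed throughout (alcohol intake, attachment, social integration, BMI,
# cash margin, education, sex/gender, marital status, previous health,
# occupation, smoking).
CONFOUNDER_ORDER: tuple[str, ...] = (
    "alcohol",
    "avat",
    "avsi",
    "bmi",
    "cash_margin",
    "education",
    "sex",
    "marital",
    "previous_health",
    "occupation",
    "smoking",
)


def default_codebook() -> VariableCodebook:
    """Codebook for the standard study variables.

    Reference groups: low alcohol intake, high attachment (AVAT score >= 10),
    high social integration (AVSI score <= 13), normal BMI, access to a cash
    margin, university education, woman, married/cohabiting, good previous
    health, low-to-medium white-collar occupation, non-smoker.
    """
    return VariableCodebook(
        (
            Variable(
                "alcohol",
                ("low", "high"),
                "low",
                # index < 140 is low intake; 140 itself counts as high
                ThresholdRule((140.0,), ("low", "high"), right=False),
            ),
            Variable(
                "avat",
                ("low", "high"),
                "high",
                # attachment score >= 10 is the reference (high) group
                ThresholdRule((10.0,), ("low", "high"), right=False),
            ),
            Variable(
                "avsi",
                ("high", "low"),
                "high",
                # social-integration score <= 13 is the reference group
                ThresholdRule((13.0,), ("high", "low"), right=True),
            ),
            Variable(
                "bmi",
                ("normal", "overweight", "obese"),
                "normal",
                ThresholdRule((25.0, 30.0), ("normal", "overweight", "obese"), right=False),
            ),
            Variable("cash_margin", ("access", "no_access"), "access"),
            Variable(
                "education",
                ("university", "upper_secondary", "secondary"),
                "university",
            ),
            Variable("sex", ("woman", "man"), "woman"),
            Variable("marital", ("married", "single"), "married"),
            Variable("previous_health", ("good", "poor"), "good"),
            Variable(
                "occupation",
                ("low_medium_white_collar", "high_white_collar", "blue_collar"),
                "low_medium_white_collar",
            ),
            Variable("smoking", ("none", "le10", "gt10"), "none"),
        )
    )


STUDY_COLUMNS = ("outcome", "exposure")


@dataclass
class CohortTable:
    """Validated per-participant analysis table.

    ``data`` holds participant id, 0/1 ``outcome`` (poor self-rated health),
    0/1 ``exposure`` (unemployed), and one string column per codebook
    confounder.  ``n_dropped`` counts rows removed by complete-case
    filtering at load time.
    """

    data: pd.DataFrame
    codebook: VariableCodebook
    n_dropped: int = 0

    def __post_init__(self):
        for col in STUDY_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"cohort table lacks required column {col!r}")
        for col in STUDY_COLUMNS:
            vals = set(self.data[col].unique())
            if not vals <= {0, 1}:
                raise CodingError(f"{col} must be 0/1; saw {sorted(vals - {0, 1})[:5]}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def y(self) -> np.ndarray:
        return self.data["outcome"].to_numpy(dtype=float)

    @property
    def x(self) -> np.ndarray:
        return self.data["exposure"].to_numpy(dtype=float)

    @property
    def n_exposed(self) -> int:
        return int(self.data["exposure"].sum())

    def subset(self, rows: np.ndarray) -> "CohortTable":
        """Row-subset (e.g. a bootstrap resample); keeps codebook, resets drop count."""
        return CohortTable(self.data.iloc[rows].reset_index(drop=True), self.codebook, 0)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def validation_report(self) -> dict:
        """Rows read/kept/dropped plus per-variable level counts."""
        counts = {}
        for v in self.codebook.variables:
            if v.name in self.data.columns:
                vc = self.data[v.name].value_counts()
                counts[v.name] = {lvl: int(vc.get(lvl, 0)) for lvl in v.levels}
        return {
            "rows_read": len(self.data) + self.n_dropped,
            "rows_kept": len(self.data),
            "rows_dropped": self.n_dropped,
            "n_exposed": self.n_exposed,
            "n_unexposed": len(self.data) - self.n_exposed,
            "level_counts": counts,
        }

    def write_validation_report(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.validation_report(), fh, indent=2)


@dataclass(frozen=True)
class DesignMatrix:
    """Numeric regression design with column provenance.

    First column is the intercept; each categorical variable with L levels
    contributes L-1 reference-coded indicator columns; exposure, when
    included, is the final column.
    """

    matrix: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise DimensionError("design matrix shape does not match labels")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def column_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise SchemaError(f"no design column labelled {label!r}") from None


def load_cohort(
    path: str | Path, codebook: VariableCodebook
) -> tuple[CohortTable, int]:
    """Read a cohort CSV, apply complete-case filtering, validate codings.

    Rows missing any study variable (outcome, exposure, or any codebook
    confounder present in the file header) are dropped; the count of dropped
    rows is returned alongside the table and recorded on it.

    Raises
    ------
    SchemaError
        If a required column is absent.
    CodingError
        If a confounder value is not a declared level (reported with
        variable name, row number and offending value).
    """
    confounders = [v.name for v in codebook.variables if v.name in CONFOUNDER_ORDER]
    df = pd.read_csv(path, dtype={name: str for name in confounders})
    required = list(STUDY_COLUMNS) + confounders
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"cohort file lacks required column {col!r}")
    study_cols = [c for c in df.columns if c in required]
    n_read = len(df)
    df = df.dropna(subset=study_cols).reset_index(drop=True)
    n_dropped = n_read - len(df)

    for col in STUDY_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = ~values.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CodingError(
                f"{col}: row {row} has value {df[col].iloc[row]!r}, expected 0/1"
            )
        df[col] = values.astype(int)

    for v in codebook.variables:
        if v.name not in df.columns or v.name in STUDY_COLUMNS:
            continue
        bad = ~df[v.name].isin(v.levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CodingError(
                f"{v.name}: row {row} has undeclared level {df[v.name].iloc[row]!r}"
            )

    table = CohortTable(df, codebook, n_dropped=n_dropped)
    return table, n_dropped


def code_bmi(weight_kg: float, height_m: float) -> str:
    """Categorise body-mass index: <25 normal, [25, 30) overweight, >=30 obese."""
    if weight_kg <= 0 or height_m <= 0:
        raise DomainError("weight and height must be positive")
    bmi = weight_kg / height_m**2
    return default_codebook()["bmi"].threshold.apply(bmi)


def code_thresholded(value: float, variable: str) -> str:
    """Dichotomise a continuous score for AVSI, AVAT or the alcohol index.

    AVSI <= 13 and AVAT >= 10 fall in the reference group; an alcohol index
    below 140 is low intake (reference), 140 and above high.
    """
    if variable not in ("avsi", "avat", "alcohol"):
        raise DomainError(f"no threshold rule for variable {variable!r}")
    return default_codebook()[variable].threshold.apply(value)


def _encode_frame(
    df: pd.DataFrame, codebook: VariableCodebook, variables: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    labels: list[str] = ["intercept"]
    for name in variables:
        var = codebook[name]
        values = df[name].to_numpy()
        for level in var.levels:
            if level == var.reference:
                continue
            cols.append((values == level).astype(float))
            labels.append(f"{name}[{level}]")
    return np.column_stack(cols), labels


def build_design(
    cohort: CohortTable,
    variables: Iterable[str],
    include_exposure: bool = False,
) -> DesignMatrix:
    """Intercept + reference-coded indicators (+ exposure as last column).

    Column order is deterministic: variables in the order given, levels in
    codebook declaration order with the reference level omitted.
    """
    variables = list(variables)
    if len(cohort) == 0:
        raise DimensionError("cannot build a design matrix for an empty cohort")
    for name in variables:
        if name not in cohort.codebook:
            raise SchemaError(f"variable {name!r} not in codebook")
        if name not in cohort.data.columns:
            raise SchemaError(f"variable {name!r} not in cohort table")
    X, labels = _encode_frame(cohort.data, cohort.codebook, variables)
    if include_exposure:
        X = np.column_stack([X, cohort.x])
        labels.append("exposure")
    return DesignMatrix(X, tuple(labels))
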