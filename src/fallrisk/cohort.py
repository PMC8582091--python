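"""Cohort data model: variable registry, derived variables, validation, CSV I/O.

The pipeline's single tabular currency is the :class:`CohortTable`, a thin
wrapper around a pandas DataFrame with one row per participant.  Ten
fall-risk components are registered by default, split into *intrinsic*
factors (disease burden, impairments, cognition, physical function, balance,
fear of falling, affordance perception, gait) and *exposure* factors
(habitual physical activity, environmental hazards).  Each component carries
a direction: risk-increasing components enter the composite score with a
positive sign, protective components are flipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "default_registry",
    "COMPONENT_ORDER",
    "FallStatus",
    "classify_fall_status",
    "ipaq_met_week",
    "affordance_abs_error",
    "CohortTable",
    "CohortValidationError",
    "CellError",
    "load_cohort",
    "write_cohort",
    "validate_cohort",
]

MANDATORY_COLUMNS = ("age", "sex", "falls_12m")
BODY_COLUMNS = ("weight_kg", "height_cm", "waist_cm", "bmi")

#: Tokens treated as missing when reading CSV cells.
NA_TOKENS = ("", "NA", "na", "NaN", "nan")


@dataclass(frozen=True)
class VariableSpec:
    """Registry entry for one fall-risk component.

    Parameters
    ----------
    name:
        Column name in the cohort table.
    role:
        ``"intrinsic"`` (person-level attribute) or ``"exposure"``
        (opportunity for a fall: activity, environment).
    direction:
        ``"risk_increasing"`` or ``"protective"``.  Protective components
        are multiplied by -1 before Z-score summation.
    valid_range:
        Closed interval ``(low, high)``; ``None`` means unbounded on that
        side.
    units:
        Free-text units, for reports.
    integer:
        Whether the variable is integer-valued (count or questionnaire
        total); the synthetic generator rounds such variables.
    """

    name: str
    role: str
    direction: str
    valid_range: tuple[float | None, float | None]
    units: str = ""
    integer: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("intrinsic", "exposure"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.direction not in ("risk_increasing", "protective"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def sign(self) -> int:
        """Contribution sign in the composite score (-1 for protective)."""
        return -1 if self.direction == "protective" else +1

    def in_range(self, value: float) -> bool:
        lo, hi = self.valid_range
        if lo is not None and value < lo:
            return False
        if hi is not None and value > hi:
            return False
        return True


def default_registry() -> dict[str, VariableSpec]:
    """The ten registered score components, in canonical order.

    Six components are protective (higher = lower fall risk): cognition
    (MMSE), physical function (CPF), multidimensional balance (FAB),
    affordance-perception absolute error, gait (Tinetti gait section) and
    physical activity (IPAQ MET-min/week).  The remaining four are
    risk-increasing: chronic-disease count, physical-impairment count, fear
    of falling (FES-I) and environmental-hazard count.
    """
    specs = [
        VariableSpec("chronic_diseases", "intrinsic", "risk_increasing",
                     (0, None), "count", integer=True),
        VariableSpec("physical_impairments", "intrinsic", "risk_increasing",
                     (0, 6), "count", integer=True),
        VariableSpec("cognitive", "intrinsic", "protective",
                     (0, 30), "MMSE points", integer=True),
        VariableSpec("physical_function", "intrinsic", "protective",
                     (0, 24), "CPF points", integer=True),
        VariableSpec("balance", "intrinsic", "protective",
                     (0, 40), "FAB points", integer=True),
        VariableSpec("fear_of_falling", "intrinsic", "risk_increasing",
                     (16, 64), "FES-I points", integer=True),
        VariableSpec("affordance_error", "intrinsic", "protective",
                     (0, None), "cm"),
        VariableSpec("gait", "intrinsic", "protective",
                     (0, 12), "points", integer=True),
        VariableSpec("physical_activity", "exposure", "protective",
                     (0, None), "MET-min/week"),
        VariableSpec("environmental_hazards", "exposure", "risk_increasing",
                     (0, 34), "count", integer=True),
    ]
    return {s.name: s for s in specs}


#: Canonical component column order.
COMPONENT_ORDER = tuple(default_registry())


class FallStatus(NamedTuple):
    """Binary and three-level faller classification."""

    binary: str        # "occasional" | "recurrent"
    three_level: str   # "zero_falls" | "one_fall" | "two_plus"


def classify_fall_status(falls_12m: int) -> FallStatus:
    """Classify a participant by self-reported falls in the last 12 months.

    Occasional fallers fell once or not at all; recurrent fallers fell
    twice or more.
    """
    if isinstance(falls_12m, float) and not float(falls_12m).is_integer():
        raise ValueError(f"falls_12m must be an integer, got {falls_12m}")
    falls = int(falls_12m)
    if falls < 0:
        raise ValueError(f"falls_12m must be non-negative, got {falls}")
    if falls == 0:
        return FallStatus("occasional", "zero_falls")
    if falls == 1:
        return FallStatus("occasional", "one_fall")
    return FallStatus("recurrent", "two_plus")


def ipaq_met_week(walk_min_day: float, walk_days: float,
                  mod_min_day: float, mod_days: float,
                  vig_min_day: float, vig_days: float) -> float:
    """Weekly metabolic expenditure (MET-min/week) from the short IPAQ.

    Walking is weighted 3.3 MET, moderate activity 4.0 MET and vigorous
    activity 8.0 MET; each contributes minutes/day x days/week x weight.
    """
    args = (walk_min_day, walk_days, mod_min_day, mod_days,
            vig_min_day, vig_days)
    if any(a < 0 for a in args):
        raise ValueError("IPAQ inputs must be non-negative")
    if any(d > 7 for d in (walk_days, mod_days, vig_days)):
        raise ValueError("days/week cannot exceed 7")
    return (3.3 * walk_min_day * walk_days
            + 4.0 * mod_min_day * mod_days
            + 8.0 * vig_min_day * vig_days)


def affordance_abs_error(real_cm: float, estimated_cm: float) -> float:
    """Absolute error |real - estimated| of the stepping-forward estimate."""
    if real_cm < 0 or estimated_cm < 0:
        raise ValueError("stepping-forward distances must be non-negative")
    return abs(real_cm - estimated_cm)


class CellError(NamedTuple):
    """A validation problem localised to one cell."""

    row: int          # 0-based row index in the table
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}, column {self.column!r}: {self.message}"


class CohortValidationError(ValueError):
    """Raised when a cohort fails validation; carries per-cell errors."""

    def __init__(self, errors: list[CellError] | None = None,
                 message: str | None = None):
        self.errors = errors or []
        if message is None:
            lines = "; ".join(str(e) for e in self.errors[:10])
            more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
            message = f"cohort validation failed: {lines}{more}"
        super().__init__(message)


@dataclass
class CohortTable:
    """Participants x variables, with missing cells preserved as NaN.

    ``data`` always contains the mandatory demographic columns (``id``,
    ``age``, ``sex``, ``falls_12m``) plus whichever registered components
    and optional body-composition fields were supplied.  ``provenance``
    records whether the table is real or synthetic and, if synthetic, the
    seed and config hash.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=lambda: {"source": "unknown"})

    @property
    def n(self) -> int:
        return len(self.data)

    def components(self, registry: Mapping[str, VariableSpec] | None = None) -> list[str]:
        registry = registry or default_registry()
        return [c for c in registry if c in self.data.columns]

    def fall_status(self) -> pd.Series:
        """Binary faller label per participant."""
        return self.data["falls_12m"].map(
            lambda f: classify_fall_status(f).binary)

    def fall_group(self) -> pd.Series:
        """Three-level fall-count group per participant."""
        return self.data["falls_12m"].map(
            lambda f: classify_fall_status(f).three_level)

    def recurrent_indicator(self) -> np.ndarray:
        """0/1 vector: 1 = recurrent faller (>= 2 falls)."""
        return (self.data["falls_12m"].to_numpy() >= 2).astype(int)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), dict(self.provenance))


_SEX_ALIASES = {"f": "female", "female": "female", "m": "male", "male": "male"}


def _canonical_sex(value: object) -> str | None:
    if isinstance(value, str):
        return _SEX_ALIASES.get(value.strip().lower())
    return None


def validate_cohort(table: CohortTable,
                    registry: Mapping[str, VariableSpec] | None = None,
                    permissive: bool = False) -> list[CellError]:
    """Validate ranges and demographics; raise or coerce out-of-range cells.

    With ``permissive=False`` (default) any problem raises
    :class:`CohortValidationError` naming each offending cell.  With
    ``permissive=True`` out-of-range component values are coerced to
    missing and returned as warnings instead.
    """
    registry = registry or default_registry()
    df = table.data
    errors: list[CellError] = []
    warnings: list[CellError] = []

    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise CohortValidationError(
                message=f"mandatory column {col!r} missing from cohort")

    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise CohortValidationError(
            message=f"duplicate participant ids: {dups[:5]}")

    for i, (age, sex, falls) in enumerate(
            zip(df["age"], df["sex"], df["falls_12m"])):
        if pd.isna(age) or age < 65:
            errors.append(CellError(i, "age", f"age must be >= 65, got {age}"))
        if sex not in ("female", "male"):
            errors.append(CellError(i, "sex", f"unrecognised sex {sex!r}"))
        if pd.isna(falls) or falls < 0 or float(falls) != int(falls):
            errors.append(CellError(
                i, "falls_12m", f"falls must be a non-negative integer, got {falls}"))

    for name, spec in registry.items():
        if name not in df.columns:
            continue
        values = df[name]
        for i, v in enumerate(values):
            if pd.isna(v):
                continue  # missingness is legal pre-imputation
            if not spec.in_range(float(v)):
                err = CellError(i, name,
                                f"value {v} outside valid range {spec.valid_range}")
                if permissive:
                    df.loc[df.index[i], name] = np.nan
                    warnings.append(err)
                else:
                    errors.append(err)

    if "bmi" in df.columns and "weight_kg" in df.columns and "height_cm" in df.columns:
        sub = df[["weight_kg", "height_cm", "bmi"]].dropna()
        expected = sub["weight_kg"] / (sub["height_cm"] / 100.0) ** 2
        bad = (expected - sub["bmi"]).abs() > 0.1
        for idx in sub.index[bad]:
            errors.append(CellError(int(df.index.get_loc(idx)), "bmi",
                                    "bmi inconsistent with weight/height"))

    if errors:
        raise CohortValidationError(errors)
    return warnings


def load_cohort(path, registry: Mapping[str, VariableSpec] | None = None,
                permissive: bool = False) -> CohortTable:
    """Read a cohort CSV, canonicalise sex codes, and validate.

    Empty cells and ``NA`` tokens are preserved as missing.  Unparseable
    numeric cells and out-of-range values are reported with their row and
    column; out-of-range component cells are coerced to missing instead
    when ``permissive=True``.
    """
    registry = registry or default_registry()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("age", "falls_12m"):
        if col not in df.columns:
            raise CohortValidationError(
                message=f"mandatory column {col!r} missing from {path}")
    if "sex" not in df.columns:
        raise CohortValidationError(
            message=f"mandatory column 'sex' missing from {path}")
    if "id" not in df.columns:
        df.insert(0, "id", [f"P{i + 1:04d}" for i in range(len(df))])

    errors: list[CellError] = []
    numeric_cols = [c for c in df.columns if c not in ("id", "sex")]
    out = pd.DataFrame({"id": df["id"]})
    out["age"] = np.nan
    out["sex"] = [None] * len(df)
    for i, raw in enumerate(df["sex"]):
        canon = _canonical_sex(raw)
        if canon is None and raw not in NA_TOKENS:
            errors.append(CellError(i, "sex", f"unrecognised sex code {raw!r}"))
        out.loc[out.index[i], "sex"] = canon
    for col in numeric_cols:
        parsed = np.full(len(df), np.nan)
        for i, raw in enumerate(df[col]):
            if raw in NA_TOKENS:
                continue
            try:
                parsed[i] = float(raw)
            except ValueError:
                errors.append(CellError(i, col, f"unparseable numeric {raw!r}"))
        out[col] = parsed
    if errors:
        raise CohortValidationError(errors)

    table = CohortTable(out, {"source": "file", "path": str(path)})
    validate_cohort(table, registry, permissive=permissive)
    return table


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort CSV (missing cells empty, <= 6 significant digits)."""
    table.data.to_csv(path, index=False, float_format="%.6g", na_rep="")
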