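"""Continuous fall risk score (cFRs).

Each of the ten registered components is regressed on age and sex by
ordinary least squares over the cohort being scored; the standardized
residual (residual divided by the residual SD) is the component Z-score.
Z-scores of the six protective components (cognition, physical function,
balance, affordance perception, gait, physical activity) are multiplied by
-1, and the signed Z-scores are summed into the cFRs.  By construction the
cFRs has mean zero over the fitting sample; higher values indicate higher
fall risk.

The score is sample-specific: Z-scores are standardized against the cohort
in hand.  To score new individuals against a frozen reference, fit once,
save the model (:func:`save_model`) and apply it (:func:`apply_model`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableSpec, default_registry

__all__ = [
    "ComponentZ",
    "ScoreResult",
    "ScoreModel",
    "DegenerateComponentError",
    "residual_zscore",
    "compose_cfrs",
    "score_cohort",
    "save_model",
    "load_model",
    "apply_model",
]


class DegenerateComponentError(ValueError):
    """A component has (near-)zero residual variance after age/sex adjustment."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(
            f"component {name!r} has zero residual variance after regression "
            "on age and sex; it cannot be standardized")


@dataclass
class ComponentZ:
    """Age/sex-adjusted standardized residuals for one component.

    ``coef`` holds (intercept, age slope, female contrast); ``resid_sd`` is
    the sample SD (n-1 denominator) of the OLS residuals used for
    standardization.
    """

    name: str
    z: np.ndarray
    coef: np.ndarray
    resid_sd: float


@dataclass
class ScoreResult:
    """Per-participant cFRs plus the signed component Z table."""

    cfrs: np.ndarray
    z_table: pd.DataFrame            # unsigned z, one column per component
    signs: dict[str, int]            # -1 for protective components
    components: dict[str, ComponentZ] = field(default_factory=dict)

    def signed_z(self) -> pd.DataFrame:
        """Component Z-scores after direction flips (columns sum to cfrs)."""
        out = self.z_table.copy()
        for name, s in self.signs.items():
            out[name] = s * out[name]
        return out

    def to_frame(self) -> pd.DataFrame:
        df = self.z_table.add_prefix("z_")
        df["cfrs"] = self.cfrs
        return df


def _design(age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    female = np.asarray([1.0 if s == "female" else 0.0 for s in sex])
    return np.column_stack([np.ones(len(age)), np.asarray(age, float), female])


def residual_zscore(values, age, sex, name: str = "") -> ComponentZ:
    """Standardized residuals of ``values`` regressed on age and sex.

    OLS of the component on intercept + age + female indicator, then
    z_i = (value_i - fitted_i) / SD(residuals) with the n-1 denominator.
    Raises :class:`DegenerateComponentError` when the component is an exact
    linear function of age and sex (including a constant).
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.isnan(values).any():
        raise ValueError(
            f"component {name!r} has missing values; impute before scoring")
    n = len(values)
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if np.var(age) == 0:
        raise ValueError("age variance is zero; cannot adjust for age")
    x = _design(age, sex)
    coef, *_ = np.linalg.lstsq(x, values, rcond=None)
    resid = values - x @ coef
    resid_sd = float(np.std(resid, ddof=1))
    scale = max(1.0, float(np.std(values)))
    if resid_sd <= 1e-10 * scale:
        raise DegenerateComponentError(name or "<unnamed>")
    return ComponentZ(name=name, z=resid / resid_sd, coef=coef,
                      resid_sd=resid_sd)


def compose_cfrs(z_map: Mapping[str, ComponentZ],
                 registry: Mapping[str, VariableSpec] | None = None) -> ScoreResult:
    """Sum signed component Z-scores into the cFRs.

    Every registered component must be present with aligned participant
    order; protective components contribute with a -1 sign.
    """
    registry = registry or default_registry()
    missing = [name for name in registry if name not in z_map]
    if missing:
        raise ValueError(f"cannot compose cFRs, missing components: {missing}")
    lengths = {len(cz.z) for cz in z_map.values()}
    if len(lengths) != 1:
        raise ValueError(f"component z vectors are misaligned: lengths {sorted(lengths)}")

    signs = {name: registry[name].sign for name in registry}
    z_table = pd.DataFrame({name: z_map[name].z for name in registry})
    cfrs = np.zeros(lengths.pop())
    for name in registry:
        cfrs = cfrs + signs[name] * z_map[name].z
    return ScoreResult(cfrs=cfrs, z_table=z_table, signs=signs,
                       components=dict(z_map))


def _check_scorable(table: CohortTable) -> None:
    sex = table.data["sex"]
    counts = sex.value_counts()
    if counts.get("female", 0) < 2 or counts.get("male", 0) < 2:
        raise ValueError("scoring requires at least 2 participants of each sex")
    if float(np.var(table.data["age"].to_numpy(float))) == 0.0:
        raise ValueError("scoring requires non-degenerate age variance")


def score_cohort(table: CohortTable,
                 registry: Mapping[str, VariableSpec] | None = None,
                 stratify_by_sex: bool = False) -> ScoreResult:
    """Fit the cFRs on a complete cohort.

    With ``stratify_by_sex=True`` each component is regressed on age
    separately within each sex and standardized within sex (an alternative
    reading of "sex-specific"); the default adjusts for sex as an indicator
    covariate in one pooled regression.
    """
    registry = registry or default_registry()
    _check_scorable(table)
    df = table.data
    absent = [name for name in registry if name not in df.columns]
    if absent:
        raise ValueError(f"cohort lacks registered components: {absent}")

    age = df["age"].to_numpy(float)
    sex = df["sex"].to_numpy()
    z_map: dict[str, ComponentZ] = {}
    if not stratify_by_sex:
        for name in registry:
            z_map[name] = residual_zscore(df[name].to_numpy(float), age, sex, name)
    else:
        for name in registry:
            values = df[name].to_numpy(float)
            z = np.empty_like(values)
            coef_parts, sd_parts = {}, {}
            for s in ("female", "male"):
                idx = np.where(sex == s)[0]
                if len(idx) < 4:
                    raise ValueError(
                        f"sex-stratified scoring needs >= 4 {s} participants")
                x = np.column_stack([np.ones(len(idx)), age[idx]])
                coef, *_ = np.linalg.lstsq(x, values[idx], rcond=None)
                resid = values[idx] - x @ coef
                resid_sd = float(np.std(resid, ddof=1))
                if resid_sd <= 1e-10 * max(1.0, float(np.std(values))):
                    raise DegenerateComponentError(name)
                z[idx] = resid / resid_sd
                coef_parts[s], sd_parts[s] = coef, resid_sd
            cz = ComponentZ(name=name, z=z,
                            coef=np.concatenate([coef_parts["female"],
                                                 coef_parts["male"]]),
                            resid_sd=float("nan"))
            cz.per_sex = {"coef": coef_parts, "resid_sd": sd_parts}  # type: ignore[attr-defined]
            z_map[name] = cz
    return compose_cfrs(z_map, registry)


@dataclass
class ScoreModel:
    """Frozen reference fit: per-component coefficients and residual SD."""

    coef: dict[str, list[float]]      # name -> [intercept, age, female]
    resid_sd: dict[str, float]
    signs: dict[str, int]


def save_model(result: ScoreResult, path) -> None:
    """Serialize a pooled-regression fit as structured text (JSON)."""
    model = {
        "coef": {n: cz.coef.tolist() for n, cz in result.components.items()},
        "resid_sd": {n: cz.resid_sd for n, cz in result.components.items()},
        "signs": result.signs,
    }
    with open(path, "w") as fh:
        json.dump(model, fh, indent=1)


def load_model(path) -> ScoreModel:
    with open(path) as fh:
        raw = json.load(fh)
    return ScoreModel(coef={k: list(v) for k, v in raw["coef"].items()},
                      resid_sd={k: float(v) for k, v in raw["resid_sd"].items()},
                      signs={k: int(v) for k, v in raw["signs"].items()})


def apply_model(table: CohortTable, model: ScoreModel) -> ScoreResult:
    """Score a cohort against a frozen reference fit.

    Z-scores use the stored coefficients and residual SDs, so the mean cFRs
    of the new cohort is generally not zero — it is measured on the
    reference sample's scale.
    """
    df = table.data
    age = df["age"].to_numpy(float)
    sex = df["sex"].to_numpy()
    x = _design(age, sex)
    z_map: dict[str, ComponentZ] = {}
    for name, coef in model.coef.items():
        if name not in df.columns:
            raise ValueError(f"cohort lacks component {name!r}")
        values = df[name].to_numpy(float)
        if np.isnan(values).any():
            raise ValueError(f"component {name!r} has missing values")
        resid = values - x @ np.asarray(coef)
        z_map[name] = ComponentZ(name=name, z=resid / model.resid_sd[name],
                                 coef=np.asarray(coef),
                                 resid_sd=model.resid_sd[name])
    z_table = pd.DataFrame({n: cz.z for n, cz in z_map.items()})
    cfrs = sum(model.signs[n] * z_map[n].z for n in z_map)
    return ScoreResult(cfrs=np.asarray(cfrs), z_table=z_table,
                       signs=dict(model.signs), components=z_map)
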