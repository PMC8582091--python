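"""Synthetic cohort generator.

The real study cohort is not public, so the pipeline is exercised on
synthetic cohorts that reproduce the analysis' statistical structure: a
two-group mixture (occasional vs. recurrent fallers) with group-specific
component means and SDs, an exchangeable within-group correlation, and
missing-at-random gaps at configurable per-variable rates.  The shipped
defaults are the published group summaries of the 504-person study sample
(prevalence of recurrent fallers 29.4%, 77.6% women).

Components are drawn from a within-group multivariate normal and then
rounded (integer-valued scales) and clipped into each variable's valid
range; this reproduces the published marginal means/SDs and ranges but not
the real joint distribution (see the methods note for what that implies).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import COMPONENT_ORDER, CohortTable, default_registry

__all__ = [
    "Normal",
    "GroupStats",
    "GeneratorConfig",
    "table1_defaults",
    "generate_cohort",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for an infeasible generator configuration."""


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float


@dataclass(frozen=True)
class GroupStats:
    """Per-group marginal distribution of one variable."""

    occasional: Normal
    recurrent: Normal


# Published group means/SDs (occasional n=356, recurrent n=148) for the ten
# score components and age.
_TABLE1 = {
    "chronic_diseases":      ((2.2, 1.6), (3.3, 2.2)),
    "physical_impairments":  ((2.4, 1.5), (4.0, 1.7)),
    "cognitive":             ((27.0, 3.2), (22.2, 4.2)),
    "physical_function":     ((21.2, 3.5), (19.1, 5.1)),
    "balance":               ((30.3, 6.1), (26.5, 9.0)),
    "fear_of_falling":       ((20.1, 4.9), (25.9, 8.6)),
    "affordance_error":      ((8.5, 7.3), (7.9, 7.0)),
    "gait":                  ((11.6, 1.1), (11.1, 1.8)),
    "physical_activity":     ((2069.5, 1933.7), (1753.6, 1712.9)),
    "environmental_hazards": ((11.2, 6.5), (9.5, 6.8)),
}
_TABLE1_AGE = ((73.1, 6.4), (73.8, 6.5))

# Published per-variable missingness proportions.
_MISSING_RATES = {
    "cognitive": 0.013,
    "physical_function": 0.028,
    "balance": 0.011,
    "fear_of_falling": 0.017,
    "affordance_error": 0.085,
    "gait": 0.043,
    "physical_activity": 0.046,
}

# Stable sub-stream indices so adding a variable or concern does not perturb
# draws for existing ones (see _rng).
_STREAMS = {
    "group": 0,
    "sex": 1,
    "age": 2,
    "components": 3,
    "falls": 4,
}
_MISSING_STREAM_BASE = 100  # + component index in COMPONENT_ORDER


@dataclass
class GeneratorConfig:
    """Study-condition knobs for :func:`generate_cohort`.

    Defaults are the published cohort: n=504, 29.4% recurrent fallers,
    77.6% women, Table-1 group means/SDs, exchangeable within-group
    correlation rho=0.2 among the raw components, and the published
    per-variable missingness rates.
    """

    n: int = 504
    prevalence_recurrent: float = 0.294
    prop_female: float = 0.776
    age: GroupStats = field(default_factory=lambda: GroupStats(
        Normal(*_TABLE1_AGE[0]), Normal(*_TABLE1_AGE[1])))
    components: dict[str, GroupStats] = field(default_factory=lambda: {
        name: GroupStats(Normal(*occ), Normal(*rec))
        for name, (occ, rec) in _TABLE1.items()})
    rho: float = 0.2
    correlation: np.ndarray | None = None  # overrides exchangeable rho
    #: P(one fall | occasional); the study does not publish the 0/1 split.
    p_one_fall: float = 0.3
    #: falls | recurrent = 2 + Poisson(extra_falls_mean)
    extra_falls_mean: float = 1.0
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(_MISSING_RATES))
    #: relative missingness multiplier for the oldest age tertile (MAR on age)
    older_missing_multiplier: float = 1.5
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        k = len(self.components)
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (k, k):
                raise ConfigError(f"correlation must be {k}x{k}, got {c.shape}")
            return c
        c = np.full((k, k), self.rho)
        np.fill_diagonal(c, 1.0)
        return c

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be non-negative")
        for p, label in ((self.prevalence_recurrent, "prevalence_recurrent"),
                         (self.prop_female, "prop_female"),
                         (self.p_one_fall, "p_one_fall")):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{label} must be in [0, 1], got {p}")
        for name, gs in {**self.components, "age": self.age}.items():
            for grp in (gs.occasional, gs.recurrent):
                if grp.sd <= 0:
                    raise ConfigError(f"{name}: sd must be > 0, got {grp.sd}")
        for name, r in self.missing_rates.items():
            if not 0.0 <= r < 1.0:
                raise ConfigError(f"missing rate for {name} must be in [0, 1)")
            if name not in self.components:
                raise ConfigError(f"missing rate for unknown component {name!r}")
        eigvals = np.linalg.eigvalsh(self.correlation_matrix())
        if eigvals.min() < -1e-10:
            raise ConfigError("correlation matrix is not positive semi-definite")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.correlation is not None:
            d["correlation"] = np.asarray(self.correlation).tolist()
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)

        def _gs(v):
            if isinstance(v, GroupStats):
                return v
            return GroupStats(Normal(**v["occasional"]), Normal(**v["recurrent"]))

        if "age" in d:
            d["age"] = _gs(d["age"])
        if "components" in d:
            d["components"] = {k: _gs(v) for k, v in d["components"].items()}
        if d.get("correlation") is not None:
            d["correlation"] = np.asarray(d["correlation"], dtype=float)
        return cls(**d)


def table1_defaults() -> GeneratorConfig:
    """Generator configuration pre-filled with the published group summaries."""
    return GeneratorConfig()


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one concern, stable under new concerns."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_cohort(config: GeneratorConfig | None = None) -> CohortTable:
    """Draw a synthetic cohort under ``config``.

    Group membership is Bernoulli(prevalence); components come from the
    group's multivariate normal (exchangeable correlation by default) and
    are rounded/clipped into their valid ranges; falls counts are assigned
    consistently with group membership; missingness is MAR with the oldest
    age tertile missing at ``older_missing_multiplier`` times the rate of
    the younger tertiles, renormalised to the configured marginal rate.
    """
    config = config or table1_defaults()
    config.validate()
    registry = default_registry()
    names = [c for c in COMPONENT_ORDER if c in config.components]
    extra = [c for c in config.components if c not in names]
    names += extra  # user-added components keep config order
    n = config.n

    provenance = {"source": "synthetic", "seed": config.seed,
                  "config_hash": config.config_hash()}
    if n == 0:
        cols = ["id", "age", "sex", "falls_12m", *names]
        return CohortTable(pd.DataFrame(columns=cols), provenance)

    recurrent = _rng(config.seed, _STREAMS["group"]).random(n) < config.prevalence_recurrent
    female = _rng(config.seed, _STREAMS["sex"]).random(n) < config.prop_female

    age_rng = _rng(config.seed, _STREAMS["age"])
    age_draw = age_rng.standard_normal(n)
    age = np.where(recurrent,
                   config.age.recurrent.mean + config.age.recurrent.sd * age_draw,
                   config.age.occasional.mean + config.age.occasional.sd * age_draw)
    age = np.clip(age, 65.0, None)

    corr = config.correlation_matrix()
    # eigen-decomposition tolerates the PSD boundary where Cholesky fails
    w, v = np.linalg.eigh(corr)
    mixer = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = _rng(config.seed, _STREAMS["components"]).standard_normal((n, len(names))) @ mixer.T

    df = pd.DataFrame({"id": [f"S{i + 1:04d}" for i in range(n)],
                       "age": age,
                       "sex": np.where(female, "female", "male")})

    falls_rng = _rng(config.seed, _STREAMS["falls"])
    one_fall = falls_rng.random(n) < config.p_one_fall
    extra_falls = falls_rng.poisson(config.extra_falls_mean, n)
    df["falls_12m"] = np.where(recurrent, 2 + extra_falls,
                               one_fall.astype(int))

    for j, name in enumerate(names):
        gs = config.components[name]
        x = np.where(recurrent,
                     gs.recurrent.mean + gs.recurrent.sd * z[:, j],
                     gs.occasional.mean + gs.occasional.sd * z[:, j])
        spec = registry.get(name)
        if spec is not None:
            if spec.integer:
                x = np.round(x)
            lo, hi = spec.valid_range
            x = np.clip(x, lo if lo is not None else -np.inf,
                        hi if hi is not None else np.inf)
        df[name] = x

    # MAR missingness keyed to age tertile: the oldest third is missing at
    # `older_missing_multiplier` times the younger rate, renormalised so the
    # marginal rate matches the configured target.
    if config.missing_rates:
        t_hi = np.quantile(age, 2.0 / 3.0)
        oldest = age > t_hi
        frac_old = oldest.mean()
        mult = config.older_missing_multiplier
        for name, rate in config.missing_rates.items():
            if rate <= 0 or name not in df.columns:
                continue
            base = rate / (1.0 - frac_old + mult * frac_old)
            p = np.where(oldest, min(mult * base, 0.999), base)
            stream = _MISSING_STREAM_BASE + names.index(name)
            mask = _rng(config.seed, stream).random(n) < p
            df.loc[mask, name] = np.nan

    return CohortTable(df, provenance)
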