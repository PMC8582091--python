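"""Group-comparison statistics and study planning.

Covers the descriptive analysis surrounding the score: two-sample t-tests
and Pearson chi-square tests between occasional and recurrent fallers,
Cohen's d with confidence intervals and magnitude bands, one-way ANOVA with
Tukey HSD across the three fall-count groups, and the finite-population
sample-size formula for a proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, default_registry

__all__ = [
    "EffectSize",
    "GroupComparison",
    "AnovaResult",
    "cohens_d_from_summary",
    "cohens_d",
    "classify_magnitude",
    "two_sample_t",
    "chi_square_prop",
    "anova_tukey",
    "min_sample_size",
    "table_one",
]

# |d| magnitude bands (Batterham-Hopkins); the boundary 2.0 is assigned to
# very_large since the printed bands leave it unallocated.
_MAGNITUDE_BANDS = [(0.2, "trivial"), (0.6, "small"), (1.2, "moderate"),
                    (2.0, "large")]


@dataclass
class EffectSize:
    d: float
    ci_low: float
    ci_high: float
    ci_level: float
    magnitude: str


@dataclass
class GroupComparison:
    variable: str
    kind: str                  # "t" | "welch_t" | "chi_square" | "anova"
    statistic: float
    p_value: float
    group_stats: dict          # per-group mean/sd/n (or counts for chi-square)


@dataclass
class AnovaResult:
    f: float
    p_value: float
    #: adjusted p-value and mean difference per pair of three-level groups
    tukey: dict[tuple[str, str], dict]


def classify_magnitude(d: float) -> str:
    """Magnitude label for an effect size |d|."""
    if not math.isfinite(d):
        raise ValueError(f"d must be finite, got {d}")
    a = abs(d)
    for bound, label in _MAGNITUDE_BANDS:
        if a < bound:
            return label
    return "very_large"


def cohens_d_from_summary(mean_ref: float, sd_ref: float, n_ref: int,
                          mean_cmp: float, sd_cmp: float, n_cmp: int,
                          ci_level: float = 0.90) -> EffectSize:
    """Cohen's d (comparison minus reference, pooled SD) with a CI.

    The CI uses the normal-approximation standard error
    sqrt((n_ref+n_cmp)/(n_ref*n_cmp) + d^2/(2*(n_ref+n_cmp))).  In the
    faller analysis the reference group is the occasional fallers and the
    comparison group the recurrent fallers, so positive d means the
    component is higher among recurrent fallers.
    """
    if sd_ref <= 0 or sd_cmp <= 0:
        raise ValueError("group SDs must be positive")
    if n_ref < 2 or n_cmp < 2:
        raise ValueError("group sizes must be >= 2")
    pooled = math.sqrt(((n_ref - 1) * sd_ref ** 2 + (n_cmp - 1) * sd_cmp ** 2)
                       / (n_ref + n_cmp - 2))
    d = (mean_cmp - mean_ref) / pooled
    n_tot = n_ref + n_cmp
    se = math.sqrt(n_tot / (n_ref * n_cmp) + d ** 2 / (2 * n_tot))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return EffectSize(d=d, ci_low=d - z * se, ci_high=d + z * se,
                      ci_level=ci_level, magnitude=classify_magnitude(d))


def cohens_d(ref, cmp, ci_level: float = 0.90) -> EffectSize:
    """Cohen's d between two samples (reference first)."""
    ref = np.asarray(ref, float)
    cmp = np.asarray(cmp, float)
    return cohens_d_from_summary(ref.mean(), ref.std(ddof=1), len(ref),
                                 cmp.mean(), cmp.std(ddof=1), len(cmp),
                                 ci_level)


def two_sample_t(values_a, values_b, variable: str = "",
                 welch: bool = False) -> GroupComparison:
    """Independent two-sample t-test (Student's pooled by default)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: no within-group variance
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, b.mean() - a.mean()), 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        variable=variable, kind="welch_t" if welch else "t",
        statistic=float(t), p_value=float(p),
        group_stats={"a": {"mean": a.mean(), "sd": a.std(ddof=1), "n": len(a)},
                     "b": {"mean": b.mean(), "sd": b.std(ddof=1), "n": len(b)}})


def chi_square_prop(counts, variable: str = "",
                    correction: bool = False) -> GroupComparison:
    """Pearson chi-square test on a 2x2 contingency table.

    No continuity correction by default; pass ``correction=True`` for
    Yates' correction.
    """
    table = np.asarray(counts)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return GroupComparison(variable=variable, kind="chi_square",
                           statistic=float(stat), p_value=float(p),
                           group_stats={"counts": table.tolist(), "dof": int(dof)})


_PAIRS = (("zero_falls", "one_fall"), ("zero_falls", "two_plus"),
          ("one_fall", "two_plus"))
_LEVELS = ("zero_falls", "one_fall", "two_plus")


def anova_tukey(values, groups) -> AnovaResult:
    """One-way ANOVA across the three fall-count groups with Tukey HSD.

    ``groups`` holds the three-level labels (zero_falls / one_fall /
    two_plus); adjusted p-values come from the studentized range
    distribution.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    samples = {lvl: values[groups == lvl] for lvl in _LEVELS}
    for lvl, s in samples.items():
        if len(s) < 2:
            raise ValueError(f"group {lvl!r} needs at least 2 observations")
    arrays = [samples[lvl] for lvl in _LEVELS]
    if all(s.std(ddof=1) == 0 for s in arrays) and \
            len({s.mean() for s in arrays}) == 1:
        f, p = 0.0, 1.0
        tukey = {pair: {"p_adj": 1.0, "diff": 0.0} for pair in _PAIRS}
        return AnovaResult(f=f, p_value=p, tukey=tukey)
    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    tukey = {}
    for (ga, gb) in _PAIRS:
        i, j = _LEVELS.index(ga), _LEVELS.index(gb)
        tukey[(ga, gb)] = {"p_adj": float(hsd.pvalue[i, j]),
                           "diff": float(samples[gb].mean() - samples[ga].mean())}
    return AnovaResult(f=float(f), p_value=float(p), tukey=tukey)


def min_sample_size(population_n: int, z: float = 1.96,
                    error_d: float = 0.05, p: float = 0.5) -> int:
    """Minimum sample size for estimating a proportion in a finite population.

    ceil( N z^2 p(1-p) / (d^2 (N-1) + z^2 p(1-p)) ), capped at N — the
    finite-population-corrected formula used by epidemiology sample-size
    calculators.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if error_d <= 0:
        raise ValueError("error_d must be positive")
    if population_n < 1:
        raise ValueError("population_n must be >= 1")
    num = population_n * z ** 2 * p * (1 - p)
    den = error_d ** 2 * (population_n - 1) + z ** 2 * p * (1 - p)
    return min(math.ceil(num / den), population_n)


def table_one(table: CohortTable, scores=None, welch: bool = False) -> pd.DataFrame:
    """Occasional-vs-recurrent summary: means +/- SD, p, Cohen's d (90% CI).

    One row per numeric variable (age, body composition if present, the ten
    components, and the cFRs when ``scores`` is given), mirroring the
    classic cohort-characteristics table.
    """
    df = table.data
    recurrent = table.recurrent_indicator().astype(bool)
    variables = ["age"]
    variables += [c for c in ("weight_kg", "height_cm", "waist_cm", "bmi")
                  if c in df.columns]
    variables += [c for c in default_registry() if c in df.columns]
    work = df.copy()
    if scores is not None:
        work["cfrs"] = np.asarray(scores, float)
        variables.append("cfrs")

    rows = []
    for var in variables:
        occ = work.loc[~recurrent, var].dropna().to_numpy(float)
        rec = work.loc[recurrent, var].dropna().to_numpy(float)
        cmp = two_sample_t(occ, rec, variable=var, welch=welch)
        es = cohens_d(occ, rec)
        rows.append({
            "variable": var,
            "occasional_mean": occ.mean(), "occasional_sd": occ.std(ddof=1),
            "occasional_n": len(occ),
            "recurrent_mean": rec.mean(), "recurrent_sd": rec.std(ddof=1),
            "recurrent_n": len(rec),
            "p_value": cmp.p_value,
            "cohens_d": es.d, "d_ci_low": es.ci_low, "d_ci_high": es.ci_high,
            "magnitude": es.magnitude,
        })
    return pd.DataFrame(rows)
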