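"""Statistical analyses of the single and interaction experiments.

Covers the study's analysis set: per-container cannibalism bookkeeping from
census tables, one-way fixed-effects ANOVA, a binomial (logit) GLM with a
deviance chi-square test and Tjur's coefficient of discrimination, the
transformed size-variance regression, and group-mean growth rates.

The ANOVA is applied to binary mortality indicators exactly as in the
original analysis (treating 0/1 outcomes as continuous responses) — fidelity
to the published procedure is preferred over substituting a proportion test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DataError, DesignError, DomainError
from .tpc import growth_rate

__all__ = [
    "TestResult",
    "GroupSample",
    "cannibalism_counts",
    "anova_oneway",
    "binomial_glm_lrt",
    "tjur_r2",
    "size_variance_regression",
    "group_growth",
    "analyze_single",
    "analyze_interaction",
]


@dataclass(frozen=True)
class TestResult:
    """A test statistic with degrees of freedom, p-value and optional effect."""

    statistic: float
    df: tuple
    p_value: float
    effect: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "effect": self.effect,
        }


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: tuple

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise DesignError(f"group {self.label!r} is empty")


def cannibalism_counts(census: pd.DataFrame) -> pd.DataFrame:
    """Per-container cannibalized and intrinsic-death counts from a census.

    The cannibalism proxy is larvae missing at the end: initial count minus
    final live count minus all discovered carcasses.  Carcasses (unwounded
    dead) count as intrinsic mortality and are excluded from cannibalism.
    Raises :class:`DataError` when carcasses exceed the count decrement.
    """
    required = {"treatment", "container", "week", "n_alive", "n_carcasses"}
    missing = required - set(census.columns)
    if missing:
        raise DesignError(f"census missing columns: {sorted(missing)}")
    rows = []
    for (trt, cont), grp in census.groupby(["treatment", "container"], sort=True):
        grp = grp.sort_values("week")
        initial = int(grp["n_alive"].iloc[0])
        final = int(grp["n_alive"].iloc[-1])
        carcasses = int(grp["n_carcasses"].sum())
        cannibalized = initial - final - carcasses
        if cannibalized < 0:
            raise DataError(
                f"container {trt}/{cont}: {carcasses} carcasses exceed the "
                f"count decrement {initial - final}"
            )
        rows.append({
            "treatment": trt, "container": cont, "initial": initial,
            "final_alive": final, "cannibalized": cannibalized,
            "intrinsic": carcasses,
        })
    return pd.DataFrame(rows)


def anova_oneway(groups: Sequence[GroupSample]) -> TestResult:
    """Classical one-way fixed-effects ANOVA.

    F = MS_between / MS_within on (k-1, N-k) degrees of freedom, with the
    convention F = 0, p = 1 when every value in every group is identical
    (the decomposition is 0/0 there).
    """
    if len(groups) < 2:
        raise DesignError("need >= 2 groups")
    arrays = [np.asarray(g.values, dtype=float) for g in groups]
    ns = np.array([a.size for a in arrays])
    if not np.any(ns >= 2):
        raise DesignError("at least one group needs >= 2 values")
    grand = np.concatenate(arrays).mean()
    ss_between = float(sum(n * (a.mean() - grand) ** 2 for n, a in zip(ns, arrays)))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    k = len(arrays)
    n_total = int(ns.sum())
    df1, df2 = k - 1, n_total - k
    if df2 < 1:
        raise DesignError("no residual degrees of freedom")
    if ss_within == 0.0 and ss_between == 0.0:
        return TestResult(statistic=0.0, df=(df1, df2), p_value=1.0)
    ms_b = ss_between / df1
    ms_w = ss_within / df2
    if ms_w == 0.0:
        return TestResult(statistic=float("inf"), df=(df1, df2), p_value=0.0)
    f = ms_b / ms_w
    p = float(sps.f.sf(f, df1, df2))
    return TestResult(statistic=float(f), df=(df1, df2), p_value=p)


def binomial_glm_lrt(
    outcomes: Sequence[int], treatment: Sequence[str]
) -> tuple[TestResult, np.ndarray]:
    """Binomial (logit) GLM of a 0/1 outcome on a treatment factor, with a
    likelihood-ratio (deviance) chi-square test against the intercept-only
    model.

    Returns the test result (statistic = null deviance − residual deviance,
    df = levels − 1) and the fitted per-individual probabilities, which for
    this saturated one-factor model equal the observed group proportions.
    Complete separation (a group with all-0 or all-1 outcomes) is flagged
    with a warning; the deviance statistic is still well defined.
    """
    y = np.asarray(outcomes, dtype=float)
    labels = np.asarray(treatment)
    if y.shape != labels.shape:
        raise DesignError("outcomes and treatment must have equal length")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise DomainError("outcomes must be 0/1")
    levels = np.unique(labels)
    if levels.size < 2:
        raise DesignError("need >= 2 treatment levels")

    props = {lv: y[labels == lv].mean() for lv in levels}
    if any(p in (0.0, 1.0) for p in props.values()):
        warnings.warn(
            "complete separation: a treatment level has all-0 or all-1 "
            "outcomes; fitted probabilities sit on the boundary",
            stacklevel=2,
        )
    X = pd.get_dummies(pd.Categorical(labels, categories=sorted(levels)),
                       drop_first=True, dtype=float)
    X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels' own separation chatter
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(tol=1e-10, maxiter=100)
    fitted = np.asarray(res.fittedvalues, dtype=float)
    stat = float(res.null_deviance - res.deviance)
    df = int(levels.size - 1)
    p = float(sps.chi2.sf(max(stat, 0.0), df))
    return TestResult(statistic=stat, df=(df,), p_value=p,
                      effect={"deviance": float(res.deviance)}), fitted


def tjur_r2(fitted_probs: Sequence[float], outcomes: Sequence[int]) -> float:
    """Tjur's coefficient of discrimination.

    Mean fitted probability among the 1-outcomes minus the mean among the
    0-outcomes; ranges over [-1, 1] and equals 0 when fitted probabilities
    carry no outcome information.
    """
    p = np.asarray(fitted_probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise DesignError("fitted_probs and outcomes must have equal length")
    ones = y == 1
    zeros = y == 0
    if not (ones.any() and zeros.any()):
        raise DomainError("outcomes must contain at least one 0 and one 1")
    return float(p[ones].mean() - p[zeros].mean())


def size_variance_regression(
    cannibalized_counts: Sequence[float],
    initial_size_variances: Sequence[float],
    log_offset: float = 1.0,
) -> TestResult:
    """OLS of log(cannibalism count + offset) on sqrt(initial size variance).

    The transforms (log counts, square-root variances) are those used to
    normalize the cannibalism–size-variance relationship; ``log_offset``
    handles zero counts (default +1).  Reports slope, intercept, r²,
    F(1, n−2) and its p-value.
    """
    counts = np.asarray(cannibalized_counts, dtype=float)
    variances = np.asarray(initial_size_variances, dtype=float)
    if counts.shape != variances.shape:
        raise DesignError("vectors must have equal length")
    if counts.size < 3:
        raise DesignError("need >= 3 points")
    if np.any(variances < 0):
        raise DomainError("variances must be >= 0")
    yv = np.log(counts + log_offset)
    xv = np.sqrt(variances)
    if np.allclose(xv, xv[0]):
        raise DesignError("zero predictor variance")
    if np.allclose(yv, yv[0]):
        # constant response: slope and r² are identically zero
        return TestResult(
            statistic=0.0, df=(1, counts.size - 2), p_value=1.0,
            effect={"slope": 0.0, "intercept": float(yv[0]), "r2": 0.0},
        )
    X = sm.add_constant(xv)
    res = sm.OLS(yv, X).fit()
    slope = float(res.params[1])
    intercept = float(res.params[0])
    f = float(res.fvalue)
    p = float(res.f_pvalue)
    return TestResult(
        statistic=f, df=(1, int(res.df_resid)), p_value=p,
        effect={"slope": slope, "intercept": intercept, "r2": float(res.rsquared)},
    )


def group_growth(
    initial_sizes: Sequence[float],
    final_sizes: Sequence[float],
    duration: float,
) -> float:
    """Group-level specific growth rate from the means of the size vectors.

    Individuals cannot be tracked in a shared container, so the growth-rate
    formula is applied to the group means of the start and end head widths.
    """
    ini = np.asarray(initial_sizes, dtype=float)
    fin = np.asarray(final_sizes, dtype=float)
    if ini.size == 0 or fin.size == 0:
        raise DesignError("size vectors must be non-empty")
    if np.any(ini <= 0) or np.any(fin <= 0):
        raise DomainError("sizes must be > 0")
    return growth_rate(float(ini.mean()), float(fin.mean()), duration)


# ---------------------------------------------------------------------------
# report-level drivers


def analyze_single(measurements: pd.DataFrame, duration_days: float) -> dict:
    """Growth and mortality comparison for the two-arm single experiment.

    Expects measurement rows (treatment, container, larva_id, phase,
    head_width_mm) for two treatments.  Growth rates are per-larva (larvae
    are housed singly, so start and end rows pair by larva id); mortality is
    the 0/1 indicator of a missing end measurement.  Both are compared by
    one-way ANOVA, mirroring the original analysis.
    """
    growth_groups, mort_groups = [], []
    for trt, grp in measurements.groupby("treatment", sort=True):
        start = grp[grp["phase"] == "start"].set_index("larva_id")["head_width_mm"]
        end = grp[grp["phase"] == "end"].set_index("larva_id")["head_width_mm"]
        rates = [
            growth_rate(float(start[i]), float(end[i]), duration_days)
            for i in end.index if i in start.index
        ]
        died = [0 if i in end.index else 1 for i in start.index]
        if rates:
            growth_groups.append(GroupSample(label=str(trt), values=tuple(rates)))
        mort_groups.append(GroupSample(label=str(trt), values=tuple(died)))
    return {
        "growth_anova": anova_oneway(growth_groups).to_dict(),
        "mortality_anova": anova_oneway(mort_groups).to_dict(),
    }


def analyze_interaction(
    census: pd.DataFrame, measurements: pd.DataFrame, duration_days: float
) -> dict:
    """Full interaction-experiment report.

    Blocks: cannibalism (binomial GLM deviance test across treatments plus
    Tjur's r²), growth (one-way ANOVA of per-container group growth rates),
    initial and final sizes (one-way ANOVAs of container means), intrinsic
    mortality (one-way ANOVA of per-container carcass counts), and the
    size-variance regression of per-container cannibalism on initial
    head-width variance.
    """
    books = cannibalism_counts(census)

    # survival indicators per individual: alive at end = 1, cannibalized = 0;
    # intrinsic deaths are excluded from the cannibalism outcome
    outcomes, labels = [], []
    for _, row in books.iterrows():
        outcomes.extend([1] * row["final_alive"] + [0] * row["cannibalized"])
        labels.extend([row["treatment"]] * (row["final_alive"] + row["cannibalized"]))
    glm_res, fitted = binomial_glm_lrt(outcomes, labels)
    tjur = tjur_r2(fitted, outcomes)

    growth_groups, init_groups, final_groups, intr_groups = [], [], [], []
    var_by_container, cann_by_container = [], []
    for trt in sorted(books["treatment"].unique()):
        meas = measurements[measurements["treatment"] == trt]
        rates, inits, finals = [], [], []
        for cont, grp in meas.groupby("container", sort=True):
            start = grp.loc[grp["phase"] == "start", "head_width_mm"].to_numpy()
            end = grp.loc[grp["phase"] == "end", "head_width_mm"].to_numpy()
            inits.append(float(start.mean()))
            if end.size > 0:
                rates.append(group_growth(start, end, duration_days))
                finals.append(float(end.mean()))
            row = books[(books["treatment"] == trt) & (books["container"] == cont)]
            var_by_container.append(float(np.var(start, ddof=1)) if start.size > 1 else 0.0)
            cann_by_container.append(int(row["cannibalized"].iloc[0]))
        growth_groups.append(GroupSample(label=str(trt), values=tuple(rates)))
        init_groups.append(GroupSample(label=str(trt), values=tuple(inits)))
        final_groups.append(GroupSample(label=str(trt), values=tuple(finals)))
        intr = books.loc[books["treatment"] == trt, "intrinsic"]
        intr_groups.append(GroupSample(label=str(trt), values=tuple(float(v) for v in intr)))

    report = {
        "cannibalism_glm": glm_res.to_dict(),
        "tjur_r2": tjur,
        "growth_anova": anova_oneway(growth_groups).to_dict(),
        "initial_size_anova": anova_oneway(init_groups).to_dict(),
        "final_size_anova": anova_oneway(final_groups).to_dict(),
        "intrinsic_mortality_anova": anova_oneway(intr_groups).to_dict(),
        "size_variance_regression": size_variance_regression(
            cann_by_container, var_by_container
        ).to_dict(),
        "size_variance_aggregation": "per-container (one point per container)",
        "totals": {
            "initial": int(books["initial"].sum()),
            "final_alive": int(books["final_alive"].sum()),
            "cannibalized": int(books["cannibalized"].sum()),
            "intrinsic": int(books["intrinsic"].sum()),
        },
    }
    return report
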