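"""Adjusted treatment-effect estimation and design calculations.

Primary/secondary outcomes are analyzed by complete-case linear regression
(ANCOVA): follow-up value on randomized group, the five stratification
covariates and the baseline value. 'Other' symptoms use a random-intercept
mixed model per visit. Also: noncentral-t power/sample-size, subgroup
interaction (forest) tables, QALY area-under-curve and productivity change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: stratification covariates adjusted for in every regression
DEFAULT_COVARIATES = ("age_band", "imd_band", "sex", "ethnicity", "chosen_symptom")


@dataclass(frozen=True)
class EffectEstimate:
    """Adjusted between-group difference for one outcome at one visit."""

    outcome: str
    visit_month: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_analyzed: int

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI does not bracket the estimate")


@dataclass(frozen=True)
class SubgroupResult:
    variable: str
    level: str
    effect: EffectEstimate
    interaction_p: float


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample t-test design: delta in s.d. units, alpha two-sided."""

    delta: float
    sd: float = 1.0
    alpha: float = 0.05
    power: Optional[float] = None
    n1: Optional[int] = None
    n2: Optional[int] = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")


class DegenerateDesignError(ValueError):
    """The regression design matrix is rank deficient."""


def _merge_small_levels(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the trial's regression codings for sex and ethnicity.

    sex 'other' is merged into the reference level (female, the modal
    category) with a log notice; ethnicity is coded South Asian vs all
    other.
    """
    df = df.copy()
    if "sex" in df.columns and (df["sex"] == "other").any():
        n = int((df["sex"] == "other").sum())
        logger.info("sex level 'other' (n=%d) merged with reference level 'female'", n)
        df["sex"] = df["sex"].replace({"other": "female"})
    if "ethnicity" in df.columns:
        df["ethnicity"] = np.where(df["ethnicity"] == "south_asian",
                                   "south_asian", "other")
    return df


def _design_matrix(df: pd.DataFrame, covariates: Sequence[str],
                   baseline_col: Optional[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    X["group"] = (df["arm"] == "intervention").astype(float)
    for cov in covariates:
        col = df[cov]
        if col.dtype.kind in "ifu" and col.nunique() > 6:
            X[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True,
                                     dtype=float)
            X = pd.concat([X, dummies], axis=1)
    if baseline_col is not None:
        if df[baseline_col].nunique() > 1:
            X["baseline"] = df[baseline_col].astype(float)
        else:
            logger.warning("baseline value constant; dropped from adjustment")
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # name a culprit: column whose removal restores full rank; prefer
        # blaming a covariate over the intercept/group terms
        ordered = [c for c in X.columns if c not in ("Intercept", "group")] + \
            [c for c in X.columns if c in ("Intercept", "group")]
        for col in ordered:
            sub = X.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(sub) == rank:
                raise DegenerateDesignError(
                    f"design matrix rank deficient; offending covariate: {col!r}"
                )
        raise DegenerateDesignError("design matrix rank deficient")


def _fit_group_effect(y: np.ndarray, X: pd.DataFrame, outcome: str, visit: int,
                      alpha: float, weights: Optional[np.ndarray] = None) -> EffectEstimate:
    _check_rank(X)
    if weights is None:
        model = sm.OLS(y, X)
    else:
        model = sm.WLS(y, X, weights=weights)
    fit = model.fit()
    est = float(fit.params["group"])
    se = float(fit.bse["group"])
    dof = float(fit.df_resid)
    tcrit = stats.t.ppf(1 - alpha / 2, dof)
    p = 2 * stats.t.sf(abs(est) / se, dof) if se > 0 else (0.0 if est != 0 else 1.0)
    return EffectEstimate(
        outcome=outcome, visit_month=visit, estimate=est, se=se,
        ci_low=est - tcrit * se, ci_high=est + tcrit * se,
        p_value=float(p), n_analyzed=len(y),
    )


def prepare_ancova_frame(
    outcome_long: pd.DataFrame,
    cohort: pd.DataFrame,
    visit: int,
    outcome: str = "z",
) -> pd.DataFrame:
    """Complete-case analysis frame: baseline + follow-up value + covariates.

    ``outcome_long`` is tidy (participant_id, visit_month, <outcome>);
    ``cohort`` carries arm and the stratification covariates. Participants
    missing either the baseline or the visit value are dropped.
    """
    base = outcome_long[outcome_long["visit_month"] == 0][["participant_id", outcome]]
    base = base.rename(columns={outcome: "baseline_value"})
    fup = outcome_long[outcome_long["visit_month"] == visit][["participant_id", outcome]]
    fup = fup.rename(columns={outcome: "followup_value"})
    df = cohort.merge(base, on="participant_id").merge(fup, on="participant_id")
    return df.dropna(subset=["baseline_value", "followup_value"]).reset_index(drop=True)


def ancova_effect(
    outcome_long: pd.DataFrame,
    cohort: pd.DataFrame,
    visit: int,
    outcome: str = "z",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
    weights: Optional[Mapping[str, float]] = None,
) -> EffectEstimate:
    """Baseline-adjusted linear-regression treatment effect at one visit.

    Complete-case least squares of the follow-up value on a binary group
    indicator, the stratification covariates and the baseline value; the
    group coefficient is the effect, with t-based 95% CI and two-sided p.
    No multiplicity adjustment. ``weights`` (participant_id -> weight)
    switches to weighted least squares (used by the IPW sensitivity path).
    """
    df = prepare_ancova_frame(outcome_long, cohort, visit, outcome)
    if df.empty:
        raise ValueError(f"no analyzable rows at visit {visit} for outcome {outcome!r}")
    df = _merge_small_levels(df)
    usable = [c for c in covariates if df[c].nunique() > 1]
    for dropped in set(covariates) - set(usable):
        logger.warning("covariate %r constant in analysis set; dropped", dropped)
    X = _design_matrix(df, usable, "baseline_value")
    w = None
    if weights is not None:
        w = df["participant_id"].map(weights).to_numpy(dtype=float)
        if np.isnan(w).any():
            raise ValueError("weights missing for some analyzed participants")
    return _fit_group_effect(df["followup_value"].to_numpy(dtype=float), X,
                             outcome, visit, alpha, w)


def mixed_other_effect(
    other_long: pd.DataFrame,
    cohort: pd.DataFrame,
    visit: int,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Per-visit random-intercept model for the 'other' symptom VAS ratings.

    One row per tracked symptom per participant; fixed effects as in
    :func:`ancova_effect` (group, stratification covariates, baseline VAS of
    the same symptom), random intercept on participant, REML. When every
    participant contributes a single row the variance component is
    unidentifiable and the fit falls back to OLS with a log notice.
    """
    ov = other_long.copy()
    base = ov[ov["visit_month"] == 0].rename(columns={"vas": "baseline_value"})
    fup = ov[ov["visit_month"] == visit].rename(columns={"vas": "followup_value"})
    keys = ["participant_id", "symptom_label"]
    df = base[keys + ["baseline_value"]].merge(fup[keys + ["followup_value"]], on=keys)
    df = df.merge(cohort, on="participant_id")
    df = df.dropna(subset=["baseline_value", "followup_value"]).reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no analyzable 'other' symptom rows at visit {visit}")
    df = _merge_small_levels(df)
    usable = [c for c in covariates if df[c].nunique() > 1]
    X = _design_matrix(df, usable, "baseline_value")
    y = df["followup_value"].to_numpy(dtype=float)

    if df["participant_id"].duplicated().any():
        _check_rank(X)
        model = sm.MixedLM(y, X, groups=df["participant_id"])
        fit = model.fit(reml=True)
        est = float(fit.fe_params["group"])
        se = float(fit.bse_fe["group"])
        dof = len(df) - X.shape[1]
        tcrit = stats.t.ppf(1 - alpha / 2, dof)
        p = 2 * stats.t.sf(abs(est / se), dof)
        return EffectEstimate(
            outcome="other_vas", visit_month=visit, estimate=est, se=se,
            ci_low=est - tcrit * se, ci_high=est + tcrit * se,
            p_value=float(p), n_analyzed=len(df),
        )
    logger.info("single rating per participant; mixed model collapses to OLS")
    return _fit_group_effect(y, X, "other_vas", visit, alpha)


def add_tertiles(series: pd.Series, name: str) -> pd.Series:
    """Tertile labels computed on the analyzed cohort (used for age and BMI)."""
    return pd.qcut(series, 3, labels=[f"{name}_low", f"{name}_mid", f"{name}_high"])


def subgroup_forest(
    outcome_long: pd.DataFrame,
    cohort: pd.DataFrame,
    visit: int,
    variables: Mapping[str, str],
    outcome: str = "z",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> list:
    """Subgroup interaction analyses for a forest plot.

    ``variables`` maps a display name to a column of ``cohort`` holding the
    subgrouping levels. For each variable the ANCOVA model is extended with
    group x variable interaction terms (joint Wald test gives the
    interaction p), and within-level effects are estimated by refitting in
    each level. Not powered for subgroups: interpret descriptively.
    Single-level variables are skipped with a warning.
    """
    results: list = []
    for name, col in variables.items():
        levels = cohort[col].dropna().unique()
        if len(levels) < 2:
            logger.warning("subgroup variable %r has one level; skipped", name)
            continue

        df = prepare_ancova_frame(outcome_long, cohort, visit, outcome)
        df = _merge_small_levels(df)
        usable = [c for c in covariates if c != col and df[c].nunique() > 1]

        def build(usable_covs):
            X = _design_matrix(df, usable_covs, "baseline_value")
            var_d = pd.get_dummies(df[col].astype(str), prefix=col,
                                   drop_first=True, dtype=float)
            inter_cols = []
            for c in var_d.columns:
                if c not in X.columns:
                    X[c] = var_d[c]
                icol = f"group:{c}"
                X[icol] = X["group"] * var_d[c]
                inter_cols.append(icol)
            return X, inter_cols

        X, inter_cols = build(usable)
        # a derived subgrouping variable (e.g. an indicator of one chosen
        # symptom) can be collinear with a covariate; drop the covariate
        while True:
            try:
                _check_rank(X)
                break
            except DegenerateDesignError as exc:
                culprit = str(exc).split("'")[1] if "'" in str(exc) else ""
                parents = [c for c in usable if culprit.startswith(f"{c}_")]
                if not parents:
                    # culprit may be a variable dummy; find a covariate whose
                    # removal restores full rank
                    for cand in usable:
                        trial = [c for c in usable if c != cand]
                        Xt, _ = build(trial)
                        if (np.linalg.matrix_rank(Xt.to_numpy(dtype=float))
                                == Xt.shape[1]):
                            parents = [cand]
                            break
                if not parents:
                    raise
                logger.warning("covariate %r collinear with subgroup variable %r; "
                               "dropped from its interaction model", parents[0], name)
                usable = [c for c in usable if c != parents[0]]
                X, inter_cols = build(usable)
        fit = sm.OLS(df["followup_value"].to_numpy(dtype=float), X).fit()
        contrast = np.zeros((len(inter_cols), X.shape[1]))
        for i, icol in enumerate(inter_cols):
            contrast[i, X.columns.get_loc(icol)] = 1.0
        interaction_p = float(np.squeeze(fit.f_test(contrast).pvalue))

        for level in sorted(map(str, levels)):
            sub_cohort = cohort[cohort[col].astype(str) == level]
            try:
                eff = ancova_effect(outcome_long, sub_cohort, visit, outcome,
                                    covariates=[c for c in covariates if c != col],
                                    alpha=alpha)
            except (DegenerateDesignError, ValueError) as exc:
                logger.warning("subgroup %s=%s not estimable: %s", name, level, exc)
                continue
            results.append(SubgroupResult(variable=name, level=level,
                                          effect=eff, interaction_p=interaction_p))
    return results


def subgroup_frame(results: Sequence[SubgroupResult]) -> pd.DataFrame:
    """Forest-plot-ready table."""
    return pd.DataFrame(
        [
            {
                "variable": r.variable, "level": r.level,
                "estimate": r.effect.estimate, "ci_low": r.effect.ci_low,
                "ci_high": r.effect.ci_high, "p_value": r.effect.p_value,
                "n": r.effect.n_analyzed, "interaction_p": r.interaction_p,
            }
            for r in results
        ]
    )


def power_t(spec: PowerSpec) -> float:
    """Two-sided noncentral-t power of the two-sample t-test."""
    if spec.n1 is None or spec.n2 is None:
        raise ValueError("power_t needs n1 and n2")
    if spec.n1 < 2 or spec.n2 < 2:
        raise ValueError("group sizes must be at least 2")
    df = spec.n1 + spec.n2 - 2
    nc = (spec.delta / spec.sd) / math.sqrt(1 / spec.n1 + 1 / spec.n2)
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def sample_size_t(spec: PowerSpec) -> int:
    """Smallest equal per-group n reaching the requested two-sample t power."""
    if spec.power is None:
        raise ValueError("sample_size_t needs a target power")
    if spec.delta == 0:
        raise ValueError("delta = 0: requested power is unattainable")
    # normal-approximation start, then walk to the exact noncentral-t answer
    za = stats.norm.ppf(1 - spec.alpha / 2)
    zb = stats.norm.ppf(spec.power)
    n = max(2, math.ceil(2 * ((za + zb) * spec.sd / spec.delta) ** 2))
    def pw(k):
        return power_t(PowerSpec(delta=spec.delta, sd=spec.sd, alpha=spec.alpha,
                                 n1=k, n2=k))
    while pw(n) < spec.power:
        n += 1
    while n > 2 and pw(n - 1) >= spec.power:
        n -= 1
    return n


def qaly_auc(utilities: Sequence[float], times_months: Sequence[float]) -> float:
    """Trapezoidal area under the utility-time curve, in QALYs (time in years)."""
    u = np.asarray(utilities, dtype=float)
    t = np.asarray(times_months, dtype=float)
    if len(u) != len(t):
        raise ValueError("utilities and times differ in length")
    if len(t) < 2:
        raise ValueError("QALY AUC needs at least two time points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(u, t / 12.0))


def productivity_change(
    hours_long: pd.DataFrame,
    cohort: pd.DataFrame,
    visit: int,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> Tuple[pd.DataFrame, EffectEstimate]:
    """Change in weekly work hours missed, with an adjusted group effect.

    ``hours_long``: participant_id, visit_month, work_hours_missed (>= 0).
    Returns (per-arm change summary, ANCOVA effect on the follow-up value).
    Participants without follow-up hours are complete-case excluded; the
    summary reports analyzed and attrition counts.
    """
    h = hours_long.copy()
    if (h["work_hours_missed"].dropna() < 0).any():
        raise ValueError("work_hours_missed must be non-negative")
    tidy = h.rename(columns={"work_hours_missed": "hours"})
    eff = ancova_effect(tidy, cohort, visit, outcome="hours",
                        covariates=covariates, alpha=alpha)
    frame = prepare_ancova_frame(tidy, cohort, visit, "hours")
    frame["change"] = frame["followup_value"] - frame["baseline_value"]
    randomized = cohort.groupby("arm")["participant_id"].nunique()
    summary = (
        frame.groupby("arm")["change"].agg(["mean", "std", "count"]).reset_index()
        .rename(columns={"mean": "mean_change", "std": "sd_change", "count": "n_analyzed"})
    )
    summary["n_randomized"] = summary["arm"].map(randomized)
    summary["n_missing"] = summary["n_randomized"] - summary["n_analyzed"]
    return summary, eff
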