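"""Missing-data sensitivity analyses.

Multiple imputation by chained equations (predictive mean matching for
continuous variables, logistic/multinomial draws for categorical), fitted
separately within each randomized arm, with Rubin pooling of per-imputation
effects; and inverse-probability-of-follow-up weighting. Also the post hoc
ANCOVA with/without a group x weight-change interaction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from persym.analysis import (
    DEFAULT_COVARIATES,
    EffectEstimate,
    _design_matrix,
    _merge_small_levels,
    ancova_effect,
    prepare_ancova_frame,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationSpec:
    """Chained-equations configuration.

    ``predictors`` are fully observed columns feeding every conditional
    model; columns containing missing values are the imputation targets.
    Defaults: m=100 imputations, 10 cycles, 5-donor predictive mean
    matching, fitted separately within each arm.
    """

    m: int = 100
    predictors: Sequence[str] = DEFAULT_COVARIATES
    within_arm: bool = True
    cycles: int = 10
    k_pmm: int = 5
    seed: Optional[int] = None

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be at least 2")
        if not self.predictors:
            raise ValueError("predictors must be non-empty")


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of per-imputation effect estimates."""

    outcome: str
    visit_month: int
    estimate: float
    variance: float
    ci_low: float
    ci_high: float
    p_value: float
    m: int
    df: float


def _dummify(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    parts = [np.ones((len(df), 1))]
    for c in cols:
        col = df[c]
        if col.dtype.kind in "ifu":
            parts.append(col.to_numpy(dtype=float).reshape(-1, 1))
        else:
            d = pd.get_dummies(col.astype(str), drop_first=True, dtype=float)
            parts.append(d.to_numpy())
    return np.hstack(parts)


def _pmm_draw(y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray,
              k: int, rng: np.random.Generator) -> np.ndarray:
    """Bayesian-OLS predictive mean matching with k donors."""
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs
    ridge = 1e-8 * np.eye(p) * max(1.0, np.trace(XtX) / p)
    XtX_inv = np.linalg.inv(XtX + ridge)
    beta_hat = XtX_inv @ X_obs.T @ y_obs
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    beta = rng.multivariate_normal(beta_hat, sigma2 * XtX_inv, method="cholesky")
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta
    out = np.empty(len(X_mis))
    kk = min(k, n)
    for i, pm in enumerate(pred_mis):
        nearest = np.argpartition(np.abs(pred_obs - pm), kk - 1)[:kk]
        out[i] = y_obs[nearest[rng.integers(kk)]]
    return out


def _categorical_draw(y_obs: pd.Series, X_obs: np.ndarray, X_mis: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    levels = sorted(y_obs.astype(str).unique())
    if len(levels) == 1:
        return np.array([levels[0]] * len(X_mis), dtype=object)
    try:
        codes = pd.Categorical(y_obs.astype(str), categories=levels).codes
        if len(levels) == 2:
            fit = sm.Logit(codes, X_obs).fit(disp=0, maxiter=100)
            p1 = fit.predict(X_mis)
            probs = np.column_stack([1 - p1, p1])
        else:
            fit = sm.MNLogit(codes, X_obs).fit(disp=0, maxiter=100)
            probs = fit.predict(X_mis)
    except Exception:  # separation / tiny cells: fall back to marginal draws
        counts = y_obs.astype(str).value_counts().reindex(levels).to_numpy(dtype=float)
        probs = np.tile(counts / counts.sum(), (len(X_mis), 1))
    probs = np.clip(probs, 1e-9, None)
    probs = probs / probs.sum(axis=1, keepdims=True)
    cum = probs.cumsum(axis=1)
    u = rng.random(len(X_mis))[:, None]
    idx = (u > cum).sum(axis=1)
    return np.asarray(levels, dtype=object)[idx]


def _impute_block(block: pd.DataFrame, targets: List[str], spec: ImputationSpec,
                  rng: np.random.Generator) -> pd.DataFrame:
    """One chained-equations pass over one arm's data -> one completed copy."""
    work = block.copy()
    miss = {c: work[c].isna().to_numpy() for c in targets}
    # initial fill: random draws from the observed margin
    for c in targets:
        obs = work.loc[~miss[c], c].to_numpy()
        work.loc[miss[c], c] = rng.choice(obs, size=int(miss[c].sum()), replace=True)

    predictors = list(spec.predictors)
    for _ in range(spec.cycles):
        for c in targets:
            others = [t for t in targets if t != c]
            cols = predictors + others
            X = _dummify(work, cols)
            m_rows = miss[c]
            if not m_rows.any():
                continue
            X_obs, X_mis = X[~m_rows], X[m_rows]
            if block[c].dtype.kind in "ifu":
                y_obs = block.loc[~m_rows, c].to_numpy(dtype=float)
                work.loc[m_rows, c] = _pmm_draw(y_obs, X_obs, X_mis, spec.k_pmm, rng)
            else:
                y_obs = block.loc[~m_rows, c]
                work.loc[m_rows, c] = _categorical_draw(y_obs, X_obs, X_mis, rng)
    return work


def mice_impute(data: pd.DataFrame, spec: ImputationSpec) -> List[pd.DataFrame]:
    """Chained-equations multiple imputation; returns ``spec.m`` completed copies.

    Missingness must be confined to non-predictor columns; columns with no
    missing values other than the predictors are carried through untouched.
    Observed cells are never overwritten. Imputation is fitted separately
    within each arm when ``spec.within_arm`` (requires an ``arm`` column).
    """
    rng = np.random.default_rng(spec.seed)
    for p in spec.predictors:
        if p not in data.columns:
            raise ValueError(f"predictor column {p!r} absent from data")
        if data[p].isna().any():
            raise ValueError(f"predictor column {p!r} contains missing values")

    targets = [c for c in data.columns
               if c not in spec.predictors and data[c].isna().any()]
    if not targets:
        return [data.copy() for _ in range(spec.m)]

    groups: List[Tuple[str, pd.DataFrame]]
    if spec.within_arm:
        if "arm" not in data.columns:
            raise ValueError("within-arm imputation requires an 'arm' column")
        groups = [(str(a), g) for a, g in data.groupby("arm", sort=True)]
    else:
        groups = [("all", data)]
    for label, g in groups:
        for c in targets:
            if g[c].isna().all():
                raise ValueError(f"column {c!r} fully missing within arm {label!r}")

    completed = []
    for _ in range(spec.m):
        parts = [_impute_block(g, targets, spec, rng) for _, g in groups]
        full = pd.concat(parts).loc[data.index]
        completed.append(full)
    return completed


def pool_rubin(estimates: Sequence[EffectEstimate],
               dfcom: Optional[float] = None) -> PooledEstimate:
    """Combine per-imputation effects by Rubin's rules.

    Total variance = mean within-imputation variance + (1 + 1/m) x
    between-imputation variance. Degrees of freedom follow Barnard-Rubin
    when the complete-data df ``dfcom`` is supplied, otherwise the
    large-sample Rubin formula.
    """
    m = len(estimates)
    if m < 2:
        raise ValueError("pooling needs at least two imputations")
    outcomes = {e.outcome for e in estimates}
    visits = {e.visit_month for e in estimates}
    if len(outcomes) > 1 or len(visits) > 1:
        raise ValueError(f"mismatched estimates: outcomes {outcomes}, visits {visits}")

    q = np.array([e.estimate for e in estimates])
    w = np.array([e.se**2 for e in estimates])
    qbar = float(q.mean())
    W = float(w.mean())
    B = float(q.var(ddof=1))
    T = W + (1 + 1 / m) * B

    if B == 0:
        df = dfcom if dfcom is not None else math.inf
    else:
        r = (1 + 1 / m) * B / W if W > 0 else math.inf
        df_large = (m - 1) * (1 + 1 / r) ** 2
        if dfcom is None:
            df = df_large
        else:
            lam = (1 + 1 / m) * B / T
            df_obs = (dfcom + 1) / (dfcom + 3) * dfcom * (1 - lam)
            df = 1 / (1 / df_large + 1 / df_obs)

    se = math.sqrt(T)
    if math.isinf(df):
        tcrit = stats.norm.ppf(0.975)
        p = 2 * stats.norm.sf(abs(qbar / se)) if se > 0 else 0.0
    else:
        tcrit = stats.t.ppf(0.975, df)
        p = 2 * stats.t.sf(abs(qbar / se), df) if se > 0 else 0.0
    return PooledEstimate(
        outcome=estimates[0].outcome, visit_month=estimates[0].visit_month,
        estimate=qbar, variance=T, ci_low=qbar - tcrit * se,
        ci_high=qbar + tcrit * se, p_value=float(p), m=m, df=float(df),
    )


@dataclass(frozen=True)
class IPWResult:
    effect: EffectEstimate
    weights: pd.DataFrame
    n_truncated: int


def ipw_effect(
    outcome_long: pd.DataFrame,
    cohort: pd.DataFrame,
    visit: int,
    predictors: Sequence[str] = DEFAULT_COVARIATES,
    outcome: str = "z",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    floor: float = 0.02,
    alpha: float = 0.05,
) -> IPWResult:
    """Inverse-probability-of-follow-up weighted treatment effect.

    A logistic model of the follow-up indicator (non-missing outcome at the
    visit) on baseline predictors gives each participant a probability of
    follow-up; its inverse weights the ANCOVA. Fitted probabilities below
    ``floor`` are raised to the floor, with the truncation count logged.
    """
    observed = outcome_long[
        (outcome_long["visit_month"] == visit) & outcome_long[outcome].notna()
    ]["participant_id"].unique()
    df = _merge_small_levels(cohort.copy())
    df["_followed"] = df["participant_id"].isin(observed).astype(float)

    if df["_followed"].all():
        logger.info("everyone followed up; IPW reduces to unweighted ANCOVA")
        probs = pd.Series(1.0, index=df.index)
    else:
        usable = [p for p in predictors if df[p].nunique() > 1]
        X = _design_matrix(df, usable, None).drop(columns=["group"])
        Xa = X.to_numpy(dtype=float)
        model = sm.Logit(df["_followed"].to_numpy(), Xa)
        try:
            fit = model.fit(disp=0, maxiter=200)
        except Exception:  # separation / sparse cells: switch solver
            logger.warning("follow-up logistic model ill-conditioned; "
                           "refitting with BFGS")
            fit = model.fit(disp=0, maxiter=500, method="bfgs")
        probs = pd.Series(fit.predict(Xa), index=df.index)

    n_trunc = int((probs < floor).sum())
    if n_trunc:
        logger.warning("%d follow-up probabilities below %.3g truncated", n_trunc, floor)
    probs = probs.clip(lower=floor)
    weights = pd.DataFrame(
        {"participant_id": df["participant_id"], "p_followup": probs,
         "weight": 1.0 / probs}
    )
    wmap = dict(zip(weights["participant_id"], weights["weight"]))
    eff = ancova_effect(outcome_long, cohort, visit, outcome,
                        covariates=covariates, alpha=alpha, weights=wmap)
    return IPWResult(effect=eff, weights=weights, n_truncated=n_trunc)


@dataclass(frozen=True)
class WeightInteractionReport:
    """ANCOVA with and without a group x weight-change interaction term."""

    visit_month: int
    interaction_estimate: float
    interaction_ci_low: float
    interaction_ci_high: float
    interaction_p: float
    effect_with_interaction: EffectEstimate
    effect_without_interaction: EffectEstimate


def weight_interaction(
    outcome_long: pd.DataFrame,
    cohort: pd.DataFrame,
    weights_long: pd.DataFrame,
    visit: int,
    outcome: str = "z",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> WeightInteractionReport:
    """Does weight change at the visit modify the treatment effect?

    ``weights_long``: participant_id, visit_month, weight_kg. Weight change
    is the self-reported weight at the visit minus baseline. Reports the
    interaction estimate/CI/p alongside the no-interaction model.
    """
    w = weights_long.pivot_table(index="participant_id", columns="visit_month",
                                 values="weight_kg")
    if 0 not in w.columns or visit not in w.columns:
        raise ValueError(f"weight data missing at baseline or month {visit}")
    change = (w[visit] - w[0]).rename("weight_change").reset_index()
    if (change["weight_change"].dropna() == 0).all():
        raise ValueError("weight change is zero everywhere; interaction inestimable")

    df = prepare_ancova_frame(outcome_long, cohort, visit, outcome)
    df = df.merge(change, on="participant_id").dropna(subset=["weight_change"])
    df = _merge_small_levels(df).reset_index(drop=True)
    usable = [c for c in covariates if df[c].nunique() > 1]
    X = _design_matrix(df, usable, "baseline_value")
    X["weight_change"] = df["weight_change"].to_numpy(dtype=float)
    y = df["followup_value"].to_numpy(dtype=float)

    def _estimate(Xd, term):
        fit = sm.OLS(y, Xd).fit()
        est, se = float(fit.params[term]), float(fit.bse[term])
        dof = float(fit.df_resid)
        tcrit = stats.t.ppf(1 - alpha / 2, dof)
        p = 2 * stats.t.sf(abs(est) / se, dof) if se > 0 else (0.0 if est != 0 else 1.0)
        return est, se, est - tcrit * se, est + tcrit * se, float(p), len(y)

    e0 = _estimate(X, "group")
    without = EffectEstimate(outcome=outcome, visit_month=visit, estimate=e0[0],
                             se=e0[1], ci_low=e0[2], ci_high=e0[3], p_value=e0[4],
                             n_analyzed=e0[5])
    Xi = X.copy()
    Xi["group:weight_change"] = Xi["group"] * Xi["weight_change"]
    ei = _estimate(Xi, "group:weight_change")
    eg = _estimate(Xi, "group")
    with_int = EffectEstimate(outcome=outcome, visit_month=visit, estimate=eg[0],
                              se=eg[1], ci_low=eg[2], ci_high=eg[3], p_value=eg[4],
                              n_analyzed=eg[5])
    return WeightInteractionReport(
        visit_month=visit, interaction_estimate=ei[0], interaction_ci_low=ei[2],
        interaction_ci_high=ei[3], interaction_p=ei[4],
        effect_with_interaction=with_int, effect_without_interaction=without,
    )
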