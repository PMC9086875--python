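"""One-year QALYs from utility trajectories, with multiple imputation.

Utilities (1 = perfect health, 0 = as bad as dead) are measured at months
1, 6 and 12.  The one-year QALY is the area under the piecewise-linear
utility curve divided by 12 months, with the 1-month utility carried back
to month 0 (the simplest convention for the unmeasured first month).

Missing utilities — common for web-administered questionnaires — are
handled by multiple imputation under a missing-at-random assumption:
sequential Bayesian linear regression per timepoint, fitted separately per
randomisation arm, with baseline covariates (age, sex, index event type,
log peak troponin) and earlier utilities as predictors.  Per-arm fitting
keeps the imputation model from shrinking the between-arm utility contrast.
Arm-level estimates from the m completed datasets are combined with
Rubin's rules.

Utilities themselves come from a preference-based scoring of the SF-36
questionnaire; the scoring algorithm (SF-6D) is licensed and therefore a
pluggable interface here, not an implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import (ARMS, TIMEPOINTS_MONTHS, UTILITY_COLUMNS,
                             PatientRecord, UtilityTrajectory)

#: Trapezoid weights on (u1, u6, u12) for the 0-12 month AUC with u(0) := u1:
#: months 0-1 contribute u1, 1-6 contribute 5*(u1+u6)/2, 6-12 contribute
#: 6*(u6+u12)/2; divide by 12.
_AUC_WEIGHTS = np.array([1.0 + 2.5, 2.5 + 3.0, 3.0]) / 12.0


def qaly_auc(traj: UtilityTrajectory | Sequence[float]) -> float:
    """One-year QALY by the area-under-the-curve method.

    Requires a complete trajectory (run after imputation); raises
    ``ValueError`` on missing values.
    """
    if isinstance(traj, UtilityTrajectory):
        values = traj.as_tuple()
    else:
        values = tuple(traj)
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in values):
        raise ValueError("qaly_auc requires a complete utility trajectory; "
                         "impute missing values first")
    return float(_AUC_WEIGHTS @ np.asarray(values, dtype=float))


def qaly_auc_frame(frame: pd.DataFrame) -> pd.Series:
    """Vectorised QALY for a completed patient-level table."""
    u = frame[list(UTILITY_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(u).any():
        raise ValueError("utility columns contain missing values; impute first")
    return pd.Series(u @ _AUC_WEIGHTS, index=frame.index, name="qaly")


def truncate_at_death(traj: UtilityTrajectory,
                      death_month: float) -> UtilityTrajectory:
    """Set utilities to 0 from the month of death onward (deceased patients
    are retained in the analysis with truncated trajectories)."""
    vals = [0.0 if m >= death_month else v
            for m, v in zip(TIMEPOINTS_MONTHS, traj.as_tuple())]
    return UtilityTrajectory(*vals)


# ---------------------------------------------------------------------------
# Pluggable questionnaire scorer
# ---------------------------------------------------------------------------

#: Maps a dict of questionnaire domain scores to a utility in [0, 1].
UtilityScorer = Callable[[Mapping[str, float]], float]


def sf6d_scorer(domain_scores: Mapping[str, float]) -> float:
    """Placeholder for the licensed SF-36 -> SF-6D utility algorithm.

    The SF-6D scoring model is licensed through the University of Sheffield
    and is not distributed here; utilities enter the pipeline as data.
    """
    raise NotImplementedError(
        "The SF-36 to SF-6D utility algorithm is licensed (University of "
        "Sheffield) and not bundled. Provide pre-scored utilities, or plug "
        "in your own UtilityScorer.")


def toy_linear_scorer(domain_scores: Mapping[str, float]) -> float:
    """SYNTHETIC stand-in scorer for tests only: mean of 0-100 domain scores
    rescaled to [0, 1].  Not a valid preference-based utility."""
    if not domain_scores:
        raise ValueError("no domain scores")
    return float(np.clip(np.mean(list(domain_scores.values())) / 100.0, 0, 1))


# ---------------------------------------------------------------------------
# Multiple imputation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImputationSpec:
    """Settings for the sequential-regression multiple imputation."""

    m: int = 20
    predictors: tuple[str, ...] = ("age", "sex", "index_event", "troponin")
    method: str = "bayes_regression"   # alternative: "pmm"
    pmm_donors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.method not in ("bayes_regression", "pmm"):
            raise ValueError(f"unknown imputation method {self.method!r}")


def _design_matrix(frame: pd.DataFrame, predictors: Sequence[str],
                   extra_cols: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(frame))]
    for p in predictors:
        if p == "age":
            cols.append((frame["age"].to_numpy(float) - 60.0) / 10.0)
        elif p == "sex":
            cols.append((frame["sex"] == "male").to_numpy(float))
        elif p == "index_event":
            cols.append((frame["index_event"] == "STEMI").to_numpy(float))
        elif p == "troponin":
            cols.append(np.log(frame["troponin"].to_numpy(float)))
        else:
            cols.append(frame[p].to_numpy(float))
    for c in extra_cols:
        cols.append(frame[c].to_numpy(float))
    return np.column_stack(cols)


def _bayes_regression_impute(rng: np.random.Generator, X: np.ndarray,
                             y: np.ndarray, obs: np.ndarray,
                             X_mis: np.ndarray) -> np.ndarray:
    """Draw imputations from the posterior predictive of a normal linear
    model with the standard noninformative prior."""
    Xo, yo = X[obs], y[obs]
    n, k = Xo.shape
    XtX = Xo.T @ Xo
    # Ridge-free solve; fall back to pinv for degenerate designs.
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    df = max(n - k, 1)
    s2 = float(resid @ resid) / df
    sigma2_star = s2 * df / rng.chisquare(df)
    # Symmetrise before Cholesky-free sampling via eigh for robustness.
    cov = sigma2_star * (XtX_inv + XtX_inv.T) / 2.0
    beta_star = rng.multivariate_normal(beta_hat, cov, method="svd")
    mu = X_mis @ beta_star
    return mu + np.sqrt(sigma2_star) * rng.standard_normal(len(X_mis))


def _pmm_impute(rng: np.random.Generator, X: np.ndarray, y: np.ndarray,
                obs: np.ndarray, X_mis: np.ndarray, donors: int) -> np.ndarray:
    """Predictive-mean matching: draw each imputation from the observed
    values whose fitted means are closest to the missing case's fitted mean."""
    Xo, yo = X[obs], y[obs]
    beta_hat, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    fit_obs = Xo @ beta_hat
    fit_mis = X_mis @ beta_hat
    out = np.empty(len(X_mis))
    k = min(donors, len(yo))
    for i, f in enumerate(fit_mis):
        nearest = np.argsort(np.abs(fit_obs - f))[:k]
        out[i] = yo[nearest[rng.integers(k)]]
    return out


def impute_utilities(frame: pd.DataFrame,
                     spec: Optional[ImputationSpec] = None
                     ) -> list[pd.DataFrame]:
    """Produce ``m`` completed copies of a patient-level table.

    Missing ``u1,u6,u12`` cells are filled by sequential regression over
    timepoints (earlier utilities join the predictors), fitted separately in
    each arm; draws are clipped to [0, 1].  Observed cells are untouched.
    Refuses with a diagnostic if a timepoint has no observed value in some
    arm.  Reproducible given ``spec.seed``.
    """
    spec = spec or ImputationSpec()
    ucols = list(UTILITY_COLUMNS)
    for arm in frame["arm"].unique():
        sub = frame.loc[frame["arm"] == arm, ucols]
        dead_cols = [c for c in ucols if sub[c].notna().sum() == 0]
        if dead_cols:
            raise ValueError(
                f"cannot impute: timepoint(s) {dead_cols} have no observed "
                f"utility in arm {arm!r}")
    rng = np.random.default_rng(spec.seed)
    completed = []
    for _ in range(spec.m):
        filled = frame.copy()
        for arm in frame["arm"].unique():
            in_arm = (filled["arm"] == arm).to_numpy()
            for j, col in enumerate(ucols):
                y_all = filled.loc[in_arm, col].to_numpy(float)
                missing = np.isnan(frame.loc[in_arm, col].to_numpy(float))
                if not missing.any():
                    continue
                earlier = ucols[:j]
                X = _design_matrix(filled.loc[in_arm], spec.predictors, earlier)
                obs = ~missing
                if spec.method == "pmm":
                    draws = _pmm_impute(rng, X, y_all, obs, X[missing],
                                        spec.pmm_donors)
                else:
                    draws = _bayes_regression_impute(rng, X, y_all, obs,
                                                     X[missing])
                y_all[missing] = np.clip(draws, 0.0, 1.0)
                filled.loc[in_arm, col] = y_all
        completed.append(filled)
    return completed


def impute_records(records: Sequence[PatientRecord],
                   spec: Optional[ImputationSpec] = None
                   ) -> list[pd.DataFrame]:
    """Convenience wrapper: records -> m completed patient-level tables."""
    from .synthetic_data import records_to_frame
    return impute_utilities(records_to_frame(list(records)), spec)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def pool_rubin(point_estimates: Sequence[float],
               within_variances: Sequence[float]) -> tuple[float, float]:
    """Combine estimates from m imputed datasets.

    Pooled estimate = mean of the estimates; total variance = mean
    within-imputation variance + (1 + 1/m) x between-imputation variance.
    """
    q = np.asarray(point_estimates, dtype=float)
    w = np.asarray(within_variances, dtype=float)
    if q.shape != w.shape or q.ndim != 1 or len(q) < 1:
        raise ValueError("need equal-length nonempty estimate/variance lists")
    m = len(q)
    pooled = float(q.mean())
    between = float(q.var(ddof=1)) if m > 1 else 0.0
    total = float(w.mean()) + (1.0 + 1.0 / m) * between
    return pooled, total


def rubin_df(within_mean: float, between: float, m: int) -> float:
    """Rubin's reference t degrees of freedom for a pooled estimate."""
    if m < 2 or between == 0:
        return np.inf
    r = (1.0 + 1.0 / m) * between / within_mean if within_mean > 0 else np.inf
    return (m - 1) * (1.0 + 1.0 / r) ** 2 if np.isfinite(r) else float(m - 1)


@dataclass(frozen=True)
class PooledArmQalys:
    """Arm-level QALY summary pooled over imputations."""

    mean: Mapping[str, float]
    variance: Mapping[str, float]          # variance of the arm mean
    difference: float                      # intervention - control
    ci: tuple[float, float]
    p_value: float


def pooled_arm_qalys(completed: Sequence[pd.DataFrame],
                     alpha: float = 0.05) -> PooledArmQalys:
    """Arm mean QALYs and their difference, Rubin-pooled over the m
    completed datasets; CI and p from the pooled t reference."""
    est: dict[str, list[float]] = {a: [] for a in ARMS}
    wvar: dict[str, list[float]] = {a: [] for a in ARMS}
    diffs, dvars = [], []
    for frame in completed:
        q = qaly_auc_frame(frame)
        arms = frame["arm"]
        per_arm = {}
        for arm in ARMS:
            vals = q[arms == arm]
            est[arm].append(float(vals.mean()))
            wvar[arm].append(float(vals.var(ddof=1)) / len(vals))
            per_arm[arm] = vals
        diffs.append(float(per_arm["intervention"].mean()
                           - per_arm["control"].mean()))
        dvars.append(float(per_arm["intervention"].var(ddof=1))
                     / len(per_arm["intervention"])
                     + float(per_arm["control"].var(ddof=1))
                     / len(per_arm["control"]))
    means, variances = {}, {}
    for arm in ARMS:
        means[arm], variances[arm] = pool_rubin(est[arm], wvar[arm])
    diff, dvar = pool_rubin(diffs, dvars)
    m = len(completed)
    between = float(np.var(diffs, ddof=1)) if m > 1 else 0.0
    df = rubin_df(float(np.mean(dvars)), between, m)
    se = float(np.sqrt(dvar))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df) if np.isfinite(df) \
        else stats.norm.ppf(1.0 - alpha / 2.0)
    p = 2.0 * (stats.t.sf(abs(diff) / se, df) if np.isfinite(df)
               else stats.norm.sf(abs(diff) / se)) if se > 0 else (
        1.0 if diff == 0 else 0.0)
    return PooledArmQalys(mean=means, variance=variances, difference=diff,
                          ci=(diff - tcrit * se, diff + tcrit * se),
                          p_value=float(p))
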