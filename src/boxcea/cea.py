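"""Incremental cost-effectiveness analysis.

Arm contrasts use the convention Δ = intervention − control throughout.
Uncertainty around (Δcost, ΔQALY) is quantified by a nonparametric
bootstrap stratified by randomisation arm (patients resampled with
replacement within each arm at the original arm sizes), cycling over the
multiply-imputed completed datasets.  The cost-effectiveness acceptability
curve (CEAC) is the fraction of bootstrap pairs with positive net monetary
benefit, λ·ΔQALY − ΔCost > 0, as a function of the willingness to pay λ
per QALY; ties count as not cost-effective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import CONTROL, INTERVENTION

#: Default willingness-to-pay grid (EUR/QALY): 0 to 100,000 in steps of 500,
#: covering the Dutch 20,000-80,000 threshold range.
DEFAULT_WTP_GRID = np.arange(0, 100_001, 500, dtype=float)


@dataclass(frozen=True)
class IncrementalResult:
    """Point contrast between arms (intervention − control)."""

    delta_cost: float
    delta_qaly: float
    ci_cost: tuple[float, float]
    ci_qaly: tuple[float, float]
    p_cost: float
    p_qaly: float


@dataclass(frozen=True)
class CEDraws:
    """Paired bootstrap replicates of (Δcost, ΔQALY)."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.delta_cost) != len(self.delta_qaly):
            raise ValueError("cost and QALY draw vectors differ in length")
        if not (np.isfinite(self.delta_cost).all()
                and np.isfinite(self.delta_qaly).all()):
            raise ValueError("bootstrap draws must be finite")

    @property
    def B(self) -> int:
        return len(self.delta_cost)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_cost": self.delta_cost,
                             "delta_qaly": self.delta_qaly})


@dataclass(frozen=True)
class CeacCurve:
    """Probability of cost-effectiveness along a willingness-to-pay grid."""

    wtp_grid: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.wtp_grid) <= 0):
            raise ValueError("WTP grid must be strictly increasing")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid,
                             "probability": self.probability})


def mean_diff_ttest(values_a: Sequence[float], values_b: Sequence[float],
                    alpha: float = 0.05) -> tuple[float, tuple[float, float], float]:
    """Difference in means (a − b) with pooled-variance Student t CI and
    two-sided p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    diff = float(a.mean() - b.mean())
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se = float(np.sqrt(sp2 * (1.0 / na + 1.0 / nb)))
    if se == 0.0:
        return diff, (diff, diff), (1.0 if diff == 0 else 0.0)
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    p = float(2.0 * stats.t.sf(abs(diff) / se, df))
    return diff, (diff - tcrit * se, diff + tcrit * se), p


def bootstrap_ce(completed: Sequence[pd.DataFrame], B: int = 1000,
                 seed: Optional[int] = None) -> CEDraws:
    """Within-arm nonparametric bootstrap of (Δcost, ΔQALY).

    Each completed dataset must carry ``arm``, ``total_cost`` and ``qaly``
    columns.  Replicate ``b`` resamples patients with replacement within
    each arm (at the original arm sizes) from completed dataset
    ``b mod m`` — cycling over the imputations so that imputation
    uncertainty propagates into the draws.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    arrays = []
    for frame in completed:
        by_arm = {}
        for arm in (INTERVENTION, CONTROL):
            sub = frame[frame["arm"] == arm]
            if sub.empty:
                raise ValueError(f"no patients in arm {arm!r}")
            by_arm[arm] = (sub["total_cost"].to_numpy(float),
                           sub["qaly"].to_numpy(float))
        arrays.append(by_arm)
    rng = np.random.default_rng(seed)
    dc = np.empty(B)
    dq = np.empty(B)
    for b in range(B):
        by_arm = arrays[b % len(arrays)]
        means = {}
        for arm, (cost, q) in by_arm.items():
            idx = rng.integers(0, len(cost), size=len(cost))
            means[arm] = (cost[idx].mean(), q[idx].mean())
        dc[b] = means[INTERVENTION][0] - means[CONTROL][0]
        dq[b] = means[INTERVENTION][1] - means[CONTROL][1]
    return CEDraws(delta_cost=dc, delta_qaly=dq, seed=seed)


def nmb(wtp: float, delta_qaly, delta_cost):
    """Incremental net monetary benefit λ·ΔQALY − ΔCost (euros)."""
    if wtp < 0:
        raise ValueError("willingness to pay must be nonnegative")
    return wtp * np.asarray(delta_qaly) - np.asarray(delta_cost)


def ceac(draws: CEDraws, grid: Optional[np.ndarray] = None) -> CeacCurve:
    """Fraction of bootstrap pairs that are cost-effective at each
    willingness to pay (strict NMB > 0; ties are not cost-effective)."""
    if draws.B == 0:
        raise ValueError("no bootstrap draws")
    grid = DEFAULT_WTP_GRID if grid is None else np.asarray(grid, dtype=float)
    benefit = grid[:, None] * draws.delta_qaly[None, :] - draws.delta_cost[None, :]
    prob = (benefit > 0).mean(axis=1)
    return CeacCurve(wtp_grid=grid, probability=prob)


def icer(delta_cost: float, delta_qaly: float) -> tuple[Optional[float], str]:
    """Incremental cost-effectiveness ratio with CE-plane quadrant label.

    Returns ``(ratio_or_None, label)`` where the label is ``dominant``
    (cheaper and more effective), ``dominated`` (costlier and less
    effective), ``undefined`` (ΔQALY = 0) or ``icer``.
    """
    if delta_qaly == 0:
        return None, "undefined"
    if delta_cost < 0 and delta_qaly > 0:
        return None, "dominant"
    if delta_cost > 0 and delta_qaly < 0:
        return None, "dominated"
    return delta_cost / delta_qaly, "icer"


def incremental_from_completed(completed: Sequence[pd.DataFrame]
                               ) -> IncrementalResult:
    """Point incremental result: cost contrast by pooled t-test on the first
    completed dataset's costs (identical across imputations), QALY contrast
    Rubin-pooled over imputations."""
    from .qaly import pooled_arm_qalys

    frame0 = completed[0]
    cost_i = frame0.loc[frame0["arm"] == INTERVENTION, "total_cost"]
    cost_c = frame0.loc[frame0["arm"] == CONTROL, "total_cost"]
    d_cost, ci_cost, p_cost = mean_diff_ttest(cost_i, cost_c)
    pooled = pooled_arm_qalys(completed)
    return IncrementalResult(
        delta_cost=d_cost, delta_qaly=pooled.difference,
        ci_cost=ci_cost, ci_qaly=pooled.ci,
        p_cost=p_cost, p_qaly=pooled.p_value)
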