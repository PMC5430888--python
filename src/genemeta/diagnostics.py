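"""Robustness and small-study diagnostics for a pooled contrast.

* leave-one-out sensitivity analysis (does significance survive omitting any
  single study?),
* cumulative meta-analysis ordered by sample size (how the pooled OR
  stabilizes as evidence accrues),
* Egger's regression and Begg-Mazumdar rank-correlation tests for funnel
  asymmetry / publication bias, plus the funnel-plot data table,
* statistical power of a two-proportion comparison at the pooled sample
  sizes and detectable odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (
    ContrastKind,
    DegenerateInputError,
    EffectEstimate,
    GenotypeStudy,
    InsufficientStudiesError,
    PooledResult,
)
from .effect_measures import build_contrast
from .pooling import I2_THRESHOLD_DEFAULT, pool_auto

__all__ = [
    "EggerResult",
    "BeggResult",
    "PowerSpec",
    "SensitivityResult",
    "CumulativeStep",
    "leave_one_out",
    "cumulative_by_size",
    "egger_test",
    "begg_test",
    "funnel_data",
    "power_two_proportion",
]


@dataclass(frozen=True)
class EggerResult:
    """Egger regression of standardized effect on precision; intercept tests bias."""

    intercept: float
    slope: float
    t_statistic: float
    p_value: float
    df: int
    degenerate: bool = False


@dataclass(frozen=True)
class BeggResult:
    """Begg-Mazumdar rank correlation between standardized deviates and variances."""

    kendall_tau: float
    z: float
    p_value: float


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the two-proportion power calculation.

    ``p0`` is the control-arm exposure probability and ``psi`` the detectable
    odds ratio; ``alpha`` the two-sided significance level.
    """

    n_cases: int
    n_controls: int
    p0: float
    psi: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < 1.0):
            raise DegenerateInputError(f"p0 must be in (0,1), got {self.p0}")
        if self.psi <= 0:
            raise DegenerateInputError(f"psi must be positive, got {self.psi}")
        if min(self.n_cases, self.n_controls) < 1:
            raise DegenerateInputError("sample sizes must be positive")


@dataclass(frozen=True)
class SensitivityResult:
    """Leave-one-out table plus a flag for any significance flip."""

    rows: tuple[tuple[str, PooledResult], ...]
    baseline: PooledResult
    significance_flips: bool


@dataclass(frozen=True)
class CumulativeStep:
    step: int
    added_study_id: str
    included_study_ids: tuple[str, ...]
    result: PooledResult


def leave_one_out(studies: Sequence[GenotypeStudy], contrast: ContrastKind,
                  i2_threshold: float = I2_THRESHOLD_DEFAULT,
                  zero_cell_policy: str = "haldane") -> SensitivityResult:
    """Re-pool the contrast omitting each study in turn.

    The ``significance_flips`` flag is True when any omission changes whether
    the pooled 95% CI excludes 1 relative to the full-set result.
    """
    studies = list(studies)
    if len(studies) < 3:
        raise InsufficientStudiesError("leave-one-out needs at least 3 studies")

    def _pool(subset: Sequence[GenotypeStudy]) -> PooledResult:
        tables = [build_contrast(s, contrast) for s in subset]
        return pool_auto(tables, i2_threshold=i2_threshold,
                         zero_cell_policy=zero_cell_policy)

    baseline = _pool(studies)
    rows = []
    flips = False
    for omit in studies:
        result = _pool([s for s in studies if s is not omit])
        rows.append((omit.study_id, result))
        if result.effect.significant != baseline.effect.significant:
            flips = True
    return SensitivityResult(rows=tuple(rows), baseline=baseline,
                             significance_flips=flips)


def cumulative_by_size(studies: Sequence[GenotypeStudy], contrast: ContrastKind,
                       order: str = "desc",
                       i2_threshold: float = I2_THRESHOLD_DEFAULT,
                       zero_cell_policy: str = "haldane") -> list[CumulativeStep]:
    """Cumulative meta-analysis sorted by total sample size.

    Default order is descending (largest study first, so early steps are the
    most precise); ties break on study_id for determinism.  The final step
    pools the full set and is identical to :func:`pool_auto` on it.
    """
    if not studies:
        raise InsufficientStudiesError("no studies")
    if order not in ("desc", "asc"):
        raise ValueError(f"order must be 'desc' or 'asc', got {order!r}")
    key = (lambda s: (-s.n_total, s.study_id)) if order == "desc" else \
          (lambda s: (s.n_total, s.study_id))
    ranked = sorted(studies, key=key)
    steps = []
    for j in range(1, len(ranked) + 1):
        chosen = {id(s) for s in ranked[:j]}
        # pool in the original supply order so the final step is
        # bit-identical to pooling the full set directly
        included = [s for s in studies if id(s) in chosen]
        tables = [build_contrast(s, contrast) for s in included]
        result = pool_auto(tables, i2_threshold=i2_threshold,
                           zero_cell_policy=zero_cell_policy)
        steps.append(CumulativeStep(
            step=j, added_study_id=ranked[j - 1].study_id,
            included_study_ids=tuple(s.study_id for s in included),
            result=result))
    return steps


def egger_test(estimates: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's linear regression test for funnel-plot asymmetry.

    OLS of the standardized effect ``y_i = theta_i / se_i`` on precision
    ``x_i = 1 / se_i``; the intercept is tested against zero with a two-sided
    t-test on k - 2 df.  A perfect fit (zero residual variance) leaves the
    test degenerate: the intercept is reported, the p-value is NaN.
    """
    k = len(estimates)
    if k < 3:
        raise InsufficientStudiesError("Egger's test needs at least 3 studies")
    theta = np.array([e.log_or for e in estimates])
    se = np.array([e.se_log_or for e in estimates])
    x = 1.0 / se
    y = theta / se
    if np.ptp(x) == 0:
        raise DegenerateInputError("all precisions identical; Egger design is degenerate")
    fit = stats.linregress(x, y)
    if fit.intercept_stderr == 0 or not math.isfinite(fit.intercept_stderr):
        return EggerResult(intercept=float(fit.intercept), slope=float(fit.slope),
                           t_statistic=math.inf if fit.intercept else 0.0,
                           p_value=math.nan, df=k - 2, degenerate=True)
    t = float(fit.intercept / fit.intercept_stderr)
    p = float(2.0 * stats.t.sf(abs(t), k - 2))
    return EggerResult(intercept=float(fit.intercept), slope=float(fit.slope),
                       t_statistic=t, p_value=p, df=k - 2)


def begg_test(estimates: Sequence[EffectEstimate]) -> BeggResult:
    """Begg-Mazumdar rank-correlation test for publication bias.

    Standardized deviates ``u_i = (theta_i - theta_bar) / sqrt(v_i*)`` with
    ``v_i* = se_i^2 - 1/sum(1/se_j^2)`` (variance of the deviation from the
    fixed-effect pool) are rank-correlated with the variances ``se_i^2``.
    tau is Kendall's tau-b (tie-corrected); the normal deviate uses the
    untied null variance ``k(k-1)(2k+5)/18`` on the concordant-discordant
    difference.
    """
    k = len(estimates)
    if k < 3:
        raise InsufficientStudiesError("Begg's test needs at least 3 studies")
    theta = np.array([e.log_or for e in estimates])
    var = np.array([e.se_log_or for e in estimates]) ** 2
    w = 1.0 / var
    pooled = (w * theta).sum() / w.sum()
    v_star = var - 1.0 / w.sum()
    if (v_star <= 0).any():
        raise DegenerateInputError("nonpositive deviate variance; Begg's test undefined")
    u = (theta - pooled) / np.sqrt(v_star)
    tau = float(stats.kendalltau(u, var).statistic)
    if math.isnan(tau):  # all pairs tied in u or in var
        tau = 0.0
    # concordant-minus-discordant over all pairs (ties contribute zero)
    diff = 0
    for i in range(k):
        for j in range(i + 1, k):
            diff += int(np.sign(u[i] - u[j]) * np.sign(var[i] - var[j]))
    z = diff / math.sqrt(k * (k - 1) * (2 * k + 5) / 18.0)
    return BeggResult(kendall_tau=tau, z=float(z),
                      p_value=float(2.0 * stats.norm.sf(abs(z))))


def funnel_data(estimates: Sequence[EffectEstimate]) -> pd.DataFrame:
    """Plotting-ready funnel table: OR, SE of log OR, precision, per study."""
    if not estimates:
        raise InsufficientStudiesError("no estimates")
    return pd.DataFrame({
        "label": [e.label for e in estimates],
        "or": [e.or_ for e in estimates],
        "se_log_or": [e.se_log_or for e in estimates],
        "inverse_se": [1.0 / e.se_log_or for e in estimates],
    })


def power_two_proportion(spec: PowerSpec) -> float:
    """Power of an uncorrected two-sided two-proportion test to detect OR psi.

    The case-arm proportion implied by the odds ratio is
    ``p1 = psi p0 / (1 + p0 (psi - 1))``; power is
    ``Phi((|p1 - p0| - z_{1-alpha/2} sigma0) / sigma1)`` with sigma0 the null
    (pooled-proportion) SE and sigma1 the alternative SE.
    """
    p0 = spec.p0
    p1 = spec.psi * p0 / (1.0 + p0 * (spec.psi - 1.0))
    n1, n0 = spec.n_cases, spec.n_controls
    p_bar = (n1 * p1 + n0 * p0) / (n1 + n0)
    sigma0 = math.sqrt(p_bar * (1 - p_bar) * (1 / n1 + 1 / n0))
    sigma1 = math.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    z_crit = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf((abs(p1 - p0) - z_crit * sigma0) / sigma1))
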