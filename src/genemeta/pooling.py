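"""Fixed- and random-effect pooling of per-study odds ratios.

Fixed effect is the Mantel-Haenszel stratified estimator with the
Robins-Breslow-Greenland (RBG) variance for its log; random effect is
DerSimonian-Laird (DL), the moment estimator of the between-study variance
tau^2 applied to inverse-variance weights.  Heterogeneity is quantified by
Cochran's Q on the per-study Woolf log-OR estimates and Higgins'
I^2 = max(0, (Q - df)/Q) * 100, and the automatic pooler follows the usual
decision rule: random effects when I^2 >= 50%, Mantel-Haenszel otherwise.

Q and I^2 are always computed from the Woolf per-study estimates, whichever
pooling branch is taken, so the heterogeneity column of a summary table does
not depend on the branch.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .data_io import (
    ContrastKind,
    EffectEstimate,
    InsufficientStudiesError,
    PooledResult,
    TwoByTwo,
    UndefinedEstimateError,
)
from .effect_measures import odds_ratio

__all__ = [
    "cochran_q",
    "i_squared",
    "pool_fixed_mh",
    "pool_fixed_iv",
    "pool_random_dl",
    "pool_auto",
]

I2_THRESHOLD_DEFAULT = 50.0


def _theta_se(estimates: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    theta = np.array([e.log_or for e in estimates], dtype=float)
    se = np.array([e.se_log_or for e in estimates], dtype=float)
    return theta, se


def cochran_q(estimates: Sequence[EffectEstimate]) -> tuple[float, int, float]:
    """Cochran's Q of log-OR estimates under inverse-variance weights.

    Returns ``(q, df, p)`` with ``df = k - 1`` and p from chi-square.
    """
    if len(estimates) < 2:
        raise InsufficientStudiesError("Cochran's Q needs at least 2 studies")
    theta, se = _theta_se(estimates)
    w = 1.0 / se**2
    pooled = float((w * theta).sum() / w.sum())
    q = float((w * (theta - pooled) ** 2).sum())
    df = len(estimates) - 1
    return q, df, float(stats.chi2.sf(q, df))


def i_squared(q: float, df: int) -> float:
    """Higgins' I^2 percentage: max(0, (Q - df)/Q) * 100; zero when Q = 0."""
    if q < 0 or df < 1:
        raise ValueError("need q >= 0 and df >= 1")
    if q == 0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def _q_block(estimates: Sequence[EffectEstimate]) -> tuple[float, int, float, float]:
    """(q, df, p, i2) on Woolf estimates; trivial for a single study."""
    if len(estimates) < 2:
        return 0.0, 0, 1.0, 0.0
    q, df, p = cochran_q(estimates)
    return q, df, p, i_squared(q, df)


def _check_tables(tables: Sequence[TwoByTwo]) -> ContrastKind | None:
    if not tables:
        raise InsufficientStudiesError("no tables to pool")
    contrasts = {t.contrast for t in tables}
    if len(contrasts) > 1:
        raise ValueError(f"tables mix contrasts: {sorted(c.name for c in contrasts)}")
    return tables[0].contrast


def pool_fixed_mh(tables: Sequence[TwoByTwo],
                  zero_cell_policy: str = "haldane") -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled OR with RBG variance.

    ``OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i)``; the variance of its
    log follows Robins, Breslow & Greenland.  Per-study weights reported are
    the normalized MH weights ``b_i c_i / n_i``.  Q/I^2 on the Woolf
    estimates are attached for reference.
    """
    contrast = _check_tables(tables)
    cells = np.array([t.cells() for t in tables], dtype=float)
    a, b, c, d = cells.T
    n = cells.sum(axis=1)
    r_i = a * d / n
    s_i = b * c / n
    r_sum, s_sum = r_i.sum(), s_i.sum()
    if r_sum == 0 or s_sum == 0:
        raise UndefinedEstimateError("a whole exposure margin is zero; MH OR undefined")
    log_or = float(np.log(r_sum / s_sum))
    p_i = (a + d) / n
    q_i = (b + c) / n
    var = ((p_i * r_i).sum() / (2 * r_sum**2)
           + ((p_i * s_i + q_i * r_i)).sum() / (2 * r_sum * s_sum)
           + (q_i * s_i).sum() / (2 * s_sum**2))
    estimates = [odds_ratio(t, zero_cell_policy=zero_cell_policy) for t in tables]
    q, df, q_p, i2 = _q_block(estimates)
    effect = EffectEstimate.from_log(log_or, float(np.sqrt(var)), label="MH fixed")
    return PooledResult(
        effect=effect, k=len(tables), q=q, q_df=df, q_p=q_p, i_squared=i2,
        tau_squared=0.0, effect_model="fixed_mh",
        weights=tuple(s_i / s_sum), contrast=contrast,
        study_ids=tuple(t.study_id for t in tables),
    )


def pool_fixed_iv(estimates: Sequence[EffectEstimate],
                  contrast: ContrastKind | None = None,
                  _model_label: str = "fixed_iv") -> PooledResult:
    """Inverse-variance fixed-effect pooling (cross-check alternative to MH)."""
    if not estimates:
        raise InsufficientStudiesError("no estimates to pool")
    theta, se = _theta_se(estimates)
    w = 1.0 / se**2
    log_or = float((w * theta).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    q, df, q_p, i2 = _q_block(estimates)
    effect = EffectEstimate.from_log(log_or, pooled_se, label="IV fixed")
    return PooledResult(
        effect=effect, k=len(estimates), q=q, q_df=df, q_p=q_p, i_squared=i2,
        tau_squared=0.0, effect_model=_model_label,
        weights=tuple(w / w.sum()), contrast=contrast,
        study_ids=tuple(e.label for e in estimates),
    )


def pool_random_dl(estimates: Sequence[EffectEstimate],
                   contrast: ContrastKind | None = None) -> PooledResult:
    """DerSimonian-Laird random-effects pooled OR.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) on fixed
    inverse-variance weights w; the pooled estimate then uses
    w* = 1/(se^2 + tau^2).  With homogeneous estimates (Q <= df) this reduces
    to inverse-variance fixed pooling.
    """
    if len(estimates) < 2:
        raise InsufficientStudiesError("DerSimonian-Laird needs at least 2 studies")
    theta, se = _theta_se(estimates)
    w = 1.0 / se**2
    q, df, q_p = cochran_q(estimates)
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / denom)
    w_star = 1.0 / (se**2 + tau2)
    log_or = float((w_star * theta).sum() / w_star.sum())
    pooled_se = float(1.0 / np.sqrt(w_star.sum()))
    effect = EffectEstimate.from_log(log_or, pooled_se, label="DL random")
    return PooledResult(
        effect=effect, k=len(estimates), q=q, q_df=df, q_p=q_p,
        i_squared=i_squared(q, df), tau_squared=tau2, effect_model="random_dl",
        weights=tuple(w_star / w_star.sum()), contrast=contrast,
        study_ids=tuple(e.label for e in estimates),
    )


def pool_auto(tables: Sequence[TwoByTwo],
              i2_threshold: float = I2_THRESHOLD_DEFAULT,
              zero_cell_policy: str = "haldane") -> PooledResult:
    """Pool with the I^2-driven branch rule.

    Computes Q/I^2 on the Woolf per-study estimates; returns DerSimonian-Laird
    random effects when I^2 >= ``i2_threshold`` (percent), else Mantel-Haenszel
    fixed effect.  A single table pools to its own crude OR.
    """
    contrast = _check_tables(tables)
    estimates = [odds_ratio(t, zero_cell_policy=zero_cell_policy) for t in tables]
    _, _, _, i2 = _q_block(estimates)
    if len(tables) >= 2 and i2 >= i2_threshold:
        return pool_random_dl(estimates, contrast=contrast)
    return pool_fixed_mh(tables, zero_cell_policy=zero_cell_policy)
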