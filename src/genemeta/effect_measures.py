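"""Per-study effect measures: 2x2 contrast tables, odds ratios, HWE tests.

A genotype contrast collapses a study's 3x2 genotype-by-status counts into a
2x2 exposure table; the per-study odds ratio is then ``ad/bc`` with the Woolf
(logit) standard error ``sqrt(1/a + 1/b + 1/c + 1/d)``.

The Hardy-Weinberg test screens each study's control genotype distribution:
under random mating the genotype proportions are q^2, 2q(1-q), (1-q)^2 for
mutant-allele frequency q, and a deviating control group (p < 0.05) signals
genotyping or sampling problems.  The default is the asymptotic three-cell
chi-square with 1 df and no continuity correction; a conditional exact test
is available via ``method="exact"``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .data_io import (
    ContrastKind,
    DegenerateInputError,
    EffectEstimate,
    GenotypeStudy,
    HweResult,
    TwoByTwo,
    UndefinedEstimateError,
)

__all__ = ["hwe_test", "build_contrast", "odds_ratio", "ALL_CONTRASTS"]

ALL_CONTRASTS = tuple(ContrastKind)


def hwe_test(ctrl_mm: int, ctrl_mw: int, ctrl_ww: int, method: str = "chi2") -> HweResult:
    """Test a control genotype triple for Hardy-Weinberg equilibrium.

    Parameters
    ----------
    ctrl_mm, ctrl_mw, ctrl_ww
        Control counts of the homozygous-mutant, heterozygous and wild-type
        genotypes.
    method
        ``"chi2"`` (default): Pearson chi-square over the three genotype
        cells against expected counts n*q^2, n*2q(1-q), n*(1-q)^2, 1 df, no
        continuity correction.  ``"exact"``: conditional exact test summing
        the probabilities of all heterozygote counts no more likely than the
        observed one, given n and the minor-allele count.
    """
    if min(ctrl_mm, ctrl_mw, ctrl_ww) < 0:
        raise DegenerateInputError("genotype counts must be non-negative")
    n = ctrl_mm + ctrl_mw + ctrl_ww
    if n == 0:
        raise DegenerateInputError("control total is zero")
    q = (2 * ctrl_mm + ctrl_mw) / (2 * n)
    expected = (n * q * q, n * 2 * q * (1 - q), n * (1 - q) ** 2)
    if q in (0.0, 1.0):
        # monomorphic sample: the HWE fit is vacuous
        return HweResult(chi2=0.0, p_value=1.0, expected_counts=expected,
                         minor_allele_freq=min(q, 1 - q), monomorphic=True)
    obs = np.array([ctrl_mm, ctrl_mw, ctrl_ww], dtype=float)
    exp = np.array(expected)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    if method == "chi2":
        p = float(stats.chi2.sf(chi2, 1))
    elif method == "exact":
        p = _hwe_exact_p(ctrl_mm, ctrl_mw, ctrl_ww)
    else:
        raise ValueError(f"unknown HWE method {method!r}")
    return HweResult(chi2=chi2, p_value=p, expected_counts=expected,
                     minor_allele_freq=min(q, 1 - q))


def _hwe_exact_p(mm: int, mw: int, ww: int) -> float:
    """Conditional exact HWE p-value (sum of outcomes as or less probable)."""
    n = mm + mw + ww
    n_rare = 2 * mm + mw
    if n_rare > n:  # condition on the rarer allele
        mm, ww = ww, mm
        n_rare = 2 * mm + mw
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    homs_r = (n_rare - hets) // 2
    homs_c = n - hets - homs_r
    # P(het = h | n, n_rare) up to a common constant, in logs
    logp = (hets * math.log(2) - gammaln(homs_r + 1) - gammaln(hets + 1)
            - gammaln(homs_c + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[np.nonzero(hets == mw)[0][0]]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def build_contrast(study: GenotypeStudy, contrast: ContrastKind) -> TwoByTwo:
    """Collapse a study's genotype counts into the 2x2 table of a contrast.

    Rows are case/control status, columns are exposed/reference per the
    contrast definition; e.g. ``RECESSIVE`` exposes MM against MW+WW, and
    ``ALLELIC`` counts alleles (two per subject).
    """
    cm, ch, cw = study.case_mm, study.case_mw, study.case_ww
    km, kh, kw = study.ctrl_mm, study.ctrl_mw, study.ctrl_ww
    if contrast is ContrastKind.MM_VS_WW:
        cells = (cm, cw, km, kw)
    elif contrast is ContrastKind.MW_VS_WW:
        cells = (ch, cw, kh, kw)
    elif contrast is ContrastKind.MM_VS_MW:
        cells = (cm, ch, km, kh)
    elif contrast is ContrastKind.DOMINANT:
        cells = (cm + ch, cw, km + kh, kw)
    elif contrast is ContrastKind.RECESSIVE:
        cells = (cm, ch + cw, km, kh + kw)
    elif contrast is ContrastKind.ALLELIC:
        cells = (2 * cm + ch, 2 * cw + ch, 2 * km + kh, 2 * kw + kh)
    elif contrast is ContrastKind.OVERDOMINANT:
        cells = (ch, cm + cw, kh, km + kw)
    else:  # pragma: no cover - closed enumeration
        raise ValueError(f"unknown contrast {contrast!r}")
    return TwoByTwo(*map(float, cells), contrast=contrast, study_id=study.study_id)


def odds_ratio(table: TwoByTwo, zero_cell_policy: str = "haldane") -> EffectEstimate:
    """Crude odds ratio of a 2x2 table with Woolf CI and Z-test p-value.

    With a single zero cell the Haldane-Anscombe correction (default policy)
    adds 0.5 to all four cells and flags the estimate; policy ``"error"``
    raises instead.  Two or more zero cells, or an empty margin, leave the OR
    undefined regardless of policy.
    """
    a, b, c, d = table.cells()
    zeros = sum(x == 0 for x in (a, b, c, d))
    if zeros >= 2:
        raise UndefinedEstimateError(f"{table.study_id}: {zeros} zero cells, OR undefined")
    for margin, name in (((a + b), "case"), ((c + d), "control"),
                         ((a + c), "exposed"), ((b + d), "reference")):
        if margin == 0:
            raise UndefinedEstimateError(f"{table.study_id}: empty {name} margin")
    continuity = False
    if zeros == 1:
        if zero_cell_policy == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            continuity = True
        elif zero_cell_policy == "error":
            raise UndefinedEstimateError(f"{table.study_id}: zero cell with policy 'error'")
        else:
            raise ValueError(f"unknown zero_cell_policy {zero_cell_policy!r}")
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate.from_log(log_or, se, label=table.study_id,
                                   continuity_applied=continuity)
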