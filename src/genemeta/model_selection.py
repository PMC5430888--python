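"""Inheritance-model selection from the pairwise genotype odds ratios.

The decision procedure (after Thakkinstian's multiple-comparison scheme)
classifies the three pooled pairwise contrasts -- OR1 = MM vs WW,
OR2 = MW vs WW, OR3 = MM vs MW -- as significant risk (+) or not (-) and maps
the pattern to a mode of inheritance:

====================  ====  ====  ====
model                 OR1   OR2   OR3
====================  ====  ====  ====
dominant               +     +     -
recessive              +     -     +
complete overdominant  -     +     +   (OR2 a lesser risk than OR1 and OR3)
codominant             ++    +     +   (OR1's effect exceeds OR2 and OR3)
====================  ====  ====  ====

Any other pattern is undetermined, in which case all candidate genetic models
are pooled instead (:func:`fallback_all_models`).

Borderline evidence is handled by a second pass: estimates with
alpha <= p < alpha_marginal (default 0.05 <= p < 0.10) are classed MARGINAL,
ignored in the strict first pass, and promoted to ``+`` only if the strict
pass is undetermined.  This keeps clear-cut decisions free of marginal logic
while still allowing a model call when two contrasts sit just above alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .data_io import (
    ConsistencyError,
    ContrastKind,
    EffectEstimate,
    GenotypeStudy,
    PooledResult,
)
from .effect_measures import build_contrast
from .pooling import I2_THRESHOLD_DEFAULT, pool_auto

__all__ = [
    "SignificanceClass",
    "GeneticModel",
    "ModelDecision",
    "classify_effect",
    "select_model",
    "fallback_all_models",
    "FALLBACK_CONTRASTS",
    "MODEL_HEADLINE_CONTRAST",
]


class SignificanceClass(Enum):
    SIG_RISK = "+"        # p < alpha and OR > 1
    SIG_PROTECT = "p"     # p < alpha and OR < 1
    MARGINAL = "m"        # alpha <= p < alpha_marginal
    NONSIG = "-"          # p >= alpha_marginal


class GeneticModel(Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    COMPLETE_OVERDOMINANT = "complete_overdominant"
    CODOMINANT = "codominant"
    UNDETERMINED = "undetermined"


#: contrast pooled when reporting the headline result of a decided model
MODEL_HEADLINE_CONTRAST = {
    GeneticModel.DOMINANT: ContrastKind.DOMINANT,
    GeneticModel.RECESSIVE: ContrastKind.RECESSIVE,
    GeneticModel.COMPLETE_OVERDOMINANT: ContrastKind.OVERDOMINANT,
    GeneticModel.CODOMINANT: ContrastKind.MM_VS_WW,
}

#: the candidate models pooled when no single model can be determined
FALLBACK_CONTRASTS = (
    ContrastKind.MM_VS_WW,
    ContrastKind.MW_VS_WW,
    ContrastKind.MM_VS_MW,
    ContrastKind.ALLELIC,
    ContrastKind.DOMINANT,
    ContrastKind.RECESSIVE,
)


@dataclass(frozen=True)
class ModelDecision:
    """Outcome of the decision rules for one SNP."""

    pattern: tuple[SignificanceClass, SignificanceClass, SignificanceClass]
    model: GeneticModel
    marginal_used: bool
    rationale: str

    @property
    def pattern_string(self) -> str:
        return ",".join("+" if c is SignificanceClass.SIG_RISK else
                        "m" if c is SignificanceClass.MARGINAL else "-"
                        for c in self.pattern)


def classify_effect(estimate: EffectEstimate, alpha: float = 0.05,
                    alpha_marginal: float = 0.10) -> SignificanceClass:
    """Classify one estimate by its Z-test p-value and effect direction."""
    if estimate.p_value < alpha:
        return (SignificanceClass.SIG_RISK if estimate.or_ > 1.0
                else SignificanceClass.SIG_PROTECT)
    if estimate.p_value < alpha_marginal:
        return SignificanceClass.MARGINAL
    return SignificanceClass.NONSIG


def _match_pattern(plus: tuple[bool, bool, bool],
                   effects: tuple[EffectEstimate, EffectEstimate, EffectEstimate],
                   ) -> GeneticModel:
    or1, or2, or3 = effects
    if plus == (True, True, False):
        return GeneticModel.DOMINANT
    if plus == (True, False, True):
        return GeneticModel.RECESSIVE
    if plus == (False, True, True):
        # heterozygote risk must sit below both homozygote comparisons
        if abs(or2.log_or) < abs(or1.log_or) and abs(or2.log_or) < abs(or3.log_or):
            return GeneticModel.COMPLETE_OVERDOMINANT
        return GeneticModel.UNDETERMINED
    if plus == (True, True, True):
        # codominant requires the homozygote effect to dominate (OR1 = ++)
        if abs(or1.log_or) > abs(or2.log_or) and abs(or1.log_or) > abs(or3.log_or):
            return GeneticModel.CODOMINANT
        return GeneticModel.UNDETERMINED
    return GeneticModel.UNDETERMINED


def select_model(or1: PooledResult, or2: PooledResult, or3: PooledResult,
                 alpha: float = 0.05, alpha_marginal: float = 0.10,
                 policy: str = "two_pass") -> ModelDecision:
    """Map the significance pattern of (OR1, OR2, OR3) to an inheritance model.

    The three pooled results must come from the same study set (checked).
    Policy ``"two_pass"`` (default) first evaluates strictly at ``alpha``;
    only if that is undetermined are MARGINAL contrasts re-read as ``+``.
    Policy ``"strict"`` performs the first pass only.
    """
    expected = [
        (or1, ContrastKind.MM_VS_WW),
        (or2, ContrastKind.MW_VS_WW),
        (or3, ContrastKind.MM_VS_MW),
    ]
    for pooled, kind in expected:
        if pooled.contrast is not None and pooled.contrast is not kind:
            raise ConsistencyError(
                f"expected contrast {kind.name}, got {pooled.contrast.name}")
    study_sets = {frozenset(r.study_ids) for r in (or1, or2, or3) if r.study_ids}
    if len(study_sets) > 1:
        raise ConsistencyError("OR1/OR2/OR3 were pooled over different study sets")
    if policy not in ("two_pass", "strict"):
        raise ValueError(f"unknown policy {policy!r}")

    effects = (or1.effect, or2.effect, or3.effect)
    pattern = tuple(classify_effect(e, alpha, alpha_marginal) for e in effects)

    # "+" counts significance in either direction so the rules are symmetric
    # under relabeling which homozygote is the mutant (risk ORs invert to
    # significant protective ORs; magnitude clauses compare |log OR|)
    strict_plus = tuple(
        c in (SignificanceClass.SIG_RISK, SignificanceClass.SIG_PROTECT)
        for c in pattern)
    model = _match_pattern(strict_plus, effects)
    marginal_used = False
    if (model is GeneticModel.UNDETERMINED and policy == "two_pass"
            and SignificanceClass.MARGINAL in pattern):
        lenient_plus = tuple(
            c is not SignificanceClass.NONSIG  # MARGINAL promoted to "+"
            for c in pattern)
        lenient = _match_pattern(lenient_plus, effects)
        if lenient is not GeneticModel.UNDETERMINED:
            model = lenient
            marginal_used = True

    rationale = (f"pattern ({','.join(c.name for c in pattern)}) -> {model.value}"
                 + (" via marginal second pass" if marginal_used else ""))
    return ModelDecision(pattern=pattern, model=model,
                         marginal_used=marginal_used, rationale=rationale)


def fallback_all_models(studies: Sequence[GenotypeStudy], snp_id: str,
                        i2_threshold: float = I2_THRESHOLD_DEFAULT,
                        zero_cell_policy: str = "haldane",
                        ) -> dict[ContrastKind, PooledResult]:
    """Pool every candidate genetic model when no single one is determined.

    Runs :func:`pool_auto` over the six contrasts in :data:`FALLBACK_CONTRASTS`
    for the studies of ``snp_id``.
    """
    subset = [s for s in studies if s.snp_id == snp_id]
    if not subset:
        raise ValueError(f"no studies for snp_id {snp_id!r}")
    out: dict[ContrastKind, PooledResult] = {}
    for contrast in FALLBACK_CONTRASTS:
        tables = [build_contrast(s, contrast) for s in subset]
        out[contrast] = pool_auto(tables, i2_threshold=i2_threshold,
                                  zero_cell_policy=zero_cell_policy)
    return out
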