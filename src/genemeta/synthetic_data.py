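"""Synthetic multi-study case-control genotype collections with known truth.

Controls are drawn from a population in Hardy-Weinberg proportions at a
configurable mutant-allele frequency; an inbreeding-style coefficient ``f``
can distort those proportions to emulate HWE violation.  Cases re-weight the
control genotype distribution by per-genotype odds multipliers implied by the
chosen inheritance model and an odds-ratio effect (a prospective
approximation of the retrospective design -- valid for OR-based truth because
the odds ratio is invariant to outcome-based sampling).  Between-study
heterogeneity enters as a normal perturbation of the per-study log OR with
standard deviation ``tau``, matching the random-effects model under test.

Every collection is reproducible from ``seed``; per-study substreams are
derived from (seed, study index) so studies are independent and stable under
any evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeStudy

__all__ = ["SimulationConfig", "genotype_probs", "case_probs", "simulate_collection"]

MODELS = ("dominant", "recessive", "codominant_multiplicative", "overdominant", "null")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings for one collection of case-control studies.

    ``case_n``/``ctrl_n`` are either fixed per-study sizes or ``(lo, hi)``
    ranges sampled uniformly per study.  ``or_effect`` is the genotype-level
    odds ratio applied according to ``model``; ``tau`` the between-study SD
    of the log OR; ``hwe_violation_f`` an inbreeding-style distortion of the
    control genotype proportions (0 = exact HWE).
    """

    n_studies: int = 8
    case_n: int | tuple[int, int] = 500
    ctrl_n: int | tuple[int, int] = 500
    maf: float = 0.3
    model: str = "null"
    or_effect: float = 1.0
    tau: float = 0.0
    hwe_violation_f: float = 0.0
    seed: int = 0
    snp_id: str = "rsSIM"

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if not (0.0 < self.maf < 1.0):
            raise ValueError("maf must be in (0,1)")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.or_effect <= 0:
            raise ValueError("or_effect must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        genotype_probs(self.maf, self.hwe_violation_f)  # validates f


def genotype_probs(maf: float, hwe_violation_f: float = 0.0) -> tuple[float, float, float]:
    """Control genotype probabilities (p_mm, p_mw, p_ww).

    With inbreeding coefficient f: ``p_mm = q^2 + f q(1-q)``,
    ``p_mw = 2q(1-q)(1-f)``, ``p_ww = (1-q)^2 + f q(1-q)``; f = 0 recovers
    Hardy-Weinberg proportions.  Raises if any cell probability is negative.
    """
    q = maf
    f = hwe_violation_f
    probs = (q * q + f * q * (1 - q),
             2 * q * (1 - q) * (1 - f),
             (1 - q) ** 2 + f * q * (1 - q))
    if min(probs) < 0:
        raise ValueError(f"f={f} makes a genotype probability negative at maf={q}")
    return probs


def case_probs(control_probs: tuple[float, float, float], model: str,
               or_study: float) -> tuple[float, float, float]:
    """Case genotype probabilities: controls re-weighted by per-genotype odds.

    Odds multipliers (MM, MW, WW): dominant (or, or, 1); recessive
    (or, 1, 1); codominant_multiplicative (or^2, or, 1); overdominant
    (1, or, 1); null (1, 1, 1).  The product is renormalized to a simplex.
    """
    if or_study <= 0:
        raise ValueError("or_study must be positive")
    multipliers = {
        "dominant": (or_study, or_study, 1.0),
        "recessive": (or_study, 1.0, 1.0),
        "codominant_multiplicative": (or_study**2, or_study, 1.0),
        "overdominant": (1.0, or_study, 1.0),
        "null": (1.0, 1.0, 1.0),
    }[model]
    raw = [p * m for p, m in zip(control_probs, multipliers)]
    total = sum(raw)
    return tuple(p / total for p in raw)


def _draw_size(rng: np.random.Generator, size: int | tuple[int, int]) -> int:
    if isinstance(size, tuple):
        lo, hi = size
        return int(rng.integers(lo, hi + 1))
    return int(size)


def simulate_collection(config: SimulationConfig) -> list[GenotypeStudy]:
    """Generate one multi-study collection under the configured truth."""
    ctrl_probs = genotype_probs(config.maf, config.hwe_violation_f)
    log_or = math.log(config.or_effect)
    studies = []
    for i in range(config.n_studies):
        rng = np.random.default_rng([config.seed, i])
        study_log_or = rng.normal(log_or, config.tau) if config.tau > 0 else log_or
        n_case = _draw_size(rng, config.case_n)
        n_ctrl = _draw_size(rng, config.ctrl_n)
        cprobs = case_probs(ctrl_probs, config.model, math.exp(study_log_or))
        case_counts = rng.multinomial(n_case, cprobs)
        ctrl_counts = rng.multinomial(n_ctrl, ctrl_probs)
        studies.append(GenotypeStudy(
            study_id=f"sim{i:03d}",
            first_author=f"Sim{i:03d}",
            year=2000 + i,
            snp_id=config.snp_id,
            case_mm=int(case_counts[0]), case_mw=int(case_counts[1]),
            case_ww=int(case_counts[2]),
            ctrl_mm=int(ctrl_counts[0]), ctrl_mw=int(ctrl_counts[1]),
            ctrl_ww=int(ctrl_counts[2]),
            metadata={"true_log_or": f"{study_log_or:.6f}", "model": config.model},
        ))
    return studies
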