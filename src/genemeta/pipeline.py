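"""End-to-end per-SNP analysis and full-run orchestration.

For each SNP the pipeline (mirroring how such meta-analyses are reported):

1. tests each study's controls for Hardy-Weinberg equilibrium;
2. pools the three pairwise contrasts OR1/OR2/OR3 with the automatic
   fixed/random branch rule;
3. applies the inheritance-model decision rules;
4. pools the suggested model's contrast (or all six candidate models when
   undetermined);
5. runs leave-one-out sensitivity and cumulative-by-size meta-analysis on the
   headline contrast;
6. runs Egger's and Begg's publication-bias tests and emits funnel data;
7. computes the power of the pooled comparison to detect the pooled OR.

Studies deviating from HWE are flagged, not excluded, by default (the
paper-style analysis pools everything and probes HWE deviators via the
sensitivity analysis); ``hwe_policy="exclude"`` drops them before pooling.
Diagnostics requiring at least 3 studies are skipped, with a logged notice,
for smaller collections.
"""

from __future__ import annotations

import dataclasses
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import __version__
from .data_io import (
    ContrastKind,
    GenotypeStudy,
    InsufficientStudiesError,
    PooledResult,
    parse_studies,
    studies_to_csv,
    write_report,
)
from .diagnostics import (
    PowerSpec,
    cumulative_by_size,
    egger_test,
    funnel_data,
    begg_test,
    leave_one_out,
    power_two_proportion,
)
from .effect_measures import build_contrast, hwe_test, odds_ratio
from .model_selection import (
    FALLBACK_CONTRASTS,
    GeneticModel,
    MODEL_HEADLINE_CONTRAST,
    ModelDecision,
    fallback_all_models,
    select_model,
)
from .pooling import I2_THRESHOLD_DEFAULT, pool_auto
from .synthetic_data import SimulationConfig, simulate_collection

__all__ = ["AnalysisConfig", "SnpReport", "run_snp_analysis", "run_full"]

log = logging.getLogger("genemeta")

PAIRWISE = (ContrastKind.MM_VS_WW, ContrastKind.MW_VS_WW, ContrastKind.MM_VS_MW)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the analysis pipeline."""

    alpha: float = 0.05
    marginal_alpha: float = 0.10
    i2_threshold: float = I2_THRESHOLD_DEFAULT
    cumulative_order: str = "desc"
    hwe_policy: str = "flag"            # "flag" | "exclude"
    zero_cell_policy: str = "haldane"
    selection_policy: str = "two_pass"  # "two_pass" | "strict"

    def __post_init__(self) -> None:
        if self.hwe_policy not in ("flag", "exclude"):
            raise ValueError(f"hwe_policy must be 'flag' or 'exclude', got {self.hwe_policy!r}")


@dataclass
class SnpReport:
    """Structured per-SNP analysis result."""

    snp_id: str
    k: int
    n_cases: int
    n_controls: int
    hwe: dict[str, dict]
    hwe_deviating: list[str]
    pairwise: dict[str, PooledResult]
    decision: ModelDecision
    headline_contrast: ContrastKind
    headline: PooledResult
    fallback: dict[str, PooledResult] | None
    sensitivity: dict | None
    cumulative: list[dict] | None
    egger: dict | None
    begg: dict | None
    funnel: list[dict]
    power: float

    def to_dict(self) -> dict:
        pooled_rows = []

        def _row(contrast: ContrastKind, result: PooledResult, suggested: bool) -> dict:
            e = result.effect
            return {
                "contrast": contrast.value,
                "k": result.k,
                "i_squared": round(result.i_squared, 4),
                "effect_model": result.effect_model,
                "or": e.or_, "ci_low": e.ci_low, "ci_high": e.ci_high,
                "p_value": e.p_value,
                "tau_squared": result.tau_squared,
                "q": result.q, "q_df": result.q_df,
                "weights": list(result.weights),
                "study_ids": list(result.study_ids),
                "suggested": suggested,
            }

        seen = set()
        for name, res in self.pairwise.items():
            kind = ContrastKind[name]
            pooled_rows.append(_row(kind, res, suggested=False))
            seen.add(kind)
        if self.fallback is not None:
            for name, res in self.fallback.items():
                kind = ContrastKind[name]
                if kind not in seen:
                    pooled_rows.append(_row(kind, res, suggested=False))
                    seen.add(kind)
        if self.headline_contrast not in seen:
            pooled_rows.append(_row(self.headline_contrast, self.headline, suggested=True))
        else:
            for row in pooled_rows:
                if row["contrast"] == self.headline_contrast.value:
                    row["suggested"] = True
        egger = dict(self.egger) if self.egger else None
        if egger:
            for row in pooled_rows:
                if row["suggested"]:
                    row["egger_t"] = egger.get("t_statistic")
                    row["egger_p"] = egger.get("p_value")
                    row["power"] = self.power
        return {
            "snp_id": self.snp_id,
            "k": self.k,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "hwe": self.hwe,
            "hwe_deviating": self.hwe_deviating,
            "decision": {
                "pattern": self.decision.pattern_string,
                "model": self.decision.model.value,
                "marginal_used": self.decision.marginal_used,
                "rationale": self.decision.rationale,
            },
            "headline_contrast": self.headline_contrast.value,
            "pooled": pooled_rows,
            "sensitivity": self.sensitivity,
            "cumulative": self.cumulative,
            "egger": egger,
            "begg": dict(self.begg) if self.begg else None,
            "funnel": self.funnel,
            "power": self.power,
        }


def _exposed_control_fraction(studies: Sequence[GenotypeStudy],
                              contrast: ContrastKind) -> float:
    """Pooled control-arm frequency of the contrast's exposed class."""
    c = sum(build_contrast(s, contrast).c for s in studies)
    d = sum(build_contrast(s, contrast).d for s in studies)
    return c / (c + d)


def run_snp_analysis(studies: Sequence[GenotypeStudy], snp_id: str,
                     config: AnalysisConfig | None = None) -> SnpReport:
    """Run the full analysis sequence for one SNP."""
    config = config or AnalysisConfig()
    subset = [s for s in studies if s.snp_id == snp_id]
    if not subset:
        raise ValueError(f"no studies for snp_id {snp_id!r}")

    # (1) HWE screen on controls
    hwe_results, deviating = {}, []
    for s in subset:
        res = hwe_test(s.ctrl_mm, s.ctrl_mw, s.ctrl_ww)
        hwe_results[s.study_id] = {
            "chi2": res.chi2, "p_value": res.p_value,
            "minor_allele_freq": res.minor_allele_freq,
            "deviates": res.deviates,
        }
        if res.deviates:
            deviating.append(s.study_id)
            log.info("%s: controls of %s deviate from HWE (p=%.4g)",
                     snp_id, s.study_id, res.p_value)
    analysed = subset
    if config.hwe_policy == "exclude" and deviating:
        analysed = [s for s in subset if s.study_id not in deviating]
        log.info("%s: excluding %d HWE-deviating studies", snp_id, len(deviating))
        if not analysed:
            raise InsufficientStudiesError(f"{snp_id}: all studies fail the HWE screen")

    def _pool(contrast: ContrastKind) -> PooledResult:
        tables = [build_contrast(s, contrast) for s in analysed]
        return pool_auto(tables, i2_threshold=config.i2_threshold,
                         zero_cell_policy=config.zero_cell_policy)

    # (2) pairwise contrasts and (3) model decision
    pairwise = {c.name: _pool(c) for c in PAIRWISE}
    decision = select_model(
        pairwise[ContrastKind.MM_VS_WW.name],
        pairwise[ContrastKind.MW_VS_WW.name],
        pairwise[ContrastKind.MM_VS_MW.name],
        alpha=config.alpha, alpha_marginal=config.marginal_alpha,
        policy=config.selection_policy)
    log.info("%s: %s", snp_id, decision.rationale)

    # (4) headline pooling, or the six-model fallback
    fallback = None
    if decision.model is GeneticModel.UNDETERMINED:
        fb = fallback_all_models(analysed, snp_id,
                                 i2_threshold=config.i2_threshold,
                                 zero_cell_policy=config.zero_cell_policy)
        fallback = {c.name: r for c, r in fb.items()}
        headline_contrast = ContrastKind.ALLELIC
        headline = fb[headline_contrast]
        log.info("%s: undetermined model; pooled %d candidate models",
                 snp_id, len(FALLBACK_CONTRASTS))
    else:
        headline_contrast = MODEL_HEADLINE_CONTRAST[decision.model]
        headline = _pool(headline_contrast)
        log.info("%s: headline %s OR=%.3f (%.3f, %.3f) [%s]",
                 snp_id, headline_contrast.value, headline.effect.or_,
                 headline.effect.ci_low, headline.effect.ci_high,
                 headline.effect_model)

    # (5)-(6) diagnostics on the headline contrast
    headline_estimates = [
        odds_ratio(build_contrast(s, headline_contrast),
                   zero_cell_policy=config.zero_cell_policy)
        for s in analysed
    ]
    sensitivity = cumulative = egger = begg = None
    if len(analysed) >= 3:
        sens = leave_one_out(analysed, headline_contrast,
                             i2_threshold=config.i2_threshold,
                             zero_cell_policy=config.zero_cell_policy)
        sensitivity = {
            "significance_flips": sens.significance_flips,
            "rows": [{"omitted": sid,
                      "or": r.effect.or_, "ci_low": r.effect.ci_low,
                      "ci_high": r.effect.ci_high, "p_value": r.effect.p_value,
                      "effect_model": r.effect_model}
                     for sid, r in sens.rows],
        }
        eg = egger_test(headline_estimates)
        egger = {"intercept": eg.intercept, "slope": eg.slope,
                 "t_statistic": eg.t_statistic, "p_value": eg.p_value,
                 "df": eg.df, "degenerate": eg.degenerate}
        bg = begg_test(headline_estimates)
        begg = {"kendall_tau": bg.kendall_tau, "z": bg.z, "p_value": bg.p_value}
    else:
        log.info("%s: k=%d < 3, skipping sensitivity and bias diagnostics",
                 snp_id, len(analysed))
    steps = cumulative_by_size(analysed, headline_contrast,
                               order=config.cumulative_order,
                               i2_threshold=config.i2_threshold,
                               zero_cell_policy=config.zero_cell_policy)
    cumulative = [{"step": st.step, "added": st.added_study_id,
                   "or": st.result.effect.or_,
                   "ci_low": st.result.effect.ci_low,
                   "ci_high": st.result.effect.ci_high,
                   "effect_model": st.result.effect_model}
                  for st in steps]

    funnel = funnel_data(headline_estimates).to_dict(orient="records")

    # (7) power at the pooled totals to detect the pooled OR
    n_cases = sum(s.n_cases for s in analysed)
    n_controls = sum(s.n_controls for s in analysed)
    p0 = _exposed_control_fraction(analysed, headline_contrast)
    power = power_two_proportion(PowerSpec(
        n_cases=n_cases, n_controls=n_controls, p0=p0,
        psi=headline.effect.or_, alpha=config.alpha))
    log.info("%s: power %.3f at OR=%.3f, p0=%.4f", snp_id, power,
             headline.effect.or_, p0)

    return SnpReport(
        snp_id=snp_id, k=len(analysed), n_cases=n_cases, n_controls=n_controls,
        hwe=hwe_results, hwe_deviating=deviating, pairwise=pairwise,
        decision=decision, headline_contrast=headline_contrast,
        headline=headline, fallback=fallback, sensitivity=sensitivity,
        cumulative=cumulative, egger=egger, begg=begg, funnel=funnel,
        power=power)


def run_full(input_path: str | Path | None, out_dir: str | Path,
             config: AnalysisConfig | None = None,
             simulation: SimulationConfig | None = None,
             seed: int | None = None) -> dict:
    """Analyze a study table (or a simulated one) and write the run outputs.

    Writes ``report.json``, ``summary.tsv``, ``funnel.tsv``,
    ``cumulative.tsv`` and ``run.log`` into ``out_dir``; returns the report
    dict.  Exactly one of ``input_path`` / ``simulation`` must be given.
    """
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        if (input_path is None) == (simulation is None):
            raise ValueError("provide exactly one of input_path or simulation")
        if simulation is not None:
            if seed is not None:
                simulation = dataclasses.replace(simulation, seed=seed)
            studies = simulate_collection(simulation)
            studies_to_csv(studies, out_dir / "simulated_studies.csv")
            log.info("simulated %d studies (seed=%d, model=%s, or=%.3f)",
                     len(studies), simulation.seed, simulation.model,
                     simulation.or_effect)
        else:
            input_path = Path(input_path)
            if not input_path.exists():
                raise FileNotFoundError(f"input table not found: {input_path}")
            studies = parse_studies(input_path)
            log.info("parsed %d studies from %s", len(studies), input_path)

        snp_ids = []
        for s in studies:           # preserve input order
            if s.snp_id not in snp_ids:
                snp_ids.append(s.snp_id)
        report = {
            "genemeta_version": __version__,
            "python": platform.python_version(),
            "config": dataclasses.asdict(config),
            "seed": seed if seed is not None else (
                simulation.seed if simulation else None),
            "n_studies": len(studies),
            "snps": {sid: run_snp_analysis(studies, sid, config).to_dict()
                     for sid in snp_ids},
        }
        write_report(report, out_dir / "report.json", format="json")
        write_report(report, out_dir / "summary.tsv", format="tsv")
        _write_tsv(out_dir / "funnel.tsv",
                   ["snp_id", "label", "or", "se_log_or", "inverse_se"],
                   [(sid, row["label"], row["or"], row["se_log_or"], row["inverse_se"])
                    for sid, snp in report["snps"].items()
                    for row in snp["funnel"]])
        _write_tsv(out_dir / "cumulative.tsv",
                   ["snp_id", "step", "added", "or", "ci_low", "ci_high", "effect_model"],
                   [(sid, row["step"], row["added"], row["or"], row["ci_low"],
                     row["ci_high"], row["effect_model"])
                    for sid, snp in report["snps"].items()
                    for row in (snp["cumulative"] or [])])
        log.info("wrote report for %d SNPs to %s", len(snp_ids), out_dir)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_tsv(path: Path, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(v) for v in row) + "\n")
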