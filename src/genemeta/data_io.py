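"""Study tables, shared domain types and report serialization.

The atomic input record is a :class:`GenotypeStudy`: one case-control study's
genotype counts for a single biallelic SNP, with genotypes labelled by role --
``MM`` homozygous mutant (two copies of the minor/risk allele), ``MW``
heterozygous, ``WW`` homozygous wild type.  One schema therefore serves SNPs
regardless of which nucleotide the mutant allele is (the allele letters are
metadata, not computation).

Study tables are delimited text (comma or tab) with one row per
``(study_id, snp_id)`` and columns::

    study_id, first_author, year, snp_id,
    case_mm, case_mw, case_ww, ctrl_mm, ctrl_mw, ctrl_ww [, metadata...]

Counts must be non-negative integers; fractional counts are rejected rather
than rounded so data-entry slips surface immediately.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import IO, Iterable

__all__ = [
    "ContrastKind",
    "GenotypeStudy",
    "TwoByTwo",
    "EffectEstimate",
    "PooledResult",
    "HweResult",
    "SchemaError",
    "ValidationError",
    "DuplicateStudyError",
    "UnsupportedFormatError",
    "DegenerateInputError",
    "UndefinedEstimateError",
    "InsufficientStudiesError",
    "ConsistencyError",
    "parse_studies",
    "studies_to_csv",
    "write_report",
    "read_report",
    "load_il7ra",
]


# ---------------------------------------------------------------------------
# errors shared across modules
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """Input table is missing a required column."""


class ValidationError(ValueError):
    """A row violates a GenotypeStudy invariant."""


class DuplicateStudyError(ValueError):
    """Two rows share the same (study_id, snp_id)."""


class UnsupportedFormatError(ValueError):
    """Requested serialization format is not supported."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but statistically degenerate."""


class UndefinedEstimateError(ValueError):
    """An odds ratio cannot be computed from this 2x2 table."""


class InsufficientStudiesError(ValueError):
    """Fewer studies supplied than the statistic requires."""


class ConsistencyError(ValueError):
    """Results passed together were not computed on the same study set."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class ContrastKind(Enum):
    """Collapse of the 3x2 genotype-by-status table into a 2x2 table.

    ``MM_VS_WW``/``MW_VS_WW``/``MM_VS_MW`` are the pairwise genotype odds
    ratios OR1/OR2/OR3 whose joint significance pattern drives inheritance
    model selection; the remainder are the named genetic models.
    """

    MM_VS_WW = "MM vs WW"          # OR1
    MW_VS_WW = "MW vs WW"          # OR2
    MM_VS_MW = "MM vs MW"          # OR3
    DOMINANT = "MM+MW vs WW"
    RECESSIVE = "MM vs MW+WW"
    ALLELIC = "M vs W"
    OVERDOMINANT = "MW vs MM+WW"


@dataclass(frozen=True)
class GenotypeStudy:
    """One study's case/control genotype counts plus metadata."""

    study_id: str
    first_author: str
    year: int
    snp_id: str
    case_mm: int
    case_mw: int
    case_ww: int
    ctrl_mm: int
    ctrl_mw: int
    ctrl_ww: int
    metadata: dict | None = None

    def __post_init__(self) -> None:
        for name in ("case_mm", "case_mw", "case_ww", "ctrl_mm", "ctrl_mw", "ctrl_ww"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ValidationError(f"{self.study_id}/{self.snp_id}: {name}={v!r} is not an integer")
            if v < 0:
                raise ValidationError(f"{self.study_id}/{self.snp_id}: {name}={v} is negative")
        if self.n_cases == 0:
            raise ValidationError(f"{self.study_id}/{self.snp_id}: case total is zero")
        if self.n_controls == 0:
            raise ValidationError(f"{self.study_id}/{self.snp_id}: control total is zero")
        if not self.snp_id:
            raise ValidationError(f"{self.study_id}: snp_id is empty")

    @property
    def n_cases(self) -> int:
        return self.case_mm + self.case_mw + self.case_ww

    @property
    def n_controls(self) -> int:
        return self.ctrl_mm + self.ctrl_mw + self.ctrl_ww

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 exposure table: (a, b) exposed/unexposed cases, (c, d) controls.

    Cells are floats so a Haldane-Anscombe half-count correction can be
    represented; raw tables carry integer-valued cells.
    """

    a: float
    b: float
    c: float
    d: float
    contrast: ContrastKind
    study_id: str = ""

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EffectEstimate:
    """Log odds ratio with Woolf-type standard error, 95% CI and Z-test p."""

    log_or: float
    se_log_or: float
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    label: str = ""
    continuity_applied: bool = False

    @classmethod
    def from_log(cls, log_or: float, se: float, label: str = "",
                 continuity_applied: bool = False) -> "EffectEstimate":
        from scipy import stats

        if se <= 0:
            raise DegenerateInputError(f"{label}: standard error must be positive, got {se}")
        z = log_or / se
        return cls(
            log_or=log_or,
            se_log_or=se,
            or_=math.exp(log_or),
            ci_low=math.exp(log_or - 1.96 * se),
            ci_high=math.exp(log_or + 1.96 * se),
            p_value=2.0 * stats.norm.sf(abs(z)),
            label=label,
            continuity_applied=continuity_applied,
        )

    @property
    def significant(self) -> bool:
        """CI excludes the null OR of 1 (equivalently Z-test p < 0.05)."""
        return self.ci_low > 1.0 or self.ci_high < 1.0


@dataclass(frozen=True)
class PooledResult:
    """A pooled effect with heterogeneity statistics and branch bookkeeping."""

    effect: EffectEstimate
    k: int
    q: float
    q_df: int
    q_p: float
    i_squared: float
    tau_squared: float
    effect_model: str                      # "fixed_mh" | "random_dl" | "fixed_iv"
    weights: tuple[float, ...]             # normalized per-study weights
    contrast: ContrastKind | None = None
    study_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class HweResult:
    """Hardy-Weinberg goodness-of-fit result on a control genotype triple."""

    chi2: float
    p_value: float
    expected_counts: tuple[float, float, float]
    minor_allele_freq: float
    df: int = 1
    monomorphic: bool = False

    @property
    def deviates(self) -> bool:
        return self.p_value < 0.05


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = (
    "study_id", "first_author", "year", "snp_id",
    "case_mm", "case_mw", "case_ww", "ctrl_mm", "ctrl_mw", "ctrl_ww",
)
_COUNT_COLUMNS = REQUIRED_COLUMNS[4:]


def _to_int(value: str, row_num: int, name: str) -> int:
    text = str(value).strip()
    try:
        as_float = float(text)
    except ValueError:
        raise ValidationError(f"row {row_num}: {name}={value!r} is not a number") from None
    if not as_float.is_integer():
        raise ValidationError(f"row {row_num}: {name}={value!r} is fractional; counts must be integers")
    return int(as_float)


def parse_studies(path_or_stream: str | Path | IO[str],
                  delimiter: str | None = None) -> list[GenotypeStudy]:
    """Parse a delimited study table into validated :class:`GenotypeStudy` records.

    The delimiter is auto-detected between comma and tab from the header line
    unless given explicitly.  Input order is preserved; duplicate
    ``(study_id, snp_id)`` pairs, missing columns and invalid counts raise.
    """
    if isinstance(path_or_stream, (str, Path)):
        with open(path_or_stream, "r", encoding="utf-8") as handle:
            return parse_studies(handle, delimiter=delimiter)

    text = path_or_stream.read()
    lines = text.splitlines()
    if not lines:
        return []
    if delimiter is None:
        delimiter = "\t" if lines[0].count("\t") >= lines[0].count(",") else ","

    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    header = reader.fieldnames or []
    for col in REQUIRED_COLUMNS:
        if col not in header:
            raise SchemaError(f"missing required column {col!r}")
    meta_cols = [c for c in header if c not in REQUIRED_COLUMNS]

    studies: list[GenotypeStudy] = []
    seen: set[tuple[str, str]] = set()
    for row_num, row in enumerate(reader, start=2):
        counts = {name: _to_int(row[name], row_num, name) for name in _COUNT_COLUMNS}
        metadata = {c: row[c] for c in meta_cols if row.get(c) not in (None, "")} or None
        study = GenotypeStudy(
            study_id=row["study_id"].strip(),
            first_author=row["first_author"].strip(),
            year=_to_int(row["year"], row_num, "year"),
            snp_id=row["snp_id"].strip(),
            metadata=metadata,
            **counts,
        )
        key = (study.study_id, study.snp_id)
        if key in seen:
            raise DuplicateStudyError(f"row {row_num}: duplicate (study_id, snp_id) = {key}")
        seen.add(key)
        studies.append(study)
    return studies


def studies_to_csv(studies: Iterable[GenotypeStudy], path_or_stream: str | Path | IO[str],
                   delimiter: str = ",") -> None:
    """Serialize studies back to the table dialect :func:`parse_studies` reads."""
    if isinstance(path_or_stream, (str, Path)):
        with open(path_or_stream, "w", encoding="utf-8", newline="") as handle:
            studies_to_csv(studies, handle, delimiter=delimiter)
            return
    studies = list(studies)
    meta_cols: list[str] = []
    for s in studies:
        for key in (s.metadata or {}):
            if key not in meta_cols:
                meta_cols.append(key)
    writer = csv.writer(path_or_stream, delimiter=delimiter, lineterminator="\n")
    writer.writerow(list(REQUIRED_COLUMNS) + meta_cols)
    for s in studies:
        meta = s.metadata or {}
        writer.writerow(
            [s.study_id, s.first_author, s.year, s.snp_id,
             s.case_mm, s.case_mw, s.case_ww, s.ctrl_mm, s.ctrl_mw, s.ctrl_ww]
            + [meta.get(c, "") for c in meta_cols]
        )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = (
    "snp_id", "contrast", "k", "i_squared", "effect_model",
    "or", "ci_low", "ci_high", "p_value", "egger_t", "egger_p", "power",
    "suggested",
)


def _pooled_rows(report: dict) -> list[dict]:
    rows = []
    for snp_id, snp in report.get("snps", {}).items():
        for row in snp.get("pooled", []):
            rows.append({"snp_id": snp_id, **row})
    return rows


def write_report(report: dict, path: str | Path, format: str = "json") -> None:
    """Write an analysis report as JSON (full, round-trippable) or TSV (pooled rows).

    The TSV mirrors a per-contrast summary table: contrast, I-squared, effect
    model, OR with CI, p, Egger t/p and power, with the suggested genetic
    model flagged.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(report, handle, indent=2, sort_keys=True)
            handle.write("\n")
    elif format == "tsv":
        with open(path, "w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(SUMMARY_COLUMNS)
            for row in _pooled_rows(report):
                writer.writerow([row.get(col, "") for col in SUMMARY_COLUMNS])
    else:
        raise UnsupportedFormatError(f"unsupported report format {format!r}; use 'json' or 'tsv'")


def read_report(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_report` (exact round-trip)."""
    with open(path, "r", encoding="utf-8") as handle:
        return json.load(handle)


# ---------------------------------------------------------------------------
# bundled IL7RA study table
# ---------------------------------------------------------------------------

def load_il7ra() -> list[GenotypeStudy]:
    """Load the bundled IL7RA multiple-sclerosis case-control study table.

    27 studies covering four IL7RA SNPs (rs3194051, rs987107, rs11567686,
    rs11567685), transcribed from the source publication's genotype-count
    table.  Every row's counts sum to that study's published case and control
    totals (enforced by the test suite).
    """
    ref = resources.files("genemeta").joinpath("data/il7ra_table2.csv")
    with ref.open("r", encoding="utf-8") as handle:
        return parse_studies(handle)
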