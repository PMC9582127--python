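"""Study-level genotype-count tables: data model, I/O, and result serialization.

The atomic record is one case-control study's genotype counts for a single
biallelic variant and disease outcome.  Counts are stored in the orientation
of the input file (major/minor re-orientation happens downstream, see
:mod:`credmeta.genetic_models`).  Result rows are serialized to a TSV whose
columns mirror the summary tables of genetic-association field synopses:
pooled OR with CI, heterogeneity, Venice code, FPRP and the final
credibility verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

ETHNICITIES = ("Asian", "Caucasian", "African", "Other")
STRATA = ("Overall",) + ETHNICITIES
GENETIC_MODELS = ("allelic", "dominant", "recessive")

CSV_COLUMNS = [
    "study_id",
    "first_author",
    "pub_year",
    "disease",
    "variant_id",
    "gene",
    "ethnicity",
    "case_hom_major",
    "case_het",
    "case_hom_minor",
    "ctrl_hom_major",
    "ctrl_het",
    "ctrl_hom_minor",
]

Z_CRIT = 1.959964  # two-sided 95% normal critical value


class SchemaError(ValueError):
    """Input table does not match the documented CSV schema."""


class ValidationError(ValueError):
    """A data row violates a domain invariant."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm of a study (cases or controls)."""

    hom_major: int
    het: int
    hom_minor: int

    def __post_init__(self) -> None:
        for name in ("hom_major", "het", "hom_minor"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.hom_major + self.het + self.hom_minor

    def swapped(self) -> "GenotypeCounts":
        """Counts with the homozygote classes exchanged (allele relabeling)."""
        return GenotypeCounts(self.hom_minor, self.het, self.hom_major)


@dataclass(frozen=True)
class StudyRecord:
    """One study's genotype counts for one variant/disease/ethnicity."""

    study_id: str
    first_author: str
    pub_year: int
    disease: str
    variant_id: str
    gene: str
    ethnicity: str
    cases: GenotypeCounts
    controls: GenotypeCounts
    is_first_published: bool = False

    def __post_init__(self) -> None:
        if self.ethnicity not in ETHNICITIES:
            raise ValidationError(
                f"unknown ethnicity {self.ethnicity!r}; allowed: {list(ETHNICITIES)}"
            )
        if self.cases.total <= 0 or self.controls.total <= 0:
            raise ValidationError(
                f"study {self.study_id}: cases and controls must each total > 0"
            )


@dataclass(frozen=True)
class AssociationKey:
    """Identifies one pooled analysis: variant x disease x stratum x model."""

    variant_id: str
    disease: str
    stratum: str = "Overall"
    genetic_model: str = "allelic"

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValidationError(f"unknown stratum {self.stratum!r}")
        if self.genetic_model not in GENETIC_MODELS:
            raise ValidationError(f"unknown genetic model {self.genetic_model!r}")


def _mark_first_published(records: list[StudyRecord]) -> list[StudyRecord]:
    """Flag the first-published study within each (variant, disease) group.

    Ties on publication year break by study_id lexicographic order.
    """
    out = []
    groups: dict[tuple[str, str], list[StudyRecord]] = {}
    for r in records:
        groups.setdefault((r.variant_id, r.disease), []).append(r)
    first_ids = {
        key: min(grp, key=lambda r: (r.pub_year, r.study_id)).study_id
        for key, grp in groups.items()
    }
    for r in records:
        flag = first_ids[(r.variant_id, r.disease)] == r.study_id
        out.append(replace(r, is_first_published=flag))
    return out


def read_study_table(path: str | Path) -> list[StudyRecord]:
    """Read a study-table CSV into validated :class:`StudyRecord` objects.

    Raises :class:`SchemaError` when a required column is missing and
    :class:`ValidationError` (citing the 1-based data row number) for
    negative/non-integer counts or unknown ethnicity labels.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    count_cols = CSV_COLUMNS[7:]
    records: list[StudyRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        vals = {}
        for col in count_cols:
            raw = getattr(row, col)
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise ValidationError(f"row {i}: {col}={raw!r} is not an integer")
            if v < 0:
                raise ValidationError(f"row {i}: {col}={v} is negative")
            vals[col] = v
        try:
            year = int(row.pub_year)
        except (TypeError, ValueError):
            raise ValidationError(f"row {i}: pub_year={row.pub_year!r} is not an integer")
        try:
            rec = StudyRecord(
                study_id=row.study_id,
                first_author=row.first_author,
                pub_year=year,
                disease=row.disease,
                variant_id=row.variant_id,
                gene=row.gene,
                ethnicity=row.ethnicity,
                cases=GenotypeCounts(
                    vals["case_hom_major"], vals["case_het"], vals["case_hom_minor"]
                ),
                controls=GenotypeCounts(
                    vals["ctrl_hom_major"], vals["ctrl_het"], vals["ctrl_hom_minor"]
                ),
            )
        except ValidationError as e:
            raise ValidationError(f"row {i}: {e}") from None
        key = (rec.study_id, rec.variant_id, rec.disease)
        if key in seen:
            raise ValidationError(
                f"row {i}: duplicate (study_id, variant_id, disease) = {key}"
            )
        seen.add(key)
        records.append(rec)
    return _mark_first_published(records)


def write_study_table(records: Iterable[StudyRecord], path: str | Path) -> None:
    """Serialize records back to the standard CSV schema (counts exact)."""
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "first_author": r.first_author,
                "pub_year": r.pub_year,
                "disease": r.disease,
                "variant_id": r.variant_id,
                "gene": r.gene,
                "ethnicity": r.ethnicity,
                "case_hom_major": r.cases.hom_major,
                "case_het": r.cases.het,
                "case_hom_minor": r.cases.hom_minor,
                "ctrl_hom_major": r.controls.hom_major,
                "ctrl_het": r.controls.het,
                "ctrl_hom_minor": r.controls.hom_minor,
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result-table serialization (summary-table style formatting)
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "gene",
    "variant",
    "alleles",
    "disease",
    "stratum",
    "datasets",
    "cases",
    "controls",
    "genetic_model",
    "effect_model",
    "or_ci",
    "p",
    "i_squared",
    "p_q",
    "venice_code",
    "fprp",
    "credibility",
]


def format_p(p: float | None) -> str:
    """Render a p-value to 3 decimals, with values below 0.001 as '<0.001'."""
    if p is None:
        return ""
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


def format_or_ci(or_value: float, ci_low: float, ci_high: float) -> str:
    """Render 'OR (low-high)' with 3-decimal rounding and an en dash."""
    return f"{or_value:.3f} ({ci_low:.3f}–{ci_high:.3f})"


def write_results_table(rows: Sequence[dict], path: str | Path) -> None:
    """Write graded association results as a UTF-8 TSV.

    Each entry of ``rows`` is a flat dict carrying the pooled estimate and,
    for graded (nominally significant) associations, the Venice code, FPRP
    and credibility verdict; non-significant rows leave those cells empty.
    Expected numeric keys: or, ci_low, ci_high, p, i_squared, p_q.
    """
    out = []
    for r in rows:
        i2 = r.get("i_squared")
        if i2 is not None and not (0.0 <= i2 <= 100.0):
            raise ValueError(f"I² out of [0, 100]: {i2}")
        out.append(
            {
                "gene": r.get("gene", ""),
                "variant": r.get("variant", ""),
                "alleles": r.get("alleles", ""),
                "disease": r.get("disease", ""),
                "stratum": r.get("stratum", ""),
                "datasets": r.get("datasets", ""),
                "cases": r.get("cases", ""),
                "controls": r.get("controls", ""),
                "genetic_model": r.get("genetic_model", ""),
                "effect_model": r.get("effect_model", ""),
                "or_ci": format_or_ci(r["or"], r["ci_low"], r["ci_high"])
                if r.get("or") is not None
                else "",
                "p": format_p(r.get("p")),
                "i_squared": f"{i2:.1f}" if i2 is not None else "",
                "p_q": format_p(r.get("p_q")),
                "venice_code": r.get("venice_code", "") or "",
                "fprp": format_p(r.get("fprp")),
                "credibility": r.get("credibility", "") or "",
            }
        )
    df = pd.DataFrame(out, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
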