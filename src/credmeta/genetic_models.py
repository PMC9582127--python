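"""Genetic contrast models, allele orientation, and Hardy-Weinberg screening.

Three standard contrasts turn genotype counts into a 2x2 exposure-by-status
table: allelic (minor vs major allele counts, denominator 2N), dominant
(carriers of >=1 minor allele vs non-carriers) and recessive (minor
homozygotes vs all others).  The effect allele is fixed per association
group as the pooled-control minor allele, so a single study's frequency
noise cannot flip effect direction within a group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from scipy import stats

from .study_table import GenotypeCounts, StudyRecord, GENETIC_MODELS


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-status contingency table (cases x exposed layout)."""

    case_exposed: float
    case_unexposed: float
    ctrl_exposed: float
    ctrl_unexposed: float

    def __post_init__(self) -> None:
        if min(
            self.case_exposed, self.case_unexposed, self.ctrl_exposed, self.ctrl_unexposed
        ) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.case_exposed, self.case_unexposed, self.ctrl_exposed, self.ctrl_unexposed)

    @property
    def has_zero_cell(self) -> bool:
        return any(c == 0 for c in self.cells)

    @property
    def is_informative(self) -> bool:
        """False when an exposure margin is empty (OR undefined even corrected)."""
        return (self.case_exposed + self.ctrl_exposed) > 0 and (
            self.case_unexposed + self.ctrl_unexposed
        ) > 0

    def with_continuity(self, c: float = 0.5) -> "TwoByTwo":
        """Add ``c`` to every cell when any cell is zero; otherwise unchanged."""
        if not self.has_zero_cell:
            return self
        return TwoByTwo(*(x + c for x in self.cells))


@dataclass(frozen=True)
class HweResult:
    chi_square: float
    p_value: float
    passes: bool


def minor_allele_frequency(g: GenotypeCounts) -> float:
    """Frequency of the minor allele: (2*hom_minor + het) / (2*total)."""
    if g.total <= 0:
        raise ValueError("genotype total must be positive")
    return (2 * g.hom_minor + g.het) / (2 * g.total)


def pooled_control_maf(records: Sequence[StudyRecord]) -> float:
    """Minor-allele frequency of the pooled control genotype counts."""
    pooled = GenotypeCounts(
        sum(r.controls.hom_major for r in records),
        sum(r.controls.het for r in records),
        sum(r.controls.hom_minor for r in records),
    )
    return minor_allele_frequency(pooled)


def orient_minor_allele(records: Sequence[StudyRecord]) -> list[StudyRecord]:
    """Orient a (variant, disease) group so the effect allele is the pooled-control minor allele.

    The decision is made once from the pooled control frequency: when it
    exceeds 0.5 the homozygote classes are swapped in every record (cases and
    controls alike).  Applying the function twice is the identity.
    """
    if not records:
        raise ValueError("empty record group")
    if pooled_control_maf(records) > 0.5:
        return [
            replace(r, cases=r.cases.swapped(), controls=r.controls.swapped())
            for r in records
        ]
    return list(records)


def derive_two_by_two(
    cases: GenotypeCounts, controls: GenotypeCounts, model: str
) -> TwoByTwo:
    """Build the 2x2 exposure table for one study under a genetic model.

    Inputs must already be oriented so that ``hom_minor`` counts minor-allele
    homozygotes.
    """
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    if model == "allelic":
        return TwoByTwo(
            2 * cases.hom_minor + cases.het,
            2 * cases.hom_major + cases.het,
            2 * controls.hom_minor + controls.het,
            2 * controls.hom_major + controls.het,
        )
    if model == "dominant":
        return TwoByTwo(
            cases.hom_minor + cases.het,
            cases.hom_major,
            controls.hom_minor + controls.het,
            controls.hom_major,
        )
    return TwoByTwo(  # recessive
        cases.hom_minor,
        cases.het + cases.hom_major,
        controls.hom_minor,
        controls.het + controls.hom_major,
    )


def hwe_chi_square(controls: GenotypeCounts, alpha: float = 0.05) -> HweResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions in controls.

    Expected counts use the observed allele frequency; no continuity
    correction.  Monomorphic samples (MAF 0 or 1) trivially conform:
    chi-square 0, p 1.
    """
    n = controls.total
    if n <= 0:
        raise ValueError("control total must be positive")
    q = minor_allele_frequency(controls)
    if q == 0.0 or q == 1.0:
        return HweResult(0.0, 1.0, True)
    p = 1.0 - q
    expected = (n * p * p, n * 2 * p * q, n * q * q)
    observed = (controls.hom_major, controls.het, controls.hom_minor)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2, p_value, p_value >= alpha)
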