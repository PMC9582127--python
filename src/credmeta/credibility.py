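"""Venice-criteria grading, false-positive report probability, and verdicts.

The Venice criteria grade a nominally significant pooled association on
three axes, each A/B/C:

* **amount of evidence** — sample size supporting the association.  Graded
  A above 1,000, B from 100 to 1,000, C below 100.  The counting basis is
  the least-common exposure group summed over cases and controls (alleles
  under the allelic model, subjects otherwise); a plain total-sample-size
  basis is available as an option.
* **replication** — between-study consistency via I²: A at I² <= 25%, B for
  25% < I² < 50%, C at I² >= 50%.
* **protection from bias** — C when a bias test fires, a sensitivity check
  fails, or the pooled OR is small (between 0.87 and 1.15) without
  confirmation from large-scale genome-wide studies; B when the inputs
  needed to judge bias are missing; A otherwise.

The three-letter code maps to a class: AAA = strong, any C = weak,
otherwise moderate.  The false-positive report probability

    FPRP = p(1 - pi) / (p(1 - pi) + power * pi)

(with p the observed pooled p-value, pi the prior probability that the
association is real, and power the probability of detecting a target OR of
1.5 at level p) is graded strong below 0.05, moderate up to 0.2, weak
above.  A strong FPRP upgrades the Venice class one level; a weak FPRP
downgrades it one level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .bias_tests import BiasReport
from .meta_engine import MetaResult
from .sensitivity import SensitivityReport
from .study_table import Z_CRIT

FPRP_PRIOR = 0.05
FPRP_TARGET_OR = 1.5
FPRP_CUTOFF = 0.2
SMALL_OR_RISK = 1.15
SMALL_OR_PROTECTIVE = 0.87

_LEVELS = ("weak", "moderate", "strong")


@dataclass(frozen=True)
class VeniceGrade:
    amount: str
    replication: str
    bias_protection: str

    def __post_init__(self) -> None:
        for g in (self.amount, self.replication, self.bias_protection):
            if g not in "ABC" or len(g) != 1:
                raise ValueError(f"grade must be A, B or C, got {g!r}")

    @property
    def code(self) -> str:
        return self.amount + self.replication + self.bias_protection

    @property
    def venice_class(self) -> str:
        if self.code == "AAA":
            return "strong"
        if "C" in self.code:
            return "weak"
        return "moderate"


@dataclass(frozen=True)
class FprpResult:
    alpha: float
    power: float
    prior: float
    fprp: float

    @property
    def grade(self) -> str:
        if self.fprp < 0.05:
            return "strong"
        if self.fprp <= FPRP_CUTOFF:
            return "moderate"
        return "weak"

    @property
    def noteworthy(self) -> bool:
        return self.fprp < FPRP_CUTOFF


@dataclass(frozen=True)
class CredibilityVerdict:
    venice: VeniceGrade
    fprp: FprpResult

    @property
    def venice_class(self) -> str:
        return self.venice.venice_class

    @property
    def fprp_grade(self) -> str:
        return self.fprp.grade

    @property
    def final(self) -> str:
        return combine_levels(self.venice_class, self.fprp_grade)


def combine_levels(venice_class: str, fprp_grade: str) -> str:
    """One-level upgrade/downgrade of the Venice class by the FPRP grade.

    Strong FPRP upgrades, weak FPRP downgrades, moderate leaves unchanged;
    the result is clamped to [Weak, Strong].
    """
    i = _LEVELS.index(venice_class)
    if fprp_grade == "strong":
        i = min(i + 1, 2)
    elif fprp_grade == "weak":
        i = max(i - 1, 0)
    return _LEVELS[i].capitalize()


def venice_amount_grade(evidence_count: float) -> str:
    """Grade the amount of evidence: A > 1000, B in [100, 1000], C < 100."""
    if evidence_count > 1000:
        return "A"
    if evidence_count >= 100:
        return "B"
    return "C"


def least_common_exposure_count(meta: MetaResult) -> float:
    """Subjects (alleles under the allelic model) in the rarer exposure group.

    Summed over cases and controls of all pooled datasets; this is the
    sample-size basis for the amount-of-evidence grade.
    """
    exposed = sum(t.case_exposed + t.ctrl_exposed for t in meta.tables)
    unexposed = sum(t.case_unexposed + t.ctrl_unexposed for t in meta.tables)
    return min(exposed, unexposed)


def venice_replication_grade(i_squared: float) -> str:
    """Grade replication from I²: A <= 25 < B < 50 <= C."""
    if not (0.0 <= i_squared <= 100.0):
        raise ValueError(f"I² out of [0, 100]: {i_squared}")
    if i_squared <= 25.0:
        return "A"
    if i_squared < 50.0:
        return "B"
    return "C"


def venice_bias_grade(
    meta: MetaResult,
    bias: BiasReport | None,
    sens: SensitivityReport | None,
    gwas_confirmed: bool = False,
) -> str:
    """Grade protection from bias for a nominally significant association.

    C when any bias test fires, any sensitivity check fails, or the pooled
    OR lies in the small-effect band (0.87, 1.15) without genome-wide
    confirmation; B when the bias or sensitivity inputs are absent
    (insufficient information); A otherwise.
    """
    or_value = meta.pooled.or_value
    small_effect = SMALL_OR_PROTECTIVE < or_value < SMALL_OR_RISK
    if small_effect and not gwas_confirmed:
        return "C"
    if bias is not None and bias.bias_detected:
        return "C"
    if sens is not None and not sens.overall_robust:
        return "C"
    if bias is None or not bias.available or sens is None:
        return "B"
    return "A"


def power_at_or(
    target_or: float, se: float, alpha: float, z_crit: float | None = None
) -> float:
    """Normal-approximation power to detect ``target_or`` at two-sided ``alpha``.

    Protective targets (< 1) are inverted so power is evaluated on the
    magnitude of the log OR.  ``z_crit`` overrides the alpha-derived
    critical value (used to reproduce spreadsheet conventions).
    """
    if target_or <= 0:
        raise ValueError("target OR must be positive")
    if target_or < 1:
        target_or = 1.0 / target_or
    z_a = stats.norm.isf(alpha / 2.0) if z_crit is None else z_crit
    mu = math.log(target_or) / se
    return float(stats.norm.cdf(mu - z_a) + stats.norm.cdf(-mu - z_a))


def fprp(alpha: float, power: float, prior: float) -> FprpResult:
    """False-positive report probability of a nominally significant result.

    ``alpha`` is the observed two-sided p-value of the pooled estimate,
    ``power`` the probability of detecting the target OR at that level,
    ``prior`` the prior probability the association is real.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if not (0.0 < power <= 1.0):
        raise ValueError("power must be in (0, 1]")
    if not (0.0 < prior < 1.0):
        raise ValueError("prior must be in (0, 1)")
    num = alpha * (1.0 - prior)
    value = num / (num + power * prior)
    return FprpResult(alpha=alpha, power=power, prior=prior, fprp=value)


def fprp_for_meta(
    meta: MetaResult,
    prior: float = FPRP_PRIOR,
    target_or: float = FPRP_TARGET_OR,
) -> FprpResult:
    """FPRP of a pooled result: alpha = its p-value, power at the target OR."""
    alpha = meta.pooled.p_value
    power = power_at_or(target_or, meta.pooled.se, alpha)
    return fprp(alpha, power, prior)


def alpha_from_ci(ci_low: float, ci_high: float, or_value: float) -> float:
    """Recover the two-sided p-value from a printed OR and 95% CI.

    The log-scale SE is ln(hi/lo) / (2 * 1.959964); used in grading-only
    mode where only summary rows are available.
    """
    se = math.log(ci_high / ci_low) / (2.0 * Z_CRIT)
    z = abs(math.log(or_value)) / se
    return float(2.0 * stats.norm.sf(z))


def combine_credibility(venice: VeniceGrade, fprp_result: FprpResult) -> CredibilityVerdict:
    """Final Strong/Moderate/Weak verdict from the Venice code and FPRP grade."""
    return CredibilityVerdict(venice=venice, fprp=fprp_result)


def grade_association(
    meta: MetaResult,
    bias: BiasReport | None,
    sens: SensitivityReport | None,
    *,
    gwas_confirmed: bool = False,
    prior: float = FPRP_PRIOR,
    target_or: float = FPRP_TARGET_OR,
    amount_basis: str = "least_common_exposure",
) -> CredibilityVerdict:
    """Full credibility grading of one significant pooled association."""
    if amount_basis == "least_common_exposure":
        count = least_common_exposure_count(meta)
    elif amount_basis == "total":
        count = meta.n_cases + meta.n_controls
    else:
        raise ValueError(f"unknown amount_basis {amount_basis!r}")
    venice = VeniceGrade(
        amount=venice_amount_grade(count),
        replication=venice_replication_grade(meta.i_squared),
        bias_protection=venice_bias_grade(meta, bias, sens, gwas_confirmed),
    )
    return combine_credibility(venice, fprp_for_meta(meta, prior, target_or))
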