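"""Per-study effect estimation and fixed/random-effects pooling.

Fixed-effect pooling uses the count-level Mantel-Haenszel odds ratio with
the Robins-Breslow-Greenland variance; the inverse-variance estimator is
retained as a cross-check.  Heterogeneity is quantified by Cochran's Q
(inverse-variance weights around the inverse-variance fixed mean, the
Higgins convention) and I² = max(0, 100*(Q - df)/Q).  When the Q test's
p-value falls below 0.1, the DerSimonian-Laird random-effects model is
selected; otherwise the fixed-effect (MH) result is reported.

Continuity handling follows the common meta-analysis convention for sparse
2x2 tables: 0.5 is added to all four cells of a study only when that study
has a zero cell; studies with an empty exposure margin carry no information
about the odds ratio and are dropped with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genetic_models import TwoByTwo, derive_two_by_two, orient_minor_allele
from .study_table import AssociationKey, StudyRecord, Z_CRIT

logger = logging.getLogger("credmeta")

MIN_DATASETS = 3  # minimum data sources for a pooled analysis
HETEROGENEITY_ALPHA = 0.1  # Q-test threshold selecting the random-effects model


@dataclass(frozen=True)
class EffectEstimate:
    """An odds ratio with normal-theory CI on the log scale."""

    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"standard error must be positive, got {self.se}")

    @property
    def or_value(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z_CRIT * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z_CRIT * self.se)

    @property
    def z(self) -> float:
        return self.log_or / self.se

    @property
    def p_value(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))


@dataclass(frozen=True)
class MetaResult:
    """Pooled result for one association key."""

    key: AssociationKey
    k: int
    n_cases: int
    n_controls: int
    effect_model: str  # "fixed" | "random"
    pooled: EffectEstimate
    q_stat: float
    df: int
    p_q: float
    i_squared: float
    tau_squared: float
    fixed: EffectEstimate
    random: EffectEstimate | None
    effects: tuple[EffectEstimate, ...]
    tables: tuple[TwoByTwo, ...]
    records: tuple[StudyRecord, ...]

    @property
    def significant(self) -> bool:
        return self.pooled.p_value < 0.05


@dataclass(frozen=True)
class SkippedResult:
    """Marker for an association that could not be pooled."""

    key: AssociationKey
    k: int
    reason: str


def study_effect(t: TwoByTwo, continuity: float = 0.5) -> EffectEstimate | None:
    """Woolf log-OR and standard error for one 2x2 table.

    A zero cell triggers adding ``continuity`` to all four cells.  A table
    with an empty exposure margin is non-informative and returns ``None``
    (the caller logs and drops it).
    """
    if not t.is_informative:
        logger.warning("non-informative 2x2 table dropped: %s", t.cells)
        return None
    t = t.with_continuity(continuity)
    a, b, c, d = t.cells
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(log_or, se)


def pool_fixed_mh(tables: Sequence[TwoByTwo], continuity: float = 0.5) -> EffectEstimate:
    """Mantel-Haenszel pooled OR with the Robins-Breslow-Greenland variance."""
    tables = [t.with_continuity(continuity) for t in tables if t.is_informative]
    if not tables:
        raise ValueError("no informative tables to pool")
    sr = ss = 0.0
    spr = spsqr = sqs = 0.0
    for t in tables:
        a, b, c, d = t.cells
        n = a + b + c + d
        r = a * d / n
        s = b * c / n
        p = (a + d) / n
        q = (b + c) / n
        sr += r
        ss += s
        spr += p * r
        spsqr += p * s + q * r
        sqs += q * s
    if sr == 0 or ss == 0:
        raise ValueError("Mantel-Haenszel OR undefined (zero weight sum)")
    log_or = math.log(sr / ss)
    var = spr / (2 * sr * sr) + spsqr / (2 * sr * ss) + sqs / (2 * ss * ss)
    return EffectEstimate(log_or, math.sqrt(var))


def pool_fixed_iv(effects: Sequence[EffectEstimate]) -> EffectEstimate:
    """Inverse-variance weighted fixed-effect pooling of log ORs."""
    if not effects:
        raise ValueError("no effects to pool")
    w = np.array([1.0 / (e.se * e.se) for e in effects])
    y = np.array([e.log_or for e in effects])
    return EffectEstimate(float(np.sum(w * y) / np.sum(w)), float(1.0 / math.sqrt(np.sum(w))))


def cochran_q(
    effects: Sequence[EffectEstimate], pooled_log_or: float | None = None
) -> tuple[float, int, float]:
    """Cochran's Q with inverse-variance weights; returns (Q, df, p).

    For a single study Q = 0, df = 0 and p = 1 by convention.  ``pooled_log_or``
    defaults to the inverse-variance fixed mean.
    """
    k = len(effects)
    if k <= 1:
        return 0.0, 0, 1.0
    if pooled_log_or is None:
        pooled_log_or = pool_fixed_iv(effects).log_or
    q = sum((e.log_or - pooled_log_or) ** 2 / (e.se * e.se) for e in effects)
    df = k - 1
    return float(q), df, float(stats.chi2.sf(q, df))


def i_squared(q_stat: float, df: int) -> float:
    """Higgins I² in percent: max(0, 100*(Q - df)/Q); 0 when Q = 0."""
    if q_stat <= 0:
        return 0.0
    return max(0.0, 100.0 * (q_stat - df) / q_stat)


def dersimonian_laird(
    effects: Sequence[EffectEstimate],
) -> tuple[float, EffectEstimate]:
    """DerSimonian-Laird method-of-moments random-effects pooling.

    Returns (tau², pooled estimate).  With tau² = 0 the result coincides
    exactly with inverse-variance fixed pooling.
    """
    k = len(effects)
    if k < 2:
        raise ValueError("random-effects pooling needs at least two studies")
    w = np.array([1.0 / (e.se * e.se) for e in effects])
    y = np.array([e.log_or for e in effects])
    fixed_mean = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - fixed_mean) ** 2))
    c = float(np.sum(w) - np.sum(w * w) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (np.array([e.se * e.se for e in effects]) + tau2)
    pooled = EffectEstimate(
        float(np.sum(w_star * y) / np.sum(w_star)),
        float(1.0 / math.sqrt(np.sum(w_star))),
    )
    return tau2, pooled


def run_meta(
    group: Sequence[StudyRecord],
    key: AssociationKey,
    *,
    continuity: float = 0.5,
    min_datasets: int = MIN_DATASETS,
    heterogeneity_alpha: float = HETEROGENEITY_ALPHA,
    orient: bool = True,
) -> MetaResult | SkippedResult:
    """Pool one stratum x genetic-model association.

    ``group`` holds the study records of one (variant, disease) pair already
    restricted to the key's stratum.  The group is oriented to the pooled
    control minor allele (unless ``orient=False`` for pre-oriented input),
    2x2 tables are derived under the key's genetic model, sparse tables are
    continuity-corrected, and the fixed (MH) estimate is computed.  The
    random-effects (DL) model is selected when the Q test's p < 0.1.

    Associations with fewer than ``min_datasets`` informative datasets are
    skipped with a reason, mirroring the at-least-three-data-sources rule.
    """
    if not group:
        raise ValueError("empty study group")
    if len(group) < min_datasets:
        return SkippedResult(key, len(group), "fewer than three data sources")
    records = orient_minor_allele(group) if orient else list(group)
    raw_tables = [derive_two_by_two(r.cases, r.controls, key.genetic_model) for r in records]
    kept: list[tuple[StudyRecord, TwoByTwo, EffectEstimate]] = []
    for rec, tab in zip(records, raw_tables):
        eff = study_effect(tab, continuity)
        if eff is None:
            logger.warning(
                "%s %s %s: study %s non-informative under %s model, dropped",
                key.variant_id, key.disease, key.stratum, rec.study_id, key.genetic_model,
            )
            continue
        kept.append((rec, tab, eff))
    if len(kept) < min_datasets:
        return SkippedResult(
            key, len(kept), "fewer than three data sources"
        )
    records_k = tuple(r for r, _, _ in kept)
    tables = tuple(t for _, t, _ in kept)
    effects = tuple(e for _, _, e in kept)

    fixed = pool_fixed_mh(tables, continuity)
    q, df, p_q = cochran_q(effects)
    i2 = i_squared(q, df)
    tau2, random_est = dersimonian_laird(effects)
    use_random = p_q < heterogeneity_alpha
    pooled = random_est if use_random else fixed
    return MetaResult(
        key=key,
        k=len(kept),
        n_cases=sum(r.cases.total for r in records_k),
        n_controls=sum(r.controls.total for r in records_k),
        effect_model="random" if use_random else "fixed",
        pooled=pooled,
        q_stat=q,
        df=df,
        p_q=p_q,
        i_squared=i2,
        tau_squared=tau2,
        fixed=fixed,
        random=random_est,
        effects=effects,
        tables=tables,
        records=records_k,
    )
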