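"""Robustness checks for significant pooled associations.

Three perturbations are re-analysed with the full pooling procedure
(including re-selection of fixed vs random effects per subset): omitting
each single dataset in turn, excluding studies whose controls deviate from
Hardy-Weinberg equilibrium, and excluding the first-published study.  An
association is called robust when every available re-analysis preserves
both the effect direction and nominal significance (p < 0.05) of the full
result; the narrative qualitative criterion ("removal did not alter the
summary ORs") is operationalized by that rule.

Orientation of the effect allele is inherited from the full analysis:
subsets are never re-oriented, so a perturbation cannot silently flip the
reported allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .genetic_models import hwe_chi_square
from .meta_engine import MetaResult, SkippedResult, run_meta
from .study_table import StudyRecord

logger = logging.getLogger("credmeta")

SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class SensitivityReport:
    loo_results: tuple[MetaResult, ...] | None
    loo_robust: bool
    hwe_excluded_result: MetaResult | None
    hwe_robust: bool
    first_study_excluded_result: MetaResult | None
    first_robust: bool

    @property
    def overall_robust(self) -> bool:
        return self.loo_robust and self.hwe_robust and self.first_robust


def _preserves(full: MetaResult, sub: MetaResult, alpha: float) -> bool:
    same_direction = (full.pooled.log_or >= 0) == (sub.pooled.log_or >= 0)
    return same_direction and sub.pooled.p_value < alpha


def leave_one_out(
    group: Sequence[StudyRecord],
    full: MetaResult,
    *,
    alpha: float = SIGNIFICANCE_ALPHA,
    **meta_kwargs,
) -> tuple[tuple[MetaResult, ...] | None, bool]:
    """Re-pool the association omitting each dataset in turn.

    Returns (k re-pooled results, robust flag).  When removing one dataset
    would drop the group below the pooling minimum (k - 1 < 3) the check is
    not performed and reported absent (vacuously robust).
    """
    k = len(group)
    min_k = meta_kwargs.get("min_datasets", 3)
    if k - 1 < min_k:
        logger.info("%s: leave-one-out skipped (k-1 < %d)", full.key, min_k)
        return None, True
    results = []
    robust = True
    for i in range(k):
        subset = [r for j, r in enumerate(group) if j != i]
        res = run_meta(subset, full.key, orient=False, **meta_kwargs)
        assert isinstance(res, MetaResult)
        results.append(res)
        if not _preserves(full, res, alpha):
            robust = False
    return tuple(results), robust


def exclude_scenario(
    group: Sequence[StudyRecord],
    full: MetaResult,
    scenario: str,
    *,
    alpha: float = SIGNIFICANCE_ALPHA,
    hwe_alpha: float = 0.05,
    **meta_kwargs,
) -> tuple[MetaResult | None, bool]:
    """Re-pool after removing HWE-violating or first-published studies.

    ``scenario`` is "hwe_violators" or "first_published".  Returns
    (re-pooled result or None, robust flag).  Absent — with a vacuously
    true flag — when the filter removes nothing or leaves fewer than the
    pooling minimum.
    """
    if scenario == "hwe_violators":
        kept = [
            r for r in group if hwe_chi_square(r.controls, hwe_alpha).passes
        ]
    elif scenario == "first_published":
        kept = [r for r in group if not r.is_first_published]
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if len(kept) == len(group):
        return None, True
    min_k = meta_kwargs.get("min_datasets", 3)
    if len(kept) < min_k:
        logger.info(
            "%s: scenario %s leaves %d datasets (< %d), skipped",
            full.key, scenario, len(kept), min_k,
        )
        return None, True
    res = run_meta(kept, full.key, orient=False, **meta_kwargs)
    assert isinstance(res, MetaResult)
    return res, _preserves(full, res, alpha)


def compute_sensitivity_report(
    group: Sequence[StudyRecord],
    full: MetaResult,
    *,
    alpha: float = SIGNIFICANCE_ALPHA,
    hwe_alpha: float = 0.05,
    **meta_kwargs,
) -> SensitivityReport:
    """Run all sensitivity checks for one significant association.

    ``group`` must already be oriented (the full analysis' orientation is
    reused for every subset).
    """
    loo_results, loo_robust = leave_one_out(group, full, alpha=alpha, **meta_kwargs)
    hwe_res, hwe_robust = exclude_scenario(
        group, full, "hwe_violators", alpha=alpha, hwe_alpha=hwe_alpha, **meta_kwargs
    )
    first_res, first_robust = exclude_scenario(
        group, full, "first_published", alpha=alpha, hwe_alpha=hwe_alpha, **meta_kwargs
    )
    return SensitivityReport(
        loo_results=loo_results,
        loo_robust=loo_robust,
        hwe_excluded_result=hwe_res,
        hwe_robust=hwe_robust,
        first_study_excluded_result=first_res,
        first_robust=first_robust,
    )
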