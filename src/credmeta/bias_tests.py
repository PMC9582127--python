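"""Small-study, publication-bias and excess-significance diagnostics.

Egger's test regresses the standardized effect (log OR / SE) on precision
(1 / SE) and examines the intercept: under no small-study effect the
intercept is zero.  Begg's test rank-correlates variance-standardized
deviations from the pooled estimate with the variances, using the
continuity-corrected normal approximation with tie correction.  The
excess-significance test compares the observed number of individually
significant studies with the number expected given each study's power to
detect the pooled effect.

All tests require at least three studies; with fewer they are recorded as
absent rather than raising.  Following common practice for these
low-powered diagnostics, a result is called biased at p < 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genetic_models import TwoByTwo
from .meta_engine import EffectEstimate, pool_fixed_iv

BIAS_ALPHA = 0.1
STUDY_ALPHA = 0.05  # per-study significance level inside excess-significance

MIN_K = 3


@dataclass(frozen=True)
class BiasReport:
    egger_intercept: float | None
    egger_p: float | None
    begg_tau: float | None
    begg_p: float | None
    excess_observed: int | None
    excess_expected: float | None
    excess_p: float | None
    bias_detected: bool

    @property
    def available(self) -> bool:
        return self.egger_p is not None or self.begg_p is not None


def _intercept_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS intercept and its two-sided t-test p-value (k-2 df)."""
    k = len(x)
    res = stats.linregress(x, y)
    if res.intercept_stderr == 0:
        return float(res.intercept), 1.0
    t = res.intercept / res.intercept_stderr
    return float(res.intercept), float(2.0 * stats.t.sf(abs(t), k - 2))


def egger_test(effects: Sequence[EffectEstimate]) -> tuple[float, float] | None:
    """Egger regression asymmetry test; None when fewer than 3 studies."""
    if len(effects) < MIN_K:
        return None
    prec = np.array([1.0 / e.se for e in effects])
    z = np.array([e.log_or / e.se for e in effects])
    if np.ptp(prec) == 0:
        # constant precision: intercept inseparable from slope
        return None
    return _intercept_t_test(prec, z)


def harbord_test(tables: Sequence[TwoByTwo]) -> tuple[float, float] | None:
    """Harbord score-based asymmetry test for 2x2 count data.

    Uses the score Z = a - E[a] and its hypergeometric variance V per study,
    regressing Z/sqrt(V) on sqrt(V).  Less prone than Egger's test to
    inflated type-I error when the odds ratio is large.
    """
    tables = [t for t in tables if t.is_informative]
    if len(tables) < MIN_K:
        return None
    zs, vs = [], []
    for t in tables:
        a, b, c, d = t.cells
        n = a + b + c + d
        e_a = (a + b) * (a + c) / n
        v = (a + b) * (c + d) * (a + c) * (b + d) / (n * n * (n - 1))
        if v <= 0:
            continue
        zs.append((a - e_a) / math.sqrt(v))
        vs.append(math.sqrt(v))
    if len(zs) < MIN_K or np.ptp(vs) == 0:
        return None
    return _intercept_t_test(np.array(vs), np.array(zs))


def _kendall_s_and_var(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Kendall S statistic, tie-corrected variance of S, and tau-b."""
    n = len(x)
    s = 0
    for i in range(n - 1):
        s += int(np.sum(np.sign((x[i + 1:] - x[i]) * (y[i + 1:] - y[i]))))

    def tie_sizes(v: np.ndarray) -> np.ndarray:
        _, counts = np.unique(v, return_counts=True)
        return counts[counts > 1].astype(float)

    tx, ty = tie_sizes(x), tie_sizes(y)
    n0 = n * (n - 1) / 2.0
    n1 = float(np.sum(tx * (tx - 1) / 2.0))
    n2 = float(np.sum(ty * (ty - 1) / 2.0))
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    tau = s / denom if denom > 0 else 0.0

    v0 = n * (n - 1) * (2 * n + 5)
    vt = float(np.sum(tx * (tx - 1) * (2 * tx + 5)))
    vu = float(np.sum(ty * (ty - 1) * (2 * ty + 5)))
    var = (v0 - vt - vu) / 18.0
    if n > 2:
        var += (
            float(np.sum(tx * (tx - 1) * (tx - 2)))
            * float(np.sum(ty * (ty - 1) * (ty - 2)))
            / (9.0 * n * (n - 1) * (n - 2))
        )
    var += (
        float(np.sum(tx * (tx - 1)))
        * float(np.sum(ty * (ty - 1)))
        / (2.0 * n * (n - 1))
    )
    return float(s), var, float(tau)


def begg_test(effects: Sequence[EffectEstimate]) -> tuple[float, float] | None:
    """Begg-Mazumdar rank correlation test; None when fewer than 3 studies.

    Standardizes each deviation from the pooled fixed estimate by
    sqrt(v_i - v_pooled) and rank-correlates with the variances, using the
    continuity-corrected normal approximation.
    """
    if len(effects) < MIN_K:
        return None
    pooled = pool_fixed_iv(effects)
    v = np.array([e.se * e.se for e in effects])
    y = np.array([e.log_or for e in effects])
    v_pooled = pooled.se * pooled.se
    denom = np.sqrt(np.maximum(v - v_pooled, 1e-300))
    t = (y - pooled.log_or) / denom
    if np.allclose(t, t[0]):
        return 0.0, 1.0
    s, var, tau = _kendall_s_and_var(t, v)
    if var <= 0:
        return tau, 1.0
    z = (abs(s) - 1.0) / math.sqrt(var) if abs(s) > 1 else 0.0
    return tau, float(2.0 * stats.norm.sf(z))


def power_to_detect(mu: float, se: float, alpha: float = STUDY_ALPHA) -> float:
    """Normal-approximation power of a study (SE ``se``) to detect log OR ``mu``."""
    z_a = stats.norm.isf(alpha / 2.0)
    r = abs(mu) / se
    return float(stats.norm.cdf(r - z_a) + stats.norm.cdf(-r - z_a))


def excess_significance(
    effects: Sequence[EffectEstimate],
    pooled: EffectEstimate | None,
    alpha: float = STUDY_ALPHA,
) -> tuple[int, float, float] | None:
    """Observed vs expected number of individually significant studies.

    Expected = sum over studies of the power to detect the pooled effect at
    the per-study level ``alpha``.  The p-value is a chi-square
    goodness-of-fit on the two bins (significant / not), replaced by an
    exact binomial tail for fewer than 10 studies.  Returns
    (observed, expected, p) or None when inputs are insufficient.
    """
    if pooled is None or len(effects) < MIN_K:
        return None
    k = len(effects)
    observed = sum(1 for e in effects if e.p_value < alpha)
    expected = sum(power_to_detect(pooled.log_or, e.se, alpha) for e in effects)
    if expected <= 0 or expected >= k:
        return observed, expected, 1.0
    if k < 10:
        pi = expected / k
        if observed >= expected:
            p = float(stats.binom.sf(observed - 1, k, pi))
        else:
            p = float(stats.binom.cdf(observed, k, pi))
    else:
        a = (observed - expected) ** 2 / expected + (observed - expected) ** 2 / (
            k - expected
        )
        p = float(stats.chi2.sf(a, 1))
    return observed, expected, p


def compute_bias_report(
    effects: Sequence[EffectEstimate],
    tables: Sequence[TwoByTwo],
    pooled: EffectEstimate | None,
    *,
    bias_alpha: float = BIAS_ALPHA,
    egger_method: str = "egger",
    enable_excess_significance: bool = False,
) -> BiasReport:
    """Run the available bias diagnostics for one association group.

    ``egger_method`` selects the classic Egger regression (default) or the
    Harbord score variant.  The excess-significance test is optional; when
    enabled it contributes to ``bias_detected`` only if observed > expected
    and its p < ``bias_alpha``.
    """
    if egger_method == "harbord":
        egger = harbord_test(tables)
    elif egger_method == "egger":
        egger = egger_test(effects)
    else:
        raise ValueError(f"unknown egger_method {egger_method!r}")
    begg = begg_test(effects)
    excess = (
        excess_significance(effects, pooled) if enable_excess_significance else None
    )

    detected = False
    if egger is not None and egger[1] < bias_alpha:
        detected = True
    if begg is not None and begg[1] < bias_alpha:
        detected = True
    if excess is not None and excess[0] > excess[1] and excess[2] < bias_alpha:
        detected = True
    return BiasReport(
        egger_intercept=egger[0] if egger else None,
        egger_p=egger[1] if egger else None,
        begg_tau=begg[0] if begg else None,
        begg_p=begg[1] if begg else None,
        excess_observed=excess[0] if excess else None,
        excess_expected=excess[1] if excess else None,
        excess_p=excess[2] if excess else None,
        bias_detected=detected,
    )
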