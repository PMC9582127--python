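"""Synthetic case-control genotype tables with known truth.

The generator emulates the statistical structure the pooling pipeline
assumes: control genotypes in Hardy-Weinberg proportions at a chosen minor
allele frequency, case genotypes tilted by a per-allele (log-additive)
odds ratio so that the allelic OR target is well defined, optional
between-study heterogeneity on the log OR scale, optional
significance-dependent censoring (publication bias), and optional
heterozygote-deficit distortion of controls (HWE violation).  Everything
is reproducible from an integer seed.

The module also ships the printed summary statistics of the source
synthesis' 54 pooled associations (40 of them credibility-graded) as a
packaged TSV, so the grading layer can be exercised without access to the
underlying per-study counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .credibility import alpha_from_ci
from .genetic_models import derive_two_by_two
from .meta_engine import study_effect
from .study_table import GenotypeCounts, StudyRecord


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic association group.

    Defaults mirror a typical stratum of the synthesized literature: a
    handful of datasets with on the order of a thousand cases and a
    thousand controls each, a common variant (control MAF 0.3), a
    per-allele OR of 1.5, no between-study heterogeneity, no publication
    censoring, and HWE-conforming controls.
    """

    k: int = 4
    per_allele_or: float = 1.5
    maf: float = 0.3
    n_cases: int | list[int] = 1000
    n_controls: int | list[int] = 1000
    tau_squared: float = 0.0
    censor_nonsignificant: float = 1.0
    hwe_violation_rate: float = 0.0
    hwe_het_deficit: float = 0.3
    seed: int = 0
    variant_id: str = "rs1000001"
    gene: str = "SYN1"
    disease: str = "LC"
    ethnicity: str = "Asian"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.per_allele_or <= 0:
            raise ConfigError("per_allele_or must be positive")
        if not (0.0 < self.maf <= 0.5):
            raise ConfigError("maf must be in (0, 0.5]")
        if self.tau_squared < 0:
            raise ConfigError("tau_squared must be non-negative")
        for name in ("censor_nonsignificant", "hwe_violation_rate", "hwe_het_deficit"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")

    def sizes(self) -> tuple[list[int], list[int]]:
        def expand(v) -> list[int]:
            if isinstance(v, int):
                return [v] * self.k
            if len(v) != self.k:
                raise ConfigError("per-study size list must have length k")
            return list(v)

        return expand(self.n_cases), expand(self.n_controls)


def _genotype_probs(q: float) -> np.ndarray:
    """HWE genotype probabilities (hom_major, het, hom_minor) at minor freq q."""
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


def _distort_het_deficit(probs: np.ndarray, deficit: float) -> np.ndarray:
    """Move a fraction of heterozygote mass to the homozygotes (inbreeding-like)."""
    moved = probs[1] * deficit
    out = np.array([probs[0] + moved / 2, probs[1] - moved, probs[2] + moved / 2])
    if np.any(out < 0) or not math.isclose(out.sum(), 1.0, rel_tol=1e-9):
        raise ConfigError("invalid genotype probabilities after HWE distortion")
    return out


def _case_probs(ctrl_probs: np.ndarray, psi: float) -> np.ndarray:
    """Case genotype probabilities under the multiplicative risk model."""
    w = ctrl_probs * np.array([1.0, psi, psi * psi])
    return w / w.sum()


def generate_studies(config: SyntheticConfig) -> list[StudyRecord]:
    """Draw one synthetic association group of study records.

    Per study the log OR is drawn Normal(ln psi, tau²); control genotypes
    are multinomial at HWE proportions (optionally het-deficit distorted);
    case genotype probabilities are the control probabilities tilted by
    (1, psi_i, psi_i²).  With ``censor_nonsignificant`` < 1, a study whose
    allelic test is non-significant at 0.05 is retained only with that
    probability, emulating publication bias.  Identical seeds give
    identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n_cases, n_controls = config.sizes()
    ctrl_base = _genotype_probs(config.maf)
    records: list[StudyRecord] = []
    for i in range(config.k):
        psi_i = math.exp(
            rng.normal(math.log(config.per_allele_or), math.sqrt(config.tau_squared))
        )
        ctrl_probs = ctrl_base
        if rng.random() < config.hwe_violation_rate:
            ctrl_probs = _distort_het_deficit(ctrl_base, config.hwe_het_deficit)
        ctrl_counts = rng.multinomial(n_controls[i], ctrl_probs)
        case_counts = rng.multinomial(n_cases[i], _case_probs(ctrl_probs, psi_i))
        rec = StudyRecord(
            study_id=f"{config.variant_id}-{config.disease}-S{i + 1:02d}",
            first_author=f"Author{i + 1}",
            pub_year=2008 + i,
            disease=config.disease,
            variant_id=config.variant_id,
            gene=config.gene,
            ethnicity=config.ethnicity,
            cases=GenotypeCounts(*(int(c) for c in case_counts)),
            controls=GenotypeCounts(*(int(c) for c in ctrl_counts)),
        )
        if config.censor_nonsignificant < 1.0:
            eff = study_effect(derive_two_by_two(rec.cases, rec.controls, "allelic"))
            nonsig = eff is None or eff.p_value >= 0.05
            if nonsig and rng.random() > config.censor_nonsignificant:
                continue
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Packaged summary fixture (printed pooled results of the source synthesis)
# ---------------------------------------------------------------------------


def _parse_p(text: str) -> float | None:
    """Printed p-value string to a number; '<x' maps to x/2, 'Na' to None."""
    if text in ("", "Na"):
        return None
    if text.startswith("<"):
        return float(text[1:]) / 2.0
    return float(text)


def table1_fixture() -> pd.DataFrame:
    """Printed summary rows of the 54 pooled associations (40 graded).

    Columns include the pooled OR with CI, printed p-value and heterogeneity
    strings, the Venice code / FPRP / credibility cells (empty for
    non-significant rows), plus convenience columns: ``p_numeric`` (printed
    value, with '<0.001' mapped below the threshold), ``p_recovered``
    (recovered from the printed OR and CI via the normal approximation),
    ``significant`` and ``graded`` flags.
    """
    with resources.files("credmeta").joinpath("data/table1_summary.tsv").open(
        "r", encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    for col in ("or", "ci_low", "ci_high"):
        df[col] = df[col].astype(float)
    df["datasets"] = df["datasets"].astype(int)
    df["cases"] = df["cases"].astype(int)
    df["controls"] = df["controls"].astype(int)
    df["i_squared_num"] = [
        float(v) if v not in ("", "Na") else np.nan for v in df["i_squared"]
    ]
    df["p_numeric"] = [_parse_p(v) for v in df["p"]]
    df["p_q_numeric"] = [_parse_p(v) for v in df["p_q"]]
    df["fprp_numeric"] = [_parse_p(v) for v in df["fprp"]]
    df["p_recovered"] = [
        alpha_from_ci(lo, hi, orv)
        for lo, hi, orv in zip(df["ci_low"], df["ci_high"], df["or"])
    ]
    df["significant"] = [
        p is not None and p < 0.05 for p in df["p_numeric"]
    ]
    df["graded"] = df["venice_code"] != ""
    return df
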