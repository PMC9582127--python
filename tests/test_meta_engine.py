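"""Effect estimation, pooling, heterogeneity, and model selection."""

import math
import subprocess

import numpy as np
import pytest

from credmeta.genetic_models import TwoByTwo
from credmeta.meta_engine import (
    EffectEstimate,
    MetaResult,
    SkippedResult,
    cochran_q,
    dersimonian_laird,
    i_squared,
    pool_fixed_iv,
    pool_fixed_mh,
    run_meta,
    study_effect,
)
from credmeta.study_table import AssociationKey
from credmeta.synthetic_data import SyntheticConfig, generate_studies

from conftest import make_record

KEY = AssociationKey("rs1", "LC", "Overall", "allelic")


class TestStudyEffect:
    def test_hand_arithmetic(self):
        e = study_effect(TwoByTwo(10, 90, 5, 95))
        assert e.or_value == pytest.approx(950 / 450, rel=1e-4)
        assert e.se == pytest.approx(math.sqrt(1 / 10 + 1 / 90 + 1 / 5 + 1 / 95), rel=1e-4)

    def test_zero_cell_continuity_corrected(self):
        e = study_effect(TwoByTwo(0, 100, 5, 95))
        expected = (0.5 * 95.5) / (100.5 * 5.5)
        assert e.or_value == pytest.approx(expected, rel=1e-4)

    def test_symmetric_table_gives_unity(self):
        assert study_effect(TwoByTwo(10, 90, 10, 90)).or_value == pytest.approx(1.0)

    def test_empty_exposure_margin_is_non_informative(self):
        assert study_effect(TwoByTwo(0, 100, 0, 100)) is None

    def test_ci_brackets_point_estimate(self):
        e = study_effect(TwoByTwo(10, 90, 5, 95))
        assert e.ci_low < e.or_value < e.ci_high


class TestFixedPooling:
    def test_single_table_identity(self):
        t = TwoByTwo(10, 90, 5, 95)
        assert pool_fixed_mh([t]).or_value == pytest.approx(study_effect(t).or_value)

    def test_mantel_haenszel_hand_value(self):
        pooled = pool_fixed_mh([TwoByTwo(10, 90, 5, 95), TwoByTwo(20, 80, 10, 90)])
        assert pooled.or_value == pytest.approx(13.75 / 6.25, rel=1e-9)

    def test_duplicated_table_keeps_the_or(self):
        t = TwoByTwo(10, 90, 5, 95)
        assert pool_fixed_mh([t, t]).or_value == pytest.approx(study_effect(t).or_value)

    def test_iv_equal_weights_is_mean(self):
        effs = [EffectEstimate(0.0, 0.5), EffectEstimate(1.0, 0.5)]
        assert pool_fixed_iv(effs).log_or == pytest.approx(0.5)

    def test_iv_single_effect_identity(self):
        e = EffectEstimate(0.3, 0.1)
        pooled = pool_fixed_iv([e])
        assert (pooled.log_or, pooled.se) == (pytest.approx(0.3), pytest.approx(0.1))

    def test_mh_iv_agree_on_homogeneous_large_count_groups(self):
        """Count-level MH and inverse-variance pooling within 2% when cells are big."""
        checked = 0
        for seed in range(40):
            recs = generate_studies(
                SyntheticConfig(k=6, per_allele_or=1.5, n_cases=800, n_controls=800, seed=seed)
            )
            res = run_meta(recs, KEY)
            assert isinstance(res, MetaResult)
            if min(min(t.cells) for t in res.tables) < 20:
                continue
            iv = pool_fixed_iv(res.effects)
            assert res.fixed.or_value == pytest.approx(iv.or_value, rel=0.02)
            checked += 1
        assert checked >= 30


class TestHeterogeneity:
    def test_identical_effects_give_zero_q(self):
        effs = [EffectEstimate(0.2, 0.1)] * 4
        q, df, p = cochran_q(effs)
        assert q == pytest.approx(0.0)
        assert (df, p) == (3, pytest.approx(1.0))

    def test_hand_value(self):
        q, df, _ = cochran_q([EffectEstimate(0.0, 0.5), EffectEstimate(1.0, 0.5)])
        assert q == pytest.approx(2.0)
        assert df == 1

    def test_single_study_convention(self):
        assert cochran_q([EffectEstimate(0.1, 0.2)]) == (0.0, 0, 1.0)

    @pytest.mark.parametrize(
        "q, df, expected", [(2.0, 1, 50.0), (2.0, 2, 0.0), (10.0, 4, 60.0), (0.0, 0, 0.0)]
    )
    def test_i_squared_formula(self, q, df, expected):
        assert i_squared(q, df) == pytest.approx(expected)


class TestDerSimonianLaird:
    def test_tau_squared_hand_value(self):
        tau2, _ = dersimonian_laird([EffectEstimate(0.0, 0.5), EffectEstimate(1.0, 0.5)])
        assert tau2 == pytest.approx(0.25)

    def test_zero_tau_reproduces_fixed_iv(self):
        effs = [EffectEstimate(0.20, 0.1), EffectEstimate(0.21, 0.12), EffectEstimate(0.19, 0.11)]
        tau2, pooled = dersimonian_laird(effs)
        iv = pool_fixed_iv(effs)
        assert tau2 == 0.0
        assert pooled.log_or == pytest.approx(iv.log_or, abs=1e-12)
        assert pooled.se == pytest.approx(iv.se, abs=1e-12)

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            dersimonian_laird([EffectEstimate(0.0, 0.5)])

    def test_matches_metafor_oracle(self, tmp_path):
        """R metafor (rma, method='DL') agrees on tau², pooled log OR and SE."""
        effs = [
            EffectEstimate(0.50, 0.20),
            EffectEstimate(0.10, 0.15),
            EffectEstimate(-0.20, 0.30),
            EffectEstimate(0.80, 0.25),
            EffectEstimate(0.30, 0.10),
        ]
        yi = ",".join(str(e.log_or) for e in effs)
        vi = ",".join(str(e.se**2) for e in effs)
        script = tmp_path / "dl.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"fit <- rma(yi=c({yi}), vi=c({vi}), method='DL')\n"
            "cat(fit$tau2, fit$beta[1], fit$se, sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout.split()
        tau2_r, b_r, se_r = map(float, out)
        tau2, pooled = dersimonian_laird(effs)
        assert tau2 == pytest.approx(tau2_r, rel=1e-6)
        assert pooled.log_or == pytest.approx(b_r, rel=1e-6)
        assert pooled.se == pytest.approx(se_r, rel=1e-6)


class TestRunMeta:
    def test_two_datasets_skipped(self):
        recs = [make_record("S1"), make_record("S2")]
        res = run_meta(recs, KEY)
        assert isinstance(res, SkippedResult)
        assert res.reason == "fewer than three data sources"

    def test_homogeneous_group_selects_fixed(self):
        recs = generate_studies(SyntheticConfig(k=4, per_allele_or=1.5, seed=3))
        res = run_meta(recs, KEY)
        assert isinstance(res, MetaResult)
        assert res.p_q > 0.1
        assert res.effect_model == "fixed"
        assert res.pooled == res.fixed

    def test_heterogeneous_group_selects_random(self):
        # two sub-populations with opposite strong effects
        recs = generate_studies(SyntheticConfig(k=2, per_allele_or=3.0, seed=4)) + [
            make_record(f"N{i}", cases=(900, 95, 5), controls=(700, 270, 30))
            for i in range(2)
        ]
        res = run_meta(recs, KEY)
        assert isinstance(res, MetaResult)
        assert res.p_q < 0.1
        assert res.effect_model == "random"
        assert res.pooled == res.random
        assert res.tau_squared > 0

    def test_totals_and_df(self):
        recs = generate_studies(SyntheticConfig(k=5, seed=5))
        res = run_meta(recs, KEY)
        assert res.k == 5
        assert res.df == 4
        assert res.n_cases == sum(r.cases.total for r in recs)
        assert res.n_controls == sum(r.controls.total for r in recs)

    def test_recessive_with_no_minor_homozygotes_drops_studies(self):
        # MAF so low that hom_minor is absent everywhere: all non-informative
        recs = [
            make_record(f"S{i}", cases=(95, 5, 0), controls=(96, 4, 0))
            for i in range(4)
        ]
        res = run_meta(recs, AssociationKey("rs1", "LC", "Overall", "recessive"))
        assert isinstance(res, SkippedResult)
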