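"""Venice grading, FPRP, and the combined credibility verdict."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from credmeta.bias_tests import BiasReport
from credmeta.credibility import (
    VeniceGrade,
    alpha_from_ci,
    combine_levels,
    fprp,
    fprp_for_meta,
    grade_association,
    least_common_exposure_count,
    power_at_or,
    venice_amount_grade,
    venice_bias_grade,
    venice_replication_grade,
)
from credmeta.meta_engine import MetaResult, run_meta
from credmeta.sensitivity import SensitivityReport
from credmeta.study_table import AssociationKey
from credmeta.synthetic_data import SyntheticConfig, generate_studies

KEY = AssociationKey("rs1", "LC", "Overall", "allelic")


def bias_report(detected=False):
    return BiasReport(0.0, 0.9 if not detected else 0.01, 0.0, 0.9, None, None, None, detected)


def sens_report(robust=True):
    return SensitivityReport(None, robust, None, True, None, True)


def meta_with_or(or_value, se=0.05):
    """A significant MetaResult with a chosen pooled OR (synthetic scaffold)."""
    recs = generate_studies(SyntheticConfig(k=4, per_allele_or=1.5, seed=17))
    base = run_meta(recs, KEY)
    assert isinstance(base, MetaResult)
    import dataclasses

    from credmeta.meta_engine import EffectEstimate

    est = EffectEstimate(math.log(or_value), se)
    return dataclasses.replace(base, pooled=est, fixed=est)


class TestVeniceAmount:
    @pytest.mark.parametrize(
        "count, grade",
        [(1500, "A"), (1001, "A"), (1000, "B"), (500, "B"), (100, "B"), (99, "C"), (50, "C")],
    )
    def test_thresholds(self, count, grade):
        assert venice_amount_grade(count) == grade

    def test_least_common_exposure_basis(self):
        recs = generate_studies(SyntheticConfig(k=4, seed=17))
        res = run_meta(recs, KEY)
        count = least_common_exposure_count(res)
        exposed = sum(t.case_exposed + t.ctrl_exposed for t in res.tables)
        unexposed = sum(t.case_unexposed + t.ctrl_unexposed for t in res.tables)
        assert count == min(exposed, unexposed)
        assert exposed + unexposed == 2 * (res.n_cases + res.n_controls)  # allelic


class TestVeniceReplication:
    @pytest.mark.parametrize(
        "i2, grade",
        [(25.9, "B"), (0.0, "A"), (84.4, "C"), (25.0, "A"), (50.0, "C"), (49.9, "B")],
    )
    def test_thresholds(self, i2, grade):
        assert venice_replication_grade(i2) == grade

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            venice_replication_grade(101.0)


class TestVeniceBias:
    def test_clean_large_effect_is_a(self):
        meta = meta_with_or(1.630)
        assert venice_bias_grade(meta, bias_report(False), sens_report(True)) == "A"

    def test_bias_detected_is_c(self):
        meta = meta_with_or(1.307)
        assert venice_bias_grade(meta, bias_report(True), sens_report(True)) == "C"

    def test_sensitivity_failure_is_c(self):
        meta = meta_with_or(1.63)
        assert venice_bias_grade(meta, bias_report(False), sens_report(False)) == "C"

    def test_small_or_without_gwas_confirmation_is_c(self):
        meta = meta_with_or(1.124)
        assert venice_bias_grade(meta, bias_report(False), sens_report(True)) == "C"

    def test_small_or_with_gwas_confirmation_escapes_c(self):
        meta = meta_with_or(1.124)
        grade = venice_bias_grade(
            meta, bias_report(False), sens_report(True), gwas_confirmed=True
        )
        assert grade == "A"

    def test_small_protective_or_is_c(self):
        meta = meta_with_or(0.90)
        assert venice_bias_grade(meta, bias_report(False), sens_report(True)) == "C"

    def test_missing_inputs_is_b(self):
        meta = meta_with_or(1.63)
        assert venice_bias_grade(meta, None, sens_report(True)) == "B"
        assert venice_bias_grade(meta, bias_report(False), None) == "B"


class TestPower:
    def test_vanishing_se_gives_full_power(self):
        assert power_at_or(1.5, 1e-6, 0.05) == pytest.approx(1.0)

    def test_boundary_symmetry(self):
        z = stats.norm.isf(0.025)
        se = math.log(1.5) / z
        expected = 0.5 + stats.norm.cdf(-2 * z)
        assert power_at_or(1.5, se, 0.05) == pytest.approx(expected, abs=1e-9)

    def test_normal_cdf_hand_value(self):
        assert power_at_or(1.5, 0.2, 0.05) == pytest.approx(0.527, abs=5e-4)

    def test_protective_target_inverted(self):
        assert power_at_or(1 / 1.5, 0.2, 0.05) == pytest.approx(
            power_at_or(1.5, 0.2, 0.05)
        )


class TestFprp:
    def test_hand_value(self):
        assert fprp(0.05, 0.8, 0.05).fprp == pytest.approx(0.0475 / 0.0875, rel=1e-9)

    def test_small_alpha_limit(self):
        assert fprp(1e-12, 0.8, 0.05).fprp < 1e-9

    def test_prior_near_one_limit(self):
        assert fprp(0.05, 0.8, 1 - 1e-9).fprp == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize(
        "value, grade", [(0.049, "strong"), (0.05, "moderate"), (0.2, "moderate"), (0.21, "weak")]
    )
    def test_grade_bands(self, value, grade):
        from credmeta.credibility import FprpResult

        res = FprpResult(alpha=0.01, power=1.0, prior=0.05, fprp=value)
        assert res.grade == grade
        assert res.noteworthy == (value < 0.2)

    @settings(max_examples=200, derandomize=True)
    @given(
        a1=st.floats(1e-6, 0.5),
        a2=st.floats(1e-6, 0.5),
        power=st.floats(0.01, 1.0),
        prior=st.floats(1e-4, 0.999),
        delta=st.floats(1e-4, 0.5),
    )
    def test_monotonicity(self, a1, a2, power, prior, delta):
        """FPRP increases in alpha, decreases in power and prior."""
        lo, hi = sorted((a1, a2))
        if lo < hi:
            assert fprp(lo, power, prior).fprp <= fprp(hi, power, prior).fprp
        base = fprp(lo, power, prior).fprp
        if power - delta > 0.01:
            assert fprp(lo, power - delta, prior).fprp >= base
        if prior + delta < 0.999:
            assert fprp(lo, power, prior + delta).fprp <= base


class TestCombine:
    @pytest.mark.parametrize(
        "code, fgrade, final",
        [
            ("AAA", "strong", "Strong"),
            ("BAA", "strong", "Strong"),
            ("AAC", "strong", "Moderate"),
            ("AAA", "weak", "Moderate"),
            ("AAA", "moderate", "Strong"),
            ("ACC", "weak", "Weak"),
            ("ABA", "moderate", "Moderate"),
        ],
    )
    def test_upgrade_downgrade_rules(self, code, fgrade, final):
        venice = VeniceGrade(code[0], code[1], code[2])
        assert combine_levels(venice.venice_class, fgrade) == final

    @pytest.mark.parametrize(
        "code, cls", [("AAA", "strong"), ("BAA", "moderate"), ("ABB", "moderate"), ("AAC", "weak")]
    )
    def test_venice_class_rule(self, code, cls):
        assert VeniceGrade(code[0], code[1], code[2]).venice_class == cls


class TestAlphaRecovery:
    def test_published_row_recovers_sub_millesimal_p(self):
        # OR 1.630 (1.293-2.054): z about 4.14, p about 3.5e-5
        p = alpha_from_ci(1.293, 2.054, 1.630)
        assert p < 0.001
        assert p == pytest.approx(3.5e-5, rel=0.1)


class TestGradeAssociation:
    def test_full_grading_of_clean_synthetic_association(self):
        recs = generate_studies(
            SyntheticConfig(k=5, per_allele_or=1.5, n_cases=1500, n_controls=1500, seed=23)
        )
        res = run_meta(recs, KEY)
        verdict = grade_association(res, bias_report(False), sens_report(True))
        assert verdict.venice.code == "AAA"
        assert verdict.fprp_grade == "strong"
        assert verdict.final == "Strong"

    def test_amount_basis_switch(self):
        recs = generate_studies(SyntheticConfig(k=4, seed=17))
        res = run_meta(recs, KEY)
        v1 = grade_association(res, bias_report(False), sens_report(True), amount_basis="total")
        assert v1.venice.amount == "A"
        with pytest.raises(ValueError):
            grade_association(res, None, None, amount_basis="bogus")

    def test_fprp_alpha_is_pooled_p(self):
        recs = generate_studies(SyntheticConfig(k=4, seed=17))
        res = run_meta(recs, KEY)
        assert fprp_for_meta(res).alpha == pytest.approx(res.pooled.p_value)
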