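"""Biodiesel property equations and fuel-standard compliance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from algatrait.biodiesel import (
    ASTM_D6751,
    EN14214,
    BiodieselError,
    cetane_number,
    check_compliance,
    cold_filter_plugging_point,
    degree_of_unsaturation,
    evaluate_properties,
    flag_inconsistent_row,
    iodine_value,
    long_chain_saturation_factor,
    oxidative_stability,
    saponification_value,
)
from algatrait.fame import (
    ClassTotals,
    FAMEComponent,
    FAMEProfile,
    FattyAcid,
    fame_molecular_mass,
)


def _single(n, d, pct, omega="unspecified"):
    return FAMEProfile((FAMEComponent(FattyAcid(n, d, omega), pct),))


class TestReferenceProfile:
    """The published composition reproduces its printed descriptor row."""

    def test_saponification_value(self, reference_profile):
        assert saponification_value(reference_profile) == pytest.approx(
            171.39, abs=0.5
        )

    def test_iodine_value(self, reference_profile):
        assert iodine_value(reference_profile) == pytest.approx(169.05, abs=0.5)

    def test_degree_of_unsaturation(self, reference_profile):
        from algatrait.fame import class_totals

        assert degree_of_unsaturation(class_totals(reference_profile)) == (
            pytest.approx(122.92, abs=1e-9)
        )

    def test_lcsf_and_cfpp(self, reference_profile):
        lcsf = long_chain_saturation_factor(reference_profile)
        assert lcsf == pytest.approx(2.371, abs=0.005)
        assert cold_filter_plugging_point(lcsf) == pytest.approx(-9.03, abs=0.01)

    def test_oxidative_stability(self, reference_profile):
        # X = 6.81 + 3.84 + 31.55 = 42.20 -> 117.9295/42.20 + 2.5905
        assert oxidative_stability(reference_profile) == pytest.approx(
            5.39, abs=0.02
        )

    def test_omega6_only_os_uses_smaller_x(self, reference_profile):
        full = oxidative_stability(reference_profile)
        w6 = oxidative_stability(reference_profile, omega6_only=True)
        assert w6 > full  # X shrinks from 42.20 to 10.65, OS rises


class TestSingleComponentValues:
    def test_sv_pure_palmitate(self):
        assert saponification_value(_single(16, 0, 100.0)) == pytest.approx(
            207.06, abs=0.05
        )

    def test_iv_pure_oleate(self):
        assert iodine_value(_single(18, 1, 100.0, "w9")) == pytest.approx(
            85.67, abs=0.05
        )

    def test_iv_all_saturated_is_zero(self):
        assert iodine_value(_single(16, 0, 100.0)) == 0.0

    def test_lcsf_heavy_saturates_by_hand(self):
        profile = FAMEProfile(
            (
                FAMEComponent(FattyAcid(20, 0), 1.0),
                FAMEComponent(FattyAcid(22, 0), 1.0),
                FAMEComponent(FattyAcid(24, 0), 1.0),
            )
        )
        assert long_chain_saturation_factor(profile) == pytest.approx(4.5)

    def test_lcsf_ignores_short_and_unsaturated(self):
        profile = FAMEProfile(
            (
                FAMEComponent(FattyAcid(14, 0), 10.0),
                FAMEComponent(FattyAcid(18, 1, "w9"), 50.0),
            )
        )
        assert long_chain_saturation_factor(profile) == 0.0


class TestFormulaStructure:
    def test_cfpp_intercept(self):
        assert cold_filter_plugging_point(0.0) == pytest.approx(-16.477)

    def test_cfpp_published_cross_row(self):
        # second strain's printed LCSF reproduces its printed CFPP
        assert cold_filter_plugging_point(2.99) == pytest.approx(-7.08, abs=0.02)

    def test_cn_published_cross_row(self):
        # second strain's printed SV/IV reproduce its printed CN
        assert cetane_number(205.11, 171.65) == pytest.approx(34.29, abs=0.02)

    def test_cn_structure_at_zero_iv(self):
        assert cetane_number(5458.0 / 12.5, 0.0) == pytest.approx(46.3 + 12.5)

    def test_cn_decreasing_in_iv(self):
        assert cetane_number(180.0, 100.0) > cetane_number(180.0, 150.0)

    def test_cn_rejects_nonpositive_sv(self):
        with pytest.raises(BiodieselError):
            cetane_number(0.0, 10.0)

    def test_du_arithmetic(self):
        assert degree_of_unsaturation(ClassTotals(0, 10, 20)) == 50.0
        assert degree_of_unsaturation(ClassTotals(0, 0, 0)) == 0.0

    def test_os_unit_quotient(self):
        assert oxidative_stability(_single(18, 2, 100.0, "w6")) < (
            oxidative_stability(_single(18, 2, 50.0, "w6"))
        )
        prof = _single(18, 2, 100.0, "w6")
        # X = 100 -> 117.9295/100 + 2.5905
        assert oxidative_stability(prof) == pytest.approx(1.179295 + 2.5905)

    def test_os_undefined_without_c18_polyunsaturates(self):
        with pytest.raises(BiodieselError, match="not computable"):
            oxidative_stability(_single(16, 0, 100.0))

    @pytest.mark.parametrize("fn", [saponification_value, iodine_value])
    def test_empty_profile_rejected(self, fn):
        with pytest.raises(BiodieselError):
            fn(FAMEProfile(()))


@st.composite
def small_profiles(draw):
    pool = [(14, 0), (16, 0), (16, 1), (18, 0), (18, 1), (18, 2), (18, 3),
            (20, 0), (20, 4), (22, 6)]
    n = draw(st.integers(1, 8))
    keys = draw(st.lists(st.sampled_from(pool), min_size=n, max_size=n,
                         unique=True))
    weights = draw(st.lists(st.floats(0.01, 12.0), min_size=n, max_size=n))
    return FAMEProfile(
        tuple(FAMEComponent(FattyAcid(c, d), w) for (c, d), w in zip(keys, weights))
    )


@given(small_profiles())
def test_sv_iv_match_per_component_oracle(profile):
    sv = sum(560.0 * c.weight_percent / fame_molecular_mass(c.acid) for c in profile)
    iv = sum(
        254.0 * c.acid.double_bonds * c.weight_percent / fame_molecular_mass(c.acid)
        for c in profile
    )
    assert saponification_value(profile) == pytest.approx(sv, rel=1e-12)
    assert iodine_value(profile) == pytest.approx(iv, rel=1e-12)


@given(small_profiles(), st.floats(0.1, 2.0))
def test_sv_iv_homogeneous_in_weights(profile, scale):
    if profile.total_percent * scale > 100:
        return
    scaled = FAMEProfile(
        tuple(
            FAMEComponent(c.acid, c.weight_percent * scale) for c in profile
        )
    )
    assert saponification_value(scaled) == pytest.approx(
        scale * saponification_value(profile), rel=1e-9
    )
    assert iodine_value(scaled) == pytest.approx(
        scale * iodine_value(profile), rel=1e-9, abs=1e-12
    )


class TestEvaluateProperties:
    def test_fields_equal_individual_operations(self, reference_profile):
        from algatrait.fame import class_totals

        props = evaluate_properties(reference_profile)
        assert props.sv == saponification_value(reference_profile)
        assert props.iv == iodine_value(reference_profile)
        assert props.lcsf == long_chain_saturation_factor(reference_profile)
        assert props.cfpp == cold_filter_plugging_point(props.lcsf)
        assert props.cn == cetane_number(props.sv, props.iv)
        assert props.os_hours == oxidative_stability(reference_profile)
        totals = class_totals(reference_profile)
        assert props.du == degree_of_unsaturation(totals)

    def test_internal_consistency_invariants(self, reference_profile):
        props = evaluate_properties(reference_profile)
        assert props.du == pytest.approx(
            props.mufa_percent + 2 * props.pufa_percent, abs=1e-9
        )
        assert props.cfpp == pytest.approx(
            3.1417 * props.lcsf - 16.477, abs=1e-9
        )

    def test_pure_palmitate_hand_values(self):
        props = evaluate_properties(_single(16, 0, 100.0))
        assert props.du == 0.0
        assert props.iv == 0.0
        assert props.lcsf == pytest.approx(10.0)
        assert props.cfpp == pytest.approx(3.1417 * 10 - 16.477, abs=1e-9)
        assert props.os_hours is None  # no C18:2/C18:3 content

    def test_empty_profile_rejected(self):
        with pytest.raises(BiodieselError):
            evaluate_properties(FAMEProfile(()))


class TestCompliance:
    def test_reference_strain_verdicts_en14214(self, reference_profile):
        props = evaluate_properties(reference_profile)
        report = check_compliance(props, EN14214)
        assert not report.verdict("iv").passed  # 169 > 120
        assert not report.verdict("cn").passed  # < 51
        assert report.verdict("cfpp").passed  # -9.03 within [-20, 5]

    def test_astm_os_passes(self, reference_profile):
        props = evaluate_properties(reference_profile)
        report = check_compliance(props, ASTM_D6751)
        assert report.verdict("os").passed  # 5.39 >= 3

    def test_every_configured_criterion_appears_once(self, reference_profile):
        props = evaluate_properties(reference_profile)
        report = check_compliance(props, EN14214)
        names = [c.criterion for c in report.criteria]
        assert sorted(names) == ["cfpp", "cn", "iv", "os"]

    def test_undefined_os_fails_os_bound(self):
        props = evaluate_properties(_single(16, 0, 100.0))
        report = check_compliance(props, ASTM_D6751)
        assert not report.verdict("os").passed


class TestPublishedRowConsistency:
    """The equations reproduce one published row exactly but not the
    study strain's printed CN/OS — the implementation flags, not forces."""

    def test_consistent_row_flagged_consistent(self):
        flags = flag_inconsistent_row(
            {"sv": 205.11, "iv": 171.65, "cn": 34.29, "lcsf": 2.99,
             "cfpp": -7.08}
        )
        assert flags["cn_consistent"]
        assert flags["cfpp_consistent"]

    def test_study_strain_cn_flagged_inconsistent(self):
        flags = flag_inconsistent_row(
            {"sv": 171.39, "iv": 169.05, "cn": 35.04, "lcsf": 2.37,
             "cfpp": -9.03}
        )
        assert not flags["cn_consistent"]  # formula gives ~40.11, not 35.04
        assert flags["cfpp_consistent"]
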