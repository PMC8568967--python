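"""Trait matching: decision tree, availability windows, cover aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nectarweb.traits import (
    AccessibilityVerdict,
    FlowerMorphology,
    InsectMorphology,
    Reason,
    accessible_cover,
    nectar_accessible,
    nectar_available,
    trait_coverage_report,
    verdict_matrix,
)


def insect(head=1.0, x=1.0, z=0.1, a0=1, a1=365):
    return InsectMorphology("ins", head, x, z, a0, a1)


def flower(w=1.0, h=1.0, p=0.5, d=None, ntype="floral", f0=1, f1=365):
    return FlowerMorphology("fl", w, h, p, d, ntype, f0, f1)


def oracle_accessible(r, x, z, w, h, p, d):
    """Independent nested-conditional coding of the accessibility rules."""
    if w >= 2 * r:
        if x >= p:
            if d is None:
                return True
            if z <= d:
                return True
            return False
        return False
    if x >= h + p:
        if d is None:
            return True
        if z <= d:
            return True
        return False
    return False


class TestDecisionTree:
    @pytest.mark.parametrize(
        "ins,fl,accessible,reason",
        [
            # extrafloral nectar is accessible to any insect
            (insect(), flower(ntype="extrafloral"), True, Reason.EXTRAFLORAL),
            (insect(head=50, x=0.01), flower(ntype="both"), True, Reason.EXTRAFLORAL),
            # head enters but proboscis cannot span the nectar holder
            (insect(0.4, 0.3, 0.05), flower(1.0, 2.0, 1.0, 0.2), False,
             Reason.FAIL_PENETRATION_REACH),
            # head excluded, long proboscis spans corolla + tube, narrow enough
            (insect(2.0, 1.5, 0.1), flower(1.0, 0.5, 0.8, 0.3), True,
             Reason.OPEN_REACH),
            # proboscis too wide for the nectar tube
            (insect(0.4, 5.0, 0.4), flower(1.0, 0.5, 0.2, 0.3), False,
             Reason.FAIL_TUBE_WIDTH),
            # no nectar at all
            (insect(), flower(ntype="none"), False, Reason.FAIL_NO_NECTAR),
            # head enters and reaches into an open nectary
            (insect(1.0, 0.8, 0.15), flower(2.0, 1.0, 0.5, None), True,
             Reason.HEAD_ENTRY_REACH),
        ],
    )
    def test_examples(self, ins, fl, accessible, reason):
        v = nectar_accessible(ins, fl)
        assert v.accessible is accessible
        assert v.reason is reason

    def test_missing_trait_is_verdict_not_exception(self):
        fl = FlowerMorphology("fl", opening_width=None, corolla_height=1.0, nectar_depth=0.5)
        v = nectar_accessible(insect(), fl)
        assert not v.accessible and v.reason is Reason.FAIL_MISSING_TRAIT

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            InsectMorphology("i", -1.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            FlowerMorphology("f", opening_width=-0.5)

    def test_verdict_consistency_enforced(self):
        with pytest.raises(ValueError):
            AccessibilityVerdict(True, Reason.FAIL_NO_NECTAR)

    def test_oracle_grid_agreement_small(self):
        # 3^7 spot grid; the full 5^7 sweep runs in the acceptance suite
        vals = [0.2, 1.0, 3.0]
        dvals = [None, 0.05, 1.0]
        for head in vals:
            for x in vals:
                for z in vals:
                    for w in vals:
                        for h in vals:
                            for p in vals:
                                for d in dvals:
                                    got = nectar_accessible(
                                        insect(head, x, z), flower(w, h, p, d)
                                    ).accessible
                                    assert got == oracle_accessible(
                                        head / 2, x, z, w, h, p, d
                                    )

    @settings(max_examples=200, derandomize=True)
    @given(
        head=st.floats(0.1, 5), x=st.floats(0.1, 8), z=st.floats(0.01, 1),
        w=st.floats(0, 6), h=st.floats(0, 4), p=st.floats(0, 4),
        d=st.one_of(st.none(), st.floats(0.01, 1)),
        bump=st.floats(0.01, 3),
    )
    def test_monotonicity(self, head, x, z, w, h, p, d, bump):
        base = nectar_accessible(insect(head, x, z), flower(w, h, p, d)).accessible
        # longer proboscis never loses access
        assert nectar_accessible(insect(head, x + bump, z), flower(w, h, p, d)).accessible >= base
        # thinner proboscis never loses access
        z2 = max(z - bump, 1e-6)
        assert nectar_accessible(insect(head, x, z2), flower(w, h, p, d)).accessible >= base
        # deeper nectar / taller corolla never grants access
        assert nectar_accessible(insect(head, x, z), flower(w, h, p + bump, d)).accessible <= base
        assert nectar_accessible(insect(head, x, z), flower(w, h + bump, p, d)).accessible <= base


class TestAvailability:
    def test_window_overlap(self):
        ins = insect(a0=140, a1=160)
        assert nectar_available(flower(f0=100, f1=150), ins)
        assert not nectar_available(flower(f0=100, f1=120), ins)

    def test_extrafloral_producer_always_available(self):
        ins = insect(a0=10, a1=20)
        assert nectar_available(flower(ntype="extrafloral", f0=200, f1=210), ins)

    def test_no_nectar_never_available(self):
        assert not nectar_available(flower(ntype="none"), insect())

    def test_survey_mode(self):
        ins = insect(a0=140, a1=160)
        fl = flower()
        assert nectar_available(fl, ins, "survey", survey_stage=6, survey_date=150)
        assert not nectar_available(fl, ins, "survey", survey_stage=2, survey_date=150)
        assert not nectar_available(fl, ins, "survey", survey_stage=6, survey_date=100)
        with pytest.raises(ValueError):
            nectar_available(fl, ins, "survey", survey_stage=11, survey_date=150)


class TestAccessibleCover:
    def test_hand_sum(self):
        flora = {
            "A": flower(2.0, 0.2, 0.1),   # easily accessible
            "B": flower(0.1, 5.0, 5.0),   # unreachable
            "C": flower(ntype="extrafloral"),
        }
        covers = {"A": 30.0, "B": 20.0, "C": 10.0}
        assert accessible_cover(covers, flora, insect()) == pytest.approx(40.0)

    def test_bounds(self):
        flora = {"A": flower(2.0, 0.2, 0.1), "B": flower(ntype="extrafloral")}
        covers = {"A": 15.0, "B": 25.0}
        assert accessible_cover(covers, flora, insect()) == pytest.approx(40.0)
        assert accessible_cover(covers, {"A": flower(ntype="none"), "B": flower(ntype="none")}, insect()) == 0.0

    def test_missing_species_warn_and_contribute_zero(self):
        flora = {"A": flower(2.0, 0.2, 0.1)}
        with pytest.warns(UserWarning):
            total = accessible_cover({"A": 10.0, "ghost": 50.0}, flora, insect())
        assert total == pytest.approx(10.0)

    def test_additive_and_order_invariant(self):
        flora = {c: flower(2.0, 0.2, 0.1) for c in "ABCD"}
        c1 = {"A": 1.0, "B": 2.0}
        c2 = {"C": 3.0, "D": 4.0}
        both = {**c2, **c1}
        ins = insect()
        assert accessible_cover(both, flora, ins) == pytest.approx(
            accessible_cover(c1, flora, ins) + accessible_cover(c2, flora, ins)
        )


class TestCoverageReport:
    def test_complete_and_incomplete(self):
        full = {f"s{i}": flower(1, 1, 1, 0.1) for i in range(10)}
        rep = trait_coverage_report(full)
        assert rep["species_complete_fraction"] == 1.0
        full["s9"] = flower(1, 1, 1, None)
        rep = trait_coverage_report(full)
        assert rep["species_complete_fraction"] == pytest.approx(0.9)
        assert rep["per_trait"]["tube_diameter"] == pytest.approx(0.9)
        assert rep["incomplete_species"] == ["s9"]

    def test_empty_flora(self):
        rep = trait_coverage_report({})
        assert rep["n_species"] == 0
        assert np.isnan(rep["species_complete_fraction"])


def test_verdict_matrix_shape(mini):
    vm = verdict_matrix(mini["morphology"], mini["parasitoids"])
    assert vm.shape == (4, 2)
    assert set(np.unique(vm.to_numpy())) <= {0, 1}
    # morphology-only verdicts for the miniature dataset
    assert vm.loc["plant_c"].tolist() == [1, 1]  # extrafloral
    assert vm.loc["plant_d"].tolist() == [0, 0]  # no nectar
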