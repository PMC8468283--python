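"""Dose-response scaling of pooled relative risks."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from grainsave import (
    DoseResponseRR,
    ExtrapolationWarning,
    IntakeGap,
    ValidationError,
    compute_gap,
    scale_risk_reduction,
)

CRC_RR = DoseResponseRR("colorectal cancer", 0.83, 0.78, 0.89, 90.0, n_studies=6)
TC_RR = DoseResponseRR("total cancer mortality", 0.85, 0.80, 0.91, 90.0, n_studies=6)


@st.composite
def rr_records(draw):
    central = draw(st.floats(0.5, 1.15))
    lo = draw(st.floats(0.0, 0.2))
    hi = draw(st.floats(0.0, 0.2))
    return DoseResponseRR(
        "synthetic",
        rr_central=central,
        rr_lower=max(central - lo, 1e-3),
        rr_upper=central + hi,
        reference_dose=draw(st.floats(10.0, 200.0)),
    )


class TestComputeGap:
    @pytest.mark.parametrize(
        "current, target, expected",
        [(21, 48, 27), (48, 48, 0), (17, 48, 31)],
    )
    def test_gap_is_target_minus_current(self, current, target, expected):
        assert compute_gap(current, target).gap == expected

    def test_negative_intakes_rejected(self):
        with pytest.raises(ValidationError):
            compute_gap(-1, 48)
        with pytest.raises(ValidationError):
            compute_gap(21, -48)


class TestScaleRiskReduction:
    @pytest.mark.parametrize(
        "rr, expected_pct",
        [
            (CRC_RR, (5.1, 3.3, 6.6)),
            (TC_RR, (4.5, 2.7, 6.0)),
        ],
    )
    def test_published_reductions_for_27g_gap(self, rr, expected_pct):
        red = scale_risk_reduction(rr, 27.0)
        got = (100 * red.central, 100 * red.lower, 100 * red.upper)
        assert got == pytest.approx(expected_pct, abs=1e-9)

    def test_null_effect_gives_zero_reduction(self):
        rr = DoseResponseRR("null", 1.0, 1.0, 1.0, 90.0)
        red = scale_risk_reduction(rr, 27.0)
        assert (red.central, red.lower, red.upper) == (0.0, 0.0, 0.0)

    def test_bound_swap(self):
        """The weakest protection (upper RR) gives the lowest reduction."""
        red = scale_risk_reduction(CRC_RR, 27.0)
        assert red.lower == pytest.approx((1 - 0.89) * 27 / 90)
        assert red.upper == pytest.approx((1 - 0.78) * 27 / 90)

    def test_gap_equal_to_dose_recovers_one_minus_rr(self):
        red = scale_risk_reduction(CRC_RR, 90.0)
        assert red.central == 1.0 - 0.83

    def test_intake_gap_object_accepted(self):
        red = scale_risk_reduction(CRC_RR, compute_gap(21, 48))
        assert red.gap == 27.0

    def test_extrapolation_beyond_dose_warns(self):
        with pytest.warns(ExtrapolationWarning):
            red = scale_risk_reduction(CRC_RR, 120.0)
        assert "extrapolated" in red.flags

    def test_harmful_rr_flagged_not_rejected(self):
        rr = DoseResponseRR("harmful", 1.10, 1.02, 1.20, 90.0)
        with pytest.warns(UserWarning):
            red = scale_risk_reduction(rr, 27.0)
        assert red.central < 0
        assert "increased_risk" in red.flags
        assert red.lower <= red.central <= red.upper

    def test_negative_gap_rejected(self):
        with pytest.raises(ValidationError):
            scale_risk_reduction(CRC_RR, -1.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            scale_risk_reduction(CRC_RR, 27.0, mode="quadratic")

    def test_strict_content_units_divides_by_content_dose(self):
        """90 g product = 48 g content, so the strict mode scales by 27/48."""
        red = scale_risk_reduction(CRC_RR, 27.0, strict_content_units=True)
        assert red.scaling_dose == pytest.approx(48.0)
        assert red.central == pytest.approx((1 - 0.83) * 27 / 48)

    @given(rr=rr_records(), gap=st.floats(0.0, 100.0))
    def test_linearity_in_gap(self, rr, gap):
        one = scale_risk_reduction(rr, gap)
        two = scale_risk_reduction(rr, 2 * gap)
        assert two.central == pytest.approx(2 * one.central, rel=1e-12, abs=1e-15)

    @given(rr=rr_records(), gap=st.floats(0.0, 100.0))
    def test_bound_ordering_preserved(self, rr, gap):
        red = scale_risk_reduction(rr, gap)
        assert red.lower <= red.central + 1e-12
        assert red.central <= red.upper + 1e-12

    @given(
        central=st.floats(0.8, 1.0),
        frac=st.floats(0.0, 0.5),
    )
    def test_log_linear_agrees_to_first_order(self, central, frac):
        """1 - RR^k and (1 - RR) k stay close for RR in [0.8, 1], k <= 0.5.

        The gap is widest at the corner RR = 0.8, k = 0.5, where
        1 - sqrt(0.8) = 0.10557 vs 0.1 linearly, i.e. 0.0056.
        """
        rr = DoseResponseRR("x", central, central, central, 90.0)
        gap = frac * 90.0
        lin = scale_risk_reduction(rr, gap, mode="linear")
        log = scale_risk_reduction(rr, gap, mode="log-linear")
        assert abs(lin.central - log.central) <= 0.0056

    def test_log_linear_at_full_dose_equals_one_minus_rr(self):
        red = scale_risk_reduction(CRC_RR, 90.0, mode="log-linear")
        assert red.central == pytest.approx(1 - 0.83)


class TestValidation:
    def test_rr_bounds_must_be_ordered(self):
        with pytest.raises(ValidationError):
            DoseResponseRR("bad", 0.83, 0.89, 0.78, 90.0)

    def test_rr_lower_must_be_positive(self):
        with pytest.raises(ValidationError):
            DoseResponseRR("bad", 0.83, 0.0, 0.89, 90.0)

    def test_reference_dose_must_be_positive(self):
        with pytest.raises(ValidationError):
            DoseResponseRR("bad", 0.83, 0.78, 0.89, 0.0)

    def test_intake_gap_may_be_negative_but_intakes_not(self):
        assert IntakeGap(48, 21).gap == -27
        with pytest.raises(ValidationError):
            IntakeGap(-1, 21)
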