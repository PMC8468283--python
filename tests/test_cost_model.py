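"""Expenditure inflation and annual savings computation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from grainsave import (
    DoseResponseRR,
    ExpenditureTable,
    SavingsCell,
    ValidationError,
    compute_savings,
    inflate,
    scale_risk_reduction,
)

CRC_REDUCTION = scale_risk_reduction(
    DoseResponseRR("colorectal cancer", 0.83, 0.78, 0.89, 90.0), 27.0
)


def small_table(amounts, condition="c", year="2020"):
    return ExpenditureTable(
        condition, year,
        tuple((f"cat{i}", a) for i, a in enumerate(amounts)),
    )


amount_lists = st.lists(st.floats(0.0, 5000.0), min_size=1, max_size=12)


class TestExpenditureTable:
    def test_total_is_category_sum(self):
        t = small_table([1.0, 2.5, 3.5])
        assert t.total == pytest.approx(7.0)

    def test_negative_amount_rejected(self):
        with pytest.raises(ValidationError):
            small_table([1.0, -0.1])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValidationError):
            ExpenditureTable("c", "2020", (("a", 1.0), ("a", 2.0)))

    def test_stated_total_checked_within_rounding_tolerance(self):
        # two categories printed at 1 decimal: tolerance 2 * 0.05
        ExpenditureTable("c", "2020", (("a", 1.04), ("b", 2.0)), stated_total=3.1)
        with pytest.raises(ValidationError):
            ExpenditureTable("c", "2020", (("a", 1.3), ("b", 2.0)), stated_total=3.1)

    def test_csv_round_trip(self, tmp_path):
        t = small_table([0.3, 113.8, 195.2])
        p = tmp_path / "t.csv"
        t.to_csv(p)
        back = ExpenditureTable.from_csv(p, condition="c", year="2020")
        assert back == t

    def test_csv_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("name,value\nx,1\n")
        with pytest.raises(ValidationError):
            ExpenditureTable.from_csv(p, condition="c", year="2020")


class TestInflate:
    def test_identity_factor(self):
        t = small_table([1.0, 2.0])
        assert inflate(t, 1.0).categories == t.categories

    def test_scales_every_category_and_relabels_year(self):
        t = small_table([10.0, 20.0], year="2015-16")
        out = inflate(t, 1.1, year="2020")
        assert out.year == "2020"
        assert out.names == t.names
        assert [a for _, a in out.categories] == pytest.approx([11.0, 22.0])

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValidationError):
            inflate(small_table([1.0]), 0.0)

    @given(amounts=amount_lists, factor=st.floats(0.5, 2.0))
    def test_round_trip(self, amounts, factor):
        t = small_table(amounts)
        back = inflate(inflate(t, factor), 1.0 / factor)
        for (_, a), (_, b) in zip(t.categories, back.categories):
            assert b == pytest.approx(a, rel=1e-12, abs=1e-12)


class TestComputeSavings:
    def test_universal_crc_total(self):
        """728.9 m expenditure at 5.1% (3.3-6.6) reduction, full uptake."""
        t = small_table([728.9])
        rep = compute_savings(t, CRC_REDUCTION, 1.0)
        assert rep.total.central == pytest.approx(37.17, abs=0.005)
        assert rep.total.lower == pytest.approx(24.05, abs=0.005)
        assert rep.total.upper == pytest.approx(48.11, abs=0.005)

    def test_single_category_value(self):
        t = small_table([129.6])
        rep = compute_savings(t, CRC_REDUCTION, 1.0)
        assert rep.total.central == pytest.approx(6.61, abs=0.005)

    def test_zero_uptake_gives_zero_savings(self):
        t = small_table([1.0, 2.0, 3.0])
        rep = compute_savings(t, CRC_REDUCTION, 0.0)
        assert rep.total == SavingsCell.zero()
        assert all(c == SavingsCell.zero() for _, c in rep.per_category)

    def test_uptake_out_of_range_rejected(self):
        t = small_table([1.0])
        for bad in (-0.1, 1.1):
            with pytest.raises(ValidationError):
                compute_savings(t, CRC_REDUCTION, bad)

    def test_negative_reduction_flagged(self):
        rr = DoseResponseRR("harmful", 1.1, 1.05, 1.15, 90.0)
        with pytest.warns(UserWarning):
            red = scale_risk_reduction(rr, 27.0)
        with pytest.warns(UserWarning):
            rep = compute_savings(small_table([100.0]), red, 1.0)
        assert "cost_increase" in rep.flags
        assert rep.total.central < 0

    @given(amounts=amount_lists, uptake=st.floats(0.0, 1.0), k=st.floats(0.0, 3.0))
    def test_homogeneity_in_amounts_and_uptake(self, amounts, uptake, k):
        t = small_table(amounts)
        doubled = small_table([a * k for a in amounts])
        base = compute_savings(t, CRC_REDUCTION, uptake)
        scaled = compute_savings(doubled, CRC_REDUCTION, uptake)
        assert scaled.total.central == pytest.approx(
            k * base.total.central, rel=1e-9, abs=1e-9
        )
        half = compute_savings(t, CRC_REDUCTION, uptake / 2)
        assert half.total.central == pytest.approx(
            base.total.central / 2, rel=1e-9, abs=1e-12
        )

    @given(amounts=amount_lists, uptake=st.floats(0.0, 1.0))
    def test_additivity_total_equals_collapsed_table(self, amounts, uptake):
        t = small_table(amounts)
        collapsed = small_table([sum(amounts)])
        many = compute_savings(t, CRC_REDUCTION, uptake)
        one = compute_savings(collapsed, CRC_REDUCTION, uptake)
        assert many.total.central == pytest.approx(
            one.total.central, rel=1e-9, abs=1e-9
        )

    @given(amounts=amount_lists, uptake=st.floats(0.0, 1.0))
    def test_bound_ordering_in_every_cell(self, amounts, uptake):
        rep = compute_savings(small_table(amounts), CRC_REDUCTION, uptake)
        for _, c in list(rep.per_category) + [("total", rep.total)]:
            assert c.lower <= c.central <= c.upper
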