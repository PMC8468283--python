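"""Expenditure tables and annual cost savings.

A disease's direct healthcare expenditure is broken into named service
categories (allied health, GP services, pharmaceuticals, hospital services,
...) in AUD million for a given year.  The model's core assumption is a
1:1 proportionality between risk and cost: each 1% decline in disease risk
saves 1% of every cost category.  Under a population-uptake scenario with
uptake fraction u, the annual saving for a category with amount E is

    saving = E * RRR * u

applied bound-for-bound to the risk-reduction confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError
from .risk import RiskReduction

#: tolerance per category when checking a stated total against the
#: category sum (both may be printed rounded to 0.1)
_TOTAL_TOL_PER_CATEGORY = 0.05


@dataclass(frozen=True)
class ExpenditureTable:
    """Named healthcare cost categories (AUD million) for a condition/year.

    ``categories`` is an ordered tuple of ``(name, amount)`` pairs; order is
    preserved through the whole pipeline so reports mirror the source table.
    A ``stated_total`` (as printed in a source) is checked against the
    category sum within display-rounding tolerance.
    """

    condition: str
    year: str
    categories: tuple[tuple[str, float], ...]
    stated_total: float | None = None

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValidationError(f"{self.condition!r}: no cost categories")
        names = [n for n, _ in self.categories]
        if len(set(names)) != len(names):
            raise ValidationError(f"{self.condition!r}: duplicate category names")
        for name, amount in self.categories:
            if amount < 0:
                raise ValidationError(
                    f"{self.condition!r}/{name!r}: negative amount {amount}"
                )
        if self.stated_total is not None:
            tol = _TOTAL_TOL_PER_CATEGORY * len(self.categories)
            if abs(self.stated_total - self.total) > tol:
                raise ValidationError(
                    f"{self.condition!r}: stated total {self.stated_total} "
                    f"differs from category sum {self.total:.4f} by more "
                    f"than {tol}"
                )

    @property
    def total(self) -> float:
        """Sum of category amounts, AUD million."""
        return float(sum(amount for _, amount in self.categories))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.categories)

    def amount(self, name: str) -> float:
        for n, a in self.categories:
            if n == name:
                return a
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.categories, columns=["category", "amount"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        condition: str,
        year: str,
        stated_total: float | None = None,
    ) -> "ExpenditureTable":
        """Read a ``category,amount`` CSV into a table."""
        df = pd.read_csv(path)
        missing = {"category", "amount"} - set(df.columns)
        if missing:
            raise ValidationError(
                f"{path}: missing column(s) {sorted(missing)}; "
                "expected header 'category,amount'"
            )
        cats = tuple(
            (str(r.category), float(r.amount)) for r in df.itertuples(index=False)
        )
        return cls(condition=condition, year=year, categories=cats,
                   stated_total=stated_total)


def inflate(
    table: ExpenditureTable, factor: float, year: str | None = None
) -> ExpenditureTable:
    """Multiply every category amount by a price-index ``factor``.

    Used to bring base-year expenditure to current-year dollars (e.g. via
    a consumer price index health-group ratio).  ``year`` relabels the
    result; if omitted the original year label is kept.
    """
    if not factor > 0:
        raise ValidationError(f"inflation factor must be positive, got {factor}")
    return replace(
        table,
        year=table.year if year is None else year,
        categories=tuple((n, a * factor) for n, a in table.categories),
        stated_total=None,
    )


@dataclass(frozen=True)
class SavingsCell:
    """A monetary saving with 95% CI, AUD million."""

    central: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        tol = 1e-9 * max(1.0, abs(self.central))
        if not (self.lower <= self.central + tol and self.central <= self.upper + tol):
            raise ValidationError(
                f"savings bounds out of order: "
                f"({self.lower}, {self.central}, {self.upper})"
            )

    def scale(self, k: float) -> "SavingsCell":
        """Multiply all bounds by a non-negative factor."""
        if k < 0:
            raise ValidationError(f"scale factor must be non-negative, got {k}")
        return SavingsCell(self.central * k, self.lower * k, self.upper * k)

    def __add__(self, other: "SavingsCell") -> "SavingsCell":
        return SavingsCell(
            self.central + other.central,
            self.lower + other.lower,
            self.upper + other.upper,
        )

    @classmethod
    def zero(cls) -> "SavingsCell":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SavingsReport:
    """Per-category and total savings for one condition under one scenario."""

    condition: str
    scenario_name: str
    per_category: tuple[tuple[str, SavingsCell], ...]
    total: SavingsCell
    annual: bool = True
    flags: tuple[str, ...] = ()

    def cell(self, name: str) -> SavingsCell:
        for n, c in self.per_category:
            if n == name:
                return c
        raise KeyError(name)


def compute_savings(
    table: ExpenditureTable,
    reduction: RiskReduction,
    uptake: float,
    scenario_name: str = "",
) -> SavingsReport:
    """Annual savings per category: amount x risk reduction x uptake.

    ``table`` should be the current-year (inflated) expenditure table.
    ``uptake`` is the fraction of the population adopting the target
    intake, in [0, 1].  A negative risk reduction (harmful exposure)
    produces a report flagged ``"cost_increase"`` rather than an error.
    """
    if not 0.0 <= uptake <= 1.0:
        raise ValidationError(f"uptake must be in [0, 1], got {uptake}")

    flags: list[str] = []
    if reduction.central < 0:
        warnings.warn(
            f"{reduction.outcome!r}: negative risk reduction; 'savings' are "
            "cost increases",
            UserWarning,
            stacklevel=2,
        )
        flags.append("cost_increase")

    cells = tuple(
        (
            name,
            SavingsCell(
                central=amount * reduction.central * uptake,
                lower=amount * reduction.lower * uptake,
                upper=amount * reduction.upper * uptake,
            ),
        )
        for name, amount in table.categories
    )
    total = SavingsCell.zero()
    for _, c in cells:
        total = total + c
    return SavingsReport(
        condition=table.condition,
        scenario_name=scenario_name,
        per_category=cells,
        total=total,
        annual=True,
        flags=tuple(flags),
    )
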