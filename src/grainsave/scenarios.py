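"""Population-uptake scenarios and their 5-year horizon blocks.

Uptake is modelled as a step function: a named scenario fixes the fraction
of the adult population adopting the intake target, and (for the staged
adoption timeline) each scenario occupies one block of the planning
horizon — by default four scenarios (5%, 15%, 50%, 100%) on 5-year blocks
of a 20-year horizon.  Scenarios are data, not code: any number of
scenarios and any block length are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ValidationError


@dataclass(frozen=True)
class Scenario:
    """A named uptake fraction bound to a horizon block."""

    name: str
    uptake: float
    block_index: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.uptake <= 1.0:
            raise ValidationError(
                f"scenario {self.name!r}: uptake must be in [0, 1], "
                f"got {self.uptake}"
            )
        if self.block_index < 0 or self.block_index != int(self.block_index):
            raise ValidationError(
                f"scenario {self.name!r}: block_index must be a non-negative "
                f"integer, got {self.block_index}"
            )


@dataclass(frozen=True)
class ScenarioSchedule:
    """An ordered set of scenarios on a blocked planning horizon."""

    scenarios: tuple[Scenario, ...]
    block_length: int = 5
    horizon: int = 20

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValidationError("schedule has no scenarios")
        if self.block_length < 1:
            raise ValidationError(f"block_length must be >= 1, got {self.block_length}")
        if self.horizon < 1:
            raise ValidationError(f"horizon must be >= 1, got {self.horizon}")
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ValidationError("scenario names must be unique")
        blocks = [s.block_index for s in self.scenarios]
        if len(set(blocks)) != len(blocks):
            raise ValidationError("scenario block indices must be unique")
        if self.block_length * len(self.scenarios) > self.horizon:
            raise ValidationError(
                f"{len(self.scenarios)} blocks of {self.block_length} years "
                f"do not fit a {self.horizon}-year horizon"
            )

    def block_years(self, scenario: Scenario) -> tuple[int, int]:
        """Closed year range [first, last] of the scenario's block."""
        first = scenario.block_index * self.block_length
        return first, first + self.block_length - 1

    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.scenarios)

    def tiles_horizon(self) -> bool:
        """True if the blocks cover the horizon exactly, without gaps."""
        blocks = sorted(s.block_index for s in self.scenarios)
        return (
            blocks == list(range(len(blocks)))
            and self.block_length * len(blocks) == self.horizon
        )


#: the four standard scenarios: (name, uptake fraction)
DEFAULT_SCENARIOS: tuple[tuple[str, float], ...] = (
    ("very pessimistic", 0.05),
    ("pessimistic", 0.15),
    ("optimistic", 0.50),
    ("universal", 1.00),
)


def default_schedule() -> ScenarioSchedule:
    """The standard schedule: 5/15/50/100% uptake on 5-year blocks, 20 years.

    Block 0 (years 0-4) is the very pessimistic short-term scenario;
    block 3 (years 15-19) is universal adoption.
    """
    return ScenarioSchedule(
        scenarios=tuple(
            Scenario(name, uptake, i)
            for i, (name, uptake) in enumerate(DEFAULT_SCENARIOS)
        ),
        block_length=5,
        horizon=20,
    )
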