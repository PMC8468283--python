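"""End-to-end orchestration of the three-step cost-of-illness model.

Step 1 fixes the intake gap and the uptake-scenario schedule; step 2
scales each outcome's pooled relative risk to a risk reduction for that
gap; step 3 applies the reduction, category by category, to the
current-year expenditure table under every scenario.  Discounting then
produces present values per 5-year block, per-scenario horizon totals,
and the staged incremental-adoption total.

Everything is deterministic: the same config yields the same bundle,
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import AnalysisConfig
from .costs import SavingsCell, SavingsReport, compute_savings
from .discounting import block_sum, horizon_total, incremental_total
from .exceptions import ValidationError
from .risk import RiskReduction, scale_risk_reduction


@dataclass(frozen=True)
class ResultsBundle:
    """All model outputs for one config.

    Attributes
    ----------
    reductions : dict
        condition -> :class:`RiskReduction` for the configured gap.
    annual : dict
        condition -> scenario name -> annual :class:`SavingsReport`.
    block_discounted : dict
        condition -> scenario name -> block index -> discounted
        :class:`SavingsCell` (present value of that scenario's annual
        total over that block's years).
    scenario_totals : dict
        condition -> scenario name -> discounted total over the whole
        horizon.
    incremental : dict
        condition -> staged-adoption discounted total (each scenario
        active during its own block).
    """

    reductions: dict[str, RiskReduction]
    annual: dict[str, dict[str, SavingsReport]]
    block_discounted: dict[str, dict[str, dict[int, SavingsCell]]]
    scenario_totals: dict[str, dict[str, SavingsCell]]
    incremental: dict[str, SavingsCell]
    config: AnalysisConfig


def run_pipeline(config: AnalysisConfig) -> ResultsBundle:
    """Run the full model for every outcome and scenario in ``config``.

    The savings step uses each condition's *current-year* expenditure
    table.  A negative intake gap (current above target) is rejected:
    the model prices closing a shortfall, not creating one.
    """
    if config.intakes.gap < 0:
        raise ValidationError(
            f"negative intake gap ({config.intakes.gap} g/day): current "
            "intake already exceeds the target"
        )

    schedule = config.schedule
    reductions: dict[str, RiskReduction] = {}
    annual: dict[str, dict[str, SavingsReport]] = {}
    block_discounted: dict[str, dict[str, dict[int, SavingsCell]]] = {}
    scenario_totals: dict[str, dict[str, SavingsCell]] = {}
    incremental: dict[str, SavingsCell] = {}

    for outcome in config.outcomes:
        condition = outcome.condition
        reduction = scale_risk_reduction(
            outcome.rr,
            config.intakes,
            mode=config.scaling_mode,
            strict_content_units=config.strict_content_units,
        )
        reductions[condition] = reduction
        table = config.expenditure[condition].current

        annual[condition] = {
            s.name: compute_savings(table, reduction, s.uptake, s.name)
            for s in schedule.scenarios
        }

        per_scenario_annual = {
            name: report.total for name, report in annual[condition].items()
        }
        block_discounted[condition] = {
            s.name: {
                b.block_index: block_sum(
                    per_scenario_annual[s.name],
                    config.discount,
                    *schedule.block_years(b),
                )
                for b in schedule.scenarios
            }
            for s in schedule.scenarios
        }
        scenario_totals[condition] = {
            name: horizon_total(cell, config.discount, schedule.horizon)
            for name, cell in per_scenario_annual.items()
        }
        incremental[condition] = incremental_total(
            per_scenario_annual, schedule, config.discount
        )

    return ResultsBundle(
        reductions=reductions,
        annual=annual,
        block_discounted=block_discounted,
        scenario_totals=scenario_totals,
        incremental=incremental,
        config=config,
    )
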