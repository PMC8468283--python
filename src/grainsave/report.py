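"""Report rendering: publication-style tables and lossless CSV.

Two output families:

* display tables (markdown or aligned text) mirroring the conventional
  layout — scenarios as columns, cost categories as rows, cells formatted
  ``central (lower-upper)`` with a display floor for sub-precision values
  (``"<0.01"``), and a discounted table of 5-year blocks, per-scenario
  horizon totals and the staged incremental total;

* lossless CSV carrying full-precision values alongside the rounded
  display string, so a rendered bundle can be reloaded exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .costs import SavingsCell, SavingsReport
from .exceptions import ValidationError
from .pipeline import ResultsBundle
from .rounding import format_amount

TOTAL_ROW = "All direct health savings"
FORMATS = ("csv", "markdown", "text")

EN_DASH = "–"


def format_cell(cell: SavingsCell, ndigits: int, floor: bool = True) -> str:
    """Render ``central (lower-upper)`` at the given display precision."""
    return "%s (%s%s%s)" % (
        format_amount(cell.central, ndigits, floor),
        format_amount(cell.lower, ndigits, floor),
        EN_DASH,
        format_amount(cell.upper, ndigits, floor),
    )


def annual_frame(bundle: ResultsBundle, condition: str) -> pd.DataFrame:
    """Display table of annual savings: categories x scenarios."""
    ndigits = bundle.config.decimals_for(condition)
    reports = bundle.annual[condition]
    order = bundle.config.schedule.names()
    first = reports[order[0]]
    rows = {}
    for name, _ in first.per_category:
        rows[name] = [
            format_cell(reports[s].cell(name), ndigits) for s in order
        ]
    rows[TOTAL_ROW] = [format_cell(reports[s].total, ndigits) for s in order]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(order))


def discounted_frame(bundle: ResultsBundle, ndigits: int = 1) -> pd.DataFrame:
    """Display table of discounted savings.

    One row per (year block, condition), then per-condition horizon totals
    and the staged incremental totals; scenarios as columns.
    """
    schedule = bundle.config.schedule
    order = schedule.names()
    conditions = list(bundle.annual)
    rows: dict[str, list[str]] = {}
    for block_scenario in schedule.scenarios:
        first, last = schedule.block_years(block_scenario)
        for condition in conditions:
            label = f"years {first}-{last}: {condition}"
            rows[label] = [
                format_cell(
                    bundle.block_discounted[condition][s][block_scenario.block_index],
                    ndigits,
                )
                for s in order
            ]
    for condition in conditions:
        rows[f"{schedule.horizon}-year total: {condition}"] = [
            format_cell(bundle.scenario_totals[condition][s], ndigits)
            for s in order
        ]
    for condition in conditions:
        rows[f"incremental adoption total: {condition}"] = [
            format_cell(bundle.incremental[condition], ndigits)
            if s == order[-1] else "-"
            for s in order
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(order))


def _grid(df: pd.DataFrame, index_header: str = "") -> list[list[str]]:
    header = [index_header] + [str(c) for c in df.columns]
    body = [[str(i)] + [str(v) for v in row] for i, row in zip(df.index, df.values)]
    return [header] + body


def frame_to_markdown(df: pd.DataFrame, index_header: str = "") -> str:
    grid = _grid(df, index_header)
    lines = [
        "| " + " | ".join(grid[0]) + " |",
        "| " + " | ".join("---" for _ in grid[0]) + " |",
    ]
    lines += ["| " + " | ".join(row) + " |" for row in grid[1:]]
    return "\n".join(lines) + "\n"


def frame_to_text(df: pd.DataFrame, index_header: str = "") -> str:
    grid = _grid(df, index_header)
    widths = [max(len(row[i]) for row in grid) for i in range(len(grid[0]))]
    out = []
    for r, row in enumerate(grid):
        out.append("  ".join(v.ljust(w) for v, w in zip(row, widths)).rstrip())
        if r == 0:
            out.append("  ".join("-" * w for w in widths))
    return "\n".join(out) + "\n"


def annual_records(bundle: ResultsBundle) -> pd.DataFrame:
    """Tidy full-precision annual savings (one row per cell)."""
    rows = []
    for condition, reports in bundle.annual.items():
        ndigits = bundle.config.decimals_for(condition)
        for scenario, report in reports.items():
            for name, cell in list(report.per_category) + [(TOTAL_ROW, report.total)]:
                rows.append(
                    {
                        "condition": condition,
                        "scenario": scenario,
                        "category": name,
                        "central": cell.central,
                        "lower": cell.lower,
                        "upper": cell.upper,
                        "display": format_cell(cell, ndigits),
                    }
                )
    return pd.DataFrame(rows)


def discounted_records(bundle: ResultsBundle, ndigits: int = 1) -> pd.DataFrame:
    """Tidy full-precision discounted savings (blocks, totals, incremental)."""
    schedule = bundle.config.schedule
    rows = []
    for condition in bundle.annual:
        for scenario, blocks in bundle.block_discounted[condition].items():
            for block_scenario in schedule.scenarios:
                first, last = schedule.block_years(block_scenario)
                cell = blocks[block_scenario.block_index]
                rows.append(
                    {
                        "condition": condition,
                        "scenario": scenario,
                        "kind": "block",
                        "first_year": first,
                        "last_year": last,
                        "central": cell.central,
                        "lower": cell.lower,
                        "upper": cell.upper,
                        "display": format_cell(cell, ndigits),
                    }
                )
        for scenario, cell in bundle.scenario_totals[condition].items():
            rows.append(
                {
                    "condition": condition,
                    "scenario": scenario,
                    "kind": "horizon_total",
                    "first_year": 0,
                    "last_year": schedule.horizon - 1,
                    "central": cell.central,
                    "lower": cell.lower,
                    "upper": cell.upper,
                    "display": format_cell(cell, ndigits),
                }
            )
        cell = bundle.incremental[condition]
        rows.append(
            {
                "condition": condition,
                "scenario": "",
                "kind": "incremental_total",
                "first_year": 0,
                "last_year": schedule.horizon - 1,
                "central": cell.central,
                "lower": cell.lower,
                "upper": cell.upper,
                "display": format_cell(cell, ndigits),
            }
        )
    return pd.DataFrame(rows)


def read_annual_csv(path: str | Path) -> dict[str, dict[str, SavingsReport]]:
    """Reload an annual-savings CSV into in-memory reports (lossless)."""
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, dict[str, SavingsReport]] = {}
    for (condition, scenario), group in df.groupby(
        ["condition", "scenario"], sort=False
    ):
        cells = []
        total = None
        for row in group.itertuples(index=False):
            cell = SavingsCell(float(row.central), float(row.lower), float(row.upper))
            if row.category == TOTAL_ROW:
                total = cell
            else:
                cells.append((str(row.category), cell))
        if total is None:
            raise ValidationError(f"{path}: no total row for {condition}/{scenario}")
        out.setdefault(str(condition), {})[str(scenario)] = SavingsReport(
            condition=str(condition),
            scenario_name=str(scenario),
            per_category=tuple(cells),
            total=total,
        )
    return out


def render_report(
    bundle: ResultsBundle, fmt: str, out_dir: str | Path
) -> list[Path]:
    """Write the bundle to ``out_dir`` in one format; return written paths."""
    if fmt not in FORMATS:
        raise ValidationError(
            f"unknown format {fmt!r}; supported formats: {', '.join(FORMATS)}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if fmt == "csv":
        # 17 significant digits guarantee binary round-trip of every value
        p = out / "annual_savings.csv"
        annual_records(bundle).to_csv(p, index=False, float_format="%.17g")
        written.append(p)
        p = out / "discounted_savings.csv"
        discounted_records(bundle).to_csv(p, index=False, float_format="%.17g")
        written.append(p)
        return written

    render = frame_to_markdown if fmt == "markdown" else frame_to_text
    ext = "md" if fmt == "markdown" else "txt"
    for condition in bundle.annual:
        slug = condition.replace(" ", "_")
        p = out / f"annual_{slug}.{ext}"
        p.write_text(
            f"Annual direct healthcare savings, {condition} (AUD million)\n\n"
            + render(annual_frame(bundle, condition), "Direct health expenditure savings")
        )
        written.append(p)
    p = out / f"discounted_savings.{ext}"
    p.write_text(
        "Discounted savings at 5-year increments (AUD million, present value)\n\n"
        + render(discounted_frame(bundle), "Period / condition")
    )
    written.append(p)
    return written
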