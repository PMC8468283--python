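"""Randomised, structurally valid model inputs for property testing.

Generates expenditure tables, pooled relative risks, intake gaps,
scenario schedules and discount rates that satisfy the same invariants as
the bundled national fixtures, so every pipeline stage can be exercised on
thousands of cases without any real dataset.  Category amounts are drawn
log-normal (real disease-expenditure categories span four orders of
magnitude); RR confidence intervals are built outward from the central
estimate so bound ordering holds by construction.

One global seed drives everything; each generator derives its own
sub-stream from (seed, component tag), so adding a new generator never
shifts the draws of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .costs import ExpenditureTable, inflate
from .discounting import DiscountSpec
from .exceptions import ValidationError
from .risk import DoseResponseRR, IntakeGap
from .scenarios import Scenario, ScenarioSchedule


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic input generator.

    Defaults mirror the structure of the bundled national inputs: ten cost
    categories around a heavy-tailed AUD 100 m scale, protective-to-mildly-
    harmful RRs per a 90 g/day dose, gaps up to ~50 g/day, the standard
    uptake ladder and discount rates around the conventional 7%.
    """

    seed: int = 0
    n_categories: int = 10
    amount_scale: float = 100.0
    amount_sigma: float = 1.5
    rr_range: tuple[float, float] = (0.75, 1.05)
    ci_halfwidth_range: tuple[float, float] = (0.0, 0.08)
    gap_range: tuple[float, float] = (5.0, 50.0)
    uptake_set: tuple[float, ...] = (0.05, 0.15, 0.50, 1.00)
    rate_range: tuple[float, float] = (0.0, 0.10)
    reference_dose: float = 90.0

    def __post_init__(self) -> None:
        problems = []
        if self.n_categories < 1:
            problems.append(f"n_categories must be >= 1, got {self.n_categories}")
        for name in ("rr_range", "ci_halfwidth_range", "gap_range", "rate_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                problems.append(f"{name} is empty: ({lo}, {hi})")
        lo, hi = self.rr_range
        if not (0.0 < lo and hi <= 1.2):
            problems.append(f"rr_range must lie within (0, 1.2], got ({lo}, {hi})")
        if not self.uptake_set:
            problems.append("uptake_set is empty")
        if problems:
            raise ValidationError("; ".join(problems))


def _rng(spec: SyntheticSpec, tag: str) -> np.random.Generator:
    """Deterministic per-component sub-stream from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())])
    )


def generate_expenditure(spec: SyntheticSpec) -> ExpenditureTable:
    """A positive, heavy-tailed expenditure table with auto-named categories."""
    rng = _rng(spec, "expenditure")
    amounts = rng.lognormal(
        mean=np.log(spec.amount_scale), sigma=spec.amount_sigma,
        size=spec.n_categories,
    )
    categories = tuple(
        (f"category {i + 1:02d}", float(a)) for i, a in enumerate(amounts)
    )
    return ExpenditureTable(
        condition="synthetic condition", year="2020", categories=categories
    )


def generate_rr(spec: SyntheticSpec) -> DoseResponseRR:
    """A pooled RR record with ordered CI bounds around a drawn central."""
    rng = _rng(spec, "rr")
    central = float(rng.uniform(*spec.rr_range))
    h_lo = float(rng.uniform(*spec.ci_halfwidth_range))
    h_hi = float(rng.uniform(*spec.ci_halfwidth_range))
    lower = max(central - h_lo, 1e-6)
    upper = central + h_hi
    return DoseResponseRR(
        outcome="synthetic outcome",
        rr_central=central,
        rr_lower=lower,
        rr_upper=upper,
        reference_dose=spec.reference_dose,
        n_studies=int(rng.integers(2, 12)),
    )


def generate_gap(spec: SyntheticSpec) -> IntakeGap:
    """Current/target intakes whose difference falls in ``gap_range``."""
    rng = _rng(spec, "gap")
    current = float(rng.uniform(0.0, 40.0))
    gap = float(rng.uniform(*spec.gap_range))
    return IntakeGap(current_intake=current, target_intake=current + gap)


def generate_schedule(spec: SyntheticSpec) -> ScenarioSchedule:
    """A schedule with one block per uptake value, tiling its horizon."""
    uptakes = sorted(spec.uptake_set)
    block_length = 5
    return ScenarioSchedule(
        scenarios=tuple(
            Scenario(f"scenario {i + 1}", u, i) for i, u in enumerate(uptakes)
        ),
        block_length=block_length,
        horizon=block_length * len(uptakes),
    )


def generate_discount(spec: SyntheticSpec) -> DiscountSpec:
    rng = _rng(spec, "discount")
    return DiscountSpec(rate=float(rng.uniform(*spec.rate_range)))


@dataclass(frozen=True)
class SyntheticBundle:
    """One complete randomized input set for an end-to-end run."""

    expenditure: ExpenditureTable
    rr: DoseResponseRR
    intakes: IntakeGap
    schedule: ScenarioSchedule
    discount: DiscountSpec
    inflation_factor: float


def generate_bundle(spec: SyntheticSpec) -> SyntheticBundle:
    """Draw every pipeline input from one spec (deterministic in the seed)."""
    rng = _rng(spec, "inflation")
    return SyntheticBundle(
        expenditure=generate_expenditure(spec),
        rr=generate_rr(spec),
        intakes=generate_gap(spec),
        schedule=generate_schedule(spec),
        discount=generate_discount(spec),
        inflation_factor=float(rng.uniform(1.0, 1.3)),
    )


def write_bundle(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Emit a synthetic input bundle (config + CSV) loadable by the pipeline.

    Writes ``expenditure_current.csv`` / ``expenditure_base.csv`` (the base
    table back-deflated by the drawn inflation factor) and a ``config.yaml``
    referencing them.  Returns the config path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    b = generate_bundle(spec)

    current = b.expenditure
    base = inflate(current, 1.0 / b.inflation_factor, year="base")
    current.to_csv(out / "expenditure_current.csv")
    base.to_csv(out / "expenditure_base.csv")

    config = {
        "title": f"synthetic input bundle (seed {spec.seed})",
        "intakes": {
            "current": b.intakes.current_intake,
            "target": b.intakes.target_intake,
            "product_to_content_ratio": b.intakes.product_to_content_ratio,
        },
        "outcomes": [
            {
                "outcome": b.rr.outcome,
                "condition": current.condition,
                "rr": b.rr.rr_central,
                "ci_lower": b.rr.rr_lower,
                "ci_upper": b.rr.rr_upper,
                "dose_g": b.rr.reference_dose,
                "n_studies": b.rr.n_studies,
            }
        ],
        "scenarios": {
            "block_length": b.schedule.block_length,
            "horizon": b.schedule.horizon,
            "schedule": [
                {"name": s.name, "uptake": s.uptake, "block": s.block_index}
                for s in b.schedule.scenarios
            ],
        },
        "discount": {"rate": b.discount.rate},
        "expenditure": {
            current.condition: {
                "base": {"file": "expenditure_base.csv", "year": "base"},
                "current": {"file": "expenditure_current.csv", "year": "2020"},
            }
        },
        "rounding": {current.condition: 2},
        "options": {"scaling": "linear", "strict_content_units": False},
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
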