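# Methods

## Model

`grainsave` implements a deterministic, desk-scale cost-of-illness model
linking population whole-grain intake to direct healthcare expenditure.
It has three stages.

**Risk scaling.** Input is a pooled dose–response relative risk
RR (95% CI: RR_l–RR_u) per reference daily dose D of whole-grain food,
taken from published meta-analyses, plus an intake gap g = target −
current intake. Assuming the dose–response is linear over the scaled
range, the fractional risk reduction is

    RRR = (1 − RR) · g / D,

applied to each CI bound with the order swapped (RR_u → RRR lower bound,
RR_l → RRR upper). The model does no pooling itself; heterogeneity
statistics (I², P_het) are carried as metadata only. Two deliberate unit
choices are exposed:

* The default divides the gap (grams of whole-grain *content*) by the
  reference dose as published (grams of whole-grain *product*): 27/90.
  This is the convention of the national analysis the bundled fixture
  reproduces, and with the bundled RRs it yields exactly 5.1% (3.3–6.6)
  and 4.5% (2.7–6.0). Since 30 g of product carries ≈ 16 g of content,
  a `strict_content_units` option instead divides by D/(30/16) = 48 g of
  content, giving 9.6% for colorectal cancer. Both are implemented because
  the published convention mixes units; the default is documented as
  fixture-faithful rather than as the package's judgement on intent.
* A log-linear variant RRR = 1 − RR^(g/D) is available (`scaling:
  log-linear`). For RR ∈ [0.8, 1] and g/D ≤ 0.5 it agrees with the linear
  form to within 0.0056 absolute (worst case at RR = 0.8, g/D = 0.5);
  default is linear.

Gaps larger than D trigger an extrapolation warning (the pooled curve is
being extended beyond its data); RR > 1 is accepted for generality but
flagged `increased_risk`, and downstream "savings" become flagged cost
increases. Negative gaps are rejected by the pipeline: the model prices
closing a shortfall.

**Annual savings.** Direct expenditure for a condition is a list of named
cost categories E_c in AUD million for a stated year. The core behavioural
assumption is 1:1 proportionality: each 1% decline in risk saves 1% of
every category. Under uptake fraction u ∈ [0, 1],

    S_c = E_c · RRR · u,

per CI bound, with totals computed from unrounded cells. Savings are
therefore linear (homogeneous and additive) in the expenditure amounts
and in u; these invariants are property-tested. `inflate()` multiplies a
base-year table by a price-index factor (e.g. a CPI health-group ratio);
the bundled pipeline does not apply it, because the fixture already
carries the published current-year column — re-inflating printed,
rounded base values would compound rounding drift (the fixture's implied
per-category factors vary from about 1.136 to 1.2 around the aggregate
1.1383). `inflate()` is exercised by tests, including the consistency
check that the aggregate factor reproduces each current-year category
within 1-decimal printing tolerance.

**Discounting.** A real annual rate r (default 0.07) converts future
savings to present value, PV(n) = S/(1+r)ⁿ, year 0 undiscounted. Block
present values use the closed-form geometric sum evaluated with
`log1p`/`expm1` (stable for r → 0; r = 0 returns the year count), and are
compared in tests against a naive year-by-year loop. Three aggregates:
per-block sums over closed ranges [first, last], horizon totals over
years 0…H−1 (default H = 20), and the staged incremental-adoption total
Σ_s block_sum(S_s, block of s), which requires the schedule's blocks to
tile the horizon exactly. With one scenario occupying the whole horizon
the incremental total collapses to the ordinary annuity, a tested
identity.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| current, target intake | 21, 48 g/day | national median vs recommended daily target (adults) |
| reference dose D | 90 g/day product | dose the pooled RRs refer to (≈ 3 servings ≈ 48 g content) |
| product:content | 30/16 | grams of whole-grain food per gram of whole grain |
| uptake ladder | 5/15/50/100% | very pessimistic → universal adoption |
| block length, horizon | 5, 20 years | staged-adoption timeline (year 0 = current year) |
| discount rate r | 0.07/year | conservative real rate used across Australian jurisdictions |
| rounding | 2 dp (CRC), 1 dp (total cancers) | display only; all arithmetic unrounded |

## Numerical choices

* All monetary values are double precision end to end; rounding is
  display-only, half-away-from-zero, applied after snapping to 9 decimals
  so binary representation noise cannot flip an exact tie (0.765 stored
  as 0.76499999999999968 still prints 0.77). Values that would display as
  positive zero at the chosen precision print as a floor string
  (`<0.01` / `<0.1`), configurable off.
* CSV reports carry 17-significant-digit values beside the display
  strings and reload bit-for-bit (`float_precision="round_trip"`).
* Savings-cell bound ordering is validated with a 1e-9 relative slack;
  construction preserves ordering exactly, the slack only absorbs
  floating-point summation across categories.
* Config validation accumulates every problem before raising, so a file
  is fixable in one pass.

## Synthetic data

The generator emulates the *structure* of the real inputs: log-normal
category amounts (heavy-tailed, like real disease-expenditure tables
whose categories span four orders of magnitude) around an AUD 100 m
scale; RR centrals uniform on [0.75, 1.05] with CI half-widths up to
0.08, built outward from the central so ordering holds by construction;
gaps of 5–50 g/day; the standard uptake ladder; rates on [0, 0.10]. One
global seed drives all draws through per-component sub-streams
(`SeedSequence([seed, crc32(tag)])`), so outputs are reproducible and
adding a generator never shifts existing streams.

What it does not emulate: correlations between category sizes and
outcomes, uncertainty in the expenditure figures themselves (treated as
exact by the model), non-linear dose–response shapes, time-varying
expenditure, or behavioural adoption dynamics (uptake is a step function
per block). Passing property tests therefore demonstrate arithmetic
correctness and invariant preservation over valid inputs — not that the
proportional risk-to-cost assumption holds in any real population.

## Known limitations

* The 1% risk → 1% cost proportionality ignores fixed costs, screening
  programs and capacity effects; it is the standard simplification of
  this model family, not an estimated relationship.
* Only direct healthcare costs are modelled; productivity and mortality
  (indirect) costs are out of scope, so totals understate the full
  economic burden avoided.
* CIs are propagated deterministically bound-for-bound; no probabilistic
  sensitivity analysis (Monte Carlo over parameter distributions) is
  performed, and the bounds inherit only the RR uncertainty.
* The linear scaling is an interpolation assumption; the extrapolation
  warning fires when a gap exceeds the pooled dose, but the number it
  produces is still linear.
* The bundled expenditure columns are printed to 1 decimal; small
  internal inconsistencies of the source tables (category sums vs printed
  totals differing by 0.1) are accepted at display-rounding tolerance
  rather than silently repaired.
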