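# Methods

## Model structure

The model compares PRS-guided prevention against standard pediatric care
for a hypothetical cohort of 10,000 children entering at age 10 and
followed annually to age 80 or death. Children are stratified by CAD
polygenic risk score into the top 2% (`top2`), the next 18% (`next18`),
and the bottom 80% (`bottom80`). Under the PRS-guided arm the top 20%
receive intensive lifestyle intervention and the top 2% additionally
receive statin therapy; under standard care no PRS-based action is taken.

The Markov engine uses four mutually exclusive states — alive event-free,
alive post-nonfatal-event (MI or stroke), cardiovascular death, and
non-cardiovascular death — with both death states absorbing. Event hazards
are zero before age 40 (screening and intervention occupy ages 10–40; the
model deliberately ignores pre-40 mortality and morbidity) and from age 40
are constant annual probabilities obtained by annualizing 10-year
cumulative incidences: `a = 1 − (1 − p₁₀)^(1/10)`. CAD and stroke hazards
are treated as independent competing causes within a cycle
(`p_event = 1 − (1 − a_CAD)(1 − a_stroke)`); an active intervention scales
both by `1 − RRR`; the acute case-fatality rate splits events into fatal
and nonfatal. The bottom-80% stratum carries one sixth of the top-20%
incidence, the unique assignment consistent with a threefold top-quintile
risk gradient and a preserved population mean.

Cycle convention: annual cycles, transitions at cycle end, rewards
credited to the state occupied during the cycle, no half-cycle correction
(none is prescribed for this analysis; the option would change absolute
QALY levels, not the economic deltas, which are driven by per-case
quantities — see below). Background non-cardiovascular mortality defaults
to zero so base-case traces are self-contained; a per-cycle life-table
column can be supplied. Post-event occupancy carries the plain age-band
utility by default (a configurable multiplier exists for exploration),
because the economic ledger accounts for event QALY impacts through fixed
per-case quantities rather than state-utility decrements.

## Parameters

All inputs live in a typed registry (`prsecon/data/base_case.yaml`), each
with base value, units, a PSA distribution, and a provenance note. The
distributed inputs:

| parameter | base | distribution |
|---|---|---|
| 10-y CAD incidence, top 20% PRS | 0.12 | Beta(120, 880) |
| 10-y stroke incidence, top 20% | 0.12 | Beta(120, 880) |
| relative risk reduction | 0.30 | RR ~ Lognormal, median 0.70, 95% CI 0.60–0.80 |
| utilities (10–40 / 40–60 / >60) | 0.95 / 0.92 / 0.85 | Normal, SD 0.02 / 0.03 / 0.04 |
| acute CAD & stroke fatality | 0.20 | Beta(100, 400) |
| QALY loss per fatal event | 12.4 | Normal(12.4, 1.2) |
| genetic test cost (per child) | $400 | Gamma, CV 20% |
| statin + monitoring (annual) | $250 | Gamma, CV 20% |
| lifetime event cost (per case) | $421,487 | Gamma, CV 25% |

Fixed inputs: discount rate 3%/yr, medical inflation 5%/yr, $100,000 per
QALY, $200,000 productivity per case, 15% co-benefit multiplier, 13.3
QALYs gained per prevented case, cohort 10,000, risk fractions 0.20/0.02,
30-year program horizon. Stroke inputs equal CAD inputs throughout (no
harmonized stroke-specific sources). Intervention adherence is not a
separate parameter: the 30% RRR is taken as the net effect of an adherent
program, and its lognormal uncertainty subsumes adherence variation.

Distribution conventions: gamma is parameterized by (mean, CV) with
`shape = 1/CV²`, `scale = mean·CV²`; the treatment-effect lognormal is
anchored at the relative-risk *median* (the printed CI is not
multiplicatively symmetric about 0.70, so a mean-anchored parameterization
would not reproduce the stated interval), with
`σ = ln(CI_high/CI_low)/(2·1.96)` ≈ 0.0734. Construction validates that
every distribution is centered on its base value (mean for beta, gamma,
normal; `1 − median` for the RR lognormal) to 1e-9.

## Cost-benefit ledger

Per-case economic quantities are ledger inputs, not Markov outputs; the
engine's role is structural (traces, scenario deltas), matching how the
analysis is constructed. The ledger computes, for the 2,000-child
high-risk group:

- events prevented `ΔE = n·p₁₀·RRR` and absolute risk reduction `100·p₁₀·RRR`;
- direct savings `ΔE × $421,487`; QALYs `ΔE × 13.3` (rounded to an integer
  before valuation at $100,000, matching the published arithmetic:
  957.6 → 958 → $95.8M); productivity `ΔE × $200,000`;
- screening savings: uniform annual screening of the whole cohort ages
  40–70 at $250/screen ($75M, undiscounted) versus stratified screening
  (high-risk 20% from age 40, the rest from age 50: $55M), saving $20M.
  The $250 unit cost, the age-70 horizon, and the age-50 deferred start
  are a reconstruction — the unique simple schedule reproducing both
  totals simultaneously — and are asserted jointly in tests;
- a 15% co-benefit multiplier applied to the sum of the four lines above;
- program cost: $4.0M one-time testing plus the statin present value for
  200 children at $250/yr over 30 years.

**Rounding convention.** Each benefit line is rounded half-up to $0.1M
before summation, so the total reproduces the published $184.6M exactly;
unrounded values are retained alongside (`BenefitLedger.unrounded`).
Half-up rounding is done in decimal arithmetic so that 24.075M → 24.1M.

**Statin annuity.** The standard ordinary-annuity factor at 3% over 30
years is 19.60044, giving $980,022; the source analysis prints $970,000
(implied factor 19.4, a 1.0% difference with no stated derivation). The
printed value is the default so headline figures reproduce;
`program_cost(..., annuity="computed")` gives the standard annuity.

**ICER numerator.** Gross program cost over QALYs gained
($4.97M / 958 = $5,188/QALY). Netting downstream savings into the
numerator would make the intervention dominant (negative ICER) and is
deliberately not done — the positive printed ratio pins this convention.

**Break-even.** Smallest integer k with k × (average per-case benefit) ≥
program cost; with per-case ≈ $2.56M this gives 2 (a narrower
direct+QALY+productivity bundle gives 3; the reported range is 2–3).

**Adjusted figures.** `NPV = B·((1+i)/(1+d))^30` ≈ $328.7M and adjusted
ROI ≈ 6514% — the growth-factor convention confirmed by reproducing the
published values within 0.05%.

## Probabilistic sensitivity analysis

1000 Monte Carlo draws by default. Per draw, every non-fixed parameter is
redrawn — incidences, RR, fatality, utilities, QALY losses, and the three
cost inputs — and the full ledger (including its rounding convention) is
recomputed; per-case QALY gain, screening schedule, productivity, and the
co-benefit multiplier are fixed constants. One `numpy` Generator seeded
once drives the run, with parameters visited in registry order, so results
are bit-reproducible; normal draws are truncated to their support
(utilities [0,1], losses [0,∞)) by resampling rather than clipping, which
preserves the conditional shape at the cost of variable stream consumption
per draw. Summaries are means and empirical 2.5/97.5 percentiles (the
source's "95% confidence interval" is not otherwise specified). The CEAC
evaluates net monetary benefit `λ·ΔQALY − C` per draw on a $0–$100,000
grid in $1,000 steps.

Reconstruction caveat: with Beta(120,880) incidence and the stated
lognormal RR, the events-prevented 95% interval is ≈ 46–98, wider than the
published 58–86; the exact RR sampling used by the source is unstated.
Means (≈ 71.5 vs 72) and the ≥99% cost-effectiveness probability at
$50,000/QALY agree; interval widths are therefore checked only at the
order-of-magnitude level.

## Scenario fixtures

The three illustrative scenario rows (low PRS: 82 y / 70.0 QALYs; high PRS
without prevention: 72 y / 53.9 QALYs; with prevention: 79 y / 67.2 QALYs,
with 10-year MI/stroke/fatal-MI risks) are shipped as fixtures, not
recomputed: they are labeled illustrative by the source and are not
derivable from the utility schedule under any simple cycle convention.
Only their differences — 7 life-years gained, 13.3 QALYs added, the
fivefold fatal-MI gradient — are modeled (and tested) quantities.

## Country localization

Localized results use two positive factors per country: `cost_factor`
scales program cost (ICER scales linearly with it) and `benefit_factor`
scales monetized benefits
(`ROI = 100·(b·B − c·C)/(c·C)`). The shipped factor table
(USA 1/1, UK 0.75/0.65, Germany 0.80/0.75, Canada 0.85/0.80,
Australia 0.90/0.80, France 0.85/0.75) is a synthetic reconstruction
back-derived by dividing each published country cell by the USA cell; it
reproduces all six ICER cells exactly and all ROI cells within 1%.
Whether the source scaled QALY counts, QALY prices, or both is unstated;
the two-factor form is the adopted reconstruction.

## What the synthetic inputs do and do not show

There is no patient-level data anywhere in this analysis: the model is
cohort-level and parameter-driven, and the packaged configuration encodes
published point estimates and uncertainty widths. Passing tests
demonstrate internal consistency (conservation, monotonicity, convention
arithmetic) and faithful reproduction of the published accounting — not
external validity. In particular: adult-derived incidences stand in for
nonexistent pediatric PRS outcome data; adherence, treatment disutility,
risk-labeling effects, event recurrence, and pre-40 mortality are not
modeled; and the scenario life-expectancy levels are illustrative inputs.

## Numerical choices and problem sizes

- Annualization round-trip is exact to 1e-12; trace mass conservation is
  asserted to 1e-9 over all 70 cycles.
- Degenerate (all-fixed) PSA draws reproduce the base-case ledger bitwise.
- Test problem sizes: 1000-draw PSAs for distributional checks, a
  10,000-draw loop for law-of-large-numbers convergence of sampled
  parameter means (within ~3 standard errors); the full suite runs in a
  few seconds.
- Ties in rounding are broken half-up (decimal), matching how the
  published table arithmetic behaves.

## Limitations

Single-cohort, single-entry-age deterministic cohort model; no
microsimulation, no recurrent events, no treatment disutility, no
ancestry-specific PRS performance, no currency conversion beyond the two
country factors. The statin-annuity and screening-schedule
reconstructions, and the country factor table, are package inferences
documented above rather than published inputs.
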