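# Methods

## Model overview

`fluorosim` is a discrete-time (annual-cycle), individual-level stochastic
simulation of dental caries and its sequelae among US children aged 0–19,
built to project the consequences of changing fluoride levels in public
water systems (PWS). It follows the conventions of decision-analytic
cost-effectiveness modelling: a synthetic cohort with survey weights, a
calibrated baseline disease-risk model, policy scenarios compared with
common random numbers, discounted costs and QALYs from a health-care-sector
perspective, and probabilistic plus one-way sensitivity analysis.

The causal chain is: PWS fluoride stratum → protection against caries →
annual caries incidence → treatment or an untreated-complication pathway
(abscess, extraction) → costs and QALY decrements. Excessive fluoride
(>1.5 mg/L) additionally causes dental fluorosis with a one-off cosmetic
restoration cost.

## Synthetic population

Each child carries: age (0–19), age group (2–5 / 6–12 / 13–19), sex,
race/ethnicity (Hispanic, non-Hispanic Black, non-Hispanic White, other),
income group (<130%, 130–300%, >300% of the federal poverty level),
insurance (private, public, uninsured), fluoride stratum (below detection /
0.1–≤0.6 / 0.6–≤1.5 / >1.5 mg/L), tap-water drinking, a survey weight, and
prevalent caries at baseline.

Default marginals: fluoride strata 12.4/45.7/40.4/1.5%; sex 49/51;
race/ethnicity 24.3/13.8/51.6/10.3%; ages uniform on 0–19. Income
(30/30/40%) and insurance (48/45/7%) are not published for this cohort and
are set to plausible national child-population values; both are
configurable. Tap-water drinking defaults to 0.70 (no published national
fraction exists; it matters only for the tap-water-only protection model,
and the bundled tap-water comparison uses 0.80 so that roughly four-fifths
of fluoridated-area residents retain protection). Fields are drawn
independently by default; a joint (age group × race × income) table can be
supplied where coupling matters, and is documented as an approximation
otherwise. Weights default to `national_population / n` (uniform) with a
per-stratum override; only their total matters, since all national outputs
are weight-sums. The default national scaling constant is 80 million
(approximate US population aged 0–19) and is reported in all outputs.

Children under 2 carry no caries risk and no baseline caries; they age into
the 2–5 risk group during simulation. Children passing 19 during a 10-year
run retain the 13–19 coefficients (documented approximation).

## Caries risk and protection

Annual incidence is additive-logistic: one intercept per age group plus
coefficients for sex, race/ethnicity and income. The covariate coefficients
encode relative disparities (defaults: Hispanic +0.30, non-Hispanic Black
+0.20, other +0.10 on the logit scale vs non-Hispanic White; low income
+0.40, middle +0.20 vs high; sex 0). They are configurable; only the
intercepts are calibrated, keeping the model identifiable from
age-group-level targets. A child receives the protective effect — a
multiplicative `(1 − effectiveness)` on the annual probability, base case
0.25 — when their stratum delivers ≥0.6 mg/L under the scenario:

| scenario | protected strata | fluorosis risk | program cost charged |
|---|---|---|---|
| status quo | optimal, excessive | excessive stratum | optimal + excessive capita |
| remove fluoride | none | none | none |
| optimize fluoride | suboptimal, optimal, excessive | none (excessive → optimal) | all three strata capita |

Under the `tap_water_only` protection model, protection additionally
requires drinking tap water; the program cost still accrues for all
residents of fluoridating systems, since the water is treated regardless of
who drinks it.

At most one new decayed tooth arises per child per cycle (annual binary
indicators, summed into decayed-teeth counts). Annual indicators are
independent across years and do not depend on caries history.

## Calibration

The baseline intercepts are unobserved, so they are tuned against caries
prevalence targets (defaults 21.3/51.6/57.2% for ages 2–5/6–12/13–19). We
interpret the targets as *cumulative prevalence at the child's current
age*: with annual probability `p_i` and `r_i = max(age_i − 1, 0)` completed
risk-years from age 2, the expected prevalence is `1 − (1 − p_i)^{r_i}`
under status-quo protection (the alternative — targeting incidence over the
simulation horizon — is supported via `horizon_to_age=False`). Each
target's intercept (or, for race-specific targets, an (age group × race)
cell adjustment) is found by Brent root-finding on this deterministic
weighted cohort expectation, bracketed on [−12, 8] logit units, followed by
a verification pass against every target's tolerance (default 5 pp). The
procedure is closed-form-deterministic — no Monte Carlo in the loop — hence
exactly reproducible and idempotent. The closed form uses the child's
current-age coefficients for all past years (a constant-probability
approximation to their mixed-group history); the baseline state is drawn
from the same expression, so calibration, baseline assignment and
validation are mutually consistent.

After calibration, `assign_baseline_caries` draws each child's prevalent
caries from their cumulative probability, replacing any config-assigned
baseline; validation then re-simulates the status quo and compares
weighted prevalence at cycle 0 against the targets, which genuinely tests
the calibrated risk model rather than echoing an assigned constant.

## Annual cycle

Per cycle, for each living child, in order: mortality draw (band table,
defaults 2.5e-4 / 1.5e-4 / 5e-4 per year for ages 0–4 / 5–14 / 15–19; a
death suppresses all same-cycle events); caries indicator; if incident —
untreated with probability 0.72, else treated (exam $185 + restoration
$530); if untreated — independent abscess (0.321, $818) and extraction
(0.766, $181) draws, resolved within the cycle (their probabilities sum
above 1, so they cannot be exclusive); fluorosis draw where eligible, with
the published 7% interpreted as cumulative risk over the horizon H and
converted to the annual hazard `h = 1 − (1 − p)^{1/H}` (cost $1468 once at
onset). Events are discounted by whole-cycle index `(1 + r)^{−t}` at
r = 0.03 (no half-cycle correction); children age one year per cycle.

QALY decrements per cycle are additive across states and capped at 1:
untreated caries 0.010 from the incident cycle until extraction (treated
caries: incident cycle only), abscess 0.069 in its cycle, tooth loss 0.067
from the extraction cycle onward (chronic). Fluorosis carries no
disutility, only its treatment cost.

## Common random numbers

The uniform stream is a `(n × H × 6)` array generated once per seed, one
slot per (child, cycle, event type). Compared scenarios consume the same
stream, so a child's caries indicator differs between arms only when the
policy changes their probability; a null intervention (effectiveness 0,
fluorosis off) yields exactly zero health increments, and monotonicity
properties (more effectiveness → larger removal increment; tap-water-only
increments ≤ all-residents increments) hold exactly rather than in
expectation. Streams are horizon-specific: 5- and 10-year runs of the same
seed are coupled within, not across, horizons.

## Uncertainty analysis

PSA redraws the fourteen uncertain parameters each iteration: beta for
probabilities and disutilities, gamma for costs, moment-matched
(`ν = m(1−m)/sd² − 1`, `a = mν`, `b = (1−m)ν`; `shape = (m/sd)²`,
`scale = sd²/m`) and truncated to the published range by resampling (cap
1000 attempts). Range-only parameters (e.g. effectiveness, 0.075–0.35 with
base 0.25) use a PERT-style scaled beta on [lower, upper] with mode at the
base case and λ = 4. Parameter draws are shared across the scenario pair
within an iteration; the simulation seed varies per iteration (derived from
a spawned `SeedSequence`) unless pinned; the same synthetic population is
reused across iterations (population uncertainty is not part of the
published distributional assumptions). Uncertainty intervals are empirical
2.5th/97.5th percentiles with linear interpolation between order
statistics. The one-way analysis reruns the increment with one parameter at
each published bound, all else at base case and the stream fixed, and sorts
by induced range per outcome.

## Numerical and design choices

- Calibration bracket [−12, 8] logit units, Brent `xtol` 1e-10; unreachable
  targets raise a calibration error naming the worst subgroup.
- The excessive stratum is protective against caries as well as carrying
  fluorosis risk (protection attaches to >0.6 mg/L).
- Optimizing fluoride lowers the excessive stratum to optimal: protection
  kept, fluorosis eliminated.
- Complication draws apply once per incident untreated tooth, not per year
  of its persistence.
- Program-cost savings from removal are netted into incremental cost; the
  component ledger (restoration / complication / fluorosis / program)
  decomposes every total exactly, and removal's ledger exposes the netting.
- Percentile and RNG conventions are fixed (numpy `default_rng`,
  `SeedSequence` spawning) so every result is reproducible from one seed.

## What the synthetic cohort does and does not capture

The generator reproduces configured marginal (and optionally coupled)
distributions, national scaling, and the fluoride-exposure pattern. It does
not reproduce the true joint covariate distribution of the US child
population, survey design effects, geographic clustering of fluoridation,
or dental-care utilization patterns beyond the single untreated-caries
probability. Tests passing on this cohort therefore demonstrate the
*mechanics* — calibration fidelity, oracle equivalence, conservation,
coupling — not the real-world joint distribution of risk.

Problem sizes used by the bundled analyses: cohorts of 10,000 children
(100,000 in closed-form oracle checks, 50,000 in parameter recovery), 5- and
10-year horizons, 100–1000 PSA iterations.

## Known limitations

- Per-child (not per-tooth) annual indicators cap incidence at one tooth
  per year, which bounds how far end-of-horizon *prevalence* can separate
  between scenarios: with a 25% risk reduction for the ~42% of children in
  protected strata, the remove-vs-status-quo prevalence increment cannot
  exceed ≈5 pp at any calibration, and is ≈2–3 pp at the calibrated
  baseline. Published decision models with tooth-level state spaces report
  larger prevalence separations; the decayed-teeth, QALY and cost
  increments here are internally consistent with our smaller prevalence
  increment.
- The complication pathway treats abscess and extraction as same-cycle,
  independent events; persistent untreated caries beyond extraction is the
  only chronic caries state. With the tooth-loss disutility chronic from
  extraction, the tooth-loss weight is (after effectiveness) the strongest
  QALY lever in the tornado, and the abscess unit cost the strongest cost
  lever after effectiveness — orderings that would shift under per-event
  (non-chronic) disutility accounting.
- No caries-history dependence, no halo protection for near-fluoridated
  communities, no adult outcomes, no neurocognitive outcomes, no societal
  perspective (school/work loss), no currency re-indexing (costs are used
  as 2024 USD).
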