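# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `trialkit`, in the order a reviewer is
likely to question them.

## Time and units

All supply arithmetic uses a **31-day month** (so a 62-tablet bottle at
two tablets/day lasts exactly one month, and a "year" is 372 days); the
simulator advances in 1-day ticks on real calendar dates. Doses are in
mg/day (850 mg tablets; full dose 2/day = 1700 mg/day, half dose 1/day),
lab thresholds in the units printed on the eligibility rule (cm, mg/dL,
mmHg, µmol/L). Costs are EUR per 62-tablet bottle.

## Eligibility

Criterion boundaries are inclusive exactly as stated ("85 cm or more",
"50 mg/dL or less"). The blood-pressure criterion is satisfied if either
bound is reached (systolic ≥ 130 **or** diastolic ≥ 85), the standard
ATP-III reading of "130/85 or more". The hyperglycemia exclusion
requires *two* samples above 126 mg/dL: a single high value with a
missing or normal repeat does not exclude. The 5-year cancer window,
"excessive alcohol" and interfering co-medication are intake-time boolean
flags — no operational definition exists to recompute them from history.

## State machine

The protocol flow is a closed transition table (`core.TRANSITIONS`);
anything outside it raises. `BLOCKED` (non-compliance or serious adverse
event) and `WITHDRAWN` (consent withdrawal) are reachable from every
active state; `SCREEN_FAILED`, `WITHDRAWN` and `COMPLETED` are terminal.
Screen failure is modelled as terminal because re-entry is undefined in
the workflow; non-compliance detection is accepted as an external event.
Every transition writes exactly one audit event carrying the old and new
state, so the audit log replays to the exact in-memory states
(event-sourcing round trip, tested).

## Randomization

The balancing *features* are fixed (diet: sex + family; treatment: sex +
age ≤ 67 / > 67 at randomization, floor of whole years), but the
*algorithm* behind "automatic, not modifiable" balancing was an open
design choice. We use deterministic minimization with seeded fair-coin
tie-breaks, with two deliberately different margin rules:

* **Diet (probands):** lexicographic — overall arm imbalance first, then
  the within-sex margin. This provably keeps the overall proband
  imbalance ≤ 1 after every arrival. An equal-weight sum over margins
  cannot do that: whenever the sex margin is skewed opposite to the
  overall margin the two candidate sums tie for every arrival, and coin
  tie-breaks turn the overall margin into a random walk.
* **Treatment:** minimize the worst post-assignment margin imbalance,
  then the sum of margins. In 10,000-arrival simulations every sex and
  age margin stays within ±2 (asserted in the tests); the plain
  sum-of-margins rule drifts to 3 and beyond.

Familiars inherit the proband's diet arm, appear in the balance table,
but never touch the minimization counters — counting them would bias the
margins by family size. The family rule applies to diet only; treatment
randomization treats relatives independently. Assignments are immutable.

## Blinding

The allocation list is generated once, in blocks of four bottles (two
per treatment, randomly ordered within the block), sized redundantly
(default 200,000 codes). Bottle codes are zero-padded integers with a
position-weighted mod-37 check character (37 is prime and larger than
any weight × digit-delta product, so every single-digit substitution is
caught); any unique string is accepted on import.

The X/Y aliases are themselves assigned to the two treatments by a
per-trial seeded draw, then sealed. Sealing is encrypt-then-MAC built on
HMAC-SHA256 (counter-mode keystream under an encryption subkey, tag
under a MAC subkey), fails closed on tampering or a wrong key, and is
deliberately boring: it protects the blind inside the operational store,
with key management delegated to the deployment. The on-disk bundle
never contains the key; the CLI derives a default key from the trial
seed unless one is supplied, which is a convenience for research use,
not a security boundary.

## Warehouse

A delivery is rejected outright if its expiry is under the minimum shelf
life (12 months, configurable). "Close to the expiry date" is
operationalized as the only guard that guarantees a participant never
holds expired drug: a bottle is ineligible for a dispensation if it
expires before the end of the period that dispensation covers. Among
eligible bottles, earliest expiry goes first (FEFO); short-dated bottles
skipped by one dispensation remain available for shorter coverage
periods. Stockout (not enough labelled bottles at all) and expiry-only
shortage raise distinct errors. The six-month maintenance supply is 6
bottles (372 tablets / 2 per day = 186 days), 3 at half dose. The
open-label 500 mg run-in product is a separate stock line in 30-tablet
monthly units; it never enters the blinded allocation list, and its
dispensations are labelled with a neutral product code so operational
outputs stay free of treatment names.

## Forecasting

The order formula `(A + B1 + B2) − C` fixes the components' meaning, not
their computation; our constructions are:

* **A** — exact: each randomized active participant's dispensing
  calendar (current step, next-due date, dose, planned end) is rolled
  forward and bottles falling inside the horizon are summed. This is
  cross-checked in the tests against an independent day-by-day
  enumeration, exactly.
* **B1** — trailing mean of monthly treatment randomizations (window
  default 6 months) × horizon (default 12 months) × the first-year need
  of one full-dose participant (1 + 1 + 6 + 6 = 14 bottles, the
  dispensations falling in the 372 days after randomization).
* **B2** — one run-in unit per participant currently in run-in.
* **C** — drop-out rate (default 0.032/year) × (A + B1), capped at
  A + B1; C does not discount B2 (a 30-day horizon makes run-in
  withdrawal a second-order effect).

Two lead times are kept distinct because the workflow states both: the
contractual order-scheduling lead (30 days) and the delivery lead
(60 days). The trigger orders when today is within 30 days of the last
batch expiry, or when replaying scheduled FEFO demand against current
stock projects a stockout within the delivery lead.

The patients'-pack counterfactual is `n × months × (1 − loss)` at one
full-dose bottle per month, rounded to the nearest bottle — the
reconstruction that reproduces the published 60021 for (1755, 36, 0.05).
Savings percentages are reported to one decimal; budget savings raw and
rounded to the nearest thousand.

## Simulator

The generator emulates the reference cohort's structure: Poisson monthly
accrual (default 1755/40 ≈ 43.9 consents/month for 40 months), familiars
attaching to a uniformly chosen existing family (8.2%), a 60.5% female
cohort, age ~ N(58, 8²) truncated to 30–80 (chosen so roughly one in
seven randomizations falls in the > 67 stratum; the source table does not
print an age distribution), a 21-day consent-to-screening delay, 35%
screen failure plus 7% run-in intolerance (jointly calibrated so ≈ 60%
of consenters reach randomization), constant-hazard drop-out at
0.032/year, and PI-ordered half-dose reductions at 0.05/year (the
workflow says only that these occur "occasionally"; 5% per year is our
one-time choice of a realistic rate).

Planned treatment runs from randomization to study conclusion —
`follow_up_months = 42` (the protocol's 3.5-year average follow-up) —
while the patients'-pack baseline is priced at
`pp_mean_treatment_months = 36`, the counterfactual's own stated
assumption. Keeping these two durations distinct is what makes the
projected-to-conclude term commensurate with the published analysis.

Per-participant fates (screen failure, run-in intolerance, drop-out time,
half-dose time) are drawn once at registration from a dedicated stream
via inverse-CDF sampling, so changing a rate re-uses the same underlying
randomness: raising the drop-out rate can only move withdrawals earlier.
This gives the monotonicity the tests assert (more drop-out never
increases dispensing). Logistics are automated: an initial batch at day
0, monthly order checks with a 31-day safety margin on top of the 60-day
delivery lead, 24-month shelf life on deliveries (the supplier's
stability window grew over the study; 24 months is the midpoint),
disposal of expired stock at each check, and day-by-day retry of
dispensations that hit a transient stockout.

The snapshot at recruitment close reports dispensed bottles (from the
audit log, not side tallies) plus a survival-weighted projection of every
active participant's remaining calendar (run-in participants weighted by
their probability of surviving the run-in gate; future dose reductions
are not anticipated). What passing simulations do **not** show: the
generator has no seasonal accrual, no centre effects, no partial
compliance or lost-bottle resupply, no calendar-driven heterogeneity in
planned duration — so agreement in the savings band demonstrates that
the supply policy and accounting behave correctly under the stated rates,
not that those rates describe any particular real cohort.

## Scaled-down problem sizes

The test suite runs the balance and block properties at 10,000
arrivals/blocks, the inventory and forecasting invariants over 100
simulated trials of ≈ 213 consented participants (20 accrual months,
24-month follow-up), and the savings bracket over 20 seeds at the full
reference calibration. These sizes keep the whole suite around a minute
on one CPU while leaving every rate at its study value.

## Degenerate inputs and numerical conventions

Zero accrual yields an empty estimate (B1 falls to 0 with an empty
trailing window); a zero patients'-pack baseline makes the savings
percentage undefined and raises; order components are validated
non-negative and the total is exact by construction. Rounding: B1 and C
to the nearest bottle at composition time; savings to one decimal;
budget to the nearest thousand for the headline figure. Ties in
minimization are broken by a seeded `random.Random` so identical seeds
and arrival sequences reproduce identical assignments, allocation lists
and simulations byte-for-byte.

## Known limitations

* The sealing scheme is honest but homespun; swap in a vetted AEAD
  library for production use.
* The store is a single-writer text bundle — no concurrency control, no
  user authentication beyond the role flag on each operation.
* Early resupply (lost bottles) and re-screening of screen failures are
  unsupported; both would be PI-authorized extensions of the state
  machine.
* The forecast's B1 term deliberately over-covers late joiners (it prices
  a full first year for every projected randomization inside the
  horizon); treat it as an ordering buffer, not an unbiased predictor.
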