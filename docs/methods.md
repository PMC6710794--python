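# Methods

## Model structure and assumptions

`preecon` is a single-pass expected-cost decision tree. One cohort of
pregnancies with suspected preeclampsia (median gestational week ~32) is
followed until delivery; there is no time-to-event structure, no neonatal
cost modelling, and no anticoagulant/corticosteroid costs. Costs are direct
medical costs to the Swiss healthcare system, in euros (CHF sources
converted once at the stored rate of 0.88 EUR/CHF).

Each strategy allocates the cohort over six branches: an initial
consultation taken by everyone, low and intermediate outpatient follow-up
(8 weeks), admission followed by discharge to intermediate follow-up, and
two hospitalized-until-birth pathways (suspected preeclampsia with birth;
preeclampsia arising during ambulatory care). The two strategies share the
branch structure and differ in allocation — clinical-suspicion admission
(36%, of whom 27% progress to preeclampsia) versus ratio-stratum-driven
admission — plus the per-test cost in the testing arm.

### Allocation modes

The published branch occupancies and the published rate cascade are not
mutually consistent (the rates imply ≈ 975 initial test-arm admissions
against 960 printed admission-pathway patients, and 0.36 × 0.27 × 6084 ≈ 591
against 583). The model therefore keeps both readings explicitly separated:

* **counts mode** (default): the configured base-case occupancies and
  branch totals; reproduces the published cost table cell-for-cell.
* **probability mode**: expected occupancies from the cascade. The
  downstream conditionals the published flows leave open (preeclampsia
  after ambulatory care, the low/intermediate split of ambulatory women)
  are configuration values whose defaults are derived from the base-case
  branch proportions. Used by the microsimulation and available to
  sensitivity work.

## Key parameters (base case)

| parameter | value | unit | why |
|---|---|---|---|
| births_per_year | 86,919 | births | Swiss federal statistics, 2015 |
| suspicion_rate | 0.07 | fraction | published obstetric guidance |
| test unit cost | 140.80 | EUR | cent-precision unit cost; 6084 tests total 856,627 (141 is the display rounding; 6084 × 141 would overshoot the total) |
| stratum prevalences | 0.76 / 0.11 / 0.13 | fraction | ratio ≤ 38 / 38–85 / ≥ 85 |
| admission by stratum | 0.02 / 0.55 / 0.65 | probability | ≤ 38 admission equals the share with BP > 160/110 mmHg |
| discount rate | 0.035 | per year | future-cost discounting, year 1 undiscounted |
| uptake | 1217/2600/3650/5000/6084 | patients/year | assumed 5-year adoption |
| blended birth cost (no PE) | 6,298.50 | EUR | implied by outpatient branch costs; vaginal/C-section split stored at the 1/3 C-section share |

Branch per-patient costs are *implied* values (branch total ÷ occupancy),
because identical branch labels carry different implied unit costs across
strategies (e.g. intermediate-after-hospitalization: 13,711 vs 14,848) and
no stated rule reconciles them; they are stored per strategy, not forced
together. Each branch also carries a decomposition of its per-patient cost
into outpatient-care / hospitalization / birth components (summing to the
implied cost within one cent) so that component-level sensitivity and the
birth-cost-exclusion scenario are well defined. The preeclamptic-delivery
branches are a single inseparable DRG episode and carry their whole cost
as `hospitalization`.

A bottom-up costing mode composes branch costs from tariff atoms instead
(weeks × weekly cost + episode means + delivery blend);
`costing.reconcile_branch_costs` lists both against each other. The
outpatient branches reconcile within 0.5%; the preeclamptic-delivery
branches do not (registry delivery means are far above the implied branch
costs) and are reported as discrepant rather than adjusted. The
post-discharge follow-up durations (2 weeks no-test arm, 4 weeks test arm)
are the values that approximately reproduce the implied
after-hospitalization costs and are exposed as configuration knobs.

### Tariff layer conventions

* The venipuncture fee (6.42) is administered in every setting but
  excluded from the billable per-consultation total; only this rule
  reproduces the published totals (e.g. low setting: 266.06 administered,
  259.64 billable). The catalog therefore carries per-setting billable
  flags. (The published initial-column total is 524.19; the exclusion rule
  gives 524.18 — a one-cent misprint upstream. The computed value is used.)
* The intermediate per-consultation total (546.94) cannot be reconstructed
  from its itemized positions (hand-sum 529.30); the published total is
  stored as an explicit override.
* Weekly costs divide the *administered* per-visit cost by the schedule
  (6 visits / 8 weeks low, 8/8 intermediate).
* Mean (not median) inpatient episode costs enter the model, consistent
  with cohort-expectation accounting.

## Numerical conventions

All monetary arithmetic uses `decimal.Decimal` at cent quantization;
accounting identities (branch sums, overall = medical + testing) hold at
cent precision. Composed tariff costs round to cents with banker's
rounding, the convention that reproduces the published weekly low cost
(266.06 × 6 ÷ 8 = 199.545 → 199.54); whole-euro display rounding is half
away from zero (−346.20 → −346). Cohort arithmetic is fractional
internally; integers appear only in displays. The published cost table's
own difference cell is internally off by €1 (66,469,362 − 64,363,060 =
2,106,302 vs the printed 2,106,301, the unrounded value being
2,106,301.80); the model reports the exact value. The evaluation's
headline annual saving is quoted elsewhere as 2,105,064, which no
combination of the cost-table cells yields; this model reproduces the
cost table.

Budget impact uses unrounded per-patient costs (10,925.27 / 10,579.07) and
the discounting convention `(1+r)^−(y−1)`; this reproduces the published
projection rows to within < 0.01% (residuals stem from the projection
having been printed from independently rounded cells).

## Sensitivity analysis

One-way specifications address a single parameter (relative or absolute)
and re-run the comparison; entries sort by |effect| with deterministic
label tie-breaks. Cost parameters act directly. Stratum admission
probabilities act through an expected-count reallocation in the test arm:
`cohort × prevalence × Δp` patients move between the stratum's outpatient
branch (low for ≤ 38, intermediate above) and the
admission-with-discharge branch, at the destination branch's per-patient
cost. Preeclampsia incidence is deliberately unaffected by this dial — the
admission threshold governs precautionary admissions, not disease — so the
hospitalized-until-birth branches keep their occupancies.

Retest scenarios add test volume only (fraction × population × tests per
patient × unit cost); management-pathway shifts from retest results are
not modelled. Only the 100%-retest result is exactly implied by the stated
parameters (346.20 − 140.80 ≈ 205); the other published sensitivity
magnitudes depend on unstated pathway reallocations, so the tornado CSV
reports this model's own values and the tests pin directions, not those
magnitudes.

## Synthetic data

`synthetic_cohort.simulate_patients` draws individual pregnancies from the
probability-mode cascade: stratum (test arm), admission, preeclampsia,
delivery mode (1/3 C-section), branch and pathway cost. The severe-blood-
pressure flag is drawn only in the ≤ 38 stratum and coincides with
admission there. One explicit numpy `Generator` per simulation; identical
seeds give byte-identical records.

`simulate_registry` emulates the inpatient cost registry: multinomial
group membership (36 : 101 : 164) and log-normal length-of-stay and cost
per group, with `μ = ln(median)` and `σ² = 2 ln(mean/median)` — strictly
positive, right-skewed, and pinned to exactly the two published moments
(which requires mean > median, enforced). Sample means converge to group
means within 2% at n = 100,000.

What the generator does *not* emulate: continuous biomarker values,
gestational-age dynamics, correlation between a woman's outpatient course
and her eventual delivery cost, neonatal outcomes, and any real-world
deviation of pathway costs from their branch means (costs are degenerate
given the branch). Passing convergence tests therefore shows internal
consistency between the simulation and the deterministic tree — not
external validity of the parameters themselves.

Parameter recovery uses sample proportions with Clopper–Pearson binomial
intervals (guaranteed ≥ nominal coverage); a replicate sweep checks that
95% intervals cover the generating values in ≥ 93% of simulations.

## Problem sizes

The test suite simulates up to 200,000 patients per arm for the
law-of-large-numbers checks, 100,000 registry records for moment matching,
and 50 replicates of 20,000 patients for interval coverage — sizes at
which binomial standard errors are comfortably below the asserted
tolerances while the whole suite stays in the seconds range.

## Known limitations

* Counts mode is authoritative for the base case; probability mode cannot
  reproduce the printed occupancies exactly because the published counts
  and percentages disagree (documented above), and its low/intermediate
  split rests on derived defaults.
* The cost components of the preeclamptic-delivery branches are not
  separable, so birth-cost exclusion only strips delivery costs from
  outpatient-managed pathways.
* No probabilistic sensitivity analysis is included (the deterministic
  one-way design mirrors the evaluation's scope); the microsimulation
  provides the machinery should a user build one.
* Retests carry cost but no consequence; diagnostic accuracy itself
  (NPV/PPV of the cut-offs) is an input to the branch allocation, not an
  output of this model.
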