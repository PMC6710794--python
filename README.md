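# preecon

Health-economic evaluation of adding the **sFlt-1/PlGF ratio** to standard
of care for pregnant women with **suspected preeclampsia**, from the Swiss
healthcare system's perspective.

Preeclampsia is suspected in roughly 7% of pregnancies, but most of those
women never develop the disease. The serum ratio of soluble fms-like
tyrosine kinase-1 (sFlt-1) to placental growth factor (PlGF) rules the
condition out short-term when ≤ 38, so a testing strategy can keep many
women in outpatient follow-up who would otherwise be admitted on clinical
suspicion alone. `preecon` quantifies what that is worth: it implements a
cohort **decision-tree cost model** comparing standard of care with and
without the test, a 5-year discounted **budget-impact projection** under a
testing-uptake schedule, **one-way deterministic sensitivity analysis**
(tornado output) with retest and birth-cost-exclusion scenarios, and a
patient-level **microsimulation** that cross-checks the deterministic
expectations and generates a synthetic inpatient cost registry.

The package is aimed at health-economics and HTA analysts who want the
model as tested, configurable code rather than a spreadsheet: every
parameter lives in one YAML document (`preecon.base_case_path()` ships the
Swiss base case, with per-field provenance), and every analysis is a plain
function over the loaded configuration.

## The model

A cohort of `N = ⌊births × suspicion_rate⌋` pregnancies (base case
`⌊86,919 × 0.07⌋ = 6084`) is distributed over mutually exclusive
management branches b with occupancies `n_b` and per-patient costs `c_b`:

```
total(strategy)   = Σ_b n_b · c_b  +  N · c_test · 1{strategy = test}
Δ                 = total(test) − total(no test)
saving / patient  = −Δ / N
```

Branches: low and intermediate outpatient follow-up (8 weeks), admission
with discharge to intermediate follow-up, and two hospitalized-until-birth
pathways (suspected preeclampsia with birth; preeclampsia after ambulatory
care). Under standard of care 36% of women are admitted and 27% of those
progress to preeclampsia; with testing, admission is driven by the ratio
stratum (≤ 38: 76% of women, 2% admitted; 38–85: 11%, 55%; ≥ 85: 13%,
65%). Outpatient costs come from an itemized Tarmed-style service catalog,
inpatient costs from DRG-based registry groups, and the test costs
€140.80 per determination.

The budget impact mixes tested and untested patients year by year under an
uptake schedule and discounts at `(1+r)^−(y−1)` with `r = 3.5%` (year 1
undiscounted).

## Worked example

```
$ preecon --outdir out compare
Cohort: 6084 pregnancies with suspected preeclampsia
No-test strategy total: EUR 66,469,362
Test strategy total:    EUR 64,363,060 (incl. EUR 856,627 for sFlt-1/PlGF testing)
Hospitalized until birth: 1160 (no-test) vs 822 (test)
Difference: EUR -2,106,302 (-346 per patient)
Per-patient saving of the test strategy: EUR 346

$ preecon --outdir out bia
Cumulative 5-year difference: EUR -5,867,442
```

Reading: testing every woman costs €856,627 but avoids enough
hospitalizations (338 fewer women hospitalized until birth) to save €346
per patient overall; at the assumed adoption curve the payer saves ~€5.87M
over five years. `out/` receives the branch-level comparison table, the
per-year budget-impact table, a tornado-ready sensitivity CSV
(`preecon sensitivity`), and a JSON manifest per command. The same results
are available as library calls:

```python
from preecon import load_config, base_case_path, compare
cmp = compare(load_config(base_case_path()))
print(cmp.per_patient_saving)   # 346.20
```

`preecon simulate --arm test --n 200000 --seed 7` draws synthetic
patient-level records consistent with the configured cascade and writes
them as CSV.

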