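# faersignal

Disproportionality-based adverse-event signal detection for FAERS-style
spontaneous-report data.

Spontaneous-report databases such as the FDA Adverse Event Reporting System
(FAERS) collect voluntary reports of suspected drug–adverse-event
associations. Because no denominator of exposed patients exists, safety
signals are screened by *disproportionality*: comparing how often a
drug–event pair is reported against its expectation if drug and event were
independent across the whole database. `faersignal` implements that workflow
end to end for any target drug: ingestion of quarterly ASCII bundles,
case-level deduplication, primary-suspect cohort selection, MedDRA
aggregation, four disproportionality estimators with a joint signal screen,
descriptive summaries, and age/sex/weight-stratified sensitivity analyses —
plus a synthetic-bundle generator with planted signals so the whole pipeline
can be validated against known ground truth.

## The statistics

For one drug–term pair, reports are cross-classified into the 2×2 table

|            | term      | other terms |
|------------|-----------|-------------|
| target drug (PS) | a   | b           |
| all other drugs  | c   | d           |

with N = a+b+c+d and independence expectation E = (a+b)(a+c)/N. The four
estimators are

- **ROR** = ad/bc, with 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)); zero
  cells get the Haldane 0.5 correction (flagged);
- **PRR** = [a/(a+b)] / [c/(c+d)] with its log-normal CI, plus a Pearson χ²
  over the four cells (Yates-corrected by default, switchable);
- **BCPNN information component** IC = log₂(a/E) in the default
  maximum-likelihood ("plain") form, or log₂((a+0.5)/(E+0.5)) in the
  shrunk Norén form; IC025 by the Norén approximation or the exact gamma
  posterior quantile;
- **EBGM**: simplified observed/expected a/E (which makes EBGM = 2^IC an
  exact identity with the plain IC), or the full empirical-Bayes
  gamma-Poisson shrinker — a two-component gamma mixture prior on the
  reporting-rate ratio λ, fitted by marginal maximum likelihood over all
  tables at one MedDRA level, with EBGM the posterior geometric mean and
  EB05 the 5th posterior percentile.

A pair is a **signal** when all criteria hold jointly: a ≥ 3, ROR and PRR
lower 95% bounds > 1, χ² ≥ 4, IC025 > 0, and EBGM > 2.

Case-level processing follows the FDA deduplication rule (per CASEID keep
the latest FDA_DT, break ties by largest PRIMARYID), selects the cohort by
keyword substring match on normalized drug name / active ingredient
restricted to the Primary Suspect role, normalizes age and weight unit codes
(DEC/YR/MON/WK/DY/HR, KG/LBS/GMS), and computes time-to-onset only from
day-precise dates.

## Worked example

Generate a synthetic bundle with one planted signal (relative risk 20 on
`PT_025` for the target drug), then run the screen:

```python
from faersignal import (SyntheticConfig, PlantedSignal, generate_bundle,
                        prepare_dataset, run_analysis)

cfg = SyntheticConfig(
    n_cases=5000, seed=3,
    planted_signals=[PlantedSignal("TARGETDRUG", "PT_025", 20.0)],
)
tables, truth = generate_bundle(cfg)
ds = prepare_dataset(tables, ["TARGETDRUG"])
print("counts:", ds.counts)
res = run_analysis(ds, level="PT")
print(res.positives.head(3).round(2))
print(truth.table.round(2))
```

prints

```
counts: {'reports_in': 5000, 'deduplicated': 5000, 'cohort': 519, 'pairs': 8525}
  term   a   ror  ror_low  ror_high   prr   chi2   ic  ic025  ebgm  signal
PT_025 135 19.52    14.49     26.31 16.69 690.62 2.67   2.38  6.36    True
      drug     pt   rr  expected  realized
TARGETDRUG PT_025 20.0      4.61       135
```

The planted pair is recovered: 135 of the cohort's 519 reports list
`PT_025` against a background expectation of 4.6, the ROR confidence
interval (14.5–26.3) brackets a strong excess, and the pair passes every
joint criterion (`signal = True`). EBGM (6.36) is smaller than the ROR
because within the small synthetic database the cohort contributes a
sizeable share of all `PT_025` reports, which dilutes the observed/expected
ratio — exactly the behavior seen for common events in real databases.

The same pipeline runs from the shell:

```sh
faersignal simulate --out bundle/ --n-cases 5000 --seed 3
faersignal analyze --quarters-dir bundle/ --out signals/ \
    --keyword TARGETDRUG --meddra-map bundle/meddra_map.tsv --level SOC
faersignal stratify --quarters-dir bundle/ --out strata/ --keyword TARGETDRUG
```

For real FAERS quarters, point `--quarters-dir` at the extracted ASCII files
(`DEMO23Q3.txt`, …), pass `--profile legacy` for pre-2012Q4 bundles, and
supply a licensed MedDRA PT→HLT→HLGT→SOC table as a 4-column TSV.

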