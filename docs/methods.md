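# Methods

## Data model and case processing

The pipeline consumes quarterly spontaneous-report bundles in the FAERS
ASCII dialect: "$"-delimited files DEMO, DRUG, REAC, OUTC and THER with one
header line, keyed by PRIMARYID. Two schema profiles cover the 2012Q4
schema break: `current` (PRIMARYID/CASEID) and `legacy` (ISR/CASE); both map
onto one canonical internal model, so the rest of the pipeline never sees
the era difference. The profile is chosen per run because published
analyses typically do not state how they bridged the break.

Parsing is strictly accounted: every input line either becomes a record or
increments a skipped-line counter (`records_in = parsed + skipped`), and
DEMO rows whose mandatory FDA_DT fails calendar validation are dropped into
the same counter rather than silently coerced. Dates of partial precision
(YYYY, YYYYMM) are retained with a precision flag; day-level arithmetic
(time-to-onset) is only defined between two day-precise dates, so onset is
never fabricated from a month-precision field.

Deduplication implements the FDA rule: per CASEID keep the report with the
latest FDA_DT, breaking ties by the largest PRIMARYID (numeric comparison
when ids are numeric). The operation is a pure function of the record set —
idempotent and order-independent.

Cohort selection marks a report as target-drug exposed when at least one of
its DRUG rows has the configured role code (default PS, primary suspect)
and a normalized drug name or active-ingredient string containing a
normalized keyword. Normalization uppercases, strips punctuation and
collapses whitespace, because FAERS drug names are free text full of salts,
strengths and formulations. Background reports are all other deduplicated
reports, including those that mention the drug in non-PS roles — the screen
is about *suspected* causation, and demoting concomitant mentions to the
background mirrors the PS-only cohort definition.

Unit handling: age codes DEC/YR/MON/WK/DY/HR convert to years by factors
10, 1, 1/12, 1/52, 1/365, 1/8760; weight codes KG/LBS/GMS convert to kg by
1, 0.45359237, 0.001. A missing age unit defaults to years and flags the
record. Negative ages and nonpositive weights are excluded from strata and
counted.

Binning uses half-open intervals throughout so every value lands in exactly
one bin. The stratification bins are [0,18), [18,65), [65,∞) years and
[0,50), [50,100), [100,∞) kg; the common "<18 / 18–65 / >65" and
"50–100 kg" labels overlap at their edges, so the half-open convention
assigns exactly 65 years to the ">65" stratum and exactly 100 kg to
">100 kg" — recorded in run metadata. Onset bins are [0,8), [8,29),
[29,61), [61,∞) days labeled 0–7, 8–28, 29–60, ≥60; missing onset goes to
an explicit Unknown bin.

## Disproportionality estimators

All estimators work on the 2×2 table (a,b,c,d) per drug–term pair, where
the counting unit is the distinct (report, term) pair: duplicate terms
within a report count once, and at SOC level a report counts once per SOC
regardless of how many of its PTs map there. Terms missing from the MedDRA
map at SOC level aggregate under an explicit "Unmapped" sentinel. Terms
with a below `min_count` (default 3) are retained in output but flagged out
of the screen — the standard report-count floor for this kind of screen.

- ROR = ad/bc and PRR = [a/(a+b)]/[c/(c+d)], both with log-normal Wald
  CIs. Tables with a zero cell get the Haldane 0.5 continuity correction
  on all cells and a `corrected` flag, which keeps rare terms with extreme
  ratios in the output instead of dropping them.
- χ² is the Pearson statistic over the four cells, Yates-corrected by
  default (the common choice in this literature) with a switch; the choice
  is recorded in run metadata. Tables with a zero expected cell return NaN
  and fail the χ² criterion rather than erroring.
- The information component defaults to the maximum-likelihood ("plain")
  form IC = log₂(aN/((a+b)(a+c))) = log₂(a/E). This makes
  EBGM = 2^IC an exact identity with the simplified shrinker below — the
  pattern visible in published signal tables, where the printed IC column
  is log₂ of the printed EBGM column. The shrunk Norén form
  log₂((a+0.5)/(E+0.5)) is available by config. IC025 variants: the Norén
  closed-form approximation IC − 3.3(a+0.5)^(−1/2) − 2.0(a+0.5)^(−3/2)
  (default), or the exact 2.5% quantile of the Gamma(a+0.5, E+0.5)
  posterior on the observed/expected ratio. Published IC−IC025 offsets
  vary across software packages and often match no single closed form, so
  interval bounds are variant-labeled in output metadata rather than
  presented as canonical.
- EBGM defaults to the simplified observed/expected ratio a/E with a
  log-normal lower bound at the one-sided 5% level. The full
  empirical-Bayes form (below) is a config switch, computed separately per
  MedDRA level because expectations scale differently at PT and SOC level.

The joint screen requires a ≥ 3, ROR and PRR lower 95% bounds > 1, χ² ≥ 4,
IC025 > 0 and EBGM > 2, with strict inequalities exactly where stated; each
failed criterion is named in the output. Ranking is by EBGM descending with
deterministic tie-breaks (larger a, then term lexicographic).

## Gamma-Poisson shrinker

The full MGPS models a ~ Poisson(λE) with λ drawn from a two-component
gamma mixture prior w·Gamma(α₁,β₁) + (1−w)·Gamma(α₂,β₂) (shape/rate). The
marginal of each component is negative binomial, and the prior is fitted by
maximizing the total marginal log-likelihood across all tables at one
level. Fitting starts from the fixed point (α₁=0.2, β₁=0.1, α₂=2, β₂=4,
w=1/3) and runs EM — responsibilities, weight update, then per-component
weighted negative-binomial maximization by L-BFGS in log-parameter space
with analytic gradients. EM alone crawls along the likelihood ridge of
weakly separated mixtures (thousands of iterations without meeting a 1e-8
log-likelihood tolerance), so once EM improvement falls below 1e-4 the fit
hands the current point to a direct quasi-Newton maximization of the same
marginal likelihood over all five (transformed) parameters. Both stages are
deterministic given the fixed start; non-convergence returns the best
iterate with `converged_ = False`. On flat null likelihoods (both
components equal) the optimizer may report non-convergence while the fitted
prior mean is accurate — the flag marks exactly that ridge case.

The posterior for a table is again a two-component gamma mixture with
components Gamma(αⱼ+a, βⱼ+E). EBGM is the posterior geometric mean
exp(E[ln λ|a]) via digamma; EB05 is the 5th percentile of the mixture,
found by Brent root-finding on the mixture CDF bracketed by the component
quantiles (xtol 1e-9), with degenerate mixtures (posterior weight
numerically 0 or 1) short-circuited to the surviving component's quantile.
Shrinkage behaves as the model dictates: small counts move toward the prior
mean, and the shrinkage factor of a gamma posterior approaches E/(E+β), so
EBGM converges to a/E as a and E grow together (not for large a at fixed
E — a property the tests check in its correct form).

## Synthetic bundle generator

The generator emulates the *statistical structure* the pipeline depends on,
with all randomness flowing from one integer seed (identical config + seed
⇒ byte-identical files):

- cases spread uniformly over quarters with uniform report days; duplicate
  re-reports (configurable fraction, floor(rate·n) cases) appear with a
  strictly later FDA_DT and a larger PRIMARYID version suffix, all other
  fields copied — exactly the situation the FDA dedup rule resolves;
- one primary-suspect drug per case drawn from a configurable marginal
  distribution (default: ten drugs at 10% each, so the target cohort is
  about a tenth of the database — large enough for stable tables, small
  enough that the background dominates), plus Poisson(1) extra drugs in
  non-PS roles;
- per report, k PTs (default 1–3, mean 1.7) sampled *without replacement*
  from a Zipf-like vocabulary (50 PTs, pᵢ ∝ 1/i by default — spontaneous
  report term frequencies are heavy-tailed), with weights multiplied by the
  relative risk of the primary-suspect drug's planted pairs and
  renormalized (Gumbel top-k sampling). Sampling without replacement keeps
  per-report PT sets duplicate-free, matching the counting convention.
  Renormalization means a planted relative risk r realizes as slightly less
  than r (attenuation factor 1 + p·(r−1) for a base-probability-p term),
  which is negligible for rare terms and accounted for in calibration
  tests; planted signals can be restricted to demographic subgroups to
  exercise stratified analyses;
- demographics with FAERS unit codes (ages in YR/MON/DEC, weights in
  KG/LBS) to force unit handling, and per-field missingness (defaults: age
  30%, sex 20%, weight 50%, event date 50%, therapy start 60% — the heavy
  missingness regime typical of spontaneous reports, onset in particular
  being mostly unknown);
- serious-outcome codes attached independently with small probabilities,
  so some reports carry several codes (outcome counts may exceed report
  counts, as in real descriptive tables).

Ground truth records each planted pair's baseline expectation
(n drug reports × PT marginal probability), planted relative risk and
realized count.

What the generator does *not* model: reporter behavior and reporting waves,
drug–drug interactions, realistic MedDRA vocabularies (the bundled map
assigns PTs round-robin to synthetic SOCs), correlated demographics, or
country/occupation structure. Passing tests therefore demonstrate that the
pipeline's counting, dedup, stratification and estimators are correct under
the stated statistical structure — not that real FAERS extractions are free
of the confounding and reporting biases inherent to spontaneous data.

## Descriptive summaries

Counts and percentages by sex, age bin, reporter occupation, country,
reporting year, serious outcome and onset bin, with explicit
Missing/Unknown rows. Percentages use the deduplicated cohort size as
denominator, rounded to a per-dimension precision (2 decimals for
year/onset/country, 1 for sex/age/reporter) mirroring the mixed precision
of published tables; both are configurable. Serious-outcome percentages
default to the total outcome-code denominator because one report can carry
several codes; the choice is a config switch recorded in output.

## Problem sizes and runtime

Validation runs use bundles of 3,000–6,000 cases (cohorts of roughly
300–650 reports), 20-replicate Monte-Carlo checks for null specificity and
CI coverage (2,000 null tables), and 5,000-table fits for shrinker
parameter recovery — sizes at which the binomial/Poisson expectations the
oracles compute are sharp while the full suite stays under a minute of
estimator time. The acceptance script additionally reconstructs published
summary numbers from printed table counts (1,910 reports; 5,172 drug–SOC
pairs) through the same code paths used for synthetic data, using a 10⁹-pair
background mimic where a published row's observed/expected ratio must be
reproduced at fine granularity.

## Known limitations

- No multiple-testing adjustment is applied across terms; the joint
  criterion is itself conservative under the null (about 1% of terms pass
  in null simulations) but the screen remains exploratory.
- Disproportionality quantifies reporting disproportion, not risk; no
  causal or incidence interpretation is supported.
- Record linkage beyond the FDA CASEID rule (probabilistic dedup) and
  multi-drug interaction tables are out of scope.
- The legacy-era profile maps ISR/CASE but the generator only emits the
  current dialect; legacy parsing is exercised with hand-built fixtures.
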