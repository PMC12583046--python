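# Methods

## Study design

The package implements the standard spontaneous-report study of
drug-associated serotonin syndrome in the elderly: pool quarterly FAERS
extracts, keep one version per case, restrict to patients aged ≥65 years,
identify event cases by the MedDRA preferred term "Serotonin syndrome"
(exact, case-insensitive match on the PT string — no hierarchy traversal),
take primary-suspect (role PS) drugs as the exposure, and test each drug's
reporting disproportionality against the background of all elderly reports.
A sensitivity analysis repeats the disproportionality stage on the subset
reported by healthcare professionals; it is literally a re-run of the same
stage on the filtered population, not a parallel codepath.

Two design points were genuinely open and are worth stating:

- **Background population.** The study frame is elderly patients, so the
  default background is all deduplicated reports aged ≥65 ("elderly-only").
  An all-ages background is available via `background_scope="all"`; in that
  mode event-positivity is still cohort membership (serotonin syndrome *in
  an elderly patient*), which keeps cohort ⊆ background.
- **Deduplication rule.** Spontaneous databases do not ship a dedup rule
  with the data. We use the FDA-documented convention: group by `caseid`,
  retain the version with the latest receipt date (`fda_dt`), break ties by
  the largest numeric `primaryid`, and join DRUG/REAC/OUTC/THER rows for
  the retained `primaryid` only. A partial receipt date falls back to the
  end of the quarter the row appeared in, so every version stays orderable.

Field-level conventions: age units YR/DEC/MON/WK/DY/HR convert to years
(52.1775 weeks, 365.25 days, 8766 hours per year); a missing unit means
years (the dominant FAERS unit) and ages above 125 y are treated as
recording errors. Occupation codes MD/PH/HP/OT count as healthcare
professionals, CN/LW as non-healthcare, anything else as missing. Partial
dates (YYYYMM or YYYY) in EVENT_DT/START_DT are missing for onset analysis.
Drug names are canonicalized (uppercase, trim, collapse punctuation and
whitespace, strip a fixed list of trailing salt tokens: HCL,
HYDROCHLORIDE, SULFATE, TARTRATE, MALEATE, SUCCINATE) before exact synonym
lookup; the fixed suffix list is deliberately not a greedy regex so the
mapping stays auditable. Combination products ("/" or "+") stay unmapped
unless an exact entry exists, because the suspect ingredient is ambiguous.
Unmapped names pass through flagged rather than being dropped.

## Disproportionality measures

With a = reports carrying the drug (PS) and the event, margins b, c, d,
N = a+b+c+d and E = (a+b)(a+c)/N:

- **ROR** = ad/bc; 95% Woolf interval exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
  If any cell is zero, 0.5 is added to all four cells (Haldane–Anscombe)
  and the estimate is flagged as corrected; a = 0 returns missing values
  (such a pair can never signal since a ≥ 3 is required). The correction is
  applied to the ROR only — PRR, χ², IC and EBGM tolerate zeros within
  their stated preconditions and use raw cells.
- **PRR** = [a/(a+b)]/[c/(c+d)]; χ² is the Pearson statistic
  N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)] without Yates correction.
- **IC** = log₂((a+0.5)/(E+0.5));
  IC025 = IC − 3.3(a+0.5)^(−1/2) − 2.0(a+0.5)^(−3/2), the standard
  gamma-approximation credible bound.
- **EBGM**: the observed count is modeled as a ~ Poisson(λE) with the rate
  ratio λ drawn from the two-component gamma mixture
  w·Ga(α₁,β₁) + (1−w)·Ga(α₂,β₂). Conjugacy gives a posterior mixture with
  components Ga(αᵢ+a, βᵢ+E) and posterior weight
  Q = w·m₁/(w·m₁+(1−w)·m₂), where mᵢ is the negative-binomial marginal of
  a under component i. EBGM = exp(E[ln λ]) via the digamma closed form
  Q(ψ(α₁+a)−ln(β₁+E)) + (1−Q)(ψ(α₂+a)−ln(β₂+E)); EB05 solves the mixture
  CDF at 0.05 by plain bisection to relative tolerance 1e−8, bracketed by
  the component percentiles. The default prior is the classic
  (α₁, β₁, α₂, β₂, w) = (0.2, 0.1, 2.0, 4.0, 1/3). `fit_gps_prior`
  maximizes the summed log negative-binomial marginal likelihood over ≥50
  (a, E) pairs by L-BFGS-B from five documented starts, with gamma
  parameters log-transformed and the weight logit-transformed; failures and
  degenerate inputs (all a = 0) fall back to the default prior with a
  warning. Note the two-component likelihood is weight-unidentifiable when
  the truth has one component: the fit then splits weight between two
  near-identical components whose implied marginal matches the single
  component, which is why recovery is validated on held-out marginal
  likelihood rather than on individual parameters.

**Signal rule** (all must hold): ROR025 > 1, PRR ≥ 2, χ² ≥ 4, IC025 > 0,
a ≥ 3. Missing metrics fail automatically. Strict mode adds EB05 > 2; it
is off by default because the published five-criterion rule does not
include an EBGM threshold even though all four algorithms are computed.
Volcano tables use the two-sided Fisher exact p-value under the
sum-of-smaller-probabilities convention (stated because two-sided Fisher
definitions differ; this is scipy's convention, against which it is
cross-checked), Bonferroni-adjusted with m = the number of evaluable drugs
in the run — not the number of eventual signals — because the comparison is
among all drugs analyzed.

## Time-to-onset

TTO = EVENT_DT − START_DT in whole days, with the earliest therapy-start
record of the primary-suspect drug when several exist (onset is measured
from first exposure). **Same-day onset is recorded as 0.5 days**: classes
whose events cluster on the day of administration (dermatologicals,
various) then carry a positive representable median of 0.5 d with IQR
0.5–0.5, which a 0-day convention could not express. Negative intervals and
partial/missing dates are excluded with reason codes that the run manifest
reports. Groups with fewer than two valid values are dropped. Quartiles use
linear interpolation on p·(n−1) positions (the numpy/R type-7 default),
chosen so small fixtures have exact hand-checkable values. ECDF tables are
step functions ending at exactly 1.

Rank tests: Mann-Whitney U with midrank ties; two-sided p by exhaustive
enumeration of all group assignments of the combined multiset when
n₁+n₂ ≤ 10 (counting splits at least as extreme in |U − n₁n₂/2|), else the
tie-corrected normal approximation with continuity correction. Completely
tied data give U = n₁n₂/2, p = 1. One accuracy caveat, verified
exhaustively: the exact null of U at n ≤ 10 is discrete with probability
steps up to ≈0.07, so the normal approximation cannot track the exact
p-value to 0.02 uniformly over all splits; agreement within 0.02 holds in
the small-p region (exact p ≤ 0.1) for untied data, and the uniform gap
away from singleton groups is ≤0.05. Singleton groups are degenerate for
rank comparisons and are not summarized. Multi-group comparisons use
Kruskal-Wallis (tie-corrected, χ² reference with k−1 df) with pairwise
Mann-Whitney p-values adjusted by Benjamini-Hochberg across all pairs.

## Descriptive summaries

Outcome codes collapse to one mutually exclusive worst-outcome class with
precedence Death (DE) > Life-Threatening (LT) > Hospitalization (HO) >
Disability (DS) > Other (CA, RI, OT or none); the order is conventional
severity and configurable, since code sets do not themselves define a
ranking. Age bands are 65–74, 75–84, 85–94, ≥95 with inclusive lower
bounds. Countries report the top 10 by count; sex/country/reporter missing
values appear as explicit "Missing" rows. Percentages are computed against
the full cohort size and rounded half-up to one decimal, matching how such
tables are printed.

## Synthetic data generator

The generator emits FAERS-dialect quarterly files whose study conditions
mirror a large published elderly serotonin-syndrome case series, so the
pipeline's outputs are qualitatively comparable at a glance:

- **Demographics**: sex 61.5% female / 37.6% male / 0.9% missing; elderly
  age bands in the 60.7/29.3/8.6/1.4 ratio, with 25% of reports under 65 to
  exercise cohort selection; country, reporter-occupation and outcome-class
  mixtures likewise follow the published proportions.
- **Exposure and event**: each report draws one primary-suspect drug
  uniformly from a 50-drug roster (30 nervous-system, 6 antiinfective,
  6 alimentary, 3 musculo-skeletal, 2 dermatological, 2 various,
  1 respiratory) plus 0–2 concomitants; the target PT is assigned with
  probability base_rate·λ_drug (base_rate 0.02, capped at 1). Five drugs
  (fluoxetine, sertraline, venlafaxine, tramadol, linezolid) are planted at
  λ = 10; the rest at λ = 1. At the default sizes each planted drug expects
  well over ten target-PT reports, the regime in which the five-criterion
  rule should recover them essentially always.
- **Onset times**: log-normal per ATC class, parameterized to the published
  class medians (nervous system 16.5 d with a long tail, antiinfectives and
  alimentary 1.5 d, musculo-skeletal 2.5 d, dermatologicals/various
  same-day) — making those numbers a generator self-check, not a claim of
  reproducing FAERS.
- **Plumbing stress**: 5% of cases are re-emitted as a later version
  (next-quarter receipt, version-2 id) to exercise deduplication; 30% of
  mentions use trade names and 10% carry salt suffixes to exercise
  normalization; event/start dates are missing at rate 0.2 and 2% of
  event dates are planted before therapy start as data-entry errors.

All randomness flows from one integer seed through a single
`numpy.random.default_rng` stream consumed in a fixed order (per quarter:
one vectorized draw per attribute, then per-report draws for onset and
reaction lists), so a fixed seed yields byte-identical files.

What the generator does **not** emulate: FAERS-scale cardinality (millions
of reports), real co-reporting correlation between drugs, polypharmacy
interaction effects, reporting-rate drift over calendar time, and free-text
name noise beyond trade/salt variants. Passing recovery tests therefore
demonstrates that the statistical machinery detects planted
disproportionality under realistic report structure — not that any
particular real-world drug association is reproduced.

## Problem sizes and numerics

The default synthetic study is 4 quarters × 2,500 reports (10,000); the
seeded recovery experiments use 100 runs of 2 × 3,000 reports, null
calibration uses 10,000 reports with all λ = 1, and interval-coverage
checks use 1,000 simulated tables — sizes at which every planted effect is
comfortably detectable and the full suite runs in a few minutes. EB05
bisection is bracketed by the component 5th percentiles and expands the
bracket geometrically if needed; the prior fit bounds log-parameters to
±7 and the logit weight to ±10. Degenerate inputs are handled explicitly:
empty quarters parse to empty record sets, drugs absent from the background
yield non-evaluable tables, a = 0 yields missing ROR, all-tied rank-test
samples yield p = 1, and groups under the two-value minimum are dropped and
logged.

## Known limitations

- Exact PT-string matching cannot pick up related MedDRA terms; the study
  design uses a single preferred term by construction.
- The elderly-only background is one defensible choice; estimates under an
  all-ages background differ and are available via configuration, but no
  attempt is made to adjudicate between the two.
- The normal-approximation caveat for tiny rank tests above.
- Synthetic validation bounds what the tests show about real data (see the
  generator section); the pipeline's real-data behavior inherits all the
  usual limitations of spontaneous-report analysis (underreporting,
  confounding by indication, no causal interpretation).
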