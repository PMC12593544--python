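# Methods

This note records the statistical model behind `faersig`, the numerical
and design choices that were genuinely open, and what the synthetic data
generator does and does not emulate.

## Data model and deduplication

A FAERS case (CASEID) may appear as several report versions (PRIMARYID)
with different FDA receipt dates (FDA_DT). The pipeline keeps, per case,
the version maximizing `(fda_dt, primaryid)` lexicographically: the most
recent receipt date, ties broken by the highest PRIMARYID. An FDA_DT
that is not a full calendar date sorts below every dated value, so such
versions lose all tie-breaks but are retained when they are the only
version of a case — dropping them would silently shrink the cohort. The
operation is a pure function of the row multiset: idempotent and
invariant to input order.

Drug matching is case-insensitive *substring* search over DRUGNAME and
PROD_AI, because FAERS drug names are free text with dose and brand
suffixes; exact matching would lose recall for a generic ingredient
term. Trade names are not auto-expanded — the CLI accepts repeated
`--drug` flags instead. The analysis cohort is the subset of retained
reports with at least one matching row whose role code is PS.

Normalization conventions: age units DEC×10, YR×1, MON÷12, WK÷52.1775,
DY÷365.25, HR÷8766 (years); weight KG×1, LBS×0.453592; anything
unparseable, negative, or with an unknown unit is missing. A report's
outcome codes are reduced to one category by severity priority
DE > LT > HO > DS > CA > RI > OT — the reduction makes outcome a true
partition of the cohort, so category counts sum to the cohort size.
Report year is taken from the receipt date; country from OCCR_COUNTRY;
reporter from OCCP_COD (CN→consumer, MD→physician,
HP→health professional, PH→pharmacist, other→other, empty→missing).

## Counting unit and the 2×2 table

All contingency cells count **unique (report, term) pairs** after
per-report term deduplication, for the drug and the background margins
alike. At SOC level, PTs are first mapped to their primary SOC and the
pairs re-deduplicated, so a report with several PTs in one SOC counts
once there; this is why SOC-level case counts can exceed the report
count. The comparator ("other drugs") is every deduplicated report not
in the target cohort — the standard full-database background. Reports
with no reaction rows stay in the cohort for descriptive purposes but
contribute no pairs.

## The four algorithms

With N = a+b+c+d:

* **ROR** = ad/(bc); 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
* **PRR** = a(c+d)/(c(a+b)); χ² is the Pearson statistic of the 2×2
  table, no continuity correction.
* **BCPNN IC** = log₂(aN/((a+b)(a+c))). The lower credibility bound is
  IC025 = IC − 2√V(IC) with the standard Bayesian posterior-variance
  expansion

      V(IC) = (1/ln2)² [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                        + (N−(a+b)+α−α₁)/((a+b+α₁)(1+N+α))
                        + (N−(a+c)+β−β₁)/((a+c+β₁)(1+N+β)) ],
      γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)),

  under the symmetric priors α₁=β₁=γ₁₁=1, α=β=2 (configurable). The
  point estimate is the plain observed/expected log-ratio, not the
  posterior mean.
* **EBGM** = aN/((a+c)(a+b)) — deliberately the *unshrunk*
  observed/expected ratio (identically 2^IC), with a log-normal-style
  lower bound EBGM05 = exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d)). True
  gamma-Poisson (MGPS) shrinkage is intentionally out of scope; the
  statistic is named for the convention used in the disproportionality
  screening literature this pipeline follows, and the lack of shrinkage
  matters mainly for very small a.

Signal criteria, with operators exactly as conventionally published:
ROR CI lower bound **>** 1 with a **≥** 3; PRR **≥** 2 and χ² **≥** 4
with a **≥** 3; IC025 **>** 0; EBGM05 **>** 2. The reported signal set
is the intersection of all four. A second intersection is reported after
removing terms whose SOC is on a configurable exclusion list (default:
the neoplasms SOC, which in oncology cohorts reflects disease
progression rather than drug toxicity).

**Zero cells.** Statistics are computed only when their denominator
cells are positive; otherwise the term is reported with its case count
and not-computable (NaN) markers, and every flag is false — never an
infinite estimate. The published formulas carry no continuity
correction, so none is applied by default; `--zero-cell-correction`
enables an exploratory Haldane +0.5 on all cells of zero-cell tables
only.

Ranking is by descending case count, ties broken lexicographically by
term, making output deterministic; identical inputs give bit-identical
outputs throughout.

## Time-to-onset Weibull model

Onset = EVENT_DT − (earliest day-resolution START_DT among the report's
PS target-drug therapy rows), in days. Earliest start is the
conservative reading of "drug initiation" when several therapy rows
exist. Excluded and tallied by reason: no usable therapy start, missing
or partial event date, event before start (chronologically implausible),
and same-day events — the last because the Weibull density has positive
support and the analysis convention reports a minimum of one day. Only
full 8-digit calendar dates enter the arithmetic; month- and
year-resolution dates are unusable for intervals. No censoring model:
only reports with an observed event enter.

The two-parameter Weibull is fit by maximum likelihood: the shape
equation Σtᵝln t/Σtᵝ − 1/β − mean(ln t) = 0 is solved by bracketed
Brent root finding (values pre-scaled by the sample maximum so the
powers stay finite), and the scale follows in closed form,
α = (Σtᵝ/n)^(1/β). 95% CIs are normal approximations on the *log*
parameters (respecting positivity) using the inverse observed
information, computed by central finite differences of the negative
log-likelihood (step 1e-5) and back-transformed with z = 1.96. Fits
require n ≥ 10 and more than one distinct value (a point mass has an
unbounded likelihood). Classification uses the shape CI, not the point
estimate: `early` when the upper bound is below 1, `wear_out` when the
lower bound exceeds 1, `random` otherwise.

Summary quantiles (median, IQR) use the linear-interpolation convention
(numpy's default) — documented because at a few hundred observations the
median can shift by a day across conventions. Onset histogram bins are
1–30, 31–60, 61–90, 91–180, 181–360, >360 days.

## Descriptives and subgroups

Profile partitions: sex (female/male/unknown), age strata <18, 18–64.9,
65–85, >85, missing; weight <50, 50–100, >100 kg, missing; outcome;
top-5 countries (ties alphabetical); reporter type; reporting year.
Percentages are against the whole cohort including missing, rounded
half-up to one decimal only at presentation.

Subgroup screens restrict cohort *and* comparator to the same stratum
(male cohort vs male background) — the standard convention. The age
subgroups use the two-way adult split 18–64 vs ≥65; under-18 reports
fall outside both strata.

## Synthetic data generator

The generator emulates the structural hazards of real quarters: several
tables keyed by PRIMARYID/CASEID; duplicate case versions mutating only
FDA_DT/PRIMARYID (half share the receipt date so the PRIMARYID tie-break
is observable, and half of the rest give the stale version the *higher*
PRIMARYID so date priority is observable); a target drug in ~1% of
reports as primary suspect plus a small fraction of non-PS mentions the
PS filter must reject; a brand-name variant whose ingredient appears
only in PROD_AI; background PTs drawn i.i.d. from a configurable
multinomial and collapsed to per-report sets; partial (month/year),
missing and inverted dates; and demographic/outcome/reporter fields.

Signals multiply the selection odds of designated PTs inside target-drug
reports. Because draws are i.i.d. multinomial, the expected contingency
cells have the closed form E[a] = n_t·(1−no_reac)·E_k[1−(1−p_t)^k] (and
analogously for b, c, d), which is the oracle for recovery tests.

Defaults are fixed once at study-like conditions: 20,000 reports,
target_share 0.01, PTs-per-report uniform 1–5, one planted signal at
odds ratio 10, onset Weibull(scale 32.74 days, shape 0.81) — an
early-failure regime — duplicate rate 0.10, partial/inverted/missing
event date rates 0.05/0.03/0.10, missing therapy start 0.10, and
demographic category frequencies echoing a US-dominated oncology-drug
cohort (52% male, ~50% age missing, 81% weight missing, 34% death
outcome, 63% US, 34% consumer reporters).

What the generator does **not** model: real drug co-reporting structure
(background reports carry one primary suspect plus at most one
concomitant), the depth of the MedDRA hierarchy (the bundled PT→SOC map
is a flat synthetic stand-in; MedDRA itself is licensed), country- or
reporter-specific reporting styles, secular reporting trends, and
within-report correlation between PTs. Passing tests therefore
demonstrate correctness of the *pipeline mechanics and statistics* under
a known generative model, not fidelity of any particular real-world
signal list.

## Problem sizes used in validation

Signal-recovery checks run 100 replicates of the 20,000-report
configuration; Weibull recovery uses one fit at n = 5,000 and CI
calibration over 500 replicates at n = 393; Monte-Carlo checks of the
expected-cell oracle use 60 replicates at n = 2,000. These sizes give
stable Monte-Carlo estimates for the quantities asserted (recovery
proportions, ~95% coverage) while keeping the default test run quick.

## Known limitations

* EBGM without shrinkage overstates disproportionality at very small a;
  the N ≥ 3 gates on ROR/PRR and the Bayesian IC025 partially compensate,
  and the all-four intersection is the operative signal definition.
* No stratified (age/sex-adjusted) expected counts and no
  multiple-comparison correction — screening is hypothesis-generating.
* The dedup rule is the field's receipt-date convention, not
  probabilistic record linkage; true duplicates with distinct CASEIDs
  survive it.
* "Inconsistent temporal documentation" beyond event-before-start is not
  further specified anywhere authoritative; only the explicit rule is
  enforced, other records pass through.
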