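# Methods

## Data model and counting rules

The unit of analysis is the *case* (one patient report), assembled from the
four-table csv layout used by JADER-style spontaneous reporting systems:
DEMO (case id, sex, age, report year), DRUG (case id, drug name, reporter
role), REAC (case id, MedDRA preferred term) and HIST (accepted for schema
completeness, unused by the analysis).  Rows sharing a case id are merged;
a preferred term recorded several times in one case is kept once, so every
downstream count is a count of cases rather than of drug–event rows.
Duplicate DEMO rows with conflicting demographics resolve first-wins with a
logged warning.  Input is UTF-8 by default with a configurable encoding
(real Japanese releases are CP932) and a logical→physical column map, since
physical headers vary across releases and languages.

Ages are collapsed to decade bands (<40, 40–49, …, 80–89, ≥90).
Non-numeric age terms ("youth", "elderly", …) are classified *subjective*.
The default exclusion rules drop cases with subjective age, missing sex or
missing age, in that order of precedence; the retained count is the
analysis denominator N₊₊.  Exclusion is idempotent and the per-reason
counts partition the removed cases.

Event flagging uses a Standardized MedDRA Query: a case is flagged when its
event set intersects the selected scope's preferred terms.  Both narrow and
broad scope are used by default.  SMQ tables are input files, not
hard-coded, because MedDRA is licensed and versioned; a three-term toy SMQ
is bundled for tests.

The exposed margin of a drug group counts cases with at least one exposure
to at least one member whose reporter role passes the role filter.  The
default filter counts only *suspected* exposures; the cross-class
combination listing deliberately counts all roles, since a case "in
combination with" a class member need not have that member suspected.  A
case exposed to two members of a class contributes once to the class margin
— this is visible in the bundled reference counts, where the class-level
N₁₊ (1578) is smaller than the sum of member N₁₊ (1596) while the N₁₁
values happen to coincide (176).

Reporting rates are 100·N₁₁/N₁₊ rounded half-up to one decimal (decimal
arithmetic, not binary float rounding); the rate is undefined, not zero,
when N₁₊ = 0.

## The BCPNN information component

Scoring uses the standard BCPNN hyperparameters γ₁₁ = 1, α₁ = β₁ = 1,
α = β = 2, with the joint prior count γ coupled to the margins of each
table (γ = γ₁₁(N₊₊+α)(N₊₊+β)/((N₁₊+α₁)(N₊₁+β₁))) and therefore recomputed
per table, never cached.  The variance prefactor is (1/ln 2)², i.e. natural
logs internally with outputs in bits; this is the only reading that
reproduces published credible intervals from published counts.  The 95%
interval is E(IC) ± 2√V(IC) exactly (not ±1.96).  Signals require
IC₀₂₅ > 0 strictly; inverse signals IC₉₇₅ < 0 strictly.  No
multiple-testing adjustment is applied anywhere, matching standard practice
for hypothesis-generating screens.

Numerical notes: moments are evaluated in log space and are finite for
every table with N₊₊ ≥ 1, including N₁₁ = 0 (the priors bound every factor
away from zero).  Agreement with an independent 50-digit arbitrary-
precision transcription of the formulas is tested to 10⁻¹⁰ bits.  IC values
are displayed rounded to two decimals; full precision is kept internally
and in the tsv outputs.

The reporting odds ratio (N₁₁N₀₀)/(N₁₀N₀₁) with a Wald 95% CI is provided
as a comparator only.  Any zero cell leaves its CI undefined; a zero
denominator cell leaves the point estimate undefined (infinite when
N₁₁ > 0).

## Margin calibration

Published screens typically print N₁₁ and N₁₊ per drug and the grand total
N₊₊, but not the target event's total case count N₊₁.  `calibrate_margin`
recovers it by exhaustive integer grid search (default 1..50,000),
minimizing the sum of squared deviations of E(IC) from the published ICs
across all rows, ties broken toward the smaller margin, with a warning if
the optimum sits on a range boundary.  One margin is calibrated per
database and shared by all rows.  On the bundled reference counts (13 rows,
N₊₊ = 534,287) the search returns 10,802 with an RMS residual of 0.003
bits, and all published ICs and interval bounds then reproduce within
±0.02.  The calibrated value is a reconstruction, not an assertion about
the source database.

## Synthetic reporting databases

The generator emulates the structure, not the content, of a spontaneous
reporting system.  Per case: sex and decade age band are categorical draws;
each modeled drug is an independent Bernoulli exposure (optionally tilted
by pairwise co-prescription odds multipliers, each drug in at most one pair
so expectations stay in closed form); the target event occurs with
probability 1 − Π(1 − p₀λ_d) over the exposed drugs (independent-hazard
composition, capped at 0.99 with a warning count), or p₀ for cases exposed
to no modeled drug.  The baseline p₀ applying equally to unexposed cases is
what makes λ interpretable: a drug with λ = 1 reports the event at the
background rate and has asymptotic IC exactly 0, while a rare drug with
λ = 4 has asymptotic IC ≈ 2 bits.  Flagged cases receive one to three
preferred terms from a weighted narrow/broad pool (duplicates collapse,
exercising case-level deduplication); other cases receive a background
term, and cases without modeled drugs a filler exposure, so every report
lists a drug and an event.  Disjoint random subsets get subjective ages,
missing sex or missing age to exercise the exclusion stage.  Identical
config and seed give byte-identical output files.

`truth_table` returns exact expected margins and asymptotic ICs
(log₂ P(event|exposed)/P(event)): by enumeration over exposure patterns up
to 15 drugs (handling co-prescription tilting and mandatory-exposure
resampling exactly), by independence factorization beyond that.  Expected
counts refer to post-exclusion cases (corruption is independent of
everything else, so retention scales all margins equally).

What the generator does *not* emulate: reporting dynamics over calendar
time (Weber and notoriety effects), duplicate or follow-up reports,
correlated event coding, indication-driven channeling beyond the pairwise
co-prescription knob.  Passing recovery tests therefore show that the
pipeline measures what the generative model encodes — not that real
reporting data satisfy that model.

A bundled "paper-like" configuration mimics a published screen at 1/10
scale (53,429 cases, the 12 ACE inhibitors and 9 DPP-4 inhibitors, per-drug
exposure probabilities and reporting ratios derived from the published
margins with p₀ = 0.02, demographic mix similar to the published strata).

## Validation designs

Two simulation-based checks run the full pipeline (generate → flag → count
→ score):

- **Interval coverage.** 100 databases of 50,000 cases with a single drug
  (exposure 0.003, λ = 4, p₀ = 0.02): the 95% credible interval covers the
  asymptotic IC in at least 90% of runs.  The design puts roughly a dozen
  events in N₁₁, where shrinkage is material, so this is a deliberately
  hard test of interval calibration.
- **Null calibration.** 200 databases of 20,000 cases with five λ = 1 drugs
  (exposure 0.01): the fraction of drug–event pairs classified as signals
  stays at or below 7.5% (nominal one-sided 2.5% plus a conservatism margin
  from shrinkage; the observed rate is far lower).

Database sizes were chosen as the smallest at which the asymptotic truths
are meaningfully resolved by single-database intervals.

## Design choices on genuinely open points

- **Rendering of undefined rows.** Published tables are inconsistent about
  printing an IC for zero-count drugs versus a dash.  The statistic is
  always computed and stored; only the *rendered* view substitutes an
  em-dash, by default for groups with no exposed cases at all (N₁₊ = 0),
  configurable off.
- **Follow-up report versions.** Only term-level deduplication within a
  case is modeled; collapsing multiple versions of one report is out of
  scope, as no rule for it can be stated from the available material.
- **Half-up rounding** for reporting rates, documented rather than
  banker's; both reproduce the bundled reference rates, half-up matches
  what tabulation software usually prints.
- **Cross-class cases** (flagged cases exposed to members of both classes)
  contribute to both classes' tables; they are listed, not excluded.
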