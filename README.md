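# pvsignal

Case-based disproportionality analysis of spontaneous adverse-event reports
with the Bayesian Confidence Propagation Neural Network (BCPNN) information
component.

Pharmacovigilance databases such as JADER, FAERS and VigiBase collect
spontaneous reports of suspected adverse drug reactions.  Because they have
no denominator of exposed patients, drug safety signals are screened by
*disproportionality*: for each drug (or drug class) and adverse event, the
retained reports are cross-tabulated as

|              | target AE | other AEs |       |
|--------------|-----------|-----------|-------|
| target drug  | N₁₁       | N₁₀       | N₁₊   |
| other drugs  | N₀₁       | N₀₀       | N₀₊   |
|              | N₊₁       | N₊₀       | N₊₊   |

and scored with the BCPNN information component

```
E(IC) = log₂ [ (N₁₁+γ₁₁)(N₊₊+α)(N₊₊+β) / ((N₊₊+γ)(N₁₊+α₁)(N₊₁+β₁)) ],
γ     = γ₁₁ (N₊₊+α)(N₊₊+β) / ((N₁₊+α₁)(N₊₁+β₁)),
γ₁₁ = 1,  α₁ = β₁ = 1,  α = β = 2,
```

with a matching posterior variance V(IC) and the 95% credible interval
E(IC) ± 2√V(IC).  IC₀₂₅ > 0 flags a *signal*; IC₉₇₅ < 0 flags an *inverse
signal*.  The Bayesian shrinkage keeps the statistic finite and stable at
small counts — including N₁₁ = 0 — where the reporting odds ratio (also
provided, as a comparator) breaks down.

The package is aimed at pharmacoepidemiologists who want a reproducible,
testable pipeline from the raw four-table csv layout (DEMO / DRUG / REAC /
HIST) to scored signal tables:

- **report_model** — read/write the four-table layout, case-level
  deduplication, exclusion rules (subjective or missing age, missing sex);
- **meddra_smq** — Standardized MedDRA Query definitions (narrow/broad
  scope) and once-per-case event flagging;
- **contingency** — case-based 2×2 tables for drugs and drug classes,
  demographic strata, reporting rates, class-combination case listings;
- **bcpnn** — the IC, its credible interval, signal classification, the
  ROR comparator, and calibration of an unpublished event margin from
  published IC values;
- **synthetic_reports** — a simulator of reporting databases with
  closed-form ground truth, so estimates can be validated end to end;
- **pipeline / cli** — orchestration and a `pvsignal` command.

## Worked example

Scoring the angioedema table of a well-studied ACE inhibitor from a JADER
snapshot with 534,287 retained cases, 10,802 angioedema cases, and 771
reports for the drug of which 86 mention angioedema:

```
$ pvsignal ic --n11 86 --n1plus 771 --nplus1 10802 --nplusplus 534287
n11  n1plus  nplus1  nplusplus  e_ic   v_ic      ic025   ic975   classification
86   771     10802   534287     2.389  0.026801  2.0616  2.7164  signal
```

E(IC) = 2.39 bits means angioedema is reported about 2^2.39 ≈ 5 times more
often with this drug than expected under independence; because the lower
credible bound 2.06 exceeds 0, the pair is classified a signal.

Published screens often print every count except the event margin N₊₁.
Given a TSV of published `(n11, n1plus, ic)` rows, the margin is recovered
by integer least squares:

```
$ pvsignal calibrate --rows rows.tsv --nplusplus 534287
10802
```

Synthetic end-to-end run (database → exclusions → SMQ flags → 2×2 tables →
IC tables):

```
$ pvsignal simulate --config sim.yaml --seed 7 --out db/
$ pvsignal run --config run.yaml --out results/
```

`results/per_drug.tsv` then holds one row per drug with its margins, IC
moments, credible bounds and classification; `strata.tsv`,
`combinations.tsv` and `run_log.yaml` carry the demographic breakdown, the
cross-class combination cases, and the audit log (N₊₊, exclusion counts,
checksums).

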