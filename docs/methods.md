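# Methods

## Scope and model

`vigisig` implements case/non-case disproportionality screening for
spontaneous adverse-event reporting data. The unit of analysis is the
individual case safety report (ICSR): patient demographics, a list of drug
entries (each with a role of suspected, interacting, or concomitant), and a
list of coded reaction terms. For a drug D, an outcome group G and a
demographic stratum, eligible reports are cross-classified as

|              | event in G | no event in G |
|--------------|-----------|---------------|
| **with D**   | a         | b             |
| **without D**| c         | d             |

counting each *report* once, however many matching drug entries or terms it
lists. The comparator (c, d) is every other eligible report in the stratum —
the full database background, not a restriction to other panel drugs. All
drug roles count as exposure by default; a `roles` option restricts exposure
to, e.g., suspected drugs only.

Two screening statistics are computed per cell:

* **Reporting odds ratio.** ROR = (a·d)/(b·c), the conventional odds-ratio
  form (the proportion-ratio form [a/(a+b)]/[c/(c+d)] is retained behind
  `form="printed"` for comparison). The 95% CI is the Woolf log-normal
  interval exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); significance comes
  from a two-sided Fisher exact test using the probability-mass convention
  (sum of hypergeometric probabilities ≤ that of the observed table, with a
  1 + 1e-7 relative tie guard so floating-point ties behave like exact
  ties). When b·c = 0 the point estimate is reported as undefined rather
  than silently corrected; a Haldane–Anscombe +0.5 option exists but is off
  by default. No multiple-testing correction is applied — the heatmap
  semantics are defined on raw P — but a Bonferroni column is available for
  sensitivity analysis.
* **Information component.** IC = log2((a + 0.5)/(E + 0.5)) with
  E = (a+b)(a+c)/N, the shrinkage-regularized observed-to-expected ratio
  used by the UMC tradition. IC025, the lower 95% credibility bound, uses
  the closed-form approximation IC − 3.3·(a+0.5)^−1/2 − 2·(a+0.5)^−3/2 by
  default; `method="gamma"` computes the exact 2.5% quantile of the
  Gamma(a+0.5, rate E+0.5) posterior instead. IC025 > 0 is the conventional
  signal threshold. IC is reported alongside the ROR as a confirmatory
  second channel; it never gates the heatmap category.

The Fisher P is computed in-package on a log-space ratio recurrence for the
hypergeometric pmf (stable to a few ulp per term and fast at large
margins); its correctness is asserted against an exact-integer enumeration
oracle, exhaustively for all tables with N ≤ 50 plus randomized tables up
to N = 200, at 1e-12 relative error.

## Eligibility and cohort flow

Reports pass through three accounted stages: read → deduplicate →
eligibility (drop reports missing age or sex). Provenance counters always
reconcile: total = duplicates + excluded + eligible. Deduplication runs
*before* the missing-data exclusion (the source flow does not state an
order; this one is fixed and documented). Real pharmacovigilance databases
deduplicate with probabilistic record linkage whose algorithm is not
publicly specified; this package substitutes deterministic exact-profile
matching on (age, sex, sorted drug names, sorted event terms), which is
auditable and satisfies the pipeline contract (duplicates removed before
counting). "Older" means age ≥ 65; age exactly 65 is older. Conflicting
demographics within one report id keep the first value, logged.

## Strata and signal classification

Five strata are shipped: all, female, male, younger (<65), older (≥65).
The sex pair and age pair each partition the cohort, so their cells sum
exactly to the all-stratum cells — asserted as an invariant on every
dataset.

Heatmap categories follow the published legend semantics, in rule order:
no reports of the drug in the stratum (dash) → fewer than `n_min` observed
co-reports (white; default n_min = 3, the common screening minimum — the
source never quantifies "relatively few") → ROR > 1 side split by P
(< 0.001 darkest red, < 0.01 dark red, otherwise light red) → ROR ≤ 1 side
(dark green when P < 0.01, light green otherwise). Only the two dark reds
are *significant signals*; the 0.001 sub-boundary is cosmetic and
configurable. A drug's overall significance uses a separate aggregate
"Cardiotoxicity" 2×2 whose event is membership in *any* outcome group (an
any-group alternative is available). An undefined ROR with enough cases is
classified by P alone on the elevated side, with a logged caveat.

Stratum comparison emits a discordance whenever exactly one of a stratum
pair is significant for a (drug, group), with the special kind
"no reports in comparator" when the other stratum has no reports at all.

## Vocabularies

The drug panel ships 35 tyrosine-kinase inhibitors in eight target classes
(EGFR, HER2, VEGFR, FGFR, BCR-ABL, ALK, JAK, BTK) with per-drug reference
report counts and an explicit synonym table (including the spelling
variants "cediratinib", "lolatinib", "ascriminib" seen in the source
tables). Matching is case-insensitive exact plus synonyms — no fuzzy
matching, so every mapping is deterministic and auditable.

MedDRA is licensed and cannot be redistributed. The outcome dictionary
therefore preserves the 21-group structure (group names and query-level
source labels) but fills each group with synthetic lowercase stand-in
terms. A term may belong to several groups (intracranial bleeding sits in
both hemorrhage groups) and mapping returns every match. Unknown terms map
to no group and are tallied at debug level. Real SMQ/HLT/HLGT hierarchy
resolution, ATC coding and WHODrug are out of scope.

## Synthetic data generator

Because the real database is fee-gated, the pipeline is validated on
simulated ICSRs with known ground truth. Per report: sex ~ Bernoulli
(female probability 0.608 by default), age from a mixture of uniform
integer blocks (72.5% in 18–64, 27.5% in 65–95 by default — an adult
treated-population choice), independent Bernoulli exposure per panel drug,
events per outcome group, then missingness masks and appended exact
duplicates. Exposure marginals default to the published per-drug report
counts divided by the eligible cohort size (23,181,539), i.e. real
screening-scale rarity (about 2e-5 to 1.7e-3 per drug). Group baselines
are fixed plausible screening-scale rates (0.1%–4% per group, file
`synthetic.PAPER_LIKE_GROUP_RATES`).

A planted signal (drug, group, θ) changes the event probability of exposed
reports to p1 = θ'·odds0/(1 + θ'·odds0), odds0 = p0/(1−p0), where θ' is θ
times optional sex/age modifiers. Because the comparator is all other
reports and exposures are rare, θ is (to negligible contamination) exactly
the estimand of the pipeline ROR, making parameter recovery a sharp test.
Ground truth includes closed-form expected a/b/c/d per stratum, computed by
enumerating the demographic cells and the exposure patterns of co-planted
drugs.

Every report also receives 1–3 background concomitant medications from a
200,000-name pool and Poisson(0.4) unmapped reaction terms from a
2,000-term pool. This mimics the high-cardinality fields of real reports,
keeps profiles near-unique so exact-profile deduplication removes only
true copies, and exercises unknown-drug/unknown-term handling. What the
generator does **not** model: polypharmacy correlation between panel
drugs, reporting dynamics over time, notoriety and stimulated-reporting
biases, country effects, indication channeling. Passing tests therefore
validate the *statistical machinery*, not robustness to those real-world
biases.

Profiles: `paper-like` (full panel, published demographic marginals,
missing-age 20% and missing-sex 10% independently — matching the published
28.7% overall exclusion — 2% duplicates, and a planted set spanning
θ ∈ {1, 2, 3, 5} plus a male-only and a younger-only stratum effect),
`null` (nothing planted), `stress` (an unexposed drug guaranteeing
no-report strata, near-zero group rates, heavy missingness and
duplication).

## Validation design and problem sizes

* Fisher: exhaustive oracle sweep of all 2×2 tables with N ≤ 50 (316,251
  tables) plus 2,000 seeded random tables with N ≤ 200, tolerance 1e-12
  relative — sizes chosen to keep the sweep around half a minute.
* CI calibration: 2,000 hypergeometric tables at margins N = 20,000,
  both margins 1,000 (E[a] = 50); Woolf coverage required in 95 ± 2%.
* Parameter recovery: the planted pairs without stratum modifiers are the
  registered estimands. A single n = 500,000 benchmark cannot pin a 5%
  bound per θ (per-cell log-SE ≈ 0.12–0.3 at realistic exposure), so
  recovery pools the recovery pairs of 30 independent replicates per θ
  with the Mantel–Haenszel estimator (pooled SE ≈ 0.015–0.025 per θ by
  design budget). Detection (every planted θ ≥ 3 cell with expected
  a ≥ 30 must classify dark-red), the false-signal count on unplanted
  drugs (nominal P < 0.01 family expectation), and ROR/IC concordance run
  on one full benchmark replicate.
* Determinism: identical config + seed yields byte-identical serialized
  output; the pipeline re-run check compares statistics files bytewise.

## Known limitations

* Exact-profile deduplication under-detects true duplicates that differ in
  any field and would over-collapse pathological datasets with no
  high-cardinality fields.
* The aggregate-vs-any-group choice for a drug's overall significance
  changes the significant list at the margin; both are implemented, the
  aggregate row is the default.
* The expected-cell ground truth ignores the few chance profile collisions
  removed by deduplication (order 1e-4 of reports at benchmark scale).
* Woolf intervals and the closed-form IC025 are asymptotic; at very small
  a they are screening heuristics, which is why cells with a < n_min are
  never classified beyond "few cases".
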