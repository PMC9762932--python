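# Methods

This note records the models, parameter choices and numerical conventions
behind `alsact`, and what the synthetic validation does and does not show.

## Variant and sample QC

Boundary semantics are strict removal conditions: a call is removed when
genotype quality < 10, variant quality < 20 (SNV) or < 30 (indel), or
missingness > 2%; values exactly at a boundary survive. Rarity requires
allele frequency strictly below 0.001 in both reference sets. Missingness
is a per-variant input field; no genotype-level recomputation is done.

Sample QC computes mean and SD of Ti/Tv, SNV, indel and singleton counts
once over the full input distribution (single pass, not iterative) and
removes samples outside mean ± 6 SD on any metric; note that in small
cohorts a gross outlier inflates the SD enough to shield itself, which is
an inherent property of the single-pass rule, not a bug. A sex mismatch
means both inferred and reported sex are known and differ; an unknown on
either side is not a contradiction. Samples without age of onset are
removed (ages are needed for the stratified yield).

When a variant carries several consequence terms, its impact class is the
most severe term's class. Each removed variant is attributed to the first
failing rule in the fixed order QC → frequency → impact, so audit counts
always sum to the input count.

## ACMG engine

Seven criteria are evaluated automatically from annotations alone:

| criterion | rule | default |
|---|---|---|
| PVS1 | high impact and gene in the loss-of-function-mechanism list | LoF list defaults to the union of analysed panel genes |
| PM2  | AF zero or < `pm2_max_af` in both reference sets | 1e-4 |
| PM4  | in-frame insertion/deletion or stop_lost term | — |
| BA1  | reference AF > `ba1_min_af` | 0.05 |
| BS1  | reference AF > `bs1_min_af` | 0.001 |
| PP3  | in-silico damage score ≥ `pp3_min_score` | 0.70 |
| BP4  | in-silico damage score ≤ `bp4_max_score` | 0.30 |

The in-silico score is an optional 0–1 damage probability (REVEL-like);
missing scores leave PP3/BP4 false. All thresholds are configuration, not
literature constants, and BS1 can never fire on a variant that already
passed the 0.001 rarity filter — it exists for classification of tables
that skip prioritisation.

Criteria without an automatic evaluator take values from a
`FixedCriteriaProfile`, keyed by impact class (high / moderate). Two
profiles ship: *conservative* (all manual criteria false) and *permissive*
(PP5 presumed true for high-impact variants, which upgrades a PVS1+PM2
call from likely pathogenic to pathogenic). The choice is a sensitivity
parameter; the conservative profile is the default everywhere.

The combining table is implemented with ≥-count predicates; these give the
same classes as the published exact count brackets because every superset
of a bracket is covered by an at-least-as-strong rule, and ≥ keeps the
classifier monotone in evidence. Contradiction is resolved as: any active
pathogenicity criterion while a benign-side combining rule is met yields
VUS. VUS are sub-stratified as *high probability of pathogenicity* when at
least one pathogenicity criterion is active and no benignity criterion is,
*low/medium* otherwise.

The engine is verified against an independently hand-coded brute-force
oracle by exhaustive enumeration of all profiles with ≤ 4 active criteria
(~24 000 profiles) plus 10⁵ random profiles, and by a monotonicity
property (adding pathogenic evidence never moves the class toward benign)
on 10⁴ random pairs.

## Repeats, panels, actionability

*C9orf72* counts strictly above 30 are pathogenic; *ATXN2* counts in
[29, 33] are pathogenic for reporting (an ALS risk factor); ATXN2 counts
above 33 (SCA2 range) are flagged but not counted as ALS-actionable. The
larger allele's count is interpreted, as the expansions act dominantly.

A result is actionable when it reports a moderate/high-impact variant
classified pathogenic, likely pathogenic or high-probability VUS in a
panel gene (satisfying the gene's reporting mode), or a pathogenic repeat
at a locus in the panel. The strict reading — low/medium VUS are *not*
reportable — is the default; `strict_vus=False` switches to the lenient
reading (everything not benign/likely benign), retained because the two
readings are both defensible. *ALS2* requires homozygosity; two
heterozygous variants in one gene are never combined (phase unknown).
Persons with missing data for a panel gene stay in the denominator.

The corroboration rule (four-gene sanity check, no ACMG input): any
C9orf72 expansion > 30; every retained rare SOD1 variant; TARDBP/FUS
variants with ClinVar P/LP status or an ALSoD record with ≥ 1 publication
and ≥ 2 patients; missing database flags fail closed with a warning.

## Yield statistics

Ages bin into <40, 40–49, 50–59, 60–69, ≥70 (left-closed, so onset at
exactly 40 falls in 40–49). Proportions get Wald intervals
p ± z·√(p(1−p)/n), not clipped to [0, 1]: this is the method that exactly
reproduces printed intervals such as 0.96–1.01 for 115/117 and 0.92–1.01
for 56/58, including upper bounds above 1. An exact Clopper–Pearson
alternative is available behind `method="clopper-pearson"`. Rounding is
half-up and presentation-only (2 dp for proportions, whole percent for
percentages); stored values are full precision.

## Incidence and the policy model

Crude rates are cases per person-years × 100 000. Direct standardization
weights stratum rates by a standard (census) population. CIs for weighted
Poisson sums use the exact gamma method with per-case weights `w_i`:
`X = Σ w_i d_i`, `V = Σ w_i² d_i`, `w_M = max w_i`; lower bound
`Gamma(α/2; X²/V, V/X)` (0 when X = 0), upper bound
`Gamma(1−α/2; (X+w_M)²/(V+w_M²), (V+w_M²)/(X+w_M))`. With a single unit
weight this is exactly the Garwood Poisson interval; Monte-Carlo coverage
at register-like counts is ~95%.

Expected counts are multiplied by the sporadic factor 0.875 (midpoint of
the 80–95% sporadic share) after standardization; the order commutes since
both operations are multiplicative, and it is fixed for reproducibility.

The missed-case estimator sums `E_(g,s) · p_g` over strata at or above the
age cutoff (default 40 years, which must sit on a group boundary);
probabilities may be age-only or age-by-sex (age-only is the default —
sex-specific yield estimates halve the already-small group sizes). The CI
on the missed proportion is the Wald interval on the half-up-rounded
counts — again the convention that reproduces the printed intervals
(96%–101% and 0.92–1.01) from the printed count pairs.

The shipped UK table (`alsact/data/uk_incidence_2018_2019.tsv`) carries
the published 2018–2019 age-by-sex crude rates and sporadic-adjusted
expected counts verbatim; the standard population column is back-derived
as `expected × 10⁵ / (rate × 0.875)`. One printed oddity is preserved
as-is: the female <40 rate's CI upper bound (0.011) sits below its point
estimate (0.020), apparently a typo in the source table; only point
estimates enter any computation. Only the youngest (0.23) and oldest
(0.17) broad-panel probabilities are published; the mid-range value used
as the default for the middle three groups (≈0.222) is the unique value
consistent with the published total of 115 missed cases given those
endpoints — a calibration to printed totals, not an independent
measurement, and sensitivity to it is linear and easy to explore by
passing a different probability mapping.

## Synthetic cohorts

Ages are truncated normal (mean 65, SD 12, truncated to 18–95), matching
the population mean onset age; sex is Bernoulli with male fraction 0.6.
Each person is actionable with the age-group probability from the config
(UK-like defaults above). An actionable finding is realised as a C9orf72
expansion (35–79 units) with probability 0.35, an ATXN2 intermediate
expansion with probability 0.03, or otherwise as a rare variant in a
weighted panel gene. Gene weights favour SOD1 (0.12), TARDBP (0.09) and
FUS (0.08) with the remainder spread evenly; together with the repeat
shares this makes the four-gene panel capture ≈53% of broad-panel
actionable results, matching the published overall yields (11% vs 21% in
the UK cohort). The per-gene split beyond that is arbitrary — no per-gene
breakdown is public.

Planted variants use fixed annotation recipes whose classification is
analytically known (weights 0.3/0.4/0.3):

* stop_lost, AF 0 → PVS1+PM2+PM4 → pathogenic;
* frameshift, AF 0 → PVS1+PM2 → likely pathogenic;
* missense, AF 0, score 0.9 → PM2+PP3 → VUS, high probability.

Variants planted in a biallelic-only gene are homozygous so reporting-mode
logic cannot silently drop them. Planted variants carry consistent
database flags (ClinVar P/LP), making the ACMG and corroboration routes
agree at noise 0. Background noise adds ~2 variants/person: common
missense (caught by rarity), rare synonymous (caught by impact),
low-quality calls (caught by site QC), and rare missense that survives to
classification but lands in low/medium VUS — plus 1% sex-mismatched and 1%
ageless samples for the sample filter. Registers draw Poisson case counts
with mean rate × person-years / 10⁵ per stratum.

What passing tests show: the decision chain, the interval methods and the
estimator arithmetic are correct on data with exactly the assumed
structure. What they do not show: performance on real sequencing data —
the generator plants no realistic genome positions, linkage, haplotypes,
multi-allelic sites, annotation noise, or borderline evidence profiles,
and real per-gene and per-age effects need not follow the planted model.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through numpy
Generators; equal config and seed give byte-identical outputs, and the
file pipeline stamps every output with the seed and a config hash. The
validation suite uses cohorts of 400–1551 persons, 500 seeds for Wald
coverage, 2000 replicates for gamma-CI coverage, and 20 pooled cohorts of
1551 in the acceptance script — sizes chosen so Monte-Carlo error is well
inside the tolerance being checked while the whole suite stays quick on a
single CPU.
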