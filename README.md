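# alsact

Actionability of genetic testing in amyotrophic lateral sclerosis (ALS).

In up to 20% of people with ALS a family history is reported, but Mendelian
gene variants are also found in apparently sporadic disease. With
gene-targeted therapies in trials, it matters whether testing policies that
gate on age of onset (for instance, testing sporadic patients only when
onset is below 40 years) leave treatable patients undetected. `alsact`
implements, as a tested reusable library, the full decision chain for that
question:

1. **Variant QC and prioritisation** — site QC (genotype quality ≥ 10,
   variant quality ≥ 20 for SNVs / ≥ 30 for indels, missingness ≤ 2%),
   sample QC (Ti/Tv, SNV/indel/singleton counts within mean ± 6 SD; sex
   concordance; known age of onset), and retention of rare variants
   (MAF < 0.001 in *both* an external gnomAD-NFE-style reference and an
   internal control set) of moderate or high predicted impact.
2. **ACMG/AMP classification** — a rules engine over the 28 evidence
   criteria (16 pathogenic: PVS1, PS1–4, PM1–6, PP1–5; 12 benign: BA1,
   BS1–4, BP1–7), with annotation-driven automatic evaluators, fixed-value
   profiles for criteria that would need manual review, the published
   combining table, and sub-stratification of VUS into high versus
   low/medium probability of pathogenicity.
3. **Repeat-expansion interpretation** — *C9orf72* GGGGCC > 30 repeats and
   *ATXN2* CAG 29–33 repeats (inclusive) are pathogenic for reporting.
4. **Panel and inheritance logic** — per-person actionability against the
   four-gene, broad research, and Genomics England ALS panels, with
   *ALS2* reportable only when homozygous, plus an independent
   ClinVar/ALSoD corroboration rule for the four commonest genes.
5. **Yield and policy statistics** — age-group proportions with Wald 95%
   intervals (deliberately unclipped, so near-certain proportions print
   upper bounds such as 1.01); crude and directly standardized incidence
   with exact gamma (Fay–Feuer) intervals; a 0.875 sporadic-fraction
   adjustment; and the missed-case estimator
   `missed = Σ_{strata ≥ cutoff} E_(g,s) · p_g`, where `E_(g,s)` is the
   expected number of sporadic diagnoses per year in age-sex stratum
   `(g,s)` and `p_g` the age-group probability of an actionable result.

Because the source cohort data are access-controlled, a first-class
synthetic-cohort module (`alsact.simulate`) plants actionable findings
with known per-age-group probabilities, realistic backgrounds and QC
failure modes, and emits ground truth in a sidecar the pipeline never
reads — every stage is validated against it.

## Worked example

```python
import alsact as A

uk = A.load_uk_incidence()                      # shipped UK register table
expected = uk[["age_group", "sex", "expected_sporadic_per_year"]]
by = expected.groupby("age_group")["expected_sporadic_per_year"].sum()
p_mid = (115.0 - by[">=70"] * 0.17) / by[["40-49", "50-59", "60-69"]].sum()
probs = {"<40": 0.23, "40-49": p_mid, "50-59": p_mid, "60-69": p_mid, ">=70": 0.17}

result = A.missed_estimate(expected, probs, A.PolicyConfig(age_cutoff=40.0))
print(result.missed_rounded, "of", result.total_rounded)
print(f"{result.proportion:0.2f} (95% CI {result.ci[0]:0.2f}-{result.ci[1]:0.2f})")
```

prints

```
115 of 117
0.98 (95% CI 0.96-1.01)
```

i.e. with testing restricted to onset below 40 years, about 115 of the 117
people per year in the UK expected to carry a clinically actionable result
on the broad panel would never be offered the test — 98% of them, with a
Wald interval whose upper bound exceeds 1 because the proportion is nearly
certain. The `examples/` directory has one short script per capability
(cohort simulation, classification, yield by age, policy modelling), each
printing the numbers it computes and what they mean; `alsact --help`
exposes the same stages as a thin CLI.

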