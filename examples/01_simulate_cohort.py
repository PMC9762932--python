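"""Generate a synthetic ALS cohort with planted actionable findings.

The generator emits the four tables the pipeline consumes (variants,
sample metrics, repeat calls) plus a ground-truth sidecar that the
pipeline never sees.  Everything is deterministic given the seed.
"""

import alsact as A

config = A.CohortConfig(n_persons=500, seed=42)
cohort = A.generate_cohort(config)

print(f"persons:        {len(cohort.persons)}")
print(f"variant calls:  {len(cohort.variants)}")
print(f"repeat calls:   {len(cohort.repeats)}  (C9orf72 + ATXN2 per person)")
print(f"planted actionable persons: {cohort.truth['actionable'].sum()}")
print("\nmechanisms of the planted findings:")
print(cohort.truth.loc[cohort.truth["actionable"], "mechanism"].value_counts())
print("\nfirst variant calls:")
print(cohort.variants[["person_id", "gene", "consequence_terms",
                       "af_reference", "zygosity"]].head())

# The counts above: ~20% of persons carry a planted finding (the UK-like
# age-profile default), realised as a C9orf72/ATXN2 expansion or a rare
# coding variant; the rest of the variant table is background the pipeline
# must filter out or classify as non-reportable.
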