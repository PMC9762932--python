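"""Classify variants with the ACMG rules engine.

Shows both the scalar API on a single variant and the cohort-scale
pipeline (QC -> prioritisation -> automatic evidence + fixed-value
overlay -> combining table -> VUS sub-stratification).
"""

import alsact as A
from alsact.acmg import AcmgConfig, FixedCriteriaProfile, auto_evidence, classify, merge_fixed

# --- one variant, step by step -------------------------------------------
variant = dict(
    gene="TBK1", impact="high", consequence_terms="frameshift_variant",
    af_reference=0.0, af_internal=0.0, insilico_score=float("nan"),
)
cfg = AcmgConfig(lof_genes=frozenset({"TBK1"}))
evidence = auto_evidence(variant, cfg)
evidence = merge_fixed(evidence, FixedCriteriaProfile.conservative(), "high")
result = classify(evidence)
print(f"single variant: active criteria {evidence.active()}"
      f" -> {result.acmg_class}")
# PVS1 (loss of function in an LoF-mechanism gene) + PM2 (absent from both
# reference sets) meet the likely-pathogenic combination.

# --- a whole cohort -------------------------------------------------------
cohort = A.generate_cohort(A.CohortConfig(n_persons=500, seed=42))
res = A.classify_cohort(
    cohort.variants, cohort.metrics, cohort.repeats,
    [A.load_panel("genomics_england")],
)
print("\nstage counts:", dict(res.counts))
print("\nACMG class distribution of retained variants:")
print(res.classified["acmg_class"].value_counts())
print("\nVUS sub-stratification:")
print(res.classified.loc[res.classified["acmg_class"] == "vus",
                         "vus_subclass"].value_counts())
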