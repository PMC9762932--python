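"""Site- and sample-level QC and rare-variant prioritisation.

A variant enters downstream classification only if it survives, in order:

1. site QC — genotype quality >= 10, variant quality >= 20 (SNV) / 30
   (indel), missingness <= 2%;
2. rarity — minor allele frequency strictly below 0.001 in *both* the
   external (gnomAD-NFE-style) and the internal control reference sets;
3. predicted impact — the most severe sequence-ontology consequence term
   must be of high or moderate impact.

Sample-level QC removes whole genomes whose summary metrics (Ti/Tv ratio,
SNV, indel and singleton counts) fall outside mean ± 6 SD of the cohort
distribution (computed once, not iteratively), whose genetically inferred
sex contradicts the reported sex, or whose age of onset is missing.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Sequence-ontology consequence terms counted as high impact.
HIGH_IMPACT_TERMS = frozenset({
    "stop_gained", "stop_lost", "start_lost",
    "transcript_amplification", "transcript_ablation",
    "frameshift_variant", "splice_acceptor_variant", "splice_donor_variant",
})

#: Terms counted as moderate impact.
MODERATE_IMPACT_TERMS = frozenset({
    "missense_variant", "inframe_insertion", "inframe_deletion",
    "protein_altering_variant",
})

#: Fixed attribution order for the removal audit.
REMOVAL_REASONS = ("qc", "frequency", "impact")


@dataclass(frozen=True)
class FilterThresholds:
    """QC and rarity thresholds; defaults follow strict verbatim inequalities
    (removal when GQ < 10, qual < 20/30, missingness > 2%; retention requires
    AF < 0.001 in both reference sets)."""

    min_genotype_quality: float = 10.0
    min_snv_quality: float = 20.0
    min_indel_quality: float = 30.0
    max_missingness: float = 0.02
    max_af: float = 0.001
    sd_multiplier: float = 6.0

    def __post_init__(self) -> None:
        for name in (
            "min_genotype_quality", "min_snv_quality", "min_indel_quality",
            "max_missingness", "max_af", "sd_multiplier",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _terms(terms) -> set[str]:
    if isinstance(terms, str):
        return {t for t in terms.replace(",", "&").split("&") if t}
    return set(terms)


def impact_class(consequence_terms: Sequence[str] | str) -> str:
    """Most severe impact class among a variant's consequence terms."""
    terms = _terms(consequence_terms)
    if not terms:
        raise ValueError("consequence term list must be non-empty")
    if terms & HIGH_IMPACT_TERMS:
        return "high"
    if terms & MODERATE_IMPACT_TERMS:
        return "moderate"
    return "low_or_other"


def impact_series(consequence_terms: pd.Series) -> pd.Series:
    return pd.Series(
        [impact_class(t) for t in consequence_terms],
        index=consequence_terms.index,
        name="impact",
    )


def site_filter(variant: Mapping, thresholds: FilterThresholds | None = None) -> bool:
    """True when a variant call passes site-level QC."""
    t = thresholds or FilterThresholds()
    min_qual = (
        t.min_snv_quality if variant["variant_class"] == "SNV" else t.min_indel_quality
    )
    return bool(
        variant["genotype_quality"] >= t.min_genotype_quality
        and variant["site_quality"] >= min_qual
        and variant["missingness"] <= t.max_missingness
    )


def site_filter_frame(
    variants: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> pd.Series:
    t = thresholds or FilterThresholds()
    min_qual = np.where(
        variants["variant_class"].to_numpy() == "SNV",
        t.min_snv_quality,
        t.min_indel_quality,
    )
    ok = (
        (variants["genotype_quality"].to_numpy(float) >= t.min_genotype_quality)
        & (variants["site_quality"].to_numpy(float) >= min_qual)
        & (variants["missingness"].to_numpy(float) <= t.max_missingness)
    )
    return pd.Series(ok, index=variants.index, name="pass_site_qc")


def rarity_filter(af_reference, af_internal, thresholds: FilterThresholds | None = None):
    """True when the variant is rare (AF < threshold) in both reference sets.

    Works on scalars or numpy arrays.
    """
    t = thresholds or FilterThresholds()
    return (np.asarray(af_reference) < t.max_af) & (np.asarray(af_internal) < t.max_af)


def sample_filter(
    metrics: pd.DataFrame, sd_multiplier: float = 6.0
) -> tuple[pd.Index, pd.DataFrame]:
    """Cohort-level sample QC.

    Removes samples with any of ``titv``, ``n_snv``, ``n_indel``,
    ``n_singleton`` outside mean ± ``sd_multiplier``·SD of the full input
    distribution (single pass), with contradictory inferred vs reported sex
    (an unknown on either side is not a contradiction), or with missing age
    of onset.

    Returns the retained ``person_id`` index and a per-sample audit frame
    with boolean removal reasons.
    """
    if len(metrics) < 2:
        raise ValueError("sample_filter needs at least 2 samples to define an SD")

    audit = pd.DataFrame(index=metrics.index)
    outlier = np.zeros(len(metrics), dtype=bool)
    for col in ("titv", "n_snv", "n_indel", "n_singleton"):
        x = metrics[col].to_numpy(float)
        mean, sd = x.mean(), x.std(ddof=1)
        outlier |= np.abs(x - mean) > sd_multiplier * sd
    audit["metric_outlier"] = outlier

    inferred = metrics["inferred_sex"].astype(str)
    reported = metrics["reported_sex"].astype(str)
    known = inferred.isin(["male", "female"]) & reported.isin(["male", "female"])
    audit["sex_mismatch"] = (known & (inferred != reported)).to_numpy()

    audit["missing_age"] = metrics["age_onset"].isna().to_numpy()
    audit["retained"] = ~(
        audit["metric_outlier"] | audit["sex_mismatch"] | audit["missing_age"]
    )
    audit.insert(0, "person_id", metrics["person_id"].to_numpy())
    retained = pd.Index(
        metrics.loc[audit["retained"].to_numpy(), "person_id"], name="person_id"
    )
    return retained, audit


def prioritise(
    variants: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply site QC, rarity and impact prioritisation to a variant frame.

    Returns ``(retained, audit)``.  ``retained`` is the subset of rows that
    pass all three rules, with an appended ``impact`` column; no other field
    is modified.  ``audit`` holds one row per input variant with the first
    failing rule ("qc" -> "frequency" -> "impact") or "retained", so that
    per-reason counts always sum to the input size.
    """
    t = thresholds or FilterThresholds()
    if len(variants) == 0:
        retained = variants.copy()
        retained["impact"] = pd.Series(dtype=object)
        return retained, pd.DataFrame({"reason": pd.Series(dtype=object)})

    pass_qc = site_filter_frame(variants, t).to_numpy()
    pass_rare = rarity_filter(
        variants["af_reference"].to_numpy(float),
        variants["af_internal"].to_numpy(float),
        t,
    )
    impact = impact_series(variants["consequence_terms"])
    pass_impact = impact.isin(["high", "moderate"]).to_numpy()

    reason = np.select(
        [~pass_qc, ~pass_rare, ~pass_impact],
        ["qc", "frequency", "impact"],
        default="retained",
    )
    audit = pd.DataFrame({"reason": reason}, index=variants.index)
    keep = reason == "retained"
    retained = variants.loc[keep].copy()
    retained["impact"] = impact.loc[keep]
    return retained, audit
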