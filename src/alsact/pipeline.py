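"""End-to-end orchestration: QC -> classification -> actionability -> yield
-> policy.

:func:`classify_cohort` is the in-memory core used by tests and simulation
studies; :func:`run_pipeline` wraps it with file I/O, per-stage count
logging and a JSON report whose header records the seed and a hash of the
run configuration, so a re-run can verify it saw the same inputs.
"""

from __future__ import annotations

import hashlib
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as aio
from .acmg import (
    AcmgConfig,
    FixedCriteriaProfile,
    auto_evidence_frame,
    classify_frame,
    merge_fixed_frame,
)
from .incidence import PolicyConfig, missed_estimate, stratum_expected
from .panels import PanelDefinition, actionability_frame, load_panel
from .qc import FilterThresholds, prioritise, sample_filter
from .repeats import interpret_frame
from .stats import AGE_GROUPS, yield_table


@dataclass(frozen=True)
class PipelineSettings:
    """Analysis settings shared by the in-memory and file pipelines."""

    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    fixed_profile: FixedCriteriaProfile = field(
        default_factory=FixedCriteriaProfile.conservative
    )
    acmg: Optional[AcmgConfig] = None
    strict_vus: bool = True

    def acmg_config(self, panels: Sequence[PanelDefinition]) -> AcmgConfig:
        """Default the loss-of-function gene list to the union of panel genes."""
        if self.acmg is not None:
            return self.acmg
        lof = frozenset().union(*(p.genes for p in panels)) if panels else frozenset()
        return AcmgConfig(lof_genes=lof)


@dataclass(frozen=True)
class CohortResult:
    """Everything the pipeline derives from one cohort."""

    persons: pd.DataFrame
    classified: pd.DataFrame
    evidence: pd.DataFrame
    repeats: pd.DataFrame
    actionability: Mapping[str, pd.DataFrame]
    sample_audit: pd.DataFrame
    variant_audit: pd.DataFrame
    counts: Mapping[str, int]


def classify_cohort(
    variants: pd.DataFrame,
    metrics: pd.DataFrame,
    repeats: pd.DataFrame,
    panels: Sequence[PanelDefinition],
    settings: PipelineSettings | None = None,
) -> CohortResult:
    """Run sample QC, variant prioritisation, ACMG classification, repeat
    interpretation and per-panel actionability on in-memory tables."""
    settings = settings or PipelineSettings()

    if len(metrics) >= 2:
        retained_ids, sample_audit = sample_filter(
            metrics, sd_multiplier=settings.thresholds.sd_multiplier
        )
    else:
        retained_ids = pd.Index(metrics.get("person_id", pd.Series(dtype=object)),
                                name="person_id")
        sample_audit = pd.DataFrame(
            {"person_id": retained_ids, "retained": True}
        )
    persons = (
        metrics.loc[metrics["person_id"].isin(retained_ids),
                    ["person_id", "reported_sex", "age_onset"]]
        .rename(columns={"reported_sex": "sex"})
        .reset_index(drop=True)
        if len(metrics)
        else pd.DataFrame(columns=["person_id", "sex", "age_onset"])
    )

    kept_variants = (
        variants[variants["person_id"].isin(retained_ids)].reset_index(drop=True)
        if len(variants)
        else variants
    )
    retained, variant_audit = prioritise(kept_variants, settings.thresholds)

    acmg_cfg = settings.acmg_config(list(panels))
    evidence = auto_evidence_frame(retained, acmg_cfg)
    evidence = merge_fixed_frame(evidence, settings.fixed_profile, retained.get(
        "impact", pd.Series(dtype=object)))
    classes = classify_frame(evidence)
    classified = pd.concat([retained, classes], axis=1)

    kept_repeats = (
        repeats[repeats["person_id"].isin(retained_ids)].reset_index(drop=True)
        if len(repeats)
        else repeats
    )
    interpreted = interpret_frame(kept_repeats) if len(kept_repeats) else kept_repeats

    actionability = {
        panel.name: actionability_frame(
            persons["person_id"], classified, interpreted, panel,
            strict_vus=settings.strict_vus,
        )
        for panel in panels
    }

    reason_counts = (
        variant_audit["reason"].value_counts().to_dict() if len(variant_audit) else {}
    )
    counts = {
        "n_samples_in": int(len(metrics)),
        "n_samples_retained": int(len(persons)),
        "n_variants_in": int(len(kept_variants)),
        "n_variants_retained": int(len(retained)),
        "n_removed_qc": int(reason_counts.get("qc", 0)),
        "n_removed_frequency": int(reason_counts.get("frequency", 0)),
        "n_removed_impact": int(reason_counts.get("impact", 0)),
    }
    return CohortResult(
        persons=persons,
        classified=classified,
        evidence=evidence,
        repeats=interpreted,
        actionability=actionability,
        sample_audit=sample_audit,
        variant_audit=variant_audit,
        counts=counts,
    )


def estimated_probabilities(yields: pd.DataFrame) -> dict[str, float]:
    """Age-group actionable probabilities from a yield table (age-only)."""
    return {row["age_group"]: float(row["p"]) for _, row in yields.iterrows()}


@dataclass(frozen=True)
class RunConfig:
    """File-based run configuration.

    Paths reference the variant table (.tsv or .vcf), sample metrics,
    repeat calls, and optionally a register (for the policy stage) and a
    probability table (otherwise probabilities are estimated from the
    cohort itself).  ``panels`` may be shipped panel names or JSON paths.
    """

    variants: str
    metrics: str
    repeats: str
    out_dir: str
    panels: tuple[str, ...] = ("four_gene", "genomics_england")
    register: Optional[str] = None
    probabilities: Optional[str] = None
    fixed_profile: str = "conservative"
    strict_vus: bool = True
    stratify_by_sex: bool = False
    seed: int = 0
    policy: PolicyConfig = field(default_factory=PolicyConfig)

    def config_hash(self) -> str:
        payload = {
            k: getattr(self, k)
            for k in ("variants", "metrics", "repeats", "panels", "register",
                      "probabilities", "fixed_profile", "strict_vus",
                      "stratify_by_sex", "seed")
        }
        payload["policy"] = [self.policy.sporadic_factor, self.policy.age_cutoff,
                             self.policy.ci_level]
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_fixed_profile(name: str) -> FixedCriteriaProfile:
    if name == "conservative":
        return FixedCriteriaProfile.conservative()
    if name == "permissive":
        return FixedCriteriaProfile.permissive()
    return FixedCriteriaProfile.from_json(name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages from files and write TSV/JSON outputs.

    Returns the report dict (also written to ``report.json``).  Any stage
    error is re-raised annotated with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}

    stage = "read_inputs"
    try:
        variants = aio.read_variant_table(config.variants)
        metrics = aio.read_sample_metrics(config.metrics)
        repeats = aio.read_repeat_calls(config.repeats)
        panels = [load_panel(p) for p in config.panels]
        settings = PipelineSettings(
            fixed_profile=_load_fixed_profile(config.fixed_profile),
            strict_vus=config.strict_vus,
        )

        stage = "classify"
        result = classify_cohort(variants, metrics, repeats, panels, settings)

        stage = "yield"
        yields = {}
        for panel in panels:
            if len(result.persons):
                yields[panel.name] = yield_table(
                    result.persons,
                    result.actionability[panel.name],
                    stratify_by_sex=config.stratify_by_sex,
                )
            else:
                yields[panel.name] = pd.DataFrame(
                    columns=["panel", "age_group", "n", "k", "p",
                             "ci_lower", "ci_upper"]
                )

        stage = "policy"
        policy_results = {}
        if config.register is not None:
            register = aio.read_register(config.register)
            if "standard_pop" not in register.columns:
                raise aio.SchemaError(
                    "register table needs a standard_pop column for the"
                    " policy stage"
                )
            expected = stratum_expected(register, config.policy)
            for panel in panels:
                if config.probabilities is not None:
                    probs = aio.read_probabilities(config.probabilities)
                else:
                    probs = estimated_probabilities(yields[panel.name])
                    missing = set(AGE_GROUPS) - set(probs)
                    for g in missing:  # empty stratum -> no evidence of yield
                        probs[g] = 0.0
                missed = missed_estimate(expected, probs, config.policy)
                policy_results[panel.name] = {
                    "missed": missed.missed,
                    "total": missed.total,
                    "missed_rounded": missed.missed_rounded,
                    "total_rounded": missed.total_rounded,
                    "proportion": missed.proportion,
                    "ci_lower": missed.ci[0],
                    "ci_upper": missed.ci[1],
                    "per_sex": missed.per_sex,
                }

        stage = "write_outputs"
        aio.write_tsv(result.classified, out_dir / "classified_variants.tsv", meta)
        aio.write_tsv(result.variant_audit, out_dir / "variant_audit.tsv", meta)
        aio.write_tsv(result.sample_audit, out_dir / "sample_audit.tsv", meta)
        for name, frame in result.actionability.items():
            aio.write_tsv(
                frame.reset_index(), out_dir / f"actionability_{name}.tsv", meta
            )
        for name, frame in yields.items():
            aio.write_tsv(frame, out_dir / f"yield_{name}.tsv", meta)

        report = {
            "meta": meta,
            "counts": dict(result.counts),
            "yield": {
                name: frame.to_dict(orient="records") for name, frame in yields.items()
            },
            "policy": policy_results,
        }
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
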