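"""ACMG/AMP sequence-variant classification rules engine.

The ACMG/AMP framework scores a variant against 28 named evidence criteria —
16 on the pathogenic side (PVS1; PS1–PS4; PM1–PM6; PP1–PP5) and 12 on the
benign side (BA1; BS1–BS4; BP1–BP7) — and combines the active criteria with
a fixed published table into one of five classes: benign, likely benign,
variant of uncertain significance (VUS), likely pathogenic, pathogenic.

At cohort scale a full manual evidence review per variant is impossible, so
this engine works in two stages:

1. :func:`auto_evidence` derives the criteria that depend only on the
   annotations carried by the variant record itself (impact class, allele
   frequencies in two reference sets, in-silico score, consequence terms).
2. :func:`merge_fixed` overlays a :class:`FixedCriteriaProfile` — a set of
   predefined values, keyed by impact class (high / moderate), for the
   criteria that would otherwise need manual literature review.

The combined 28-flag :class:`EvidenceProfile` is then mapped to a class by
:func:`combine`, and VUS calls are sub-stratified by :func:`stratify_vus`
into "high probability of pathogenicity" (at least one pathogenic criterion
active and no benign criterion) versus "low to medium probability".

Vectorised `*_frame` variants of each step operate on pandas DataFrames and
are what the pipeline uses; the scalar functions share the same rule code.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PATHOGENIC_CRITERIA: tuple[str, ...] = (
    "PVS1",
    "PS1", "PS2", "PS3", "PS4",
    "PM1", "PM2", "PM3", "PM4", "PM5", "PM6",
    "PP1", "PP2", "PP3", "PP4", "PP5",
)
BENIGN_CRITERIA: tuple[str, ...] = (
    "BA1",
    "BS1", "BS2", "BS3", "BS4",
    "BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7",
)
ALL_CRITERIA: tuple[str, ...] = PATHOGENIC_CRITERIA + BENIGN_CRITERIA

#: Five-class ordinal scale, benign to pathogenic.
CLASSES: tuple[str, ...] = (
    "benign", "likely_benign", "vus", "likely_pathogenic", "pathogenic",
)

VUS_SUBCLASSES: tuple[str, ...] = ("high", "low_medium", "not_applicable")

# Consequence terms that activate PM4 (protein-length-changing events).
_PM4_TERMS = frozenset({"inframe_insertion", "inframe_deletion", "stop_lost"})


@dataclass(frozen=True)
class EvidenceProfile:
    """Complete assignment of the 28 ACMG criteria to booleans."""

    flags: Mapping[str, bool]

    def __post_init__(self) -> None:
        flags = dict(self.flags)
        unknown = set(flags) - set(ALL_CRITERIA)
        if unknown:
            raise ValueError(f"unknown ACMG criteria: {sorted(unknown)}")
        for name in ALL_CRITERIA:
            flags.setdefault(name, False)
        object.__setattr__(self, "flags", flags)

    @classmethod
    def from_active(cls, active: Iterable[str] = ()) -> "EvidenceProfile":
        active = set(active)
        unknown = active - set(ALL_CRITERIA)
        if unknown:
            raise ValueError(f"unknown ACMG criteria: {sorted(unknown)}")
        return cls({name: name in active for name in ALL_CRITERIA})

    def active(self) -> tuple[str, ...]:
        return tuple(n for n in ALL_CRITERIA if self.flags[n])

    @property
    def n_pathogenic(self) -> int:
        return sum(self.flags[n] for n in PATHOGENIC_CRITERIA)

    @property
    def n_benign(self) -> int:
        return sum(self.flags[n] for n in BENIGN_CRITERIA)

    def counts(self) -> dict[str, int]:
        """Per-strength counts used by the combining table."""
        f = self.flags
        return {
            "pvs": int(f["PVS1"]),
            "ps": sum(f[n] for n in ("PS1", "PS2", "PS3", "PS4")),
            "pm": sum(f[n] for n in ("PM1", "PM2", "PM3", "PM4", "PM5", "PM6")),
            "pp": sum(f[n] for n in ("PP1", "PP2", "PP3", "PP4", "PP5")),
            "ba": int(f["BA1"]),
            "bs": sum(f[n] for n in ("BS1", "BS2", "BS3", "BS4")),
            "bp": sum(f[n] for n in ("BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7")),
        }

    def replace(self, **flags: bool) -> "EvidenceProfile":
        merged = dict(self.flags)
        merged.update(flags)
        return EvidenceProfile(merged)


@dataclass(frozen=True)
class AcmgResult:
    """Outcome of classification for one variant."""

    acmg_class: str
    vus_subclass: str
    evidence: EvidenceProfile

    def __post_init__(self) -> None:
        if (self.vus_subclass != "not_applicable") != (self.acmg_class == "vus"):
            raise ValueError("vus_subclass applies exactly when the class is vus")


# ---------------------------------------------------------------------------
# Combining rules (published ACMG/AMP table). The predicates are written with
# >= comparisons so they apply elementwise to numpy arrays as well as ints;
# >= and the published exact-count brackets give identical classes because
# every superset of a bracket is covered by an at-least-as-strong rule.
# ---------------------------------------------------------------------------

def _rule_pathogenic(pvs, ps, pm, pp):
    return (
        ((pvs >= 1) & ((ps >= 1) | (pm >= 2) | ((pm >= 1) & (pp >= 1)) | (pp >= 2)))
        | (ps >= 2)
        | ((ps >= 1) & ((pm >= 3) | ((pm >= 2) & (pp >= 2)) | ((pm >= 1) & (pp >= 4))))
    )


def _rule_likely_pathogenic(pvs, ps, pm, pp):
    return (
        ((pvs >= 1) & (pm >= 1))
        | ((ps >= 1) & (pm >= 1))
        | ((ps >= 1) & (pp >= 2))
        | (pm >= 3)
        | ((pm >= 2) & (pp >= 2))
        | ((pm >= 1) & (pp >= 4))
    )


def _rule_benign(ba, bs):
    return (ba >= 1) | (bs >= 2)


def _rule_likely_benign(bs, bp):
    return ((bs >= 1) & (bp >= 1)) | (bp >= 2)


def classify_counts(pvs, ps, pm, pp, ba, bs, bp) -> np.ndarray:
    """Map per-strength criterion counts to the five-class scale.

    Accepts scalars or equally shaped numpy arrays.  Contradictory
    evidence — any active pathogenicity criterion while a benign-side
    combining rule is met — yields ``vus``.
    """
    pvs, ps, pm, pp, ba, bs, bp = (np.asarray(x) for x in (pvs, ps, pm, pp, ba, bs, bp))
    p = _rule_pathogenic(pvs, ps, pm, pp)
    lp = _rule_likely_pathogenic(pvs, ps, pm, pp)
    b = _rule_benign(ba, bs)
    lb = _rule_likely_benign(bs, bp)
    contradiction = (b | lb) & (pvs + ps + pm + pp >= 1)
    return np.select(
        [contradiction, p, lp, b, lb],
        ["vus", "pathogenic", "likely_pathogenic", "benign", "likely_benign"],
        default="vus",
    )


def combine(evidence: EvidenceProfile) -> str:
    """Classify a complete evidence profile into one of the five classes."""
    return str(classify_counts(**evidence.counts())[()])


def stratify_vus(evidence: EvidenceProfile, acmg_class: str) -> str:
    """Sub-stratify a VUS by probability of pathogenicity.

    A VUS is "high" probability when it matches at least one of the 16
    pathogenicity criteria and none of the 12 benignity criteria, and
    "low_medium" otherwise.  Non-VUS classes get "not_applicable".
    """
    if acmg_class != "vus":
        return "not_applicable"
    if evidence.n_pathogenic >= 1 and evidence.n_benign == 0:
        return "high"
    return "low_medium"


def classify(evidence: EvidenceProfile) -> AcmgResult:
    acmg_class = combine(evidence)
    return AcmgResult(acmg_class, stratify_vus(evidence, acmg_class), evidence)


# ---------------------------------------------------------------------------
# Automatic evaluators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcmgConfig:
    """Thresholds for the annotation-driven criterion evaluators.

    Parameters
    ----------
    lof_genes
        Genes for which loss of function is an accepted disease mechanism;
        PVS1 fires only for high-impact variants in these genes.
    pm2_max_af
        PM2 (absent/extremely rare in controls) fires when the allele
        frequency is zero or below this in *both* reference sets.
    ba1_min_af
        BA1 stand-alone benign frequency threshold (default 5%).
    bs1_min_af
        BS1 threshold: frequency greater than expected for the disorder.
    pp3_min_score / bp4_max_score
        Cuts on the optional in-silico damage score (scaled 0–1) for
        computational support of pathogenicity / benignity.
    """

    lof_genes: frozenset[str] = frozenset()
    pm2_max_af: float = 1e-4
    ba1_min_af: float = 0.05
    bs1_min_af: float = 0.001
    pp3_min_score: float = 0.7
    bp4_max_score: float = 0.3

    def __post_init__(self) -> None:
        object.__setattr__(self, "lof_genes", frozenset(self.lof_genes))
        for name in ("pm2_max_af", "ba1_min_af", "bs1_min_af"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a frequency in [0, 1], got {v}")


def _term_set(terms) -> set[str]:
    if isinstance(terms, str):
        return {t for t in terms.replace(",", "&").split("&") if t}
    return set(terms)


def auto_evidence_frame(variants: pd.DataFrame, config: AcmgConfig) -> pd.DataFrame:
    """Evaluate the annotation-driven criteria for a frame of variants.

    ``variants`` must carry ``gene``, ``impact``, ``consequence_terms``,
    ``af_reference`` and ``af_internal``; ``insilico_score`` is optional
    (missing scores leave PP3/BP4 false).  Returns a boolean DataFrame with
    one column per ACMG criterion, aligned to the input index; criteria
    without an automatic evaluator are false.
    """
    n = len(variants)
    ev = pd.DataFrame(False, index=variants.index, columns=list(ALL_CRITERIA))
    if n == 0:
        return ev

    af_ref = variants["af_reference"].to_numpy(dtype=float)
    af_int = variants["af_internal"].to_numpy(dtype=float)
    impact = variants["impact"].to_numpy()
    terms = [_term_set(t) for t in variants["consequence_terms"]]

    rare_ref = (af_ref == 0.0) | (af_ref < config.pm2_max_af)
    rare_int = (af_int == 0.0) | (af_int < config.pm2_max_af)

    ev["PVS1"] = (impact == "high") & variants["gene"].isin(config.lof_genes).to_numpy()
    ev["PM2"] = rare_ref & rare_int
    ev["PM4"] = np.array([bool(t & _PM4_TERMS) for t in terms])
    ev["BA1"] = af_ref > config.ba1_min_af
    ev["BS1"] = af_ref > config.bs1_min_af

    if "insilico_score" in variants.columns:
        score = variants["insilico_score"].to_numpy(dtype=float)
        has_score = ~np.isnan(score)
        ev["PP3"] = has_score & (score >= config.pp3_min_score)
        ev["BP4"] = has_score & (score <= config.bp4_max_score)
    return ev


def auto_evidence(variant: Mapping, config: AcmgConfig) -> EvidenceProfile:
    """Scalar convenience wrapper around :func:`auto_evidence_frame`."""
    frame = auto_evidence_frame(pd.DataFrame([dict(variant)]), config)
    return EvidenceProfile(frame.iloc[0].to_dict())


# ---------------------------------------------------------------------------
# Fixed-value profiles
# ---------------------------------------------------------------------------

_IMPACT_KEYS = ("high", "moderate")


@dataclass(frozen=True)
class FixedCriteriaProfile:
    """Predefined criterion values overlaid on the automatic evaluation.

    ``forced`` maps an impact class ("high" / "moderate") to a mapping of
    criterion name -> True, False, or "auto" (keep the evaluator's value).
    Criteria not mentioned default to "auto".
    """

    name: str
    forced: Mapping[str, Mapping[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        forced = {k: dict(v) for k, v in self.forced.items()}
        for impact, rules in forced.items():
            if impact not in _IMPACT_KEYS:
                raise ValueError(f"unknown impact class in fixed profile: {impact!r}")
            for crit, value in rules.items():
                if crit not in ALL_CRITERIA:
                    raise ValueError(f"unknown ACMG criterion in fixed profile: {crit!r}")
                if value not in (True, False, "auto"):
                    raise ValueError(
                        f"fixed value for {crit} must be true/false/'auto', got {value!r}"
                    )
        object.__setattr__(self, "forced", forced)

    @classmethod
    def conservative(cls) -> "FixedCriteriaProfile":
        """All manual criteria left false; only automatic evaluators act."""
        return cls(name="conservative", forced={"high": {}, "moderate": {}})

    @classmethod
    def permissive(cls) -> "FixedCriteriaProfile":
        """Supporting-level evidence (PP5) presumed for high-impact variants."""
        return cls(name="permissive", forced={"high": {"PP5": True}, "moderate": {}})

    @classmethod
    def from_json(cls, path: str | Path) -> "FixedCriteriaProfile":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(name=payload.get("name", Path(path).stem), forced=payload["forced"])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "forced": self.forced}, fh, indent=2)
            fh.write("\n")


def merge_fixed(
    auto: EvidenceProfile, fixed: FixedCriteriaProfile, impact: str
) -> EvidenceProfile:
    """Overlay the fixed profile for one impact class onto automatic flags."""
    if impact not in _IMPACT_KEYS:
        raise ValueError(f"impact must be one of {_IMPACT_KEYS}, got {impact!r}")
    merged = dict(auto.flags)
    for crit, value in fixed.forced.get(impact, {}).items():
        if value != "auto":
            merged[crit] = bool(value)
    return EvidenceProfile(merged)


def merge_fixed_frame(
    evidence: pd.DataFrame, fixed: FixedCriteriaProfile, impact: pd.Series
) -> pd.DataFrame:
    """Vectorised :func:`merge_fixed` over a criterion frame."""
    out = evidence.copy()
    for klass in _IMPACT_KEYS:
        mask = (impact == klass).to_numpy()
        if not mask.any():
            continue
        for crit, value in fixed.forced.get(klass, {}).items():
            if value != "auto":
                out.loc[mask, crit] = bool(value)
    return out


def classify_frame(evidence: pd.DataFrame) -> pd.DataFrame:
    """Classify a criterion frame; returns ``acmg_class`` and ``vus_subclass``."""
    ps_cols = ["PS1", "PS2", "PS3", "PS4"]
    pm_cols = ["PM1", "PM2", "PM3", "PM4", "PM5", "PM6"]
    pp_cols = ["PP1", "PP2", "PP3", "PP4", "PP5"]
    bs_cols = ["BS1", "BS2", "BS3", "BS4"]
    bp_cols = ["BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7"]

    acmg_class = classify_counts(
        pvs=evidence["PVS1"].to_numpy(int),
        ps=evidence[ps_cols].to_numpy(int).sum(axis=1),
        pm=evidence[pm_cols].to_numpy(int).sum(axis=1),
        pp=evidence[pp_cols].to_numpy(int).sum(axis=1),
        ba=evidence["BA1"].to_numpy(int),
        bs=evidence[bs_cols].to_numpy(int).sum(axis=1),
        bp=evidence[bp_cols].to_numpy(int).sum(axis=1),
    )
    n_path = evidence[list(PATHOGENIC_CRITERIA)].to_numpy(int).sum(axis=1)
    n_ben = evidence[list(BENIGN_CRITERIA)].to_numpy(int).sum(axis=1)
    is_vus = acmg_class == "vus"
    subclass = np.where(
        is_vus,
        np.where((n_path >= 1) & (n_ben == 0), "high", "low_medium"),
        "not_applicable",
    )
    return pd.DataFrame(
        {"acmg_class": acmg_class, "vus_subclass": subclass}, index=evidence.index
    )
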