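"""Gene panels, inheritance-mode logic and the actionability decision.

A genetic test result for one person is *clinically actionable* when it
reports at least one of:

* a variant of predicted moderate or high impact in a panel gene,
  classified pathogenic or likely pathogenic, or a VUS of "high probability
  of pathogenicity" (benign, likely benign and low/medium VUS calls are not
  reportable);
* a pathogenic repeat expansion (*C9orf72* > 30 units, *ATXN2* 29–33
  units) at a locus included in the panel.

Per-gene reporting modes capture inheritance: most ALS genes are reportable
on a single heterozygous variant (dominant or risk alleles), while *ALS2*
is recessive and reportable only when homozygous.  Two heterozygous
variants in the same gene are never combined (phase unknown).

Three panels are shipped: the four commonest ALS genes tested clinically
(``four_gene``), a broader Mendelian-ALS research panel (``project_mine``),
and the ALS genes of the Genomics England amyotrophic lateral sclerosis /
MND panel (``genomics_england``).

:func:`corroboration_rule` implements the independent, database-driven
definition of pathogenicity used to sanity-check the ACMG route on the
four-gene panel: any C9orf72 expansion >30; any retained rare SOD1 variant;
TARDBP/FUS variants that are pathogenic/likely pathogenic in ClinVar or
present in ALSoD with >=1 publication and >=2 patients.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd

from .repeats import interpret_frame

REPORTING_MODES = ("het_reportable", "biallelic_only")

#: Names of the panel definition files shipped with the package.
SHIPPED_PANELS = ("four_gene", "project_mine", "genomics_england")


@dataclass(frozen=True)
class PanelDefinition:
    """A named gene panel with a per-gene reporting mode."""

    name: str
    modes: Mapping[str, str]

    def __post_init__(self) -> None:
        modes = dict(self.modes)
        for gene, mode in modes.items():
            if mode not in REPORTING_MODES:
                raise ValueError(f"unknown reporting mode {mode!r} for {gene}")
        object.__setattr__(self, "modes", modes)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.modes)

    def mode(self, gene: str) -> str:
        return self.modes[gene]

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelDefinition":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(name=payload["name"], modes=payload["genes"])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "genes": self.modes}, fh, indent=2)
            fh.write("\n")


def load_panel(name: str) -> PanelDefinition:
    """Load a shipped panel by name, or any panel JSON by path."""
    if name in SHIPPED_PANELS:
        resource = files("alsact") / "data" / f"panel_{name}.json"
        payload = json.loads(resource.read_text())
        return PanelDefinition(name=payload["name"], modes=payload["genes"])
    return PanelDefinition.from_json(name)


@dataclass(frozen=True)
class ActionabilityResult:
    """Actionability decision for one person against one panel."""

    person_id: str
    panel: str
    actionable: bool
    contributors: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.actionable != bool(self.contributors):
            raise ValueError("actionable must be true iff contributors is non-empty")


def variant_actionable(
    acmg_class: str,
    vus_subclass: str,
    impact: str,
    strict_vus: bool = True,
) -> bool:
    """Whether a classified variant is reportable on its own merits.

    With ``strict_vus`` (the default) only pathogenic, likely pathogenic and
    high-probability VUS calls count; with it off, every class except benign
    and likely benign counts (i.e. low/medium VUS are also reported).
    """
    if impact not in ("high", "moderate"):
        return False
    if acmg_class in ("pathogenic", "likely_pathogenic"):
        return True
    if acmg_class == "vus":
        return vus_subclass == "high" if strict_vus else True
    return False


def variant_actionable_frame(
    classified: pd.DataFrame, strict_vus: bool = True
) -> pd.Series:
    """Vectorised :func:`variant_actionable` over a classified variant frame."""
    impact_ok = classified["impact"].isin(["high", "moderate"]).to_numpy()
    cls = classified["acmg_class"].to_numpy()
    plp = (cls == "pathogenic") | (cls == "likely_pathogenic")
    if strict_vus:
        vus_ok = (cls == "vus") & (classified["vus_subclass"].to_numpy() == "high")
    else:
        vus_ok = cls == "vus"
    return pd.Series(impact_ok & (plp | vus_ok), index=classified.index,
                     name="variant_actionable")


def _variant_contributes(classified: pd.DataFrame, panel: PanelDefinition,
                         strict_vus: bool) -> pd.Series:
    in_panel = classified["gene"].isin(panel.genes).to_numpy()
    biallelic_only = classified["gene"].map(
        lambda g: panel.modes.get(g) == "biallelic_only"
    ).to_numpy(dtype=bool)
    zygosity_ok = np.where(
        biallelic_only, classified["zygosity"].to_numpy() == "homozygous", True
    )
    ok = in_panel & zygosity_ok & variant_actionable_frame(classified, strict_vus).to_numpy()
    return pd.Series(ok, index=classified.index)


def person_actionable(
    person_id: str,
    classified: pd.DataFrame,
    repeats: pd.DataFrame,
    panel: PanelDefinition,
    strict_vus: bool = True,
) -> ActionabilityResult:
    """Decide actionability for one person.

    ``classified`` and ``repeats`` are that person's classified variant and
    repeat-call frames (either may be empty).  Contributors record each
    reportable variant ("GENE chrom:pos ref>alt") or repeat locus with the
    reason it was reported.
    """
    contributors: list[tuple[str, str]] = []
    if len(classified):
        mask = _variant_contributes(classified, panel, strict_vus)
        for _, row in classified.loc[mask.to_numpy()].iterrows():
            label = f"{row['gene']} {row['chrom']}:{row['pos']} {row['ref']}>{row['alt']}"
            reason = row["acmg_class"]
            if row["acmg_class"] == "vus":
                reason = "vus_high_probability"
            contributors.append((label, reason))
    if len(repeats):
        interpreted = repeats if "pathogenic" in repeats.columns else interpret_frame(repeats)
        hits = interpreted[
            interpreted["pathogenic"] & interpreted["gene"].isin(panel.genes)
        ]
        for _, row in hits.iterrows():
            contributors.append(
                (f"{row['gene']} repeat x{row['repeat_count']}", "pathogenic_repeat")
            )
    return ActionabilityResult(
        person_id=person_id,
        panel=panel.name,
        actionable=bool(contributors),
        contributors=tuple(contributors),
    )


def actionability_frame(
    person_ids: pd.Index | pd.Series,
    classified: pd.DataFrame,
    repeats: pd.DataFrame,
    panel: PanelDefinition,
    strict_vus: bool = True,
) -> pd.DataFrame:
    """Per-person actionability for a whole cohort (vectorised).

    ``person_ids`` enumerates the cohort denominator (persons with no
    variant or repeat rows are not actionable).  Returns a frame indexed
    like ``person_ids`` with ``actionable`` and contributor counts.
    """
    ids = pd.Index(person_ids, name="person_id")
    n_var = pd.Series(0, index=ids, dtype=int)
    n_rep = pd.Series(0, index=ids, dtype=int)
    if len(classified):
        mask = _variant_contributes(classified, panel, strict_vus)
        counts = classified.loc[mask.to_numpy()].groupby("person_id").size()
        n_var = n_var.add(counts.reindex(ids, fill_value=0), fill_value=0).astype(int)
    if len(repeats):
        interpreted = repeats if "pathogenic" in repeats.columns else interpret_frame(repeats)
        hits = interpreted[
            interpreted["pathogenic"] & interpreted["gene"].isin(panel.genes)
        ]
        counts = hits.groupby("person_id").size()
        n_rep = n_rep.add(counts.reindex(ids, fill_value=0), fill_value=0).astype(int)
    out = pd.DataFrame(
        {
            "panel": panel.name,
            "n_variant_contributors": n_var,
            "n_repeat_contributors": n_rep,
        },
        index=ids,
    )
    out["actionable"] = (out["n_variant_contributors"] + out["n_repeat_contributors"]) > 0
    return out


# ---------------------------------------------------------------------------
# Database corroboration (four-gene sanity check)
# ---------------------------------------------------------------------------

_CORROBORATION_GENES = ("C9orf72", "SOD1", "TARDBP", "FUS")


def corroboration_rule(
    gene: str,
    *,
    repeat_count: int | None = None,
    clinvar_plp: bool | None = None,
    alsod_publications: int | None = None,
    alsod_patients: int | None = None,
) -> bool:
    """Database-driven pathogenicity for the four commonest ALS genes.

    C9orf72: repeat expansion > 30.  SOD1: every retained rare variant.
    TARDBP / FUS: ClinVar pathogenic or likely pathogenic, or present in
    ALSoD with at least one publication and at least two patients; missing
    database flags yield False with a warning.  Other genes: False.
    """
    if gene == "C9orf72":
        return repeat_count is not None and repeat_count > 30
    if gene == "SOD1":
        return True
    if gene in ("TARDBP", "FUS"):
        if clinvar_plp is None and alsod_publications is None:
            warnings.warn(
                f"missing ClinVar/ALSoD flags for a {gene} variant; treated as"
                " not corroborated",
                stacklevel=2,
            )
            return False
        if bool(clinvar_plp):
            return True
        return (alsod_publications or 0) >= 1 and (alsod_patients or 0) >= 2
    return False


def corroboration_frame(
    person_ids: pd.Index | pd.Series,
    retained_variants: pd.DataFrame,
    repeats: pd.DataFrame,
) -> pd.DataFrame:
    """Per-person four-gene actionability under the corroboration rule.

    ``retained_variants`` are rare moderate/high-impact variants that passed
    prioritisation (classification is not consulted — that is the point of
    the cross-check).
    """
    ids = pd.Index(person_ids, name="person_id")
    actionable = pd.Series(False, index=ids)
    if len(retained_variants):
        v = retained_variants
        sod1 = (v["gene"] == "SOD1").to_numpy()
        tf = v["gene"].isin(["TARDBP", "FUS"]).to_numpy()
        clinvar = v.get("clinvar_plp", pd.Series(False, index=v.index))
        clinvar = clinvar.fillna(False).astype(bool).to_numpy()
        pubs = v.get("alsod_publications", pd.Series(0, index=v.index))
        pubs = pubs.fillna(0).astype(int).to_numpy()
        pats = v.get("alsod_patients", pd.Series(0, index=v.index))
        pats = pats.fillna(0).astype(int).to_numpy()
        hit = sod1 | (tf & (clinvar | ((pubs >= 1) & (pats >= 2))))
        hits = v.loc[hit].groupby("person_id").size().reindex(ids, fill_value=0)
        actionable |= hits > 0
    if len(repeats):
        c9 = repeats[(repeats["gene"] == "C9orf72") & (repeats["repeat_count"] > 30)]
        hits = c9.groupby("person_id").size().reindex(ids, fill_value=0)
        actionable |= hits > 0
    return pd.DataFrame({"panel": "four_gene_corroboration", "actionable": actionable})
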