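"""Synthetic cohorts and incidence registers with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so that every downstream stage can be exercised and validated
without access-controlled sequencing data:

* persons with sex, a truncated-normal age of onset (mean 65, SD 12,
  truncated to 18–95 years), and per-age-group probabilities of carrying a
  clinically actionable result;
* "planted" actionable findings realised either as a pathogenic repeat
  expansion (*C9orf72* or intermediate *ATXN2*) or as a rare variant drawn
  from per-class annotation recipes whose ACMG outcome is analytically
  known (stop_lost at frequency 0 in a loss-of-function gene -> PVS1 + PM2
  + PM4 -> pathogenic; frameshift at frequency 0 -> PVS1 + PM2 -> likely
  pathogenic; missense at frequency 0 with a damaging in-silico score ->
  PM2 + PP3 -> high-probability VUS);
* background variants that the pipeline must discard (common, synonymous,
  or QC-failing) or classify as non-reportable (low/medium VUS);
* sample-level QC failure modes (sex-mismatched and ageless samples);
* an age-by-sex incidence register with Poisson case counts.

Ground-truth labels are emitted in a sidecar table, never in the variant
table, so the pipeline cannot read its own answers.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .panels import PanelDefinition, load_panel
from .repeats import ATXN2_RISK_RANGE
from .stats import AGE_GROUPS, bin_age_series

#: Default age-group probabilities of an actionable result (UK-like, broad
#: panel): 0.23 in the youngest and 0.17 in the oldest group; the middle
#: groups use the mid-range value implied by the printed missed-case totals.
UK_PANEL_PROBABILITIES: dict[str, float] = {
    "<40": 0.23, "40-49": 0.22, "50-59": 0.22, "60-69": 0.22, ">=70": 0.17,
}

_REPEAT_LOCI = ("C9orf72", "ATXN2")


@dataclass(frozen=True)
class AgeDistribution:
    """Truncated-normal age-of-onset model (years)."""

    mean: float = 65.0
    sd: float = 12.0
    min_age: float = 18.0
    max_age: float = 95.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.min_age - self.mean) / self.sd
        b = (self.max_age - self.mean) / self.sd
        return truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Rates of non-signal structure mixed into the cohort.

    ``background_rate`` is the Poisson mean of non-actionable variants per
    person, split among the ``background_mix`` recipes; the sample-level
    rates inject sex-mismatched and ageless samples that sample QC must
    remove.
    """

    background_rate: float = 2.0
    background_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "common_missense": 0.35,
            "rare_synonymous": 0.25,
            "vus_low_missense": 0.20,
            "benign_score_missense": 0.10,
            "qc_fail_missense": 0.10,
        }
    )
    sex_mismatch_rate: float = 0.01
    missing_age_rate: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "background_mix", dict(self.background_mix))
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        for name in ("sex_mismatch_rate", "missing_age_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.background_rate > 0:
            total = sum(self.background_mix.values())
            if total <= 0:
                raise ValueError("background_mix weights must sum to a positive value")

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(background_rate=0.0, sex_mismatch_rate=0.0, missing_age_rate=0.0)


def default_gene_weights(panel: PanelDefinition) -> dict[str, float]:
    """Relative probability each panel gene contributes a planted variant.

    The four commonest ALS genes carry extra mass (SOD1 0.12, TARDBP 0.09,
    FUS 0.08 of the variant share); the repeat loci are excluded (their
    findings are planted as expansions); the remainder is spread evenly.
    The per-gene split is otherwise arbitrary — the source cohort's
    per-gene breakdown is not public.
    """
    favoured = {"SOD1": 0.12, "TARDBP": 0.09, "FUS": 0.08}
    genes = sorted(panel.genes - set(_REPEAT_LOCI))
    weights = {g: favoured[g] for g in genes if g in favoured}
    rest = [g for g in genes if g not in favoured]
    remaining = 1.0 - sum(weights.values())
    if rest:
        for g in rest:
            weights[g] = remaining / len(rest)
    else:
        total = sum(weights.values())
        weights = {g: w / total for g, w in weights.items()}
    return weights


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_persons: int = 1551
    sex_ratio: float = 0.6
    age: AgeDistribution = field(default_factory=AgeDistribution)
    panel: Union[str, PanelDefinition] = "genomics_england"
    panel_probabilities: Mapping[str, float] = field(
        default_factory=lambda: dict(UK_PANEL_PROBABILITIES)
    )
    gene_weights: Optional[Mapping[str, float]] = None
    repeat_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"C9orf72": 0.35, "ATXN2": 0.03}
    )
    recipe_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "pathogenic": 0.30,
            "likely_pathogenic": 0.40,
            "vus_high": 0.30,
        }
    )
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive (empty cohort)")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        panel = (
            self.panel if isinstance(self.panel, PanelDefinition)
            else load_panel(self.panel)
        )
        object.__setattr__(self, "panel", panel)
        probs = dict(self.panel_probabilities)
        if set(probs) != set(AGE_GROUPS):
            raise ValueError(
                f"panel_probabilities must cover exactly the age groups"
                f" {AGE_GROUPS}, got {sorted(probs)}"
            )
        for g, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {g!r} outside [0, 1]: {p}")
        object.__setattr__(self, "panel_probabilities", probs)
        weights = dict(
            self.gene_weights
            if self.gene_weights is not None
            else default_gene_weights(panel)
        )
        if min(weights.values()) < 0 or abs(sum(weights.values()) - 1.0) > 1e-8:
            raise ValueError("gene_weights must be non-negative and sum to 1")
        unknown = set(weights) - panel.genes
        if unknown:
            raise ValueError(f"gene_weights refer to genes not in the panel: {sorted(unknown)}")
        object.__setattr__(self, "gene_weights", weights)
        rf = {locus: float(self.repeat_freqs.get(locus, 0.0)) for locus in _REPEAT_LOCI}
        if min(rf.values()) < 0 or sum(rf.values()) > 1.0:
            raise ValueError("repeat_freqs must be non-negative with sum <= 1")
        object.__setattr__(self, "repeat_freqs", rf)
        rw = dict(self.recipe_weights)
        if set(rw) - set(_PLANTED_RECIPES):
            raise ValueError(f"unknown recipe in recipe_weights: {sorted(rw)}")
        if min(rw.values()) < 0 or abs(sum(rw.values()) - 1.0) > 1e-8:
            raise ValueError("recipe_weights must be non-negative and sum to 1")
        object.__setattr__(self, "recipe_weights", rw)

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


# Annotation recipes: each row fixes the fields that drive QC and the
# automatic ACMG evaluators, so the classification outcome is known by
# construction (see module docstring).
_RECIPE_FIELDS = (
    "consequence_terms", "variant_class", "ref", "alt", "site_quality",
    "genotype_quality", "missingness", "af_reference", "af_internal",
    "insilico_score", "clinvar_plp", "alsod_publications", "alsod_patients",
)
_PLANTED_RECIPES = {
    "pathogenic": ("stop_lost", "SNV", "T", "C", 60.0, 99.0, 0.0, 0.0, 0.0,
                   np.nan, True, 2, 3),
    "likely_pathogenic": ("frameshift_variant", "indel", "GAT", "G", 60.0, 99.0,
                          0.0, 0.0, 0.0, np.nan, True, 2, 3),
    "vus_high": ("missense_variant", "SNV", "G", "A", 60.0, 99.0, 0.0, 0.0, 0.0,
                 0.9, True, 2, 3),
}
_BACKGROUND_RECIPES = {
    "common_missense": ("missense_variant", "SNV", "C", "T", 60.0, 99.0, 0.0,
                        0.01, 0.008, 0.2, False, 0, 0),
    "rare_synonymous": ("synonymous_variant", "SNV", "A", "G", 60.0, 99.0, 0.0,
                        2e-4, 2e-4, np.nan, False, 0, 0),
    "vus_low_missense": ("missense_variant", "SNV", "G", "T", 60.0, 99.0, 0.0,
                         5e-4, 4e-4, 0.5, False, 0, 0),
    "benign_score_missense": ("missense_variant", "SNV", "A", "C", 60.0, 99.0,
                              0.0, 2e-4, 2e-4, 0.1, False, 0, 0),
    "qc_fail_missense": ("missense_variant", "SNV", "T", "A", 60.0, 5.0, 0.0,
                         0.0, 0.0, np.nan, False, 0, 0),
}
_ALL_RECIPES = {**_PLANTED_RECIPES, **_BACKGROUND_RECIPES}


@dataclass(frozen=True)
class Cohort:
    """Generated cohort tables plus the ground-truth sidecar."""

    persons: pd.DataFrame
    variants: pd.DataFrame
    repeats: pd.DataFrame
    metrics: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig


def _gene_positions(panel: PanelDefinition) -> dict[str, tuple[str, int]]:
    genes = sorted(panel.genes)
    return {g: (str(i % 22 + 1), 1_000_000 * (i + 1)) for i, g in enumerate(genes)}


def _variants_from_recipes(
    person_ids: np.ndarray,
    genes: np.ndarray,
    recipes: np.ndarray,
    zygosity: np.ndarray,
    panel: PanelDefinition,
    rng: np.random.Generator,
) -> pd.DataFrame:
    lookup = pd.DataFrame.from_dict(_ALL_RECIPES, orient="index", columns=_RECIPE_FIELDS)
    attrs = lookup.loc[recipes].reset_index(drop=True)
    pos_map = _gene_positions(panel)
    chrom = np.array([pos_map[g][0] for g in genes])
    base = np.array([pos_map[g][1] for g in genes])
    pos = base + rng.integers(0, 900_000, size=len(genes))
    df = pd.DataFrame({
        "person_id": person_ids,
        "gene": genes,
        "chrom": chrom,
        "pos": pos,
        "zygosity": zygosity,
    })
    return pd.concat([df, attrs], axis=1)[
        ["person_id", "gene", "chrom", "pos", "ref", "alt", "variant_class",
         "consequence_terms", "site_quality", "genotype_quality", "missingness",
         "af_reference", "af_internal", "zygosity", "insilico_score",
         "clinvar_plp", "alsod_publications", "alsod_patients"]
    ]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate one synthetic cohort under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    panel: PanelDefinition = config.panel  # type: ignore[assignment]
    n = config.n_persons
    person_ids = np.array([f"P{i:05d}" for i in range(n)])

    sex = np.where(rng.random(n) < config.sex_ratio, "male", "female")
    age = config.age.draw(n, rng)
    age_group = bin_age_series(pd.Series(age)).to_numpy()

    p = np.array([config.panel_probabilities[g] for g in age_group])
    actionable = rng.random(n) < p

    # Mechanism of each planted actionable result: repeat expansion at one
    # of the two loci, or a rare variant in a weighted panel gene.
    mech = np.full(n, "none", dtype=object)
    idx_act = np.flatnonzero(actionable)
    shares = np.array([
        config.repeat_freqs["C9orf72"],
        config.repeat_freqs["ATXN2"],
        1.0 - sum(config.repeat_freqs.values()),
    ])
    mech_choices = np.array(["repeat_C9orf72", "repeat_ATXN2", "variant"])
    if len(idx_act):
        mech[idx_act] = mech_choices[rng.choice(3, size=len(idx_act), p=shares)]

    truth_gene = np.full(n, "", dtype=object)
    truth_gene[mech == "repeat_C9orf72"] = "C9orf72"
    truth_gene[mech == "repeat_ATXN2"] = "ATXN2"

    # Planted variants.
    idx_var = np.flatnonzero(mech == "variant")
    blocks = []
    if len(idx_var):
        gene_names = np.array(sorted(config.gene_weights))
        gene_p = np.array([config.gene_weights[g] for g in gene_names])
        genes = gene_names[rng.choice(len(gene_names), size=len(idx_var), p=gene_p)]
        truth_gene[idx_var] = genes
        recipe_names = np.array(sorted(config.recipe_weights))
        recipe_p = np.array([config.recipe_weights[r] for r in recipe_names])
        recipes = recipe_names[rng.choice(len(recipe_names), size=len(idx_var), p=recipe_p)]
        zyg = np.where(
            [panel.modes[g] == "biallelic_only" for g in genes],
            "homozygous",
            "heterozygous",
        )
        blocks.append(
            _variants_from_recipes(person_ids[idx_var], genes, recipes, zyg, panel, rng)
        )

    # Background variants.
    bg_counts = (
        rng.poisson(config.noise.background_rate, n)
        if config.noise.background_rate > 0
        else np.zeros(n, dtype=int)
    )
    n_bg = int(bg_counts.sum())
    if n_bg:
        owner = np.repeat(np.arange(n), bg_counts)
        mix_names = np.array(sorted(config.noise.background_mix))
        mix_p = np.array([config.noise.background_mix[m] for m in mix_names])
        mix_p = mix_p / mix_p.sum()
        bg_recipes = mix_names[rng.choice(len(mix_names), size=n_bg, p=mix_p)]
        panel_genes = np.array(sorted(panel.genes))
        bg_genes = panel_genes[rng.integers(0, len(panel_genes), size=n_bg)]
        bg_zyg = np.full(n_bg, "heterozygous", dtype=object)
        blocks.append(
            _variants_from_recipes(person_ids[owner], bg_genes, bg_recipes, bg_zyg, panel, rng)
        )

    if blocks:
        variants = pd.concat(blocks, ignore_index=True)
        variants = variants.sort_values(
            ["person_id", "chrom", "pos"], kind="stable"
        ).reset_index(drop=True)
    else:
        variants = _variants_from_recipes(
            np.array([]), np.array([]), np.array([], dtype=object),
            np.array([]), panel, rng,
        )

    # Repeat calls: both loci for every person; planted expansions override
    # the normal-range draws.
    c9 = rng.integers(2, 11, size=n)
    atxn2 = rng.integers(18, ATXN2_RISK_RANGE[0] - 1, size=n)
    c9[mech == "repeat_C9orf72"] = rng.integers(
        35, 80, size=int((mech == "repeat_C9orf72").sum())
    )
    atxn2[mech == "repeat_ATXN2"] = rng.integers(
        ATXN2_RISK_RANGE[0], ATXN2_RISK_RANGE[1] + 1,
        size=int((mech == "repeat_ATXN2").sum()),
    )
    repeats = pd.DataFrame({
        "person_id": np.concatenate([person_ids, person_ids]),
        "gene": ["C9orf72"] * n + ["ATXN2"] * n,
        "repeat_count": np.concatenate([c9, atxn2]),
    }).sort_values(["person_id", "gene"], kind="stable").reset_index(drop=True)

    # Sample metrics with injected QC failure modes.
    reported_sex = sex.copy()
    flip = rng.random(n) < config.noise.sex_mismatch_rate
    reported_sex[flip] = np.where(sex[flip] == "male", "female", "male")
    age_reported = age.copy()
    age_reported[rng.random(n) < config.noise.missing_age_rate] = np.nan
    metrics = pd.DataFrame({
        "person_id": person_ids,
        "titv": rng.normal(2.05, 0.04, n),
        "n_snv": rng.normal(3.6e6, 2.5e4, n).round().astype(int),
        "n_indel": rng.normal(3.7e5, 8e3, n).round().astype(int),
        "n_singleton": np.clip(rng.normal(3200, 300, n), 0, None).round().astype(int),
        "inferred_sex": sex,
        "reported_sex": reported_sex,
        "age_onset": age_reported,
    })

    persons = pd.DataFrame({
        "person_id": person_ids,
        "sex": reported_sex,
        "age_onset": age_reported,
    })
    truth = pd.DataFrame({
        "person_id": person_ids,
        "sex": sex,
        "age_onset": age,
        "age_group": age_group,
        "actionable": actionable,
        "mechanism": mech,
        "gene": truth_gene,
    })
    return Cohort(persons, variants, repeats, metrics, truth, config)


# ---------------------------------------------------------------------------
# Incidence register
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegisterConfig:
    """Conditions for a synthetic age-by-sex incidence register.

    ``strata`` rows are ``(age_group, sex, population, rate_per_100k)``;
    case counts are Poisson with mean rate x person-years / 100 000 over
    ``years`` of observation.  A familial share of each stratum's cases is
    drawn with a fraction uniform in ``familial_fraction_range``.
    """

    strata: tuple[tuple[str, str, float, float], ...]
    years: float = 2.0
    familial_fraction_range: tuple[float, float] = (0.05, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        strata = tuple(tuple(s) for s in self.strata)
        if not strata:
            raise ValueError("register needs at least one stratum")
        for g, s, pop, rate in strata:
            if pop < 0:
                raise ValueError(f"population must be non-negative, got {pop}")
            if rate < 0:
                raise ValueError(f"rate must be non-negative, got {rate}")
        if self.years < 0:
            raise ValueError("years must be non-negative")
        lo, hi = self.familial_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("familial_fraction_range must be ordered within [0, 1]")
        object.__setattr__(self, "strata", strata)

    @classmethod
    def uk_like(
        cls, catchment_population: float = 12.5e6, years: float = 2.0, seed: int = 0
    ) -> "RegisterConfig":
        """Register shaped like the national MND register catchment:
        stratum populations proportional to the census standard population,
        scaled to the catchment total, with the published crude rates."""
        from .incidence import load_uk_incidence

        uk = load_uk_incidence()
        scale = catchment_population / uk["standard_pop"].sum()
        strata = tuple(
            (r["age_group"], r["sex"], r["standard_pop"] * scale, r["rate_per_100k"])
            for _, r in uk.iterrows()
        )
        return cls(strata=strata, years=years, seed=seed)


def generate_register(config: RegisterConfig) -> pd.DataFrame:
    """Draw a register realisation: one row per age-sex stratum."""
    rng = np.random.default_rng(config.seed)
    rows = []
    lo, hi = config.familial_fraction_range
    for age_group, sex, pop, rate in config.strata:
        py = pop * config.years
        mean = rate * py / 100_000.0
        cases = int(rng.poisson(mean)) if mean > 0 else 0
        familial_fraction = rng.uniform(lo, hi)
        familial = int(rng.binomial(cases, familial_fraction)) if cases else 0
        rows.append({
            "age_group": age_group,
            "sex": sex,
            "population": pop,
            "person_years": py,
            "cases": cases,
            "familial_cases": familial,
        })
    return pd.DataFrame(rows)
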