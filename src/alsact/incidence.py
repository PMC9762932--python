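"""Incidence rates, direct standardization, and the missed-case policy model.

Crude incidence in an age-sex stratum is cases per person-years scaled to
100 000.  Direct standardization re-weights stratum rates by a standard
population (here a census population structure), giving expected diagnosis
counts per stratum and year that are comparable across populations.

Confidence intervals for weighted sums of Poisson counts use the exact
gamma method (Fay–Feuer): with per-case weights :math:`w_i` and counts
:math:`d_i`, let :math:`X = \\sum w_i d_i`, :math:`V = \\sum w_i^2 d_i`
and :math:`w_M = \\max_i w_i`; then

* lower bound = the :math:`\\alpha/2` quantile of a gamma distribution with
  shape :math:`X^2/V` and scale :math:`V/X` (0 when no cases);
* upper bound = the :math:`1-\\alpha/2` quantile with shape
  :math:`(X+w_M)^2/(V+w_M^2)` and scale :math:`(V+w_M^2)/(X+w_M)`.

For a single stratum with unit weight this reduces exactly to the Garwood
exact Poisson interval.

Because a register counts both familial and apparently sporadic disease,
and 5–20% of patients report a family history, expected counts are
multiplied by a sporadic factor of 0.875 (the midpoint of 80–95%) to
estimate sporadic-only incidence.

The policy model multiplies the sporadic expected diagnoses per age-sex
stratum by the age-group probability of an actionable genetic result and
sums over the strata at or above the testing age cutoff: with testing
restricted to onset below 40 years, every actionable result in the >=40
strata is missed.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from importlib.resources import files

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import AGE_GROUP_LOWER_BOUNDS, AGE_GROUPS, proportion_ci, round_half_up

PER = 100_000.0


@dataclass(frozen=True)
class PolicyConfig:
    """Parameters of the age-restricted testing policy model.

    ``sporadic_factor`` scales all-ALS incidence to sporadic-only (default
    0.875); ``age_cutoff`` is the onset age below which testing is offered
    (default 40 years, which must sit on an age-group boundary);
    ``ci_level`` is the confidence level for intervals.
    """

    sporadic_factor: float = 0.875
    age_cutoff: float = 40.0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.sporadic_factor <= 1.0:
            raise ValueError("sporadic_factor must be in [0, 1]")
        boundaries = set(AGE_GROUP_LOWER_BOUNDS.values()) | {float("inf")}
        if float(self.age_cutoff) not in boundaries:
            raise ValueError(
                f"age_cutoff must coincide with an age-group boundary, got"
                f" {self.age_cutoff}"
            )


def crude_rate(cases: float, person_years: float) -> float:
    """Crude incidence per 100 000 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    return PER * cases / person_years


def expected_count(rate_per_100k: float, standard_pop: float) -> float:
    """Expected diagnoses per year in a standard population at a given rate."""
    return rate_per_100k * standard_pop / PER


def sporadic_adjust(x, config: PolicyConfig | None = None):
    """Scale an incidence quantity to its sporadic-only share."""
    factor = (config or PolicyConfig()).sporadic_factor
    return np.asarray(x) * factor if np.ndim(x) else float(x) * factor


def gamma_ci(weights, cases, level: float = 0.95) -> tuple[float, float]:
    """Exact gamma (Fay–Feuer) CI for a weighted sum of Poisson counts."""
    w = np.asarray(weights, dtype=float)
    d = np.asarray(cases, dtype=float)
    if w.size == 0:
        raise ValueError("gamma_ci needs at least one stratum")
    if (w < 0).any() or (d < 0).any():
        raise ValueError("weights and cases must be non-negative")
    alpha = 1.0 - level
    x = float((w * d).sum())
    v = float((w**2 * d).sum())
    w_m = float(w.max())
    lower = 0.0 if x == 0 else float(
        sps.gamma.ppf(alpha / 2, a=x**2 / v, scale=v / x)
    )
    xu, vu = x + w_m, v + w_m**2
    upper = float(sps.gamma.ppf(1 - alpha / 2, a=xu**2 / vu, scale=vu / xu))
    return lower, upper


def standardized_rate(
    register: pd.DataFrame, level: float = 0.95
) -> dict[str, float]:
    """Directly standardized incidence per 100 000 person-years with gamma CI.

    ``register`` needs ``cases``, ``person_years`` and ``standard_pop``
    columns (one row per age-sex stratum).  When the standard population is
    proportional to the study person-years, the standardized rate equals
    the crude overall rate.
    """
    if len(register) == 0:
        raise ValueError("register must have at least one stratum")
    py = register["person_years"].to_numpy(float)
    if (py <= 0).any():
        raise ValueError("person_years must be positive in every stratum")
    d = register["cases"].to_numpy(float)
    std = register["standard_pop"].to_numpy(float)
    weights = PER * std / (py * std.sum())
    rate = float((weights * d).sum())
    lo, hi = gamma_ci(weights, d, level=level)
    return {"rate": rate, "ci_lower": lo, "ci_upper": hi}


def stratum_expected(
    register: pd.DataFrame,
    config: PolicyConfig | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-stratum crude rates and sporadic-adjusted expected annual counts.

    Reproduces the shape of an age-by-sex incidence report: crude rate per
    100 000 person-years with gamma CI, and the expected number of new
    sporadic diagnoses per year in the standard population, with the CI
    scaled by the same per-case weight.
    """
    cfg = config or PolicyConfig()
    rows = []
    for _, r in register.iterrows():
        rate = crude_rate(r["cases"], r["person_years"])
        rate_lo, rate_hi = gamma_ci([PER / r["person_years"]], [r["cases"]], level)
        w = cfg.sporadic_factor * r["standard_pop"] / r["person_years"]
        exp_lo, exp_hi = gamma_ci([w], [r["cases"]], level)
        rows.append({
            "age_group": r["age_group"],
            "sex": r["sex"],
            "cases": r["cases"],
            "person_years": r["person_years"],
            "rate": rate,
            "rate_ci_lower": rate_lo,
            "rate_ci_upper": rate_hi,
            "expected_sporadic_per_year": w * r["cases"],
            "expected_ci_lower": exp_lo,
            "expected_ci_upper": exp_hi,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MissedResult:
    """Output of the age-restriction policy estimator (per year)."""

    missed: float
    total: float
    proportion: float
    ci: tuple[float, float]
    missed_rounded: int
    total_rounded: int
    per_sex: Mapping[str, dict[str, float]]

    def __post_init__(self) -> None:
        if not 0 <= self.missed <= self.total + 1e-12:
            raise ValueError("missed must lie in [0, total]")


def _probability_for(probabilities: Mapping, age_group: str, sex: str) -> float:
    if (age_group, sex) in probabilities:
        p = probabilities[(age_group, sex)]
    elif age_group in probabilities:
        p = probabilities[age_group]
    else:
        raise ValueError(f"no actionable probability for age group {age_group!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability for {age_group!r} outside [0, 1]: {p}")
    return float(p)


def missed_estimate(
    expected: pd.DataFrame,
    probabilities: Mapping,
    config: PolicyConfig | None = None,
) -> MissedResult:
    """Expected actionable results missed per year by an age cutoff.

    ``expected`` holds sporadic expected diagnoses per year per stratum
    (columns ``age_group``, ``sex``, ``expected_sporadic_per_year``);
    ``probabilities`` maps an age group (or ``(age_group, sex)`` pair) to
    the probability of an actionable genetic result.  ``missed`` sums
    expected x probability over strata at or above the cutoff, ``total``
    over all strata.  The CI on the missed proportion is a Wald binomial
    interval on the half-up-rounded counts.
    """
    cfg = config or PolicyConfig()
    missed = total = 0.0
    per_sex: dict[str, dict[str, float]] = {}
    for _, row in expected.iterrows():
        g, s = row["age_group"], row["sex"]
        if g not in AGE_GROUPS:
            raise ValueError(f"unknown age group {g!r}")
        e = float(row["expected_sporadic_per_year"])
        contribution = e * _probability_for(probabilities, g, s)
        total += contribution
        bucket = per_sex.setdefault(s, {"missed": 0.0, "total": 0.0})
        bucket["total"] += contribution
        if AGE_GROUP_LOWER_BOUNDS[g] >= cfg.age_cutoff:
            missed += contribution
            bucket["missed"] += contribution
    if total == 0:
        return MissedResult(0.0, 0.0, 0.0, (0.0, 0.0), 0, 0, per_sex)
    k = int(round_half_up(missed))
    n = int(round_half_up(total))
    if n >= 1:
        _, lo, hi = proportion_ci(min(k, n), n, level=cfg.ci_level)
    else:
        lo = hi = 0.0
    return MissedResult(
        missed=missed,
        total=total,
        proportion=missed / total,
        ci=(lo, hi),
        missed_rounded=k,
        total_rounded=n,
        per_sex=per_sex,
    )


def load_uk_incidence() -> pd.DataFrame:
    """UK age-by-sex ALS incidence, 2018–2019 (national register, printed).

    Returns crude rates per 100 000 person-years and expected sporadic
    diagnoses per year in the census-standard population, with a derived
    ``standard_pop`` column back-computed from rate, expected count and the
    0.875 sporadic factor.
    """
    resource = files("alsact") / "data" / "uk_incidence_2018_2019.tsv"
    with resource.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["standard_pop"] = (
        df["expected_sporadic_per_year"] * PER / (df["rate_per_100k"] * 0.875)
    )
    return df
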