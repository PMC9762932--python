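"""Age binning and diagnostic-yield proportions with confidence intervals.

Persons are grouped by age of disease onset into five left-closed bins —
<40, 40–49, 50–59, 60–69, >=70 years — and the proportion carrying a
clinically actionable result is estimated per bin with a 95% Wald interval
p ± z·sqrt(p(1−p)/n).  The Wald interval is deliberately *not* clipped to
[0, 1]: near-certain proportions legitimately print upper bounds above 1
(e.g. 115/117 -> 0.96–1.01).  An exact Clopper–Pearson alternative is
available via ``method="clopper-pearson"``.

Rounding is presentation-only (half-up), never applied to stored values.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

#: The five age-of-onset groups, youngest to oldest.
AGE_GROUPS: tuple[str, ...] = ("<40", "40-49", "50-59", "60-69", ">=70")

#: Left edges of the age bins (left-closed; onset age 40 falls in 40–49).
AGE_GROUP_LOWER_BOUNDS: dict[str, float] = {
    "<40": 0.0, "40-49": 40.0, "50-59": 50.0, "60-69": 60.0, ">=70": 70.0,
}

_BIN_EDGES = np.array([0.0, 40.0, 50.0, 60.0, 70.0, np.inf])


def bin_age(age_onset: float) -> str:
    """Age group of an onset age in years (left-closed decade bins)."""
    if age_onset < 0:
        raise ValueError(f"age of onset must be non-negative, got {age_onset}")
    idx = int(np.searchsorted(_BIN_EDGES, age_onset, side="right")) - 1
    return AGE_GROUPS[idx]


def bin_age_series(ages: pd.Series) -> pd.Series:
    if (ages.dropna() < 0).any():
        raise ValueError("age of onset must be non-negative")
    binned = pd.cut(ages, _BIN_EDGES, right=False, labels=AGE_GROUPS)
    return binned.astype(object).rename("age_group")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (3.5 -> 4), for presentation only."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float, float]:
    """Binomial proportion and confidence interval.

    Returns ``(p, lower, upper)`` at full precision.  The default Wald
    interval is not clipped to [0, 1]; at p = 0 or 1 it degenerates to a
    point.  ``method="clopper-pearson"`` gives the exact interval.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    p = k / n
    if method == "wald":
        z = sps.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(p * (1 - p) / n)
        return p, p - half, p + half
    if method == "clopper-pearson":
        ci = sps.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
        return p, float(ci.low), float(ci.high)
    raise ValueError(f"unknown CI method: {method!r}")


def yield_table(
    persons: pd.DataFrame,
    actionability: pd.DataFrame,
    stratify_by_sex: bool = False,
    level: float = 0.95,
    method: str = "wald",
) -> pd.DataFrame:
    """Tabulate actionable-result proportions by age group (and sex).

    ``persons`` needs ``person_id``, ``age_onset`` and (if stratifying)
    ``sex``; ``actionability`` is a frame indexed by person_id with
    ``actionable`` and ``panel`` columns, as produced by
    :func:`alsact.panels.actionability_frame`.  Every person must have an
    age of onset (ageless samples are removed by sample QC upstream).
    """
    if persons["age_onset"].isna().any():
        raise ValueError(
            "person without age of onset reached yield_table; sample QC should"
            " have removed it"
        )
    df = persons[["person_id", "age_onset"]].copy()
    if stratify_by_sex:
        df["sex"] = persons["sex"].to_numpy()
    df["age_group"] = bin_age_series(df["age_onset"])
    merged = df.merge(
        actionability[["panel", "actionable"]],
        left_on="person_id",
        right_index=True,
        how="inner",
    )
    keys = ["panel", "age_group"] + (["sex"] if stratify_by_sex else [])
    rows = []
    for key, grp in merged.groupby(keys, sort=False):
        n = len(grp)
        k = int(grp["actionable"].sum())
        p, lo, hi = proportion_ci(k, n, level=level, method=method)
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(n=n, k=k, p=p, ci_lower=lo, ci_upper=hi)
        rows.append(row)
    out = pd.DataFrame(rows)
    order = {g: i for i, g in enumerate(AGE_GROUPS)}
    return out.sort_values(
        keys, key=lambda s: s.map(order) if s.name == "age_group" else s
    ).reset_index(drop=True)
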