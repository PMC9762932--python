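"""Crude/standardized incidence, gamma CIs, and the missed-case estimator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from alsact.incidence import (
    PolicyConfig,
    crude_rate,
    expected_count,
    gamma_ci,
    load_uk_incidence,
    missed_estimate,
    sporadic_adjust,
    standardized_rate,
    stratum_expected,
)
from alsact.stats import round_half_up


class TestCrudeRate:
    @pytest.mark.parametrize(
        "cases,py,expected", [(0, 1e6, 0.0), (10, 5e5, 2.0), (20, 1e6, 2.0)]
    )
    def test_rate_per_100k(self, cases, py, expected):
        assert crude_rate(cases, py) == pytest.approx(expected)

    def test_zero_person_years_rejected(self):
        with pytest.raises(ValueError):
            crude_rate(1, 0)


class TestExpectedCount:
    def test_examples(self):
        assert expected_count(2.0, 100_000) == pytest.approx(2.0)
        assert expected_count(0.0, 5e6) == 0.0

    def test_stratum_sum_equals_direct_standardization_total(self):
        rng = np.random.default_rng(1)
        reg = pd.DataFrame({
            "cases": rng.integers(0, 50, 6),
            "person_years": rng.uniform(1e5, 1e6, 6),
            "standard_pop": rng.uniform(1e5, 1e6, 6),
        })
        rates = 1e5 * reg["cases"] / reg["person_years"]
        total_expected = sum(
            expected_count(r, s) for r, s in zip(rates, reg["standard_pop"])
        )
        std = standardized_rate(reg)
        assert std["rate"] * reg["standard_pop"].sum() / 1e5 == pytest.approx(
            total_expected, rel=1e-12
        )


class TestGammaCI:
    def test_single_stratum_matches_poisson_exact(self):
        """Unit-weight gamma CI agrees with the Garwood exact Poisson
        interval (chi-square closed form) within 1% at d = 100."""
        d = 100
        lo, hi = gamma_ci([1.0], [d])
        garwood_lo = sps.chi2.ppf(0.025, 2 * d) / 2
        garwood_hi = sps.chi2.ppf(0.975, 2 * (d + 1)) / 2
        assert lo == pytest.approx(garwood_lo, rel=0.01)
        assert hi == pytest.approx(garwood_hi, rel=0.01)

    def test_zero_counts_lower_bound_zero_upper_positive(self):
        lo, hi = gamma_ci([0.5, 1.0, 2.0], [0, 0, 0])
        assert lo == 0.0 and hi > 0.0

    def test_empty_strata_rejected(self):
        with pytest.raises(ValueError):
            gamma_ci([], [])

    def test_monte_carlo_coverage_near_nominal(self):
        """Over simulated multi-stratum registers the 95% gamma CI covers
        the true weighted rate in 93-97% of replicates."""
        rng = np.random.default_rng(2024)
        weights = np.array([3.0, 1.5, 1.0, 0.8, 2.0, 1.2])
        means = np.array([12.0, 30.0, 55.0, 80.0, 40.0, 25.0])
        truth = float((weights * means).sum())
        reps = 2000
        covered = 0
        draws = rng.poisson(means, size=(reps, len(means)))
        for d in draws:
            lo, hi = gamma_ci(weights, d)
            covered += lo <= truth <= hi
        assert 0.93 <= covered / reps <= 0.97


class TestStandardization:
    def test_self_standardization_reproduces_crude_rate(self):
        """Using the study population as its own standard, the directly
        standardized rate equals the crude overall rate (10 sig digits)."""
        rng = np.random.default_rng(9)
        reg = pd.DataFrame({
            "cases": rng.integers(1, 80, 10),
            "person_years": rng.uniform(2e5, 2e6, 10),
        })
        reg["standard_pop"] = reg["person_years"]
        std = standardized_rate(reg)
        crude = 1e5 * reg["cases"].sum() / reg["person_years"].sum()
        assert std["rate"] == pytest.approx(crude, rel=1e-10)


class TestSporadicAdjust:
    def test_factor(self):
        assert sporadic_adjust(100.0) == pytest.approx(87.5)
        assert sporadic_adjust(0.0) == 0.0

    def test_linearity(self):
        cfg = PolicyConfig()
        a, b = 3.7, 11.2
        assert sporadic_adjust(a, cfg) + sporadic_adjust(b, cfg) == pytest.approx(
            sporadic_adjust(a + b, cfg)
        )


def _uk_expected():
    uk = load_uk_incidence()
    return uk[["age_group", "sex", "expected_sporadic_per_year"]]


def _uk_probabilities():
    """Actionable probabilities: published youngest/oldest values with the
    mid-range value implied by the published missed-case total."""
    uk = _uk_expected()
    by_group = uk.groupby("age_group")["expected_sporadic_per_year"].sum()
    oldest = by_group[">=70"] * 0.17
    middle = by_group[["40-49", "50-59", "60-69"]].sum()
    p_mid = (115.0 - oldest) / middle
    return {"<40": 0.23, "40-49": p_mid, "50-59": p_mid, "60-69": p_mid,
            ">=70": 0.17}


class TestMissedEstimate:
    def test_zero_probability_above_cutoff_misses_nothing(self):
        probs = {"<40": 0.2, "40-49": 0.0, "50-59": 0.0, "60-69": 0.0,
                 ">=70": 0.0}
        result = missed_estimate(_uk_expected(), probs)
        assert result.missed == 0.0
        assert result.total > 0

    def test_cutoff_below_youngest_group_misses_everything(self):
        result = missed_estimate(
            _uk_expected(), _uk_probabilities(), PolicyConfig(age_cutoff=0.0)
        )
        assert result.proportion == pytest.approx(1.0)

    def test_raising_the_cutoff_never_increases_missed(self):
        probs = _uk_probabilities()
        missed = [
            missed_estimate(_uk_expected(), probs,
                            PolicyConfig(age_cutoff=c)).missed
            for c in (0.0, 40.0, 50.0, 60.0, 70.0)
        ]
        assert all(a >= b for a, b in zip(missed, missed[1:]))

    def test_invalid_probability_rejected(self):
        probs = dict.fromkeys(
            ["<40", "40-49", "50-59", "60-69", ">=70"], 1.5
        )
        with pytest.raises(ValueError, match="outside"):
            missed_estimate(_uk_expected(), probs)

    def test_cutoff_off_boundary_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            PolicyConfig(age_cutoff=45.0)

    def test_published_missed_counts_reproduced_within_one(self):
        """The UK register arithmetic: expected sporadic diagnoses per
        age-sex stratum times actionable probabilities give ~115 of ~117
        actionable results missed per year under a <40y testing cutoff
        (+/-1 for rounding ambiguity), with proportion 0.98 (0.96-1.01)."""
        result = missed_estimate(_uk_expected(), _uk_probabilities())
        assert abs(result.missed_rounded - 115) <= 1
        assert abs(result.total_rounded - 117) <= 1
        assert round_half_up(result.proportion, 2) == 0.98
        assert round_half_up(result.ci[0], 2) == 0.96
        assert round_half_up(result.ci[1], 2) == 1.01

    def test_per_sex_breakdown_sums_to_totals(self):
        result = missed_estimate(_uk_expected(), _uk_probabilities())
        assert sum(v["missed"] for v in result.per_sex.values()) == pytest.approx(
            result.missed
        )
        assert sum(v["total"] for v in result.per_sex.values()) == pytest.approx(
            result.total
        )


class TestStratumExpected:
    def test_reproduces_register_shape_and_scaling(self):
        reg = pd.DataFrame({
            "age_group": ["<40", "40-49"],
            "sex": ["male", "male"],
            "cases": [4, 40],
            "person_years": [1e6, 2e6],
            "standard_pop": [5e5, 1e6],
        })
        out = stratum_expected(reg)
        assert out.loc[0, "rate"] == pytest.approx(0.4)
        # expected = sporadic_factor * rate * std_pop / 1e5
        assert out.loc[0, "expected_sporadic_per_year"] == pytest.approx(
            0.875 * 0.4 * 5e5 / 1e5
        )
        assert (out["expected_ci_lower"] <= out["expected_sporadic_per_year"]).all()
        assert (out["expected_ci_upper"] >= out["expected_sporadic_per_year"]).all()
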