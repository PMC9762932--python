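"""Synthetic cohort and register generators: determinism, planted structure,
marginal distributions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import alsact as A
from alsact.simulate import RegisterConfig, UK_PANEL_PROBABILITIES
from alsact.stats import AGE_GROUPS

FLAT = dict.fromkeys(AGE_GROUPS, 0.2)
ZERO = dict.fromkeys(AGE_GROUPS, 0.0)


class TestCohortConfig:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            A.CohortConfig(panel_probabilities=dict.fromkeys(AGE_GROUPS, 1.2))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            A.CohortConfig(n_persons=0)

    def test_age_groups_must_match_exactly(self):
        with pytest.raises(ValueError, match="age groups"):
            A.CohortConfig(panel_probabilities={"<40": 0.2})

    def test_gene_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            A.CohortConfig(gene_weights={"SOD1": 0.5})


class TestGenerateCohort:
    def test_same_seed_gives_identical_tables(self):
        a = A.generate_cohort(A.CohortConfig(n_persons=150, seed=3))
        b = A.generate_cohort(A.CohortConfig(n_persons=150, seed=3))
        for name in ("persons", "variants", "repeats", "metrics", "truth"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_different_seed_differs(self):
        a = A.generate_cohort(A.CohortConfig(n_persons=150, seed=3))
        b = A.generate_cohort(A.CohortConfig(n_persons=150, seed=4))
        assert not a.truth["actionable"].equals(b.truth["actionable"])

    def test_truth_never_leaks_into_pipeline_tables(self):
        cohort = A.generate_cohort(A.CohortConfig(n_persons=50, seed=1))
        for frame in (cohort.variants, cohort.metrics, cohort.repeats):
            assert "actionable" not in frame.columns
            assert "mechanism" not in frame.columns

    def test_zero_probability_zero_noise_yields_no_actionable_person(self):
        cfg = A.CohortConfig(
            n_persons=200, seed=2, panel_probabilities=ZERO,
            noise=A.NoiseConfig.zero(),
        )
        cohort = A.generate_cohort(cfg)
        res = A.classify_cohort(
            cohort.variants, cohort.metrics, cohort.repeats,
            [A.load_panel("genomics_england")],
        )
        assert not res.actionability["genomics_england"]["actionable"].any()
        assert not cohort.truth["actionable"].any()

    def test_planted_fraction_matches_binomial_oracle(self):
        """Mean realized actionable fraction over 200 seeds is within 3
        binomial standard errors of the flat planting probability."""
        n, p, seeds = 1000, 0.2, 200
        fractions = []
        for seed in range(seeds):
            cfg = A.CohortConfig(
                n_persons=n, seed=seed, panel_probabilities=FLAT,
                noise=A.NoiseConfig.zero(),
            )
            fractions.append(A.generate_cohort(cfg).truth["actionable"].mean())
        se = np.sqrt(p * (1 - p) / (n * seeds))
        assert abs(np.mean(fractions) - p) < 3 * se

    def test_uk_probabilities_recovered_by_pipeline(self):
        """With the UK-like defaults (0.23 youngest ... 0.17 oldest), the
        pipeline's estimated group proportions, averaged over seeds, match
        the planted probabilities within Monte-Carlo error."""
        panel = A.load_panel("genomics_england")
        seeds = 25
        sums = {g: [] for g in AGE_GROUPS}
        for seed in range(seeds):
            cohort = A.generate_cohort(A.CohortConfig(seed=seed))
            res = A.classify_cohort(
                cohort.variants, cohort.metrics, cohort.repeats, [panel]
            )
            table = A.yield_table(res.persons, res.actionability[panel.name])
            for _, row in table.iterrows():
                sums[row["age_group"]].append((row["p"], row["n"]))
        for group, observations in sums.items():
            p_true = UK_PANEL_PROBABILITIES[group]
            mean_p = np.mean([p for p, _ in observations])
            mean_n = np.mean([n for _, n in observations])
            se = np.sqrt(p_true * (1 - p_true) / (mean_n * len(observations)))
            assert abs(mean_p - p_true) < 4 * se, group

    def test_marginals_match_config(self):
        """Chi-square goodness of fit on age-group counts and binomial
        checks on sex and actionable margins, across seeds."""
        cfg0 = A.CohortConfig(n_persons=2000, panel_probabilities=FLAT,
                              noise=A.NoiseConfig.zero())
        dist = cfg0.age
        a = (dist.min_age - dist.mean) / dist.sd
        b = (dist.max_age - dist.mean) / dist.sd
        tn = sps.truncnorm(a, b, loc=dist.mean, scale=dist.sd)
        edges = [dist.min_age, 40, 50, 60, 70, dist.max_age]
        expected_p = np.diff([tn.cdf(e) for e in edges])
        passes = 0
        seeds = 20
        for seed in range(seeds):
            truth = A.generate_cohort(cfg0.with_seed(seed)).truth
            counts = truth["age_group"].value_counts().reindex(AGE_GROUPS,
                                                               fill_value=0)
            gof = sps.chisquare(counts, expected_p * len(truth))
            passes += gof.pvalue > 0.01
            # sex and planted-carrier margins within 4 SE
            assert abs((truth["sex"] == "male").mean() - 0.6) < 4 * np.sqrt(
                0.6 * 0.4 / len(truth))
            assert abs(truth["actionable"].mean() - 0.2) < 4 * np.sqrt(
                0.2 * 0.8 / len(truth))
        assert passes >= seeds - 2

    def test_als2_planted_variants_are_homozygous(self):
        weights = dict.fromkeys(["ALS2"], 1.0)
        cfg = A.CohortConfig(
            n_persons=300, seed=8, panel_probabilities=FLAT,
            gene_weights=weights, repeat_freqs={},
            noise=A.NoiseConfig.zero(),
        )
        cohort = A.generate_cohort(cfg)
        assert len(cohort.variants) > 0
        assert (cohort.variants["zygosity"] == "homozygous").all()


class TestGenerateRegister:
    def _config(self, rate, pop=500_000, years=2.0, seed=0):
        return RegisterConfig(
            strata=(("50-59", "male", pop, rate),), years=years, seed=seed
        )

    def test_zero_rate_zero_cases(self):
        reg = A.generate_register(self._config(0.0))
        assert reg["cases"].tolist() == [0]

    def test_zero_years_zero_person_years_and_cases(self):
        reg = A.generate_register(self._config(2.0, years=0.0))
        assert reg["person_years"].tolist() == [0.0]
        assert reg["cases"].tolist() == [0]

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            self._config(-1.0)

    def test_case_counts_follow_poisson_mean(self):
        """population 500k, rate 2/100k, 2 years -> mean cases ~ 20 within
        3 standard errors over 1000 seeds."""
        counts = [
            A.generate_register(self._config(2.0, seed=s))["cases"].iloc[0]
            for s in range(1000)
        ]
        se = np.sqrt(20 / 1000)
        assert abs(np.mean(counts) - 20.0) < 3 * se

    def test_deterministic_given_seed(self):
        cfg = RegisterConfig.uk_like(seed=6)
        pd.testing.assert_frame_equal(
            A.generate_register(cfg), A.generate_register(cfg)
        )

    def test_familial_cases_bounded_by_cases(self):
        reg = A.generate_register(RegisterConfig.uk_like(seed=1))
        assert (reg["familial_cases"] <= reg["cases"]).all()
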