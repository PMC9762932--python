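import pytest

import alsact as A


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free planted cohort: pipeline output must equal ground truth."""
    cfg = A.CohortConfig(n_persons=400, seed=11, noise=A.NoiseConfig.zero())
    return A.generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    return A.generate_cohort(A.CohortConfig(n_persons=600, seed=5))


@pytest.fixture(scope="session")
def shipped_panels():
    return {
        name: A.load_panel(name)
        for name in ("four_gene", "project_mine", "genomics_england")
    }


@pytest.fixture()
def variant_row():
    """A well-formed rare missense call, mutable per test."""
    def make(**overrides):
        base = dict(
            person_id="P1", gene="SOD1", chrom="21", pos=33032096, ref="G",
            alt="A", variant_class="SNV", consequence_terms="missense_variant",
            site_quality=60.0, genotype_quality=99.0, missingness=0.0,
            af_reference=0.0, af_internal=0.0, zygosity="heterozygous",
            insilico_score=float("nan"), clinvar_plp=False,
            alsod_publications=0, alsod_patients=0,
        )
        base.update(overrides)
        return base
    return make
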