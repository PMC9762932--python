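"""ACMG engine: automatic evaluators, fixed-value overlay, combining table."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alsact.acmg import (
    ALL_CRITERIA,
    BENIGN_CRITERIA,
    CLASSES,
    PATHOGENIC_CRITERIA,
    AcmgConfig,
    AcmgResult,
    EvidenceProfile,
    FixedCriteriaProfile,
    auto_evidence,
    classify,
    classify_frame,
    combine,
    merge_fixed,
    merge_fixed_frame,
    stratify_vus,
)

from acmg_oracle import oracle_class

CFG = AcmgConfig(lof_genes=frozenset({"SOD1", "TBK1"}))


def _variant(**overrides):
    base = dict(
        gene="SOD1", impact="moderate", consequence_terms="missense_variant",
        af_reference=0.0, af_internal=0.0, insilico_score=float("nan"),
    )
    base.update(overrides)
    return base


class TestEvidenceProfile:
    def test_has_exactly_28_criteria(self):
        assert len(ALL_CRITERIA) == 28
        assert len(PATHOGENIC_CRITERIA) == 16
        assert len(BENIGN_CRITERIA) == 12

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError, match="unknown ACMG"):
            EvidenceProfile.from_active(["PVS2"])

    def test_counts(self):
        e = EvidenceProfile.from_active(["PVS1", "PM1", "PM2", "BP4"])
        assert e.counts() == dict(pvs=1, ps=0, pm=2, pp=0, ba=0, bs=0, bp=1)
        assert e.n_pathogenic == 3 and e.n_benign == 1


class TestAutoEvidence:
    def test_lof_variant_in_lof_gene_sets_pvs1_and_pm2(self):
        e = auto_evidence(
            _variant(impact="high", consequence_terms="frameshift_variant"), CFG
        )
        assert set(e.active()) == {"PVS1", "PM2"}

    def test_high_impact_outside_lof_list_no_pvs1(self):
        e = auto_evidence(
            _variant(gene="ANG", impact="high",
                     consequence_terms="frameshift_variant"),
            CFG,
        )
        assert "PVS1" not in e.active()

    def test_common_variant_sets_ba1(self):
        e = auto_evidence(_variant(af_reference=0.06, af_internal=0.06), CFG)
        assert "BA1" in e.active() and "BS1" in e.active()
        assert "PM2" not in e.active()

    def test_pm2_requires_rarity_in_both_sets(self):
        e = auto_evidence(_variant(af_reference=0.0, af_internal=5e-4), CFG)
        assert "PM2" not in e.active()

    def test_pm4_from_protein_length_change(self):
        e = auto_evidence(
            _variant(impact="high", consequence_terms="stop_lost"), CFG
        )
        assert "PM4" in e.active()

    def test_missing_score_leaves_computational_criteria_false(self):
        e = auto_evidence(_variant(), CFG)
        assert set(e.active()) == {"PM2"}

    @pytest.mark.parametrize(
        "score,expected", [(0.9, "PP3"), (0.1, "BP4")]
    )
    def test_insilico_score_cuts(self, score, expected):
        e = auto_evidence(_variant(insilico_score=score, af_reference=5e-4,
                                   af_internal=5e-4), CFG)
        assert set(e.active()) == {expected}


class TestMergeFixed:
    def test_forced_value_overrides_auto(self):
        fixed = FixedCriteriaProfile("t", {"moderate": {"PP2": True}})
        merged = merge_fixed(EvidenceProfile.from_active([]), fixed, "moderate")
        assert merged.flags["PP2"] is True

    def test_all_auto_keeps_evaluator_output(self):
        merged = merge_fixed(
            EvidenceProfile.from_active([]), FixedCriteriaProfile.conservative(),
            "high",
        )
        assert merged.active() == ()

    def test_fixed_values_keyed_by_impact_class(self):
        fixed = FixedCriteriaProfile("t", {"high": {"PM1": True}})
        merged = merge_fixed(EvidenceProfile.from_active([]), fixed, "moderate")
        assert merged.flags["PM1"] is False

    def test_unknown_criterion_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="unknown ACMG criterion"):
            FixedCriteriaProfile("t", {"high": {"PXX": True}})

    def test_frame_and_scalar_merge_agree(self):
        fixed = FixedCriteriaProfile("t", {"high": {"PP5": True},
                                           "moderate": {"BP1": True}})
        ev = pd.DataFrame(False, index=range(2), columns=list(ALL_CRITERIA))
        impact = pd.Series(["high", "moderate"])
        merged = merge_fixed_frame(ev, fixed, impact)
        assert merged.loc[0, "PP5"] and not merged.loc[0, "BP1"]
        assert merged.loc[1, "BP1"] and not merged.loc[1, "PP5"]


class TestCombine:
    @pytest.mark.parametrize(
        "active,expected",
        [
            ([], "vus"),
            (["BA1"], "benign"),
            (["PVS1", "PM2"], "likely_pathogenic"),
            (["PVS1", "PS1"], "pathogenic"),
            (["PVS1", "PM2", "PM4"], "pathogenic"),
            (["BS1", "BS2"], "benign"),
            (["BS1", "BP4"], "likely_benign"),
            (["BP4", "BP7"], "likely_benign"),
            (["PS1", "BS1", "BS2"], "vus"),  # contradiction
            (["PM2"], "vus"),
        ],
    )
    def test_published_table_examples(self, active, expected):
        assert combine(EvidenceProfile.from_active(active)) == expected

    def test_exhaustive_up_to_three_active_flags_matches_oracle(self):
        for r in range(4):
            for combo in itertools.combinations(ALL_CRITERIA, r):
                e = EvidenceProfile.from_active(combo)
                assert combine(e) == oracle_class(frozenset(combo)), combo

    def test_frame_classification_matches_scalar(self):
        rng = np.random.default_rng(0)
        profiles = [
            tuple(np.array(ALL_CRITERIA)[rng.random(28) < 0.15])
            for _ in range(300)
        ]
        ev = pd.DataFrame(
            [[c in p for c in ALL_CRITERIA] for p in profiles],
            columns=list(ALL_CRITERIA),
        )
        out = classify_frame(ev)
        for i, p in enumerate(profiles):
            e = EvidenceProfile.from_active(p)
            c = combine(e)
            assert out.loc[i, "acmg_class"] == c
            assert out.loc[i, "vus_subclass"] == stratify_vus(e, c)


class TestStratifyVus:
    def test_pathogenic_only_evidence_gives_high(self):
        e = EvidenceProfile.from_active(["PM2"])
        assert stratify_vus(e, "vus") == "high"

    def test_any_benign_evidence_gives_low_medium(self):
        e = EvidenceProfile.from_active(["PM2", "BP4"])
        assert stratify_vus(e, "vus") == "low_medium"

    def test_non_vus_not_applicable(self):
        e = EvidenceProfile.from_active(["PVS1", "PM2"])
        assert stratify_vus(e, "likely_pathogenic") == "not_applicable"

    def test_result_invariant_enforced(self):
        with pytest.raises(ValueError):
            AcmgResult("pathogenic", "high", EvidenceProfile.from_active([]))


@st.composite
def _profiles(draw):
    active = draw(st.sets(st.sampled_from(ALL_CRITERIA), max_size=8))
    return EvidenceProfile.from_active(active)


@given(_profiles(), st.sampled_from(PATHOGENIC_CRITERIA))
@settings(max_examples=300, derandomize=True)
def test_adding_pathogenic_evidence_never_moves_class_toward_benign(e, crit):
    order = {c: i for i, c in enumerate(CLASSES)}
    before = combine(e)
    after = combine(e.replace(**{crit: True}))
    assert order[after] >= order[before]


@given(_profiles())
@settings(max_examples=300, derandomize=True)
def test_high_probability_vus_implies_pathogenic_evidence(e):
    result = classify(e)
    if result.vus_subclass == "high":
        assert e.n_pathogenic >= 1 and e.n_benign == 0
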