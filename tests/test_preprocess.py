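"""Reference-cause encoding, multi-cause construction, imputation,
exclusion, grouping and raw-CSMF aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vacalibration import (
    PairedRecord,
    SurveyRecord,
    contingency_to_paired,
    eava_multicause,
    encode_mits,
    exclude_sites,
    impute_paired_inconclusive,
    impute_survey_inconclusive,
    load_fixture,
    plurality_rule,
    raw_csmf,
)
from vacalibration.preprocess import PreprocessConfig, group_composition
from vacalibration.types import CauseList, children_causes


class TestEncodeMits:
    def test_two_distinct_causes_get_half_each(self, cl3):
        x = encode_mits("cause_2", "cause_1", cl3)
        assert np.array_equal(x, [0.5, 0.5, 0.0])

    def test_same_cause_twice_is_one_hot(self, cl3):
        assert np.array_equal(encode_mits("cause_3", "cause_3", cl3),
                              [0, 0, 1.0])

    def test_absent_immediate_is_one_hot(self, cl3):
        assert np.array_equal(encode_mits("cause_1", None, cl3), [1.0, 0, 0])

    def test_unknown_cause_rejected(self, cl3):
        with pytest.raises(KeyError):
            encode_mits("nonsense", None, cl3)


class TestPluralityAndRank:
    def test_plurality_picks_max_and_breaks_ties_low(self):
        assert plurality_rule(np.array([0.2, 0.2, 0.6])) == 2
        assert plurality_rule(np.array([0.5, 0.5, 0.0])) == 0
        assert plurality_rule(np.array([0.0, 1.0, 0.0])) == 1

    @pytest.mark.parametrize("first,second,w,expected", [
        ("cause_2", "cause_3", 0.75, [0.0, 0.75, 0.25]),
        ("cause_1", "cause_2", 1.0, [1.0, 0.0, 0.0]),
        ("cause_1", "cause_3", 0.6, [0.6, 0.0, 0.4]),
    ])
    def test_rank_output_construction(self, cl3, first, second, w, expected):
        assert np.allclose(eava_multicause(first, second, w, cl3), expected)

    def test_identical_first_and_second_rejected(self, cl3):
        with pytest.raises(ValueError):
            eava_multicause("cause_1", "cause_1", 0.75, cl3)

    @given(w=st.floats(0.51, 1.0), first=st.integers(0, 2))
    @settings(max_examples=50, deadline=None)
    def test_plurality_recovers_top_cause_for_any_weight(self, w, first):
        cl = CauseList("synthetic", ("cause_1", "cause_2", "cause_3"))
        second = (first + 1) % 3
        y = eava_multicause(cl.causes[first], cl.causes[second], w, cl)
        assert plurality_rule(y) == first

    def test_config_rejects_low_weight(self):
        with pytest.raises(ValueError):
            PreprocessConfig(eava_weight=0.4)


def _survey(id_, y, inconclusive=False):
    return SurveyRecord(id=id_, va={"eava": None if inconclusive else np.asarray(y, float)},
                        inconclusive={"eava": inconclusive})


def _paired(id_, underlying, y, cl, inconclusive=False, site="main"):
    return PairedRecord(
        id=id_, underlying=underlying, immediate=None,
        x=encode_mits(underlying, None, cl),
        va={"eava": None if inconclusive else np.asarray(y, float)},
        inconclusive={"eava": inconclusive}, site=site)


class TestSurveyImputation:
    def test_inconclusive_gets_mean_of_conclusive(self):
        recs = [_survey("a", [1, 0, 0]), _survey("b", [0.5, 0.5, 0]),
                _survey("c", None, inconclusive=True)]
        out = impute_survey_inconclusive(recs, "eava")
        assert np.allclose(out[2].va["eava"], [0.75, 0.25, 0.0])
        assert out[2].imputed["eava"]
        assert np.array_equal(out[0].va["eava"], [1, 0, 0])

    def test_all_conclusive_is_identity(self):
        recs = [_survey("a", [1, 0, 0])]
        assert impute_survey_inconclusive(recs, "eava") == recs

    def test_single_conclusive_record_supplies_its_own_scores(self):
        recs = [_survey("a", [0, 1, 0]), _survey("b", None, inconclusive=True)]
        out = impute_survey_inconclusive(recs, "eava")
        assert np.allclose(out[1].va["eava"], [0, 1, 0])

    def test_zero_conclusive_records_is_an_error(self):
        with pytest.raises(ValueError):
            impute_survey_inconclusive([_survey("a", None, True)], "eava")


class TestPairedImputation:
    def test_row_of_single_cause_matrix_substituted(self, cl3):
        m_single = {"cause_1": np.array([0.6, 0.3, 0.1])}
        recs = [_paired("a", "cause_1", None, cl3, inconclusive=True)]
        out = impute_paired_inconclusive(recs, "eava", cl3, m_single=m_single)
        assert np.allclose(out[0].va["eava"], [0.6, 0.3, 0.1])
        assert out[0].imputed["eava"]

    def test_m_single_computed_from_conclusive_records(self, cl3):
        recs = [
            _paired("a", "cause_1", [1, 0, 0], cl3),
            _paired("b", "cause_1", [0, 1, 0], cl3),
            _paired("c", "cause_1", None, cl3, inconclusive=True),
        ]
        out = impute_paired_inconclusive(recs, "eava", cl3)
        assert np.allclose(out[2].va["eava"], [0.5, 0.5, 0.0])

    def test_identity_matrix_gives_one_hot_at_underlying(self, cl3):
        m_single = {c: np.eye(3)[i] for i, c in enumerate(cl3.causes)}
        recs = [_paired("a", "cause_2", None, cl3, inconclusive=True)]
        out = impute_paired_inconclusive(recs, "eava", cl3, m_single=m_single)
        assert np.array_equal(out[0].va["eava"], [0, 1.0, 0])

    def test_missing_row_for_underlying_cause_names_it(self, cl3):
        recs = [_paired("a", "cause_3", None, cl3, inconclusive=True),
                _paired("b", "cause_1", [1, 0, 0], cl3)]
        with pytest.raises(ValueError, match="cause_3"):
            impute_paired_inconclusive(recs, "eava", cl3)

    def test_no_inconclusive_records_is_a_no_op(self, cl3):
        recs = [_paired("a", "cause_1", [1, 0, 0], cl3)]
        assert impute_paired_inconclusive(recs, "eava", cl3) == recs


class TestExclusionAndAggregation:
    def test_site_exclusion_counts(self, cl3):
        recs = ([_paired(f"s{i}", "cause_1", [1, 0, 0], cl3,
                         site="South Africa") for i in range(274)]
                + [_paired(f"m{i}", "cause_1", [1, 0, 0], cl3)
                   for i in range(340)])
        kept = exclude_sites(recs, ["South Africa"])
        assert len(kept) == 340
        assert exclude_sites(recs, []) == recs
        assert exclude_sites(recs, ["South Africa", "main"]) == []

    def test_raw_csmf_arithmetic(self):
        recs = [_survey("a", [1, 0, 0]), _survey("b", [0.5, 0.5, 0]),
                _survey("c", [0.75, 0.25, 0])]
        agg, q = raw_csmf(recs, "eava")
        assert np.allclose(agg, [2.25, 0.75, 0.0])
        assert np.allclose(q, [0.75, 0.25, 0.0])
        assert agg.sum() == pytest.approx(len(recs))

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError):
            raw_csmf([], "eava")


class TestGrouping:
    def test_grouping_preserves_mass(self):
        cl = children_causes({"meningitis": "other infections",
                              "typhoid fever": "other infections"})
        fine = list(cl.causes) + ["meningitis", "typhoid fever"]
        y = np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.2, 0.1])
        g = group_composition(y, fine, cl)
        assert g.sum() == pytest.approx(1.0)
        assert g[cl.index("other infections")] == pytest.approx(0.4)


class TestContingencyExpansion:
    def test_neonate_table_expands_to_340_records(self):
        t4 = load_fixture("table4")
        recs = contingency_to_paired(t4)
        assert len(recs) == 340
        cl = t4.cause_list
        inf, prem = cl.index("infection"), cl.index("prematurity")
        both = [r for r in recs
                if r.x[inf] == 0.5 and r.x[prem] == 0.5
                and r.underlying == "infection"]
        assert len(both) == 26

    def test_child_table_underlying_row_count(self):
        t3 = load_fixture("table3")
        recs = contingency_to_paired(t3)
        assert len(recs) == 426
        assert sum(r.underlying == "malaria" for r in recs) == 51
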