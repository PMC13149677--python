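"""Formula-level xenobiotic screen, fluorine filter, DBE and heteroatom profiling."""

from fractions import Fraction

import pytest

from chemtrace import FeatureRecord, classify_features, dbe_histogram, filter_fluorinated, heteroatom_summary
from chemtrace.formula import parse_formula
from chemtrace.reference import ReferenceIndex
from chemtrace.xenobiotics import PUTATIVE_XENOBIOTIC, NP_FORMULA_MATCH, PartitionSummary


def formula_feature(fid, formula):
    parsed = parse_formula(formula) if formula is not None else None
    return FeatureRecord(feature_id=fid, annotation_level="formula_only", formula=parsed)


def structure_feature(fid, formula="C6H6"):
    return FeatureRecord(
        feature_id=fid,
        annotation_level="structure",
        formula=parse_formula(formula),
        inchikey="AAAAAAAAAAAAAA-BBBBBBBBBB-N",
    )


@pytest.fixture
def np_index():
    return ReferenceIndex(np_formula_union={"C6H12O6", "C15H10O5"})


class TestClassify:
    def test_membership_on_canonical_strings(self, np_index):
        features = [
            formula_feature("f1", "O6H12C6"),   # non-Hill spelling of a natural formula
            formula_feature("f2", "C8F17KO3S"),
        ]
        result = classify_features(features, np_index)
        calls = {c.feature_id: c.call for c in result.calls}
        assert calls == {"f1": NP_FORMULA_MATCH, "f2": PUTATIVE_XENOBIOTIC}

    def test_structure_features_bypass_screen(self, np_index):
        # structure branch is never screened, even with a formula absent from the union
        result = classify_features([structure_feature("s1", "C99H2"), formula_feature("f1", "C6H12O6")], np_index)
        assert [c.feature_id for c in result.calls] == ["f1"]
        assert result.summary.n_structure == 1

    def test_empty_union_flags_everything(self):
        features = [formula_feature(f"f{i}", "C6H12O6") for i in range(5)]
        result = classify_features(features, ReferenceIndex())
        assert all(c.call == PUTATIVE_XENOBIOTIC for c in result.calls)

    def test_unparseable_formula_goes_to_side_list(self, np_index):
        result = classify_features([formula_feature("f1", None), formula_feature("f2", "C6H12O6")], np_index)
        assert result.unclassifiable == ["f1"]
        assert result.summary.n_unclassifiable == 1
        assert result.summary.n_formula_only == 2

    def test_partition_conservation_on_study(self, study_features, study_index, study):
        result = classify_features(study_features, study_index)
        s = result.summary
        assert s.n_structure + s.n_formula_only == s.n_total
        assert s.n_np_match + s.n_xenobiotic + s.n_unclassifiable == s.n_formula_only
        gt = study.ground_truth
        called_xeno = {c.feature_id for c in result.calls if c.call == PUTATIVE_XENOBIOTIC}
        assert called_xeno == set(gt.xenobiotic_ids)  # sensitivity and specificity 1.0
        called_np = {c.feature_id for c in result.calls if c.call == NP_FORMULA_MATCH}
        assert called_np == set(gt.np_match_ids)


class TestPartitionSummary:
    def test_percent_uses_all_features_denominator(self):
        s = PartitionSummary(
            n_total=24721, n_structure=900, n_formula_only=23821, n_np_match=22634, n_xenobiotic=1187
        )
        assert s.pct_xenobiotic_of_total == 4.8

    def test_half_up_rounding(self):
        # 5/200 of 4000 total = 2.5% exactly at the midpoint -> rounds up
        s = PartitionSummary(n_total=4000, n_structure=0, n_formula_only=4000, n_np_match=3900, n_xenobiotic=100)
        assert s.pct_xenobiotic_of_total == 2.5
        s = PartitionSummary(n_total=1000, n_structure=0, n_formula_only=1000, n_np_match=755, n_xenobiotic=245)
        assert s.pct_xenobiotic_of_total == 24.5

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            PartitionSummary(n_total=10, n_structure=5, n_formula_only=4, n_np_match=4, n_xenobiotic=0)


class TestFluorineFilter:
    def test_retains_fluorinated_xenobiotics_only(self, np_index):
        features = [
            formula_feature("f1", "C8F17KO3S"),   # fluorinated xenobiotic (PFOS potassium salt)
            formula_feature("f2", "C10H14Cl2"),   # xenobiotic, no fluorine
            formula_feature("f3", "C6H12O6"),     # natural formula
        ]
        calls = classify_features(features, np_index).calls
        assert [c.feature_id for c in filter_fluorinated(calls)] == ["f1"]

    def test_planted_fluorinated_subset_recovered(self, study_features, study_index, study):
        calls = classify_features(study_features, study_index).calls
        kept = filter_fluorinated(calls)
        assert [c.feature_id for c in kept] == sorted(study.ground_truth.fluorinated_ids)


class TestDbeHistogram:
    def test_binning_and_skipped_tally(self, np_index):
        features = [
            formula_feature("f1", "C4H10"),      # DBE 0
            formula_feature("f2", "C5H12"),      # DBE 0
            formula_feature("f3", "C6H6"),       # DBE 4
            formula_feature("f4", "C8F17KO3S"),  # excluded (K)
        ]
        calls = classify_features(features, np_index).calls
        hist = dbe_histogram(calls)
        assert hist.all_xenobiotic == {Fraction(0): 2, Fraction(4): 1}
        assert hist.skipped == 1

    def test_fluorinated_stratum_nested_in_overall(self, study_features, study_index):
        calls = classify_features(study_features, study_index).calls
        hist = dbe_histogram(calls)
        for edge, n in hist.fluorinated.items():
            assert n <= hist.all_xenobiotic[edge]
        n_xeno = sum(1 for c in calls if c.call == PUTATIVE_XENOBIOTIC)
        assert sum(hist.all_xenobiotic.values()) == n_xeno - hist.skipped

    def test_bad_bin_width_rejected(self, np_index):
        calls = classify_features([formula_feature("f1", "C4H10")], np_index).calls
        with pytest.raises(ValueError):
            dbe_histogram(calls, bin_width=Fraction(0))


class TestHeteroatomSummary:
    def test_features_containing_counts(self, np_index):
        features = [formula_feature("f1", "C2HF3"), formula_feature("f2", "C3H5FClS")]
        calls = classify_features(features, np_index).calls
        table = heteroatom_summary(calls)
        assert table["F"] == 2 and table["Cl"] == 1 and table["S"] == 1
        assert table["halogen_any"] == 2

    def test_empty_pool_gives_zero_table(self):
        assert set(heteroatom_summary([]).values()) == {0}

    def test_matches_planted_composition(self, study_features, study_index, study):
        calls = classify_features(study_features, study_index).calls
        assert heteroatom_summary(calls) == study.ground_truth.heteroatom_counts
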