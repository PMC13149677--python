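"""Long-format conversion, group aggregation, rankings, prevalence, clustering."""

import numpy as np
import pandas as pd
import pytest

from chemtrace import classify_features
from chemtrace.aggregate import (
    aggregate_by_group,
    prevalence,
    to_long,
    top_fluorinated_matrix,
    top_sources,
)


@pytest.fixture
def small():
    wide = pd.DataFrame(
        {"s1": [2.0, 1.0], "s2": [0.0, 3.0], "s3": [4.0, 0.0]},
        index=pd.Index(["f1", "f2"], name="feature_id"),
    )
    metadata = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "food_name": ["carrot", "carrot", "kelp"],
            "organism_name": ["Daucus carota", "Daucus carota", "Saccharina latissima"],
            "foodon_l1": ["plant", "plant", "algal"],
            "foodon_l2": ["vegetable", "vegetable", "seaweed"],
        }
    )
    return wide, metadata


class TestToLong:
    def test_row_count_and_round_trip(self, small):
        wide, _ = small
        long = to_long(wide)
        assert len(long) == wide.shape[0] * wide.shape[1]
        back = long.pivot(index="feature_id", columns="sample_id", values="intensity")
        assert back.loc[wide.index, wide.columns].equals(wide)

    def test_duplicate_labels_rejected(self, small):
        wide, _ = small
        dup = pd.concat([wide, wide.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate feature ids"):
            to_long(dup)


class TestAggregate:
    def test_block_mean_includes_zeros_and_sum(self, small):
        wide, metadata = small
        long = to_long(wide)
        # block f1 x plant = {2, 0}: mean 1.0, sum 2.0
        mean = aggregate_by_group(long, metadata, "foodon_l1", {"sub": ["f1"]}, "mean")
        assert mean.values.loc["plant", "sub"] == 1.0
        total = aggregate_by_group(long, metadata, "foodon_l1", {"sub": ["f1"]}, "sum")
        assert total.values.loc["plant", "sub"] == 2.0

    def test_log_transform_applied_after_aggregation(self, small):
        wide, metadata = small
        wide = wide.copy()
        wide.loc["f1"] = [999.0, 0.0, 0.0]
        out = aggregate_by_group(
            to_long(wide), metadata, "foodon_l1", {"sub": ["f1"]}, "sum", transform="log10p1"
        )
        assert out.values.loc["plant", "sub"] == pytest.approx(3.0)

    def test_sum_mode_conserves_grand_total(self, small):
        wide, metadata = small
        long = to_long(wide)
        out = aggregate_by_group(long, metadata, "foodon_l1", {"all": ["f1", "f2"]}, "sum")
        assert out.values["all"].sum() == pytest.approx(wide.to_numpy().sum())

    def test_mean_bounded_by_block_extremes(self, small):
        wide, metadata = small
        out = aggregate_by_group(to_long(wide), metadata, "foodon_l1", {"all": ["f1", "f2"]}, "mean")
        assert wide.to_numpy().min() <= out.values["all"].min()
        assert out.values["all"].max() <= wide.to_numpy().max()

    def test_empty_subset_yields_zero_column(self, small):
        wide, metadata = small
        out = aggregate_by_group(to_long(wide), metadata, "foodon_l1", {"none": []}, "mean")
        assert (out.values["none"] == 0.0).all()

    def test_planted_group_effect_dominates(self, study, study_features, study_index):
        from chemtrace import match_structures

        flags = match_structures(study_features, study_index)
        drug_ids = {f for f, v in flags.items() if v.matched_drug}
        out = aggregate_by_group(
            to_long(study.abundance), study.metadata, "foodon_l1", {"drugbank": drug_ids}, "mean"
        )
        col = out.values["drugbank"]
        assert col.loc["plant"] > col.drop("plant").max()


class TestTopSources:
    def test_up_to_n_semantics(self, small):
        wide, metadata = small
        ranked = top_sources(to_long(wide), metadata, "f1", n=10)
        # f1 detected in carrot (mean (2+0)/2) and kelp: 2 rows despite n=10
        assert list(ranked["food_name"]) == ["kelp", "carrot"]
        assert ranked["mean_intensity"].tolist() == [4.0, 1.0]

    def test_all_zero_feature_gives_empty_ranking(self, small):
        wide, metadata = small
        wide = wide.copy()
        wide.loc["f1"] = 0.0
        assert top_sources(to_long(wide), metadata, "f1").empty

    def test_unknown_feature_raises(self, small):
        wide, metadata = small
        with pytest.raises(KeyError):
            top_sources(to_long(wide), metadata, "nope")

    def test_ties_alphabetical(self, small):
        wide, metadata = small
        wide = wide.copy()
        wide.loc["f1"] = [3.0, 3.0, 3.0]
        ranked = top_sources(to_long(wide), metadata, "f1")
        assert list(ranked["food_name"]) == ["carrot", "kelp"]


class TestPrevalence:
    @pytest.mark.parametrize("k,n,expected", [(63, 65, 97), (194, 200, 97), (0, 65, 0), (65, 65, 100)])
    def test_percent_rounding(self, k, n, expected):
        samples = [f"s{i}" for i in range(n)]
        metadata = pd.DataFrame(
            {
                "sample_id": samples,
                "food_name": samples,
                "organism_name": ["Bos taurus"] * n,
                "foodon_l1": ["animal"] * n,
                "foodon_l2": ["dairy product"] * n,
            }
        )
        wide = pd.DataFrame(
            [[1.0] * k + [0.0] * (n - k)], index=pd.Index(["f1"], name="feature_id"), columns=samples
        )
        got = prevalence(to_long(wide), metadata, "f1", population="animal")
        assert got == (k, n, expected)

    def test_empty_population_raises(self, small):
        wide, metadata = small
        with pytest.raises(ValueError, match="empty population"):
            prevalence(to_long(wide), metadata, "f1", population="fungal")

    def test_detect_min_floor(self, small):
        wide, metadata = small
        k, n, _ = prevalence(to_long(wide), metadata, "f1", population="plant", detect_min=1.5)
        assert (k, n) == (1, 2)


class TestFluorinatedMatrix:
    def test_union_rows_and_determinism(self, study, study_features, study_index):
        calls = classify_features(study_features, study_index).calls
        long = to_long(study.abundance)
        m1 = top_fluorinated_matrix(calls, long, study.metadata, level="foodon_l1", k=10)
        m2 = top_fluorinated_matrix(calls, long, study.metadata, level="foodon_l1", k=10)
        assert m1.row_order == m2.row_order and m1.col_order == m2.col_order
        assert m1.values.equals(m2.values)
        # every row is a fluorinated planted xenobiotic, appearing exactly once
        fluor = set(study.ground_truth.fluorinated_ids)
        assert set(m1.values.index) <= fluor
        assert not m1.values.index.has_duplicates

    def test_dairy_cluster_foods_group_together(self, study, study_features, study_index):
        calls = classify_features(study_features, study_index).calls
        long = to_long(study.abundance)
        m = top_fluorinated_matrix(calls, long, study.metadata, level="food_name", k=10)
        cheese_foods = [f for f in m.col_order if f.startswith("hard_cheese_")]
        assert len(cheese_foods) == 3
        positions = sorted(m.col_order.index(f) for f in cheese_foods)
        assert positions[2] - positions[0] == 2  # contiguous leaves
        # the three planted shared features appear as rows
        assert set(study.ground_truth.dairy_cluster["feature_ids"]) <= set(m.values.index)

    def test_no_fluorinated_features_gives_empty_matrix(self, small):
        wide, metadata = small
        m = top_fluorinated_matrix([], to_long(wide), metadata)
        assert m.values.empty
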