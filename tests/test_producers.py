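"""Genus extraction and the novel-producer screen."""

import itertools

import pandas as pd
import pytest

from chemtrace import FeatureRecord, extract_genus, match_structures, rank_producers, screen_novel_producers
from chemtrace.formula import parse_formula
from chemtrace.matching import SourceMatchFlags
from chemtrace.reference import ReferenceCompound, ReferenceIndex, build_index

K1 = "AAAAAAAAAAAAAA-BBBBBBBBBB-N"
K2 = "CCCCCCCCCCCCCC-DDDDDDDDDD-N"


@pytest.mark.parametrize(
    "organism,expected",
    [
        ("Daucus carota", "Daucus"),
        ("cirsium arvense", "Cirsium"),
        ("AGASTACHE FOENICULUM", "Agastache"),
        ("Malus", "Malus"),            # bare capitalized genus accepted
        ("unknown", None),             # single lowercase token: not a binomial
        ("", None),
        ("123 carota", None),
    ],
)
def test_extract_genus(organism, expected):
    assert extract_genus(organism) == expected


def tiny_study():
    """Four plant samples across three genera, two drug-matched compounds."""
    metadata = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "food_name": ["chickpea", "anise_hyssop", "carrot", "apple"],
            "organism_name": ["Cicer arietinum", "Agastache foeniculum", "Daucus carota", "Malus domestica"],
            "foodon_l1": ["plant"] * 4,
            "foodon_l2": ["legume", "herb", "vegetable", "fruit"],
        }
    )
    abundance = pd.DataFrame(
        {
            "s1": [5.0, 1.0],
            "s2": [9.0, 1.0],
            "s3": [0.0, 1.0],
            "s4": [0.0, 1.0],
        },
        index=["ft1", "ft2"],
    )
    features = [
        FeatureRecord("ft1", "structure", parse_formula("C16H12O5"), inchikey=K1, compound_name="biochanin_like"),
        FeatureRecord("ft2", "structure", parse_formula("C9H6O3"), inchikey=K2, compound_name="ubiquitous"),
    ]
    index = build_index([
        ReferenceCompound(inchikey=K1, source_id="lotus", formula=parse_formula("C16H12O5"),
                          producing_genera=frozenset({"Cicer"})),
        ReferenceCompound(inchikey=K2, source_id="lotus", formula=parse_formula("C9H6O3"),
                          producing_genera=frozenset({"Cicer"})),
    ])
    flags = {
        "ft1": SourceMatchFlags(matched_drug=True),
        "ft2": SourceMatchFlags(matched_drug=True),
    }
    return features, abundance, metadata, index, flags


def brute_force_pairs(features, abundance, metadata, index, flags, threshold, detect_min=0.0):
    """Independent pair enumeration: loop every (compound, sample) cell."""
    meta = metadata.set_index("sample_id")
    plant = [s for s in abundance.columns if meta.loc[s, "foodon_l1"] == "plant"]
    pairs = set()
    for f in features:
        if f.annotation_level != "structure" or not flags[f.feature_id].matched_drug:
            continue
        detections = [s for s in plant if abundance.loc[f.feature_id, s] > detect_min]
        if len(detections) / len(plant) > threshold:
            continue
        known = {g.lower() for g in index.known_genera(f.inchikey, f.formula)}
        for s in abundance.columns:
            if abundance.loc[f.feature_id, s] <= detect_min:
                continue
            genus = extract_genus(str(meta.loc[s, "organism_name"]))
            if genus and genus.lower() not in known:
                pairs.add((f.inchikey, genus))
    return pairs


class TestScreen:
    def test_planted_pair_emitted_with_best_sample(self):
        features, abundance, metadata, index, flags = tiny_study()
        pairs = screen_novel_producers(
            features, abundance, metadata, index, flags, prevalence_threshold=0.5
        )
        by_compound = {p.inchikey: p for p in pairs}
        # ft1 known from Cicer, detected in Agastache: one novel pair, max-intensity sample
        assert by_compound[K1].genus == "Agastache"
        assert by_compound[K1].best_sample == "s2"
        assert by_compound[K1].max_intensity == 9.0

    def test_strict_prevalence_threshold_excludes_ubiquitous(self):
        features, abundance, metadata, index, flags = tiny_study()
        # ft2 is detected in 4/4 plant samples -> prevalence 1.0 > any sane threshold
        pairs = screen_novel_producers(
            features, abundance, metadata, index, flags, prevalence_threshold=0.5
        )
        assert all(p.inchikey != K2 for p in pairs)
        # at threshold 1.0 (not strict anymore) it comes back
        pairs = screen_novel_producers(
            features, abundance, metadata, index, flags, prevalence_threshold=1.0
        )
        assert any(p.inchikey == K2 for p in pairs)

    def test_no_pair_in_known_genus(self):
        features, abundance, metadata, index, flags = tiny_study()
        pairs = screen_novel_producers(
            features, abundance, metadata, index, flags, prevalence_threshold=1.0
        )
        for p in pairs:
            assert p.genus.lower() not in {
                g.lower() for g in index.known_genera(p.inchikey)
            }

    def test_matches_brute_force_enumeration(self):
        features, abundance, metadata, index, flags = tiny_study()
        for threshold in (0.1, 0.25, 0.5, 1.0):
            got = {
                (p.inchikey, p.genus)
                for p in screen_novel_producers(
                    features, abundance, metadata, index, flags, prevalence_threshold=threshold
                )
            }
            assert got == brute_force_pairs(features, abundance, metadata, index, flags, threshold)

    def test_raising_threshold_never_removes_pairs(self):
        features, abundance, metadata, index, flags = tiny_study()
        thresholds = [0.05, 0.1, 0.3, 0.6, 1.0]
        pair_sets = [
            {
                (p.inchikey, p.genus)
                for p in screen_novel_producers(
                    features, abundance, metadata, index, flags, prevalence_threshold=t
                )
            }
            for t in thresholds
        ]
        for smaller, larger in itertools.pairwise(pair_sets):
            assert smaller <= larger

    def test_sample_mismatch_raises(self):
        features, abundance, metadata, index, flags = tiny_study()
        with pytest.raises(ValueError, match="mismatch"):
            screen_novel_producers(
                features, abundance.rename(columns={"s1": "sX"}), metadata, index, flags
            )

    def test_planted_study_recovery(self, study, study_features, study_index):
        flags = match_structures(study_features, study_index)
        pairs = screen_novel_producers(
            study_features, study.abundance, study.metadata, study_index, flags
        )
        gt = study.ground_truth
        got = {(p.inchikey, p.genus) for p in pairs}
        expected = {(p["inchikey"], p["genus"]) for p in gt.novel_pairs}
        assert got == expected  # all planted pairs, nothing else
        best = {(p.inchikey, p.genus): p.best_sample for p in pairs}
        for p in gt.novel_pairs:
            assert best[(p["inchikey"], p["genus"])] == p["best_sample"]
        # decoys planted above the threshold are excluded entirely
        decoy_keys = {p["inchikey"] for p in gt.decoy_pairs}
        assert not {p.inchikey for p in pairs} & decoy_keys


class TestRanking:
    def test_novel_producer_outranks_known(self):
        features, abundance, metadata, index, flags = tiny_study()
        pairs = screen_novel_producers(
            features, abundance, metadata, index, flags, prevalence_threshold=0.5
        )
        ranking = rank_producers(pairs, features, abundance, metadata, index)
        top = ranking[ranking["inchikey"] == K1].iloc[0]
        assert top["rank"] == 1 and bool(top["novel"]) and top["sample_id"] == "s2"

    def test_intensity_ties_break_by_sample_id(self):
        features, abundance, metadata, index, flags = tiny_study()
        abundance = abundance.copy()
        abundance.loc["ft1"] = [7.0, 7.0, 0.0, 0.0]
        pairs = screen_novel_producers(
            features, abundance, metadata, index, flags, prevalence_threshold=0.5
        )
        ranking = rank_producers(pairs, features, abundance, metadata, index)
        sub = ranking[ranking["inchikey"] == K1]
        assert list(sub["sample_id"]) == ["s1", "s2"]
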