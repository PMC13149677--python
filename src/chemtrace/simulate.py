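"""Seed-reproducible synthetic study generator with planted ground truth.

Emulates a release-style untargeted food-metabolomics study: a dense
normalized feature × sample intensity matrix, a per-feature annotation
table (structure-level with InChIKeys for a small subset, formula-only
for the rest), per-sample metadata with binomial organism names and
two-level food-ontology labels, and reference fixtures for the three
drug-like and three natural-product sources.

Every downstream screen has constructively planted truth:

* natural-product formulas are drawn from a CHNO(S,P) grammar and
  registered in the np fixtures, so formula-only features built from them
  are guaranteed np matches;
* planted xenobiotics use formulas rejection-sampled to be absent from
  the np union; a configured subset contains fluorine with a low-DBE
  (highly saturated) bias, including a perfluorinated potassium-salt
  analog whose DBE is excluded by the incompatible-element rule;
* source matches are planted by inserting study InChIKeys into the
  drug/fcc/agrochem fixtures alongside decoy entries;
* novel compound–genus pairs assign detections of drug-matched compounds
  to samples whose genus is omitted from the compound's occurrence
  record, with prevalence kept at or below the screening threshold;
  decoy compounds are planted above the threshold to test exclusion;
* all other drug-matched compounds get occurrence records covering every
  study genus, so the novel-producer screen has no false positives by
  construction.

Intensities follow a log-normal model with Bernoulli sparsity and a
multiplicative group effect on drug-matched features in plant samples.
Random streams are split per table (metadata, references, features,
matrix, planting) so enlarging one table does not perturb the others.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .formula import MolecularFormula, format_formula

__all__ = ["StudyConfig", "GroundTruth", "Study", "generate_study"]

PLANT_ORGANISMS = [
    ("Daucus", "carota"), ("Malus", "domestica"), ("Agastache", "foeniculum"),
    ("Cicer", "arietinum"), ("Cirsium", "arvense"), ("Triticum", "aestivum"),
    ("Oryza", "sativa"), ("Solanum", "lycopersicum"), ("Vitis", "vinifera"),
    ("Prunus", "avium"), ("Citrus", "limon"), ("Allium", "cepa"),
    ("Brassica", "oleracea"), ("Capsicum", "annuum"), ("Cucumis", "melo"),
    ("Fragaria", "vesca"), ("Glycine", "max"), ("Helianthus", "annuus"),
    ("Lactuca", "sativa"), ("Mentha", "piperita"), ("Ocimum", "basilicum"),
    ("Persea", "americana"), ("Phaseolus", "vulgaris"), ("Pisum", "sativum"),
    ("Rubus", "idaeus"), ("Salvia", "officinalis"), ("Spinacia", "oleracea"),
    ("Theobroma", "cacao"), ("Vaccinium", "corymbosum"), ("Zea", "mays"),
]
ANIMAL_ORGANISMS = [
    ("Bos", "taurus"), ("Gallus", "gallus"), ("Sus", "scrofa"), ("Ovis", "aries"),
    ("Capra", "hircus"), ("Acheta", "domesticus"), ("Salmo", "salar"), ("Gadus", "morhua"),
]
ALGAL_ORGANISMS = [
    ("Saccharina", "latissima"), ("Porphyra", "umbilicalis"),
    ("Ulva", "lactuca"), ("Chondrus", "crispus"),
]
FUNGAL_ORGANISMS = [
    ("Agaricus", "bisporus"), ("Lentinula", "edodes"),
    ("Pleurotus", "ostreatus"), ("Tuber", "melanosporum"),
]
PLANT_L2 = ["vegetable", "fruit", "grain", "herb"]
ANIMAL_L2 = ["dairy product", "meat product", "egg product"]
SUPERCLASSES = [
    "Lipids and lipid-like molecules",
    "Phenylpropanoids and polyketides",
    "Organic acids and derivatives",
    "Benzenoids",
    "Organoheterocyclic compounds",
]
#: Broad therapeutic categories retained by the category selection step.
KEEP_CATEGORIES = [
    "Enzyme Inhibitors", "Antioxidants", "Anticoagulants", "Anti-Inflammatory Agents",
    "Antineoplastic Agents", "Antihypertensive Agents", "Antirheumatic Agents",
    "Analgesics", "Antipyretics", "Antifungal Agents", "Antibacterial Agents",
    "Antiviral Agents", "Antiparasitic Agents", "Bronchodilator Agents",
    "Diuretics", "Hypoglycemic Agents", "Hypolipidemic Agents",
    "Immunosuppressive Agents", "Vasodilator Agents", "Anticonvulsants",
]
#: Non-therapeutic classifications present in fixtures but never retained.
EXCLUDED_CATEGORIES = ["Industrial Dyes", "Surfactants", "Chemical Descriptor", "Food Additives"]

#: Perfluorooctanesulfonate potassium-salt analog: fluorinated xenobiotic
#: whose potassium makes its DBE undefined under the compatible-element rule.
PFOS_K_COUNTS = {"C": 8, "F": 17, "K": 1, "O": 3, "S": 1}


@dataclass
class StudyConfig:
    """Study-generation parameters.

    Defaults describe the desk-scale study: 2,000 features over 100
    samples with the release's group proportions (≈70% plant, 15%
    animal, the remainder algal and fungal), a ~4–5% planted xenobiotic
    share of all features, and planted match/novel-pair counts sized for
    exact recovery checks. :meth:`full_scale` gives the release-sized
    preset (24,721 × 500).
    """

    seed: int = 0
    n_plant: int = 70
    n_animal: int = 15
    n_algal: int = 8
    n_fungal: int = 7
    n_features_structure: int = 80
    n_features_formula_only: int = 1920
    n_np_formula_pool: int = 700
    n_np_decoy_formulas: int = 50
    n_planted_xenobiotics: int = 96
    n_planted_fluorinated: int = 12
    n_planted_drug: int = 12
    n_planted_fcc: int = 5
    n_planted_agrochem: int = 2
    n_reference_decoys: int = 20
    n_planted_novel_pairs: int = 7
    n_decoy_novel: int = 3
    prevalence_threshold: float = 0.10
    n_dairy_cluster_features: int = 3
    n_hard_cheese_samples: int = 3
    sparsity: float = 0.65
    lognormal_mean: float = 2.0
    lognormal_sigma: float = 1.0
    group_effect_multiplier: float = 10.0
    prevalence_demo: bool = False

    @property
    def n_samples(self) -> int:
        return self.n_plant + self.n_animal + self.n_algal + self.n_fungal

    @property
    def n_features(self) -> int:
        return self.n_features_structure + self.n_features_formula_only

    @classmethod
    def full_scale(cls, seed: int = 0) -> "StudyConfig":
        return cls(
            seed=seed,
            n_plant=350, n_animal=75, n_algal=40, n_fungal=35,
            n_features_structure=900, n_features_formula_only=23821,
            n_np_formula_pool=8000, n_planted_xenobiotics=1187,
            n_planted_fluorinated=126,
        )

    def validate(self) -> None:
        errors = []
        if self.n_planted_xenobiotics > self.n_features_formula_only:
            errors.append("n_planted_xenobiotics exceeds n_features_formula_only")
        if self.n_planted_fluorinated > self.n_planted_xenobiotics:
            errors.append("n_planted_fluorinated exceeds n_planted_xenobiotics")
        if self.n_planted_fluorinated < self.n_dairy_cluster_features + 1:
            errors.append("need at least n_dairy_cluster_features + 1 fluorinated xenobiotics")
        n_drug_like = self.n_planted_drug + self.n_planted_fcc + self.n_planted_agrochem
        if n_drug_like > self.n_features_structure:
            errors.append("planted source matches exceed n_features_structure")
        if self.n_planted_novel_pairs + self.n_decoy_novel > self.n_planted_drug:
            errors.append("novel + decoy compounds exceed n_planted_drug")
        if not 0.0 <= self.sparsity < 1.0:
            errors.append("sparsity must be in [0, 1)")
        if self.n_hard_cheese_samples > self.n_animal:
            errors.append("n_hard_cheese_samples exceeds n_animal")
        if self.n_plant < 1 or self.n_samples < 1:
            errors.append("need at least one plant sample")
        max_novel_detect = int(self.prevalence_threshold * self.n_plant)
        if self.n_planted_novel_pairs and max_novel_detect < 1:
            errors.append("prevalence threshold leaves no room for novel-pair detections")
        if self.prevalence_demo and (self.n_plant < 194 or self.n_animal < 63):
            errors.append("prevalence_demo requires n_plant >= 194 and n_animal >= 63")
        if errors:
            raise ValueError("infeasible study config: " + "; ".join(errors))


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator planted."""

    xenobiotic_ids: list[str]
    fluorinated_ids: list[str]
    dbe_excluded_ids: list[str]
    np_match_ids: list[str]
    matched_drug_ids: list[str]
    matched_fcc_ids: list[str]
    matched_agrochem_ids: list[str]
    novel_pairs: list[dict]
    decoy_pairs: list[dict]
    heteroatom_counts: dict[str, int]
    keep_categories: list[str]
    n_category_compounds: int
    dairy_cluster: dict
    group_effect: dict
    prevalence_demo: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "xenobiotic_ids": self.xenobiotic_ids,
            "fluorinated_ids": self.fluorinated_ids,
            "dbe_excluded_ids": self.dbe_excluded_ids,
            "np_match_ids": self.np_match_ids,
            "matched_drug_ids": self.matched_drug_ids,
            "matched_fcc_ids": self.matched_fcc_ids,
            "matched_agrochem_ids": self.matched_agrochem_ids,
            "novel_pairs": self.novel_pairs,
            "decoy_pairs": self.decoy_pairs,
            "heteroatom_counts": self.heteroatom_counts,
            "keep_categories": self.keep_categories,
            "n_category_compounds": self.n_category_compounds,
            "dairy_cluster": self.dairy_cluster,
            "group_effect": self.group_effect,
            "prevalence_demo": self.prevalence_demo,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "GroundTruth":
        return cls(**raw)


@dataclass
class Study:
    """In-memory synthetic study plus its ground truth."""

    config: StudyConfig
    abundance: pd.DataFrame          # features x samples, index feature_id
    annotations: pd.DataFrame        # feature_id, annotation_level, formula, inchikey, ...
    metadata: pd.DataFrame           # sample_id, food_name, organism_name, foodon_l1/l2
    reference_tables: dict[str, pd.DataFrame]
    ground_truth: GroundTruth

    def write(self, out_dir: str | Path) -> Path:
        """Write the study as the TSV/JSON tree every pipeline stage reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.abundance.rename_axis("feature_id").to_csv(out / "features.tsv", sep="\t")
        self.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        refs = out / "refs"
        refs.mkdir(exist_ok=True)
        for source, table in self.reference_tables.items():
            table.to_csv(refs / f"{source}.tsv", sep="\t", index=False)
        (out / "ground_truth.json").write_text(
            json.dumps(self.ground_truth.to_dict(), indent=1, sort_keys=True)
        )
        return out


def _inchikey(rng: np.random.Generator) -> str:
    letters = string.ascii_uppercase
    a = "".join(rng.choice(list(letters), size=14))
    b = "".join(rng.choice(list(letters), size=10))
    return f"{a}-{b}-N"


def _np_formula(rng: np.random.Generator) -> dict[str, int]:
    """Random natural-product-like composition over C, H, N, O, (S, P)."""
    c = int(rng.integers(5, 41))
    n = int(rng.integers(0, 5))
    dbe = int(rng.integers(0, c // 2 + 1))
    h = 2 * c + 2 + n - 2 * dbe
    counts = {"C": c, "H": h, "N": n} if n else {"C": c, "H": h}
    o = int(rng.integers(0, 13))
    if o:
        counts["O"] = o
    if rng.random() < 0.15:
        counts["S"] = 1
    if rng.random() < 0.10:
        counts["P"] = 1
    counts = {k: v for k, v in counts.items() if v > 0}
    return counts


def _fluorinated_formula(rng: np.random.Generator) -> dict[str, int]:
    """Fluorinated composition biased to low DBE (saturated chains)."""
    c = int(rng.integers(4, 21))
    f = int(rng.integers(3, min(2 * c, 18)))
    dbe = int(rng.choice([0, 0, 0, 1, 2]))
    h = max(2 * c + 2 - f - 2 * dbe, 0)
    counts = {"C": c, "F": f}
    if h:
        counts["H"] = h
    o = int(rng.integers(0, 4))
    if o:
        counts["O"] = o
    if rng.random() < 0.3:
        counts["S"] = 1
    return counts


def _chlorinated_formula(rng: np.random.Generator) -> dict[str, int]:
    c = int(rng.integers(6, 30))
    cl = int(rng.integers(1, 4))
    n = int(rng.integers(0, 3))
    dbe = int(rng.integers(0, 8))
    h = max(2 * c + 2 + n - cl - 2 * dbe, 0)
    counts = {"C": c, "Cl": cl}
    if h:
        counts["H"] = h
    if n:
        counts["N"] = n
    o = int(rng.integers(0, 6))
    if o:
        counts["O"] = o
    if rng.random() < 0.3:
        counts["S"] = 1
    if rng.random() < 0.2:
        counts["P"] = 1
    return counts


def _canonical(counts: dict[str, int]) -> str:
    return format_formula(MolecularFormula(counts))


def _heteroatom_tally(formulas: list[dict[str, int]]) -> dict[str, int]:
    # counted straight off the planted composition dicts, independent of the parser
    tally = {e: 0 for e in ("S", "P", "F", "Cl", "Br", "I")}
    tally["halogen_any"] = 0
    for counts in formulas:
        for e in ("S", "P", "F", "Cl", "Br", "I"):
            if counts.get(e, 0) >= 1:
                tally[e] += 1
        if any(counts.get(x, 0) >= 1 for x in ("F", "Cl", "Br", "I")):
            tally["halogen_any"] += 1
    return tally


def _make_metadata(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0

    def add(food: str, organism: str, l1: str, l2: str) -> None:
        nonlocal idx
        idx += 1
        rows.append(
            {
                "sample_id": f"S{idx:04d}",
                "food_name": food,
                "organism_name": organism,
                "foodon_l1": l1,
                "foodon_l2": l2,
            }
        )

    for i in range(config.n_plant):
        genus, species = PLANT_ORGANISMS[int(rng.integers(0, len(PLANT_ORGANISMS)))]
        if i == config.n_plant - 1 and config.n_plant >= 5:
            add(f"mystery_blend_{i:03d}", "unknown", "plant", "herb")
        else:
            add(f"{genus.lower()}_{species}_{i:03d}", f"{genus} {species}",
                "plant", PLANT_L2[i % len(PLANT_L2)])
    for i in range(config.n_animal):
        if i < config.n_hard_cheese_samples:
            add(f"hard_cheese_{i + 1}", "Bos taurus", "animal", "dairy product")
        else:
            genus, species = ANIMAL_ORGANISMS[int(rng.integers(0, len(ANIMAL_ORGANISMS)))]
            add(f"{genus.lower()}_{species}_{i:03d}", f"{genus} {species}",
                "animal", ANIMAL_L2[i % len(ANIMAL_L2)])
    for i in range(config.n_algal):
        genus, species = ALGAL_ORGANISMS[int(rng.integers(0, len(ALGAL_ORGANISMS)))]
        food = "sugar_kelp" if i == 0 else f"{genus.lower()}_{species}_{i:03d}"
        add(food, f"{genus} {species}", "algal", "seaweed")
    for i in range(config.n_fungal):
        genus, species = FUNGAL_ORGANISMS[int(rng.integers(0, len(FUNGAL_ORGANISMS)))]
        add(f"{genus.lower()}_{species}_{i:03d}", f"{genus} {species}", "fungal", "mushroom")
    return pd.DataFrame(rows)


def generate_study(config: StudyConfig, out_dir: Optional[str | Path] = None) -> Study:
    """Generate a complete synthetic study; optionally write it to disk.

    Fixing the seed makes the entire output (including written files)
    byte-identical across runs. Infeasible configurations raise before
    anything is generated or written.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_meta, rng_ref, rng_feat, rng_matrix, rng_plant = (
        np.random.default_rng(s) for s in streams
    )

    metadata = _make_metadata(config, rng_meta)
    sample_ids = metadata["sample_id"].tolist()
    plant_samples = metadata.loc[metadata["foodon_l1"] == "plant", "sample_id"].tolist()
    animal_samples = metadata.loc[metadata["foodon_l1"] == "animal", "sample_id"].tolist()
    cheese_samples = metadata.loc[
        metadata["food_name"].str.startswith("hard_cheese_"), "sample_id"
    ].tolist()
    genus_of = {
        r.sample_id: r.organism_name.split()[0].capitalize()
        for r in metadata.itertuples()
        if r.organism_name != "unknown"
    }
    all_genera = sorted(set(genus_of.values()))

    # --- natural-product formula pool and decoys ------------------------------
    np_pool: dict[str, dict[str, int]] = {}
    while len(np_pool) < config.n_np_formula_pool:
        counts = _np_formula(rng_ref)
        np_pool.setdefault(_canonical(counts), counts)
    np_pool_keys = sorted(np_pool)
    np_decoys: dict[str, dict[str, int]] = {}
    while len(np_decoys) < config.n_np_decoy_formulas:
        counts = _np_formula(rng_ref)
        key = _canonical(counts)
        if key not in np_pool:
            np_decoys.setdefault(key, counts)
    np_union = set(np_pool) | set(np_decoys)

    # --- structure-annotated features ----------------------------------------
    structure_rows = []
    for i in range(config.n_features_structure):
        counts = np_pool[np_pool_keys[int(rng_feat.integers(0, len(np_pool_keys)))]]
        structure_rows.append(
            {
                "feature_id": f"FT{i + 1:06d}",
                "annotation_level": "structure",
                "formula": _canonical(counts),
                "inchikey": _inchikey(rng_feat),
                "compound_name": f"compound_{i + 1:04d}",
                "superclass": SUPERCLASSES[i % len(SUPERCLASSES)],
            }
        )
    drug_ids = [r["feature_id"] for r in structure_rows[: config.n_planted_drug]]
    fcc_ids = [
        r["feature_id"]
        for r in structure_rows[config.n_planted_drug : config.n_planted_drug + config.n_planted_fcc]
    ]
    agro_start = config.n_planted_drug + config.n_planted_fcc
    agro_ids = [
        r["feature_id"]
        for r in structure_rows[agro_start : agro_start + config.n_planted_agrochem]
    ]

    # --- formula-only features -----------------------------------------------
    offset = config.n_features_structure
    n_xeno = config.n_planted_xenobiotics
    n_fluor = config.n_planted_fluorinated
    formula_rows = []
    xeno_formulas: list[dict[str, int]] = []
    fluorinated_ids: list[str] = []
    dbe_excluded_ids: list[str] = []
    used_xeno: set[str] = set()

    def fresh(make) -> dict[str, int]:
        for _ in range(10000):
            counts = make(rng_feat)
            key = _canonical(counts)
            if key not in np_union and key not in used_xeno:
                used_xeno.add(key)
                return counts
        raise RuntimeError("could not sample a formula absent from the np union")

    for j in range(config.n_features_formula_only):
        fid = f"FT{offset + j + 1:06d}"
        if j < n_xeno:
            if j < n_fluor:
                counts = PFOS_K_COUNTS if j == 0 else fresh(_fluorinated_formula)
                if j == 0:
                    used_xeno.add(_canonical(counts))
                    dbe_excluded_ids.append(fid)
                fluorinated_ids.append(fid)
            elif j < n_fluor + max(n_xeno - n_fluor, 0) // 2:
                counts = fresh(_chlorinated_formula)
            else:
                counts = fresh(_np_formula)
            xeno_formulas.append(counts)
        else:
            counts = np_pool[np_pool_keys[int(rng_feat.integers(0, len(np_pool_keys)))]]
        formula_rows.append(
            {
                "feature_id": fid,
                "annotation_level": "formula_only",
                "formula": _canonical(counts),
                "inchikey": "",
                "compound_name": "",
                "superclass": "",
            }
        )
    xenobiotic_ids = [r["feature_id"] for r in formula_rows[:n_xeno]]
    np_match_ids = [r["feature_id"] for r in formula_rows[n_xeno:]]

    annotations = pd.DataFrame(structure_rows + formula_rows)

    # --- prevalence-demo feature ---------------------------------------------
    prevalence_demo = None
    if config.prevalence_demo:
        demo_row = {
            "feature_id": "FT_PREV",
            "annotation_level": "structure",
            "formula": "C9H6O3",
            "inchikey": _inchikey(rng_feat),
            "compound_name": "hydroxycoumarin_like",
            "superclass": "Benzenoids",
        }
        annotations = pd.concat([annotations, pd.DataFrame([demo_row])], ignore_index=True)
        prevalence_demo = {
            "feature_id": "FT_PREV",
            "animal": [63, config.n_animal],
            "plant": [194, config.n_plant],
        }

    feature_ids = annotations["feature_id"].tolist()

    # --- reference fixtures ---------------------------------------------------
    np_sources = ("lotus", "coconut", "supernatural")
    np_rows: dict[str, list[dict]] = {s: [] for s in np_sources}
    for k, key in enumerate(sorted(np_union)):
        genera = sorted(
            {all_genera[int(rng_ref.integers(0, len(all_genera)))] for _ in range(1 + k % 2)}
        )
        source = np_sources[k % 3]
        row = {"inchikey": _inchikey(rng_ref), "formula": key, "genus": ";".join(genera)}
        np_rows[source].append(row)
        if k % 10 == 0:  # overlap between sources to exercise the union semantics
            np_rows[np_sources[(k + 1) % 3]].append(dict(row))

    by_id = {r["feature_id"]: r for r in structure_rows}

    # novel / decoy planting over drug-matched compounds
    novel_compound_ids = drug_ids[: config.n_planted_novel_pairs]
    decoy_compound_ids = drug_ids[
        config.n_planted_novel_pairs : config.n_planted_novel_pairs + config.n_decoy_novel
    ]
    plain_drug_ids = drug_ids[config.n_planted_novel_pairs + config.n_decoy_novel :]

    novel_pairs: list[dict] = []
    decoy_pairs: list[dict] = []
    plantable = [s for s in plant_samples if s in genus_of]
    max_novel_detect = max(int(config.prevalence_threshold * config.n_plant), 1)

    for i, fid in enumerate(novel_compound_ids):
        rec = by_id[fid]
        target = plantable[int(rng_plant.integers(0, len(plantable)))]
        target_genus = genus_of[target]
        known = sorted(set(all_genera) - {target_genus})
        known_subset = known[:2] if len(known) >= 2 else known
        # supporting detections in known-producer genera, staying under the threshold
        extra = [
            s for s in plantable
            if genus_of[s] in known_subset and s != target
        ][: max(max_novel_detect - 1, 0)][:2]
        np_rows["lotus"].append(
            {"inchikey": rec["inchikey"], "formula": rec["formula"], "genus": ";".join(known_subset)}
        )
        novel_pairs.append(
            {
                "inchikey": rec["inchikey"],
                "compound_name": rec["compound_name"],
                "feature_id": fid,
                "genus": target_genus,
                "best_sample": target,
                "detect_samples": [target] + extra,
            }
        )

    for fid in decoy_compound_ids:
        rec = by_id[fid]
        n_detect = int(config.prevalence_threshold * config.n_plant) + 3
        n_detect = min(n_detect, len(plantable))
        detect = [plantable[int(i)] for i in rng_plant.choice(len(plantable), size=n_detect, replace=False)]
        known_genus = all_genera[0]
        np_rows["coconut"].append(
            {"inchikey": rec["inchikey"], "formula": rec["formula"], "genus": known_genus}
        )
        decoy_pairs.append(
            {
                "inchikey": rec["inchikey"],
                "feature_id": fid,
                "detect_samples": detect,
                "known_genus": known_genus,
            }
        )

    # remaining drug-matched compounds: occurrence records covering every study
    # genus, so they can never produce a novel pair
    for fid in plain_drug_ids:
        rec = by_id[fid]
        np_rows["supernatural"].append(
            {"inchikey": rec["inchikey"], "formula": rec["formula"], "genus": ";".join(all_genera)}
        )

    def _drug_like_table(planted_ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
        rows = []
        for fid in planted_ids:
            rec = by_id[fid]
            n_keep = int(rng.integers(1, 4))
            cats = sorted(
                {KEEP_CATEGORIES[int(rng.integers(0, len(KEEP_CATEGORIES)))] for _ in range(n_keep)}
            )
            if rng.random() < 0.3:
                cats.append(EXCLUDED_CATEGORIES[int(rng.integers(0, len(EXCLUDED_CATEGORIES)))])
            rows.append(
                {"inchikey": rec["inchikey"], "name": rec["compound_name"], "categories": ";".join(cats)}
            )
        for d in range(config.n_reference_decoys):
            only_excluded = d % 4 == 0
            pool = EXCLUDED_CATEGORIES if only_excluded else KEEP_CATEGORIES
            cats = sorted({pool[int(rng.integers(0, len(pool)))] for _ in range(2)})
            rows.append(
                {"inchikey": _inchikey(rng), "name": f"decoy_{d:03d}", "categories": ";".join(cats)}
            )
        return pd.DataFrame(rows)

    reference_tables = {
        "drugbank": _drug_like_table(drug_ids, rng_ref),
        "fccdb": _drug_like_table(fcc_ids, rng_ref),
        "agrochem": _drug_like_table(agro_ids, rng_ref),
    }
    n_category_compounds = sum(
        any(c in KEEP_CATEGORIES for c in row["categories"].split(";"))
        for table in reference_tables.values()
        for row in table.to_dict("records")
    )
    for source in np_sources:
        reference_tables[source] = pd.DataFrame(np_rows[source])

    # --- intensity matrix -----------------------------------------------------
    n_feat, n_samp = len(feature_ids), len(sample_ids)
    values = rng_matrix.lognormal(config.lognormal_mean, config.lognormal_sigma, (n_feat, n_samp))
    mask = rng_matrix.random((n_feat, n_samp)) >= config.sparsity
    matrix = pd.DataFrame(values * mask, index=feature_ids, columns=sample_ids)

    # group effect: drug-matched features amplified in plant samples
    matrix.loc[drug_ids, plant_samples] *= config.group_effect_multiplier

    # planted novel rows: detections only where scripted
    for pair in novel_pairs:
        row = pd.Series(0.0, index=matrix.columns)
        base = float(rng_plant.lognormal(config.lognormal_mean + 2.0, 0.3))
        row[pair["best_sample"]] = base
        for s in pair["detect_samples"][1:]:
            row[s] = base * float(rng_plant.uniform(0.2, 0.8))
        matrix.loc[pair["feature_id"]] = row
    for pair in decoy_pairs:
        row = pd.Series(0.0, index=matrix.columns)
        for s in pair["detect_samples"]:
            row[s] = float(rng_plant.lognormal(config.lognormal_mean, 0.3))
        matrix.loc[pair["feature_id"]] = row

    # dairy cluster: shared fluorinated features recurring in hard cheeses
    dairy_ids = [f for f in fluorinated_ids[1 : 1 + config.n_dairy_cluster_features]]
    for fid in dairy_ids:
        row = pd.Series(0.0, index=matrix.columns)
        for s in cheese_samples:
            row[s] = float(rng_plant.lognormal(config.lognormal_mean + 3.0, 0.2))
        matrix.loc[fid] = row

    if prevalence_demo is not None:
        row = pd.Series(0.0, index=matrix.columns)
        for s in animal_samples[:63] + plant_samples[:194]:
            row[s] = float(rng_plant.lognormal(config.lognormal_mean, 0.3))
        matrix.loc["FT_PREV"] = row

    matrix = matrix.round(4)

    ground_truth = GroundTruth(
        xenobiotic_ids=xenobiotic_ids,
        fluorinated_ids=fluorinated_ids,
        dbe_excluded_ids=dbe_excluded_ids,
        np_match_ids=np_match_ids,
        matched_drug_ids=drug_ids,
        matched_fcc_ids=fcc_ids,
        matched_agrochem_ids=agro_ids,
        novel_pairs=novel_pairs,
        decoy_pairs=decoy_pairs,
        heteroatom_counts=_heteroatom_tally(xeno_formulas),
        keep_categories=list(KEEP_CATEGORIES),
        n_category_compounds=n_category_compounds,
        dairy_cluster={"feature_ids": dairy_ids, "samples": cheese_samples},
        group_effect={
            "feature_ids": drug_ids,
            "foodon_l1": "plant",
            "multiplier": config.group_effect_multiplier,
        },
        prevalence_demo=prevalence_demo,
    )

    study = Study(
        config=config,
        abundance=matrix,
        annotations=annotations,
        metadata=metadata,
        reference_tables=reference_tables,
        ground_truth=ground_truth,
    )
    if out_dir is not None:
        study.write(out_dir)
    return study
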