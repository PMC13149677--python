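"""Readers, writers, pipeline configuration and the end-to-end driver.

The canonical on-disk dialect is UTF-8 TSV with LF endings (comma
dialects are accepted via header sniffing). ``run_pipeline`` chains the
stages of the screening workflow — structure matching, the formula-level
xenobiotic screen, fluorine prioritization, the novel-producer screen
and ontology aggregation — and writes a manifest with a config hash,
input checksums and per-stage row counts so identical inputs reproduce
bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import aggregate as agg
from .formula import FormulaError, parse_formula
from .matching import FORMULA_ONLY, STRUCTURE, FeatureRecord, match_structures
from .producers import rank_producers, screen_novel_producers
from .reference import (
    SOURCE_KINDS,
    ReferenceIndex,
    build_index,
    load_reference_table,
)
from .xenobiotics import classify_features, dbe_histogram, filter_fluorinated, heteroatom_summary

logger = logging.getLogger("chemtrace")

__all__ = [
    "PipelineConfig",
    "read_feature_matrix",
    "read_annotations",
    "features_from_frame",
    "read_metadata",
    "load_references",
    "run_pipeline",
]


def _sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"empty file: {path}")
    return "\t" if "\t" in header else ","


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a wide feature × sample intensity matrix.

    First column holds feature ids, header row holds sample ids. Empty
    cells become 0 (the count is logged); duplicate feature or sample
    labels and non-numeric cells are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate feature ids")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.info("%s: %d empty cells set to 0", path, n_missing)
        df = df.fillna(0.0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    return df


def features_from_frame(df: pd.DataFrame) -> list[FeatureRecord]:
    """Convert an annotation table (DataFrame) into feature records.

    Expected columns: feature_id, annotation_level, formula, and
    optionally inchikey, compound_name, superclass. Unparseable formulas
    yield records with ``formula=None`` (logged), which downstream
    screens route to the unclassifiable side-list.
    """
    required = {"feature_id", "annotation_level", "formula"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table: missing required column(s) {sorted(missing)}")
    records = []
    n_bad = 0
    for row in df.to_dict("records"):
        try:
            formula = parse_formula(str(row["formula"]))
        except FormulaError:
            formula = None
            n_bad += 1
        records.append(
            FeatureRecord(
                feature_id=str(row["feature_id"]),
                annotation_level=str(row["annotation_level"]),
                formula=formula,
                inchikey=str(row.get("inchikey", "") or "") or None,
                compound_name=str(row.get("compound_name", "") or "") or None,
                superclass_label=str(row.get("superclass", "") or "") or None,
            )
        )
    if n_bad:
        logger.warning("annotation table: %d unparseable formulas retained as unclassifiable", n_bad)
    return records


def read_annotations(path: str | Path) -> list[FeatureRecord]:
    """Read the per-feature annotation table into feature records."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    return features_from_frame(df)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (sample_id, food_name, organism_name, foodon levels)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    required = {"sample_id", "food_name", "organism_name", "foodon_l1", "foodon_l2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def load_references(
    ref_dir: str | Path, category_delimiter: str = ";"
) -> tuple[ReferenceIndex, dict]:
    """Load every recognized reference table under ``ref_dir`` and index them.

    Files are matched by stem against the known source kinds
    (drugbank/fccdb/agrochem/lotus/coconut/supernatural), .tsv or .csv.
    Returns the built index and a load-report dict per source.
    """
    ref_dir = Path(ref_dir)
    compounds = []
    reports = {}
    for source in SOURCE_KINDS:
        for ext in (".tsv", ".csv"):
            path = ref_dir / f"{source}{ext}"
            if path.exists():
                loaded, report = load_reference_table(path, source, category_delimiter)
                compounds.extend(loaded)
                reports[source] = report.to_dict()
                break
    if not compounds:
        raise ValueError(f"no reference tables found under {ref_dir}")
    return build_index(compounds), reports


@dataclass
class PipelineConfig:
    """Validated configuration of one end-to-end pipeline run."""

    features: str
    annotations: str
    metadata: str
    references: str
    out_dir: str
    detect_min: float = 0.0
    prevalence_threshold: float = 0.10
    prevalence_denominator: str = "plant"
    novel_scope: str = "drug-matched"
    inchikey_block1: bool = False
    aggregation: str = "mean"
    category_delimiter: str = ";"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        missing = [
            p
            for p in (self.features, self.annotations, self.metadata, self.references)
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full screening workflow and write all stage outputs.

    Stages: structure matching → formula-level xenobiotic screen →
    fluorine prioritization → DBE/heteroatom profiling → novel-producer
    screen → per-source ontology aggregation. Returns the run manifest
    (also written as ``manifest.json``).
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = read_feature_matrix(config.features)
    features = read_annotations(config.annotations)
    metadata = read_metadata(config.metadata)
    index, load_reports = load_references(config.references, config.category_delimiter)

    # stage 1: structure matching
    flags = match_structures(features, index, inchikey_block1=config.inchikey_block1)
    match_df = pd.DataFrame(
        [
            {
                "feature_id": fid,
                "matched_drug": f.matched_drug,
                "matched_fcc": f.matched_fcc,
                "matched_agrochem": f.matched_agrochem,
                "categories": ";".join(sorted(f.matched_categories)),
            }
            for fid, f in sorted(flags.items())
        ]
    )
    _write_tsv(match_df, out / "matches.tsv")

    # stage 2: xenobiotic screen
    screen = classify_features(features, index)
    calls_df = pd.DataFrame(
        [
            {
                "feature_id": c.feature_id,
                "call": c.call,
                "formula": str(c.formula),
                "fluorinated": c.fluorinated,
                "dbe": "" if c.dbe.excluded else str(c.dbe.value),
            }
            for c in screen.calls
        ]
    )
    _write_tsv(calls_df, out / "xenobiotic_calls.tsv")
    summary = {
        "n_total": screen.summary.n_total,
        "n_structure": screen.summary.n_structure,
        "n_formula_only": screen.summary.n_formula_only,
        "n_np_match": screen.summary.n_np_match,
        "n_xenobiotic": screen.summary.n_xenobiotic,
        "n_unclassifiable": screen.summary.n_unclassifiable,
        "pct_xenobiotic_of_total": screen.summary.pct_xenobiotic_of_total,
        "unclassifiable_ids": screen.unclassifiable,
    }
    (out / "partition_summary.json").write_text(json.dumps(summary, indent=1))

    # stage 3: fluorine prioritization + profiling
    fluorinated = filter_fluorinated(screen.calls)
    _write_tsv(
        pd.DataFrame(
            [{"feature_id": c.feature_id, "formula": str(c.formula)} for c in fluorinated]
        ),
        out / "fluorinated.tsv",
    )
    hist = dbe_histogram(screen.calls)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "dbe_bin": float(edge),
                    "n_xenobiotic": n,
                    "n_fluorinated": hist.fluorinated.get(edge, 0),
                }
                for edge, n in sorted(hist.all_xenobiotic.items())
            ]
        ),
        out / "dbe_histogram.tsv",
    )
    het = heteroatom_summary(screen.calls)
    _write_tsv(
        pd.DataFrame([{"element": k, "n_features": v} for k, v in het.items()]),
        out / "heteroatom_table.tsv",
    )

    # stage 4: novel-producer screen
    pairs = screen_novel_producers(
        features,
        matrix,
        metadata,
        index,
        flags,
        scope=config.novel_scope,
        prevalence_threshold=config.prevalence_threshold,
        prevalence_denominator=config.prevalence_denominator,
        detect_min=config.detect_min,
    )
    pairs_df = pd.DataFrame(
        [
            {
                "inchikey": p.inchikey,
                "compound_name": p.compound_name,
                "genus": p.genus,
                "best_sample": p.best_sample,
                "max_intensity": p.max_intensity,
                "prevalence": p.prevalence,
            }
            for p in pairs
        ],
        columns=["inchikey", "compound_name", "genus", "best_sample", "max_intensity", "prevalence"],
    )
    _write_tsv(pairs_df, out / "novel_pairs.tsv")
    ranking = rank_producers(pairs, features, matrix, metadata, index, detect_min=config.detect_min)
    _write_tsv(ranking, out / "producer_ranking.tsv")

    # stage 5: ontology aggregation per matched source
    long = agg.to_long(matrix)
    subsets = {
        "drugbank": {fid for fid, f in flags.items() if f.matched_drug},
        "fccdb": {fid for fid, f in flags.items() if f.matched_fcc},
        "agrochem": {fid for fid, f in flags.items() if f.matched_agrochem},
    }
    matrix_out = agg.aggregate_by_group(
        long, metadata, "foodon_l1", subsets, aggregation=config.aggregation, transform="log10p1"
    )
    matrix_out.values.rename_axis("foodon_l1").to_csv(
        out / "source_aggregate.tsv", sep="\t", lineterminator="\n"
    )
    fluor_matrix = agg.top_fluorinated_matrix(screen.calls, long, metadata, level="foodon_l1")
    fluor_matrix.values.rename_axis("feature_id").to_csv(
        out / "fluorinated_matrix.tsv", sep="\t", lineterminator="\n"
    )
    (out / "fluorinated_matrix_order.json").write_text(
        json.dumps({"rows": fluor_matrix.row_order, "columns": fluor_matrix.col_order}, indent=1)
    )

    manifest = {
        "config_hash": _config_hash(config),
        "config": asdict(config),
        "inputs": {
            name: _sha256(Path(p))
            for name, p in (
                ("features", config.features),
                ("annotations", config.annotations),
                ("metadata", config.metadata),
            )
        },
        "load_reports": load_reports,
        "stage_counts": {
            "features": len(features),
            "samples": int(matrix.shape[1]),
            "matched_drug": int(match_df["matched_drug"].sum()),
            "matched_fcc": int(match_df["matched_fcc"].sum()),
            "matched_agrochem": int(match_df["matched_agrochem"].sum()),
            "np_match": screen.summary.n_np_match,
            "xenobiotic": screen.summary.n_xenobiotic,
            "unclassifiable": screen.summary.n_unclassifiable,
            "fluorinated": len(fluorinated),
            "novel_pairs": len(pairs_df),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
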