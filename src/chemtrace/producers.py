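"""Taxonomy-aware screen for underreported natural-product producers.

For each structure-annotated compound that matches a pharmaceutical-type
reference source, the screen compares the genus of every food sample in
which the compound is detected against the genus-level occurrence records
aggregated from the natural-product databases. A (compound, genus) pair
is flagged when the genus is absent from all known-producer records. To
retain specialized rather than ubiquitous metabolites, compounds detected
in more than a threshold fraction of the denominator population (default
10% of plant samples) are excluded entirely before pairing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .matching import STRUCTURE, FeatureRecord, SourceMatchFlags
from .reference import ReferenceIndex, normalize_genus

__all__ = ["CompoundGenusPair", "extract_genus", "screen_novel_producers", "rank_producers"]

_LATIN_TOKEN_RE = re.compile(r"^[A-Za-z][A-Za-z.\-]*$")


@dataclass(frozen=True)
class CompoundGenusPair:
    """A compound detected in a genus not recorded as one of its producers."""

    inchikey: str
    compound_name: str
    genus: str
    best_sample: str
    max_intensity: float
    prevalence: float


def extract_genus(organism_name: str) -> Optional[str]:
    """Extract the capitalized genus from a binomial organism-name string.

    The genus is the first whitespace-delimited token, case-normalized
    (``"cirsium arvense"`` → ``"Cirsium"``). Returns ``None`` for strings
    that do not look like Latin binomials: empty strings, tokens with
    non-Latin characters, or a single lowercase token such as
    ``"unknown"``.
    """
    tokens = organism_name.split()
    if not tokens:
        return None
    first = tokens[0]
    if not _LATIN_TOKEN_RE.match(first):
        return None
    if len(tokens) == 1 and not first[0].isupper():
        return None
    return normalize_genus(first)


def _check_alignment(abundance: pd.DataFrame, metadata: pd.DataFrame) -> None:
    abundance_ids = set(abundance.columns)
    metadata_ids = set(metadata["sample_id"])
    extra = sorted(abundance_ids - metadata_ids)
    missing = sorted(metadata_ids - abundance_ids)
    if extra or missing:
        raise ValueError(
            "sample id mismatch between abundance matrix and metadata; "
            f"in matrix only: {extra[:10]}; in metadata only: {missing[:10]}"
        )


def screen_novel_producers(
    features: Sequence[FeatureRecord],
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    index: ReferenceIndex,
    match_flags: Mapping[str, SourceMatchFlags],
    scope: str = "drug-matched",
    prevalence_threshold: float = 0.10,
    prevalence_denominator: str = "plant",
    detect_min: float = 0.0,
) -> list[CompoundGenusPair]:
    """Screen for compound–genus pairs absent from producer records.

    Parameters
    ----------
    features
        Feature records; only structure-annotated ones can yield pairs.
    abundance
        Wide intensity matrix, features (rows, index = feature ids) ×
        samples (columns). Missing values are treated as zero.
    metadata
        Per-sample table with ``sample_id``, ``organism_name`` and
        ``foodon_l1`` columns, aligned with the matrix columns.
    index
        Reference index providing genus-occurrence records.
    match_flags
        Output of :func:`chemtrace.matching.match_structures`, used to
        restrict scope.
    scope
        ``"drug-matched"`` (default) keeps only compounds matched to the
        pharmaceutical source; ``"all-structure"`` widens the screen to
        every structure-annotated compound.
    prevalence_threshold
        Compounds detected in strictly more than this fraction of the
        denominator population are excluded as ubiquitous.
    prevalence_denominator
        ``"plant"`` (samples with ``foodon_l1 == "plant"``) or ``"all"``.
    detect_min
        Detection floor; a sample counts as a detection when intensity is
        strictly greater than this.

    Returns
    -------
    list of :class:`CompoundGenusPair`, one per unique (compound, genus),
    each carrying the highest-intensity supporting sample, sorted by
    (inchikey, genus).
    """
    if scope not in ("drug-matched", "all-structure"):
        raise ValueError(f"unknown scope {scope!r}")
    if prevalence_denominator not in ("plant", "all"):
        raise ValueError(f"unknown prevalence denominator {prevalence_denominator!r}")
    _check_alignment(abundance, metadata)

    meta = metadata.set_index("sample_id")
    if prevalence_denominator == "plant":
        denom_samples = [s for s in abundance.columns if meta.loc[s, "foodon_l1"] == "plant"]
    else:
        denom_samples = list(abundance.columns)
    if not denom_samples:
        raise ValueError(f"prevalence denominator population {prevalence_denominator!r} is empty")

    genus_by_sample = {s: extract_genus(str(meta.loc[s, "organism_name"])) for s in abundance.columns}

    pairs: dict[tuple[str, str], CompoundGenusPair] = {}
    for feature in features:
        if feature.annotation_level != STRUCTURE:
            continue
        if scope == "drug-matched" and not match_flags.get(
            feature.feature_id, SourceMatchFlags()
        ).matched_drug:
            continue
        if feature.feature_id not in abundance.index:
            continue
        row = abundance.loc[feature.feature_id].fillna(0.0)
        n_detect = int((row[denom_samples] > detect_min).sum())
        prevalence = n_detect / len(denom_samples)
        if prevalence > prevalence_threshold:
            continue
        known = {g.lower() for g in index.known_genera(feature.inchikey, feature.formula)}
        for sample in abundance.columns:
            intensity = float(row[sample])
            if intensity <= detect_min:
                continue
            genus = genus_by_sample[sample]
            if genus is None or genus.lower() in known:
                continue
            key = (feature.inchikey, genus)
            current = pairs.get(key)
            # keep the max-intensity supporting sample; ties break to the smaller id
            if (
                current is None
                or intensity > current.max_intensity
                or (intensity == current.max_intensity and sample < current.best_sample)
            ):
                pairs[key] = CompoundGenusPair(
                    inchikey=feature.inchikey,
                    compound_name=feature.compound_name or "",
                    genus=genus,
                    best_sample=sample,
                    max_intensity=intensity,
                    prevalence=prevalence,
                )
    return [pairs[key] for key in sorted(pairs)]


def rank_producers(
    pairs: Iterable[CompoundGenusPair],
    features: Sequence[FeatureRecord],
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    index: ReferenceIndex,
    detect_min: float = 0.0,
) -> pd.DataFrame:
    """Per-compound producer ranking merging novel and known detections.

    For every compound appearing in ``pairs``, lists each sample where it
    is detected with the sample's food, genus, intensity and a
    novel-producer flag (genus absent from the compound's known-producer
    records), ordered by descending intensity with ties broken by sample
    id. Columns: inchikey, compound_name, rank, sample_id, food_name,
    genus, intensity, novel.
    """
    meta = metadata.set_index("sample_id")
    by_key = {f.inchikey: f for f in features if f.annotation_level == STRUCTURE}
    wanted = sorted({p.inchikey for p in pairs})
    rows = []
    for inchikey in wanted:
        feature = by_key.get(inchikey)
        if feature is None or feature.feature_id not in abundance.index:
            continue
        known = {g.lower() for g in index.known_genera(inchikey, feature.formula)}
        detections = []
        row = abundance.loc[feature.feature_id].fillna(0.0)
        for sample in abundance.columns:
            intensity = float(row[sample])
            if intensity <= detect_min:
                continue
            genus = extract_genus(str(meta.loc[sample, "organism_name"]))
            novel = genus is not None and genus.lower() not in known
            detections.append((-intensity, sample, genus, novel))
        detections.sort()
        for rank, (neg_intensity, sample, genus, novel) in enumerate(detections, start=1):
            rows.append(
                {
                    "inchikey": inchikey,
                    "compound_name": feature.compound_name or "",
                    "rank": rank,
                    "sample_id": sample,
                    "food_name": meta.loc[sample, "food_name"],
                    "genus": genus or "",
                    "intensity": -neg_intensity,
                    "novel": novel,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "inchikey",
            "compound_name",
            "rank",
            "sample_id",
            "food_name",
            "genus",
            "intensity",
            "novel",
        ],
    )
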