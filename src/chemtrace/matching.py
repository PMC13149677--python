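"""InChIKey matching of structure-annotated features to reference sources.

Only features annotated at the structure level (those carrying an
InChIKey) are eligible; formula-only features receive all-false flags.
Matching is exact, case-sensitive equality of the full 27-character
InChIKey against each source's identity set. An opt-in relaxed mode
compares only the first (connectivity-skeleton) block, which conflates
stereoisomers and protonation states and is therefore off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .formula import MolecularFormula
from .reference import DRUG_LIKE_SOURCES, ReferenceIndex

__all__ = ["FeatureRecord", "SourceMatchFlags", "match_structures"]

STRUCTURE = "structure"
FORMULA_ONLY = "formula_only"


@dataclass(frozen=True)
class FeatureRecord:
    """One detected molecular feature.

    ``annotation_level`` is ``"structure"`` (InChIKey present) or
    ``"formula_only"``. ``formula`` may be ``None`` only when the source
    annotation string failed to parse; such features are routed to an
    unclassifiable side-list downstream, never silently dropped.
    """

    feature_id: str
    annotation_level: str
    formula: Optional[MolecularFormula]
    inchikey: Optional[str] = None
    compound_name: Optional[str] = None
    superclass_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.annotation_level not in (STRUCTURE, FORMULA_ONLY):
            raise ValueError(f"invalid annotation_level {self.annotation_level!r}")
        if self.annotation_level == STRUCTURE and not self.inchikey:
            raise ValueError(f"structure-annotated feature {self.feature_id!r} lacks an InChIKey")


@dataclass(frozen=True)
class SourceMatchFlags:
    """Per-feature match flags against the drug-like reference sources."""

    matched_drug: bool = False
    matched_fcc: bool = False
    matched_agrochem: bool = False
    matched_categories: frozenset[str] = frozenset()

    @property
    def matched_any(self) -> bool:
        return self.matched_drug or self.matched_fcc or self.matched_agrochem


_FLAG_SOURCE = {"matched_drug": "drugbank", "matched_fcc": "fccdb", "matched_agrochem": "agrochem"}


def _block1(key: str) -> str:
    return key.split("-", 1)[0]


def match_structures(
    features: Iterable[FeatureRecord],
    index: ReferenceIndex,
    inchikey_block1: bool = False,
) -> dict[str, SourceMatchFlags]:
    """Match structure-annotated features against drug-like sources.

    Returns a feature_id → :class:`SourceMatchFlags` map covering every
    input feature. A feature may match several sources; all flags are
    kept with no precedence. Therapeutic categories attach from the
    index's category map on a drug match. Output is independent of the
    input ordering.
    """
    if inchikey_block1:
        sets = {s: {_block1(k) for k in index.source_keys(s)} for s in DRUG_LIKE_SOURCES}
        categories = {}
        for key, terms in index.category_map.items():
            categories.setdefault(_block1(key), set()).update(terms)
    else:
        sets = {s: index.source_keys(s) for s in DRUG_LIKE_SOURCES}
        categories = index.category_map

    out: dict[str, SourceMatchFlags] = {}
    for feature in features:
        if feature.annotation_level != STRUCTURE:
            out[feature.feature_id] = SourceMatchFlags()
            continue
        key = _block1(feature.inchikey) if inchikey_block1 else feature.inchikey
        flags = {attr: key in sets[source] for attr, source in _FLAG_SOURCE.items()}
        matched_categories = (
            frozenset(categories.get(key, set())) if flags["matched_drug"] else frozenset()
        )
        out[feature.feature_id] = SourceMatchFlags(
            matched_categories=matched_categories, **flags
        )
    return out
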