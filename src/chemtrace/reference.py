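"""Reference knowledge-base loading and unified indexing.

Reference sources come in two kinds:

* *drug-like* sources (pharmaceutical, food-contact, agrochemical
  registries) contribute InChIKey identity sets and therapeutic-category
  terms;
* *natural-product* sources (LOTUS-, COCONUT-, SuperNatural-style
  occurrence databases) contribute molecular formulas and producing
  genera.

All sources are plain TSV/CSV tables of (inchikey, name/formula,
categories/genus) tuples; no SDF/XML parsing of real database dumps is
attempted. :func:`build_index` folds loaded compounds into a single
:class:`ReferenceIndex` used by every downstream screen: per-source
InChIKey sets, the union of natural-product formulas (keyed on canonical
Hill strings), genus occurrence records, and a therapeutic-category map.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .formula import FormulaError, MolecularFormula, format_formula, parse_formula

__all__ = [
    "SOURCE_KINDS",
    "DRUG_LIKE_SOURCES",
    "NP_SOURCES",
    "ReferenceCompound",
    "ReferenceIndex",
    "LoadReport",
    "load_reference_table",
    "compounds_from_frame",
    "index_from_frames",
    "build_index",
    "select_therapeutic_categories",
]

#: Drug-like source identifiers (InChIKey identity + category terms).
DRUG_LIKE_SOURCES = ("drugbank", "fccdb", "agrochem")
#: Natural-product source identifiers (formula + producing genus records).
NP_SOURCES = ("lotus", "coconut", "supernatural")
SOURCE_KINDS = DRUG_LIKE_SOURCES + NP_SOURCES

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


def is_valid_inchikey(key: str) -> bool:
    """Check the 14-10-1 uppercase block pattern of a standard InChIKey."""
    return bool(INCHIKEY_RE.match(key))


def normalize_genus(genus: str) -> str:
    """Normalize a genus name to Capitalized form for case-insensitive joins."""
    return genus.strip().capitalize()


@dataclass(frozen=True)
class ReferenceCompound:
    """One reference-database entry.

    Natural-product sources carry ``formula`` and ``producing_genera``;
    drug-like sources carry ``category_terms``.
    """

    inchikey: str
    source_id: str
    name: str = ""
    formula: Optional[MolecularFormula] = None
    category_terms: frozenset[str] = frozenset()
    producing_genera: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.source_id not in SOURCE_KINDS:
            raise ValueError(f"unknown source_id {self.source_id!r}; expected one of {SOURCE_KINDS}")
        if not is_valid_inchikey(self.inchikey):
            raise ValueError(f"invalid InChIKey {self.inchikey!r}")
        if self.producing_genera and self.source_id not in NP_SOURCES:
            raise ValueError("producing_genera only valid for natural-product sources")
        if self.category_terms and self.source_id not in DRUG_LIKE_SOURCES:
            raise ValueError("category_terms only valid for drug-like sources")


@dataclass
class LoadReport:
    """Row accounting for one reference-table load."""

    path: str
    source_id: str
    rows_read: int = 0
    rows_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def rows_dropped(self) -> int:
        return sum(self.dropped.values())

    def to_dict(self) -> dict:
        return {
            "path": self.path,
            "source_id": self.source_id,
            "rows_read": self.rows_read,
            "rows_kept": self.rows_kept,
            "rows_dropped": self.rows_dropped,
            "dropped": dict(self.dropped),
        }


@dataclass
class ReferenceIndex:
    """Unified lookup over all loaded reference sources.

    Attributes
    ----------
    inchikey_sets
        source_id → set of InChIKeys in that source.
    np_formula_union
        Union of canonical Hill formula strings over the natural-product
        sources; membership here is what makes a formula "natural".
    genus_occurrence
        Compound key (InChIKey, with canonical formula string as fallback
        key) → set of producing genera, unioned over np sources. Genera
        are stored Capitalized; use :meth:`known_genera` for lookups.
    category_map
        InChIKey → set of therapeutic-category terms (drug-like sources).
    """

    inchikey_sets: dict[str, set[str]] = field(default_factory=dict)
    np_formula_union: set[str] = field(default_factory=set)
    genus_occurrence: dict[str, set[str]] = field(default_factory=dict)
    category_map: dict[str, set[str]] = field(default_factory=dict)

    def source_keys(self, source_id: str) -> set[str]:
        return self.inchikey_sets.get(source_id, set())

    def known_genera(
        self, inchikey: Optional[str] = None, formula: Optional[MolecularFormula] = None
    ) -> set[str]:
        """Producing genera recorded for a compound.

        Looks up by InChIKey first, falling back to the canonical formula
        string when no keyed record exists.
        """
        if inchikey is not None and inchikey in self.genus_occurrence:
            return self.genus_occurrence[inchikey]
        if formula is not None:
            return self.genus_occurrence.get(format_formula(formula), set())
        return set()

    def to_dict(self) -> dict:
        return {
            "inchikey_sets": {s: sorted(v) for s, v in self.inchikey_sets.items()},
            "np_formula_union": sorted(self.np_formula_union),
            "genus_occurrence": {k: sorted(v) for k, v in sorted(self.genus_occurrence.items())},
            "category_map": {k: sorted(v) for k, v in sorted(self.category_map.items())},
        }

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceIndex":
        raw = json.loads(Path(path).read_text())
        return cls(
            inchikey_sets={s: set(v) for s, v in raw["inchikey_sets"].items()},
            np_formula_union=set(raw["np_formula_union"]),
            genus_occurrence={k: set(v) for k, v in raw["genus_occurrence"].items()},
            category_map={k: set(v) for k, v in raw["category_map"].items()},
        )


def _read_table(path: str | Path) -> pd.DataFrame:
    # TSV is canonical; comma dialect accepted via sniffing on the header line.
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"empty reference table: {path}")
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def compounds_from_frame(
    df: pd.DataFrame,
    source_id: str,
    category_delimiter: str = ";",
    label: str = "<frame>",
) -> tuple[list[ReferenceCompound], LoadReport]:
    """Convert one source's table (DataFrame) into reference compounds.

    Natural-product sources require columns ``inchikey, formula, genus``;
    drug-like sources require ``inchikey, name, categories`` (categories
    delimited by ``category_delimiter``). Rows with invalid InChIKeys or
    unparseable formulas are dropped and tallied in the
    :class:`LoadReport`; duplicate InChIKeys within a source merge their
    genera/categories.
    """
    if source_id not in SOURCE_KINDS:
        raise ValueError(f"unknown source_id {source_id!r}")
    required = (
        ["inchikey", "formula", "genus"] if source_id in NP_SOURCES else ["inchikey", "name", "categories"]
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{label}: missing required column(s) {missing} for source {source_id!r}")

    report = LoadReport(path=label, source_id=source_id)
    merged: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        report.rows_read += 1
        inchikey = str(getattr(row, "inchikey")).strip()
        if not is_valid_inchikey(inchikey):
            report.drop("invalid_inchikey")
            continue
        if source_id in NP_SOURCES:
            try:
                formula = parse_formula(str(getattr(row, "formula")))
            except FormulaError:
                report.drop("unparseable_formula")
                continue
            genera = {
                normalize_genus(g)
                for g in str(getattr(row, "genus")).split(category_delimiter)
                if g.strip()
            }
            entry = merged.setdefault(
                inchikey, {"name": "", "formula": formula, "genera": set(), "categories": set()}
            )
            entry["genera"] |= genera
        else:
            name = str(getattr(row, "name")).strip()
            categories = {
                c.strip() for c in str(getattr(row, "categories")).split(category_delimiter) if c.strip()
            }
            entry = merged.setdefault(
                inchikey, {"name": name, "formula": None, "genera": set(), "categories": set()}
            )
            entry["categories"] |= categories

    compounds = [
        ReferenceCompound(
            inchikey=key,
            source_id=source_id,
            name=entry["name"],
            formula=entry["formula"],
            category_terms=frozenset(entry["categories"]),
            producing_genera=frozenset(entry["genera"]),
        )
        for key, entry in merged.items()
    ]
    report.rows_kept = len(compounds)
    return compounds, report


def load_reference_table(
    path: str | Path,
    source_id: str,
    category_delimiter: str = ";",
) -> tuple[list[ReferenceCompound], LoadReport]:
    """Load one reference source from a delimited file (see
    :func:`compounds_from_frame` for schema and drop semantics)."""
    return compounds_from_frame(
        _read_table(path), source_id, category_delimiter, label=str(path)
    )


def index_from_frames(
    tables: Mapping[str, pd.DataFrame], category_delimiter: str = ";"
) -> ReferenceIndex:
    """Build a :class:`ReferenceIndex` straight from in-memory source tables."""
    compounds: list[ReferenceCompound] = []
    for source_id, df in tables.items():
        loaded, _ = compounds_from_frame(df, source_id, category_delimiter, label=source_id)
        compounds.extend(loaded)
    return build_index(compounds)


def build_index(compounds: Iterable[ReferenceCompound]) -> ReferenceIndex:
    """Fold reference compounds into a :class:`ReferenceIndex`.

    The natural-product formula union is keyed on canonical Hill strings
    so membership checks are independent of how a formula was written.
    Genus occurrence records are registered both under the compound's
    InChIKey and under its canonical formula string, unioned over sources.
    """
    index = ReferenceIndex()
    for compound in compounds:
        index.inchikey_sets.setdefault(compound.source_id, set()).add(compound.inchikey)
        if compound.source_id in NP_SOURCES:
            if compound.formula is not None:
                canonical = format_formula(compound.formula)
                index.np_formula_union.add(canonical)
                if compound.producing_genera:
                    index.genus_occurrence.setdefault(canonical, set()).update(
                        compound.producing_genera
                    )
            if compound.producing_genera:
                index.genus_occurrence.setdefault(compound.inchikey, set()).update(
                    compound.producing_genera
                )
        elif compound.category_terms:
            index.category_map.setdefault(compound.inchikey, set()).update(compound.category_terms)
    return index


def select_therapeutic_categories(
    index: ReferenceIndex, keep: Sequence[str] | set[str]
) -> ReferenceIndex:
    """Restrict the category map to a curated set of therapeutic terms.

    Intersects every compound's category terms with ``keep``; compounds
    left with no retained category drop out of ``category_map`` but stay
    in their source identity sets. Non-therapeutic classifications
    (chemical descriptors, industrial uses) are excluded simply by not
    listing them in ``keep``.
    """
    keep_set = set(keep)
    if not keep_set:
        raise ValueError("keep must be non-empty")
    filtered = {
        key: terms & keep_set for key, terms in index.category_map.items() if terms & keep_set
    }
    return ReferenceIndex(
        inchikey_sets={s: set(v) for s, v in index.inchikey_sets.items()},
        np_formula_union=set(index.np_formula_union),
        genus_occurrence={k: set(v) for k, v in index.genus_occurrence.items()},
        category_map=filtered,
    )
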