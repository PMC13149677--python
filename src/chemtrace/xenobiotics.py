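"""Formula-level xenobiotic screen over formula-only features.

A formula-only feature whose canonical molecular formula is absent from
the union of natural-product reference formulas is classified as a
*putative xenobiotic*; a formula present in the union is an
*np_formula_match*. Structure-annotated features follow the InChIKey
matching branch and are never screened here, though they are counted in
the partition summary. Downstream prioritization filters the xenobiotic
pool for fluorine — an element essentially absent from biosynthesis but
common in agrochemicals, pharmaceuticals and persistent pollutants — and
profiles it by DBE and heteroatom content.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Sequence

from .formula import (
    DbeResult,
    HeteroatomProfile,
    HETEROATOMS,
    MolecularFormula,
    compute_dbe,
    format_formula,
    heteroatom_profile,
)
from .matching import FORMULA_ONLY, STRUCTURE, FeatureRecord
from .reference import ReferenceIndex

__all__ = [
    "XenobioticCall",
    "PartitionSummary",
    "ScreenResult",
    "DbeHistogram",
    "classify_features",
    "filter_fluorinated",
    "dbe_histogram",
    "heteroatom_summary",
    "round_half_up",
]

NP_FORMULA_MATCH = "np_formula_match"
PUTATIVE_XENOBIOTIC = "putative_xenobiotic"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (report formatting only, never internal)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class XenobioticCall:
    """Classification of one formula-only feature."""

    feature_id: str
    call: str
    formula: MolecularFormula
    fluorinated: bool
    dbe: DbeResult
    heteroatoms: HeteroatomProfile


@dataclass(frozen=True)
class PartitionSummary:
    """Feature-partition bookkeeping for the two-branch workflow.

    ``pct_xenobiotic_of_total`` uses ALL features as denominator (the
    xenobiotic share of the whole feature table), rounded half-up to one
    decimal.
    """

    n_total: int
    n_structure: int
    n_formula_only: int
    n_np_match: int
    n_xenobiotic: int
    n_unclassifiable: int = 0

    def __post_init__(self) -> None:
        if self.n_structure + self.n_formula_only != self.n_total:
            raise ValueError("partition violated: n_structure + n_formula_only != n_total")
        if self.n_np_match + self.n_xenobiotic + self.n_unclassifiable != self.n_formula_only:
            raise ValueError(
                "partition violated: n_np_match + n_xenobiotic + n_unclassifiable != n_formula_only"
            )

    @property
    def pct_xenobiotic_of_total(self) -> float:
        if self.n_total == 0:
            return 0.0
        return round_half_up(100.0 * self.n_xenobiotic / self.n_total, 1)


@dataclass
class ScreenResult:
    """Output bundle of :func:`classify_features`."""

    calls: list[XenobioticCall]
    summary: PartitionSummary
    unclassifiable: list[str]


def classify_features(
    features: Iterable[FeatureRecord], index: ReferenceIndex
) -> ScreenResult:
    """Partition features and screen the formula-only branch.

    Membership is tested on canonical Hill formula strings against the
    natural-product formula union. Formula-only features whose formula
    failed to parse go to the ``unclassifiable`` side-list so that every
    feature lands in exactly one disposition.
    """
    calls: list[XenobioticCall] = []
    unclassifiable: list[str] = []
    n_total = n_structure = 0
    for feature in features:
        n_total += 1
        if feature.annotation_level == STRUCTURE:
            n_structure += 1
            continue
        if feature.formula is None:
            unclassifiable.append(feature.feature_id)
            continue
        canonical = format_formula(feature.formula)
        call = NP_FORMULA_MATCH if canonical in index.np_formula_union else PUTATIVE_XENOBIOTIC
        calls.append(
            XenobioticCall(
                feature_id=feature.feature_id,
                call=call,
                formula=feature.formula,
                fluorinated=feature.formula["F"] >= 1,
                dbe=compute_dbe(feature.formula),
                heteroatoms=heteroatom_profile(feature.formula),
            )
        )
    n_xeno = sum(1 for c in calls if c.call == PUTATIVE_XENOBIOTIC)
    summary = PartitionSummary(
        n_total=n_total,
        n_structure=n_structure,
        n_formula_only=n_total - n_structure,
        n_np_match=len(calls) - n_xeno,
        n_xenobiotic=n_xeno,
        n_unclassifiable=len(unclassifiable),
    )
    return ScreenResult(calls=calls, summary=summary, unclassifiable=unclassifiable)


def filter_fluorinated(calls: Iterable[XenobioticCall]) -> list[XenobioticCall]:
    """Fluorine-containing putative xenobiotics, ordered by feature id."""
    kept = [c for c in calls if c.call == PUTATIVE_XENOBIOTIC and c.fluorinated]
    return sorted(kept, key=lambda c: c.feature_id)


@dataclass
class DbeHistogram:
    """Binned DBE counts for the xenobiotic pool and its fluorinated stratum.

    Bin keys are the lower bin edges (exact rationals). Features whose
    DBE is excluded (incompatible elements) are tallied in ``skipped``.
    """

    bin_width: Fraction
    all_xenobiotic: dict[Fraction, int]
    fluorinated: dict[Fraction, int]
    skipped: int


def dbe_histogram(
    calls: Iterable[XenobioticCall], bin_width: Fraction = Fraction(1, 2)
) -> DbeHistogram:
    """Histogram of DBE over putative xenobiotics, fluorinated stratum separate."""
    bin_width = Fraction(bin_width)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    all_bins: dict[Fraction, int] = {}
    f_bins: dict[Fraction, int] = {}
    skipped = 0
    for call in calls:
        if call.call != PUTATIVE_XENOBIOTIC:
            continue
        if call.dbe.excluded:
            skipped += 1
            continue
        edge = (call.dbe.value / bin_width).__floor__() * bin_width
        all_bins[edge] = all_bins.get(edge, 0) + 1
        if call.fluorinated:
            f_bins[edge] = f_bins.get(edge, 0) + 1
    return DbeHistogram(
        bin_width=bin_width, all_xenobiotic=all_bins, fluorinated=f_bins, skipped=skipped
    )


def heteroatom_summary(calls: Iterable[XenobioticCall]) -> dict[str, int]:
    """Features-containing counts per tracked heteroatom over the xenobiotic pool.

    Each element's count is the number of putative-xenobiotic features
    containing at least one atom of it (not an atom total);
    ``halogen_any`` counts features containing any of F, Cl, Br, I.
    """
    table = {element: 0 for element in HETEROATOMS}
    table["halogen_any"] = 0
    for call in calls:
        if call.call != PUTATIVE_XENOBIOTIC:
            continue
        for element in HETEROATOMS:
            if call.heteroatoms[element] >= 1:
                table[element] += 1
        if call.heteroatoms.halogen_any:
            table["halogen_any"] += 1
    return table
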