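"""Molecular formula parsing and elemental descriptors.

A molecular formula here is a flat, neutral elemental composition such as
``C21H23ClFNO2``. From the parsed composition the module derives the
quantities used throughout the screening pipeline:

* degree of unsaturation (double bond equivalents, DBE),
* Van Krevelen coordinates (H/C and O/C elemental ratios),
* heteroatom and halogen profiles (S, P, F, Cl, Br, I).

DBE is computed with exact rational arithmetic as

    DBE = C - (H + X)/2 + N/2 + 1

where ``X`` is the total halogen count (F + Cl + Br + I). The equation has
no valence term for metals or other elements, so formulas containing
elements outside {C, H, N, O, S, P, F, Cl, Br, I} are marked *excluded*
rather than assigned a number. Half-integer DBE values are reported as-is;
they indicate radical or adduct species and rounding them would distort
the DBE distribution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Mapping, Optional

__all__ = [
    "MolecularFormula",
    "DbeResult",
    "VanKrevelenPoint",
    "HeteroatomProfile",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "compute_dbe",
    "van_krevelen",
    "heteroatom_profile",
]

#: Valid IUPAC element symbols (periodic table through Og).
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

#: Elements compatible with the DBE equation (contribute a valence term or zero).
DBE_COMPATIBLE = frozenset({"C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I"})

#: Halogens summed into the X term of the DBE equation.
HALOGENS = ("F", "Cl", "Br", "I")

#: Elements tracked by the heteroatom profile.
HETEROATOMS = ("S", "P", "F", "Cl", "Br", "I")

_SUBSCRIPT_DIGITS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a formula string cannot be parsed."""


@dataclass(frozen=True)
class MolecularFormula:
    """Canonical element→count composition of a neutral molecular formula.

    ``counts`` maps element symbols to positive integer counts; elements
    with zero count are absent. Equality and hashing are defined on the
    counts alone, so two formulas written differently (``"HO2H"`` vs
    ``"H2O2"``) compare equal.
    """

    counts: Mapping[str, int]
    source_text: str = ""

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        for element, n in counts.items():
            if element not in ELEMENT_SYMBOLS:
                raise FormulaError(f"unknown element symbol {element!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {element} must be a positive integer, got {n!r}")
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __contains__(self, element: str) -> bool:
        return element in self.counts

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __str__(self) -> str:
        return format_formula(self)

    def __repr__(self) -> str:
        return f"MolecularFormula({format_formula(self)!r})"


@dataclass(frozen=True)
class DbeResult:
    """DBE value, or an excluded marker when the equation does not apply.

    ``value`` is an exact :class:`fractions.Fraction` (2·DBE is always an
    integer) or ``None`` when the formula contains elements outside the
    compatible set; ``excluded_elements`` then names the offenders.
    """

    value: Optional[Fraction]
    excluded_elements: tuple[str, ...] = ()

    @property
    def excluded(self) -> bool:
        return self.value is None


@dataclass(frozen=True)
class VanKrevelenPoint:
    """H/C vs O/C coordinates of a carbon-containing formula."""

    h_over_c: float
    o_over_c: float
    superclass_label: Optional[str] = None


@dataclass(frozen=True)
class HeteroatomProfile:
    """Counts of the six tracked heteroatoms and a combined halogen flag."""

    counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def halogen_any(self) -> bool:
        return any(self.counts.get(x, 0) >= 1 for x in HALOGENS)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)


def _clean(text: str) -> str:
    """Strip whitespace and typographic subscript markers from a formula string."""
    return text.translate(_SUBSCRIPT_DIGITS).replace("_", "").strip()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a flat neutral formula string into a :class:`MolecularFormula`.

    Accepts underscores and Unicode subscript digits as count markers
    (``"C_8F_17KO_3S"`` parses like ``"C8F17KO3S"``). Element symbols are
    tokenized greedily, longest first, so ``Cl`` is chlorine and never
    carbon + lowercase l. Repeated element tokens accumulate.

    Charges, isotopes, adducts, hydrate dots and parentheses are rejected:
    this layer handles the flat formulas of a deconvolved feature table,
    nothing richer.

    Raises
    ------
    FormulaError
        Naming the offending span for malformed tokens, unknown element
        symbols, zero multipliers, or unsupported syntax.
    """
    cleaned = _clean(text)
    if not cleaned:
        raise FormulaError("empty formula string")
    bad = re.search(r"[^A-Za-z0-9]", cleaned)
    if bad:
        raise FormulaError(
            f"unsupported character {bad.group()!r} at position {bad.start()} in {cleaned!r} "
            "(parentheses, charges, isotopes and adducts are not supported)"
        )
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN_RE.match(cleaned, pos)
        if not m or not m.group(1):
            raise FormulaError(f"malformed token at position {pos} in {cleaned!r}: {cleaned[pos:pos+3]!r}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in ELEMENT_SYMBOLS:
            # Greedy two-char match may swallow a valid one-char symbol ("Hf" in "HF" is
            # impossible since F is uppercase, but e.g. "Cx" fails here).
            raise FormulaError(f"unknown element symbol {symbol!r} at position {pos} in {cleaned!r}")
        n = int(digits) if digits else 1
        if digits and n == 0:
            raise FormulaError(f"zero multiplier for {symbol!r} at position {pos} in {cleaned!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return MolecularFormula(counts=counts, source_text=text)


def hill_order(counts: Mapping[str, int]) -> list[str]:
    """Element ordering per the Hill convention.

    Carbon first and hydrogen second when carbon is present, remaining
    elements alphabetical; without carbon, all elements alphabetical.
    """
    elements = set(counts)
    if "C" in elements:
        rest = sorted(elements - {"C", "H"})
        return ["C"] + (["H"] if "H" in elements else []) + rest
    return sorted(elements)


def format_formula(f: MolecularFormula) -> str:
    """Render a formula as its canonical Hill-order string (count 1 omitted)."""
    parts = []
    for element in hill_order(f.counts):
        n = f.counts[element]
        parts.append(element if n == 1 else f"{element}{n}")
    return "".join(parts)


def compute_dbe(f: MolecularFormula) -> DbeResult:
    """Compute double bond equivalents: DBE = C − (H + X)/2 + N/2 + 1.

    ``X`` is the summed halogen count. O, S and P contribute zero. If the
    formula contains any element outside the compatible set the result is
    an excluded marker, not a number.
    """
    incompatible = tuple(sorted(set(f.counts) - DBE_COMPATIBLE))
    if incompatible:
        return DbeResult(value=None, excluded_elements=incompatible)
    x = sum(f[h] for h in HALOGENS)
    value = Fraction(f["C"]) - Fraction(f["H"] + x, 2) + Fraction(f["N"], 2) + 1
    return DbeResult(value=value)


def van_krevelen(
    f: MolecularFormula, superclass_label: Optional[str] = None
) -> Optional[VanKrevelenPoint]:
    """H/C and O/C elemental ratios, or ``None`` for carbon-free formulas."""
    c = f["C"]
    if c < 1:
        return None
    return VanKrevelenPoint(
        h_over_c=f["H"] / c, o_over_c=f["O"] / c, superclass_label=superclass_label
    )


def heteroatom_profile(f: MolecularFormula) -> HeteroatomProfile:
    """Counts of S, P, F, Cl, Br, I in the formula."""
    return HeteroatomProfile(counts={x: f[x] for x in HETEROATOMS if f[x] >= 1})
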