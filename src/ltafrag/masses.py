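"""Exact molecular-formula arithmetic for glycolipid mass spectrometry.

This module is the numerical foundation of the package: an element-count
container (:class:`ElementComposition`), monoisotopic and nominal mass
computation, condensation (dehydration) arithmetic, and the ionisation
conventions used for direct-infusion lipid spectra:

* ``[M+Na]+``  — sodium *atom* mass added, no electron correction.  This is
  the convention under which the published calculated masses of sodiated
  glycolipid ions (e.g. 365.1060 for sodiated diglucose) are reproduced.
* ``[M-H]-``   — proton mass subtracted (1.007276 amu).
* ``[M-2H]2-`` — two protons subtracted, m/z halved (cardiolipin dianions).
* ``[M-OH]+``  — hydroxide group (O + H atom masses) subtracted; the cation
  series behind "MAG - OH" type fragments of sodiated glycolipids.

The element set is deliberately closed: C, H, N, O, P and Na cover every
residue in the lipid classes modelled here (acyl chains, glycerol, glucose,
phosphate, alanine).  Average masses and isotope patterns are out of scope.
"""

from __future__ import annotations

import re
from enum import Enum
from typing import Iterator, Mapping

__all__ = [
    "ElementComposition",
    "FormulaError",
    "AdductError",
    "Adduct",
    "MONOISOTOPIC_MASS",
    "NOMINAL_MASS",
    "PROTON_MASS",
    "WATER",
    "GLYCEROL",
    "GLUCOSE",
    "PHOSPHORIC_ACID",
    "ALANINE",
    "CARBON_DIOXIDE",
    "parse_formula",
    "monoisotopic_mass",
    "nominal_mass",
    "condense",
    "ion_mz",
]

#: Monoisotopic masses of the most abundant isotope (amu), CODATA/IUPAC.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
    "P": 30.97376163,
}

#: Integer nominal masses (amu).
NOMINAL_MASS: dict[str, int] = {"C": 12, "H": 1, "N": 14, "O": 16, "Na": 23, "P": 31}

#: Mass of the proton (amu); subtracted on deprotonation.
PROTON_MASS: float = 1.00727646688

SUPPORTED_ELEMENTS: tuple[str, ...] = ("C", "H", "N", "Na", "O", "P")

# Hill order for the closed element set: C, H, then alphabetical.
_HILL_ORDER: tuple[str, ...] = ("C", "H", "N", "Na", "O", "P")


class FormulaError(ValueError):
    """Malformed formula string or chemically impossible composition."""


class AdductError(ValueError):
    """Adduct cannot be formed from the given neutral composition."""


class ElementComposition:
    """Immutable integer element counts; the unit of all mass arithmetic.

    Supports ``+``, ``-`` and integer ``*``.  Subtraction may transiently
    produce negative counts (useful inside condensation arithmetic); use
    :meth:`is_non_negative` or :meth:`validated` before exposing a result.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for symbol, n in source.items():
                if symbol not in MONOISOTOPIC_MASS:
                    raise FormulaError(f"unsupported element symbol: {symbol!r}")
                if int(n) != n:
                    raise FormulaError(f"non-integer count for {symbol}: {n!r}")
                merged[symbol] = merged.get(symbol, 0) + int(n)
        object.__setattr__(self, "_counts", {s: n for s, n in merged.items() if n != 0})

    def __setattr__(self, name, value):  # pragma: no cover - immutability guard
        raise AttributeError("ElementComposition is immutable")

    # -- mapping-ish interface -------------------------------------------------
    def __getitem__(self, symbol: str) -> int:
        return self._counts.get(symbol, 0)

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self._counts.items()))

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._counts))

    def __len__(self) -> int:
        return len(self._counts)

    def __bool__(self) -> bool:
        return bool(self._counts)

    # -- arithmetic ------------------------------------------------------------
    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self._counts)
        for s, n in other._counts.items():
            merged[s] = merged.get(s, 0) + n
        return ElementComposition(merged)

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self._counts)
        for s, n in other._counts.items():
            merged[s] = merged.get(s, 0) - n
        return ElementComposition(merged)

    def __mul__(self, factor: int) -> "ElementComposition":
        return ElementComposition({s: n * factor for s, n in self._counts.items()})

    __rmul__ = __mul__

    # -- predicates ------------------------------------------------------------
    def is_non_negative(self) -> bool:
        return all(n >= 0 for n in self._counts.values())

    def covers(self, other: "ElementComposition") -> bool:
        """True if every element count of *other* is <= the count in self."""
        return all(self[s] >= n for s, n in other._counts.items())

    def validated(self) -> "ElementComposition":
        if not self.is_non_negative():
            raise FormulaError(f"negative element count in {self!r}")
        return self

    # -- equality / hashing ----------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementComposition):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    # -- formatting ------------------------------------------------------------
    def hill(self) -> str:
        """Canonical Hill-notation formula string (round-trips with
        :func:`parse_formula`)."""
        parts = []
        for symbol in _HILL_ORDER:
            n = self._counts.get(symbol, 0)
            if n == 0:
                continue
            if n < 0:
                raise FormulaError(f"cannot format negative count: {symbol}{n}")
            parts.append(symbol if n == 1 else f"{symbol}{n}")
        return "".join(parts)

    def __repr__(self) -> str:
        inner = ", ".join(f"{s}={n}" for s, n in sorted(self._counts.items()))
        return f"ElementComposition({inner})"


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementComposition:
    """Parse a Hill-style formula string such as ``"C3H7NO2"``.

    Counts default to 1; a zero count or any unrecognised symbol is an error.
    """
    if not text:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed formula at position {pos}: {text!r}")
        symbol, digits = match.groups()
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element symbol {symbol!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"malformed count for {symbol} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula at position {pos}: {text!r}")
    return ElementComposition(counts)


def monoisotopic_mass(comp: ElementComposition) -> float:
    """Monoisotopic mass in amu (empty composition gives 0.0)."""
    return sum(n * MONOISOTOPIC_MASS[s] for s, n in comp.items())


def nominal_mass(comp: ElementComposition) -> int:
    """Integer nominal mass in amu."""
    return sum(n * NOMINAL_MASS[s] for s, n in comp.items())


WATER = ElementComposition(H=2, O=1)
GLYCEROL = ElementComposition(C=3, H=8, O=3)
GLUCOSE = ElementComposition(C=6, H=12, O=6)
PHOSPHORIC_ACID = ElementComposition(H=3, O=4, P=1)
ALANINE = ElementComposition(C=3, H=7, N=1, O=2)
CARBON_DIOXIDE = ElementComposition(C=1, O=2)
_HYDROXYL = ElementComposition(H=1, O=1)


def condense(a: ElementComposition, b: ElementComposition, n_bonds: int = 1) -> ElementComposition:
    """Condensation product of two molecules: a + b minus ``n_bonds`` waters.

    Raises :class:`FormulaError` if the result would have a negative count
    (e.g. condensing with an empty composition that cannot supply H2O).
    """
    if n_bonds < 1:
        raise FormulaError(f"n_bonds must be >= 1, got {n_bonds}")
    return (a + b - n_bonds * WATER).validated()


class Adduct(Enum):
    """Ionisation modes used in the positive/negative direct-infusion scans."""

    SODIATED = "[M+Na]+"
    DEPROTONATED = "[M-H]-"
    DOUBLY_DEPROTONATED = "[M-2H]2-"
    HYDROXIDE_LOSS = "[M-OH]+"

    @property
    def charge(self) -> int:
        return {"[M+Na]+": 1, "[M-H]-": -1, "[M-2H]2-": -2, "[M-OH]+": 1}[self.value]

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"


def ion_mz(neutral: ElementComposition, adduct: Adduct) -> float:
    """m/z of *neutral* ionised as *adduct*.

    Sodiated cations add the sodium atom mass (no electron-mass correction);
    deprotonated ions subtract the proton mass; the dianion subtracts two
    protons and halves; hydroxide loss subtracts O + H atom masses.
    """
    neutral.validated()
    mass = monoisotopic_mass(neutral)
    if adduct is Adduct.SODIATED:
        return mass + MONOISOTOPIC_MASS["Na"]
    if adduct is Adduct.DEPROTONATED:
        if neutral["H"] < 1:
            raise AdductError(f"cannot deprotonate {neutral.hill() or '(empty)'}")
        return mass - PROTON_MASS
    if adduct is Adduct.DOUBLY_DEPROTONATED:
        if neutral["H"] < 2:
            raise AdductError(f"cannot doubly deprotonate {neutral.hill() or '(empty)'}")
        return (mass - 2 * PROTON_MASS) / 2.0
    if adduct is Adduct.HYDROXIDE_LOSS:
        if neutral["H"] < 1 or neutral["O"] < 1:
            raise AdductError(f"cannot abstract hydroxide from {neutral.hill() or '(empty)'}")
        return mass - monoisotopic_mass(_HYDROXYL)
    raise AdductError(f"unknown adduct {adduct!r}")  # pragma: no cover
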