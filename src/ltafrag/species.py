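"""Residue-level structural model of *B. subtilis* membrane lipid classes.

The classes covered are the ones that dominate direct-infusion spectra of
cold-extracted *B. subtilis* polar lipids:

======================  =======================================  ==========
class                   shorthand                                chains
======================  =======================================  ==========
glycolipid anchor       ``(32:0) DAG-Glc-Glc``                   2
LTA primer              ``(30:0) DAG-Glc-Glc-P-Gro``             2
mono-alanylated primer  ``(30:0) DAG-Glc-Glc-P-Gro-Ala``         2
di-alanylated primer    ``(30:0) DAG-Glc-Glc-P-Gro-(Ala)2``      2
phosphatidylglycerol    ``(30:0) PG``                            2
alanyl-PG               ``(30:0) Ala-PG``                        2
cardiolipin             ``(62:0) CL``                            4
lyso-cardiolipin        ``(47:0) lyso-CL``                       3
======================  =======================================  ==========

Acyl compositions are written ``(C:D)`` — total carbons : total double
bonds — optionally resolved per chain as ``(15:0/17:0)``.  Neutral formulas
follow condensation chemistry: one water is lost per ester, glycosidic and
phosphoester bond, so any resolved split of a sum composition yields the
same formula.  The hexose is fixed to glucose (the *B. subtilis* head group).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .masses import (
    Adduct,
    AdductError,
    ALANINE,
    ElementComposition,
    FormulaError,
    GLUCOSE,
    GLYCEROL,
    PHOSPHORIC_ACID,
    WATER,
    ion_mz,
)

__all__ = [
    "AcylChain",
    "LipidClass",
    "LipidSpecies",
    "parse_species",
    "species_formula",
    "precursor_mz",
]


class LipidClass(Enum):
    """Lipid class, keyed by its shorthand token."""

    DAG_ANCHOR = "DAG-Glc-Glc"
    LTA_PRIMER = "DAG-Glc-Glc-P-Gro"
    LTA_PRIMER_ALA = "DAG-Glc-Glc-P-Gro-Ala"
    LTA_PRIMER_ALA2 = "DAG-Glc-Glc-P-Gro-(Ala)2"
    PG = "PG"
    ALANYL_PG = "Ala-PG"
    CARDIOLIPIN = "CL"
    LYSO_CARDIOLIPIN = "lyso-CL"


# (n chains, hexoses, alanines, has phosphoglycerol head)
_CLASS_TRAITS: dict[LipidClass, tuple[int, int, int, bool]] = {
    LipidClass.DAG_ANCHOR: (2, 2, 0, False),
    LipidClass.LTA_PRIMER: (2, 2, 0, True),
    LipidClass.LTA_PRIMER_ALA: (2, 2, 1, True),
    LipidClass.LTA_PRIMER_ALA2: (2, 2, 2, True),
    LipidClass.PG: (2, 0, 0, True),
    LipidClass.ALANYL_PG: (2, 0, 1, True),
    LipidClass.CARDIOLIPIN: (4, 0, 0, False),
    LipidClass.LYSO_CARDIOLIPIN: (3, 0, 0, False),
}

#: Adducts each class forms under the ionisation conditions modelled here.
#: Neutral glycolipids sodiate in positive mode; phosphate-bearing lipids
#: deprotonate; cardiolipin additionally forms the 2- dianion.
COMPATIBLE_ADDUCTS: dict[LipidClass, tuple[Adduct, ...]] = {
    LipidClass.DAG_ANCHOR: (Adduct.SODIATED,),
    LipidClass.LTA_PRIMER: (Adduct.DEPROTONATED,),
    LipidClass.LTA_PRIMER_ALA: (Adduct.DEPROTONATED,),
    LipidClass.LTA_PRIMER_ALA2: (Adduct.DEPROTONATED,),
    LipidClass.PG: (Adduct.DEPROTONATED,),
    LipidClass.ALANYL_PG: (Adduct.DEPROTONATED,),
    LipidClass.CARDIOLIPIN: (Adduct.DOUBLY_DEPROTONATED, Adduct.DEPROTONATED),
    LipidClass.LYSO_CARDIOLIPIN: (Adduct.DEPROTONATED,),
}


def default_adduct(lipid_class: LipidClass) -> Adduct:
    return COMPATIBLE_ADDUCTS[lipid_class][0]


def default_polarity(lipid_class: LipidClass) -> str:
    return default_adduct(lipid_class).polarity


@dataclass(frozen=True)
class AcylChain:
    """A fatty acyl chain; the free-acid formula is C(n)H(2n-2d)O2."""

    carbons: int
    double_bonds: int = 0

    def __post_init__(self):
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if not 0 <= self.double_bonds <= self.carbons // 2:
            raise ValueError(
                f"double bonds {self.double_bonds} out of range for C{self.carbons}"
            )

    @property
    def free_acid(self) -> ElementComposition:
        n, d = self.carbons, self.double_bonds
        return ElementComposition(C=n, H=2 * n - 2 * d, O=2)

    def __str__(self) -> str:
        return f"({self.carbons}:{self.double_bonds})"


# Dominant B. subtilis acyl pairs: the paper's species resolve to odd
# iso/anteiso chains, (15:0) and (17:0).
_PREFERRED_PAIRS: dict[tuple[int, int], tuple[AcylChain, AcylChain]] = {
    (30, 0): (AcylChain(15), AcylChain(15)),
    (32, 0): (AcylChain(15), AcylChain(17)),
    (34, 0): (AcylChain(17), AcylChain(17)),
}


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid class plus acyl composition (resolved chains optional)."""

    lipid_class: LipidClass
    total_carbons: int
    total_double_bonds: int = 0
    chains: tuple[AcylChain, ...] | None = None

    def __post_init__(self):
        n_chains = self.n_chains
        if self.chains is not None:
            if len(self.chains) != n_chains:
                raise ValueError(
                    f"{self.lipid_class.value} carries {n_chains} chains, "
                    f"got {len(self.chains)}"
                )
            if sum(c.carbons for c in self.chains) != self.total_carbons or sum(
                c.double_bonds for c in self.chains
            ) != self.total_double_bonds:
                raise ValueError("resolved chains do not sum to the stated composition")
        if self.total_carbons < 2 * n_chains:
            raise ValueError(f"total carbons {self.total_carbons} too small")
        if self.total_double_bonds < 0:
            raise ValueError("negative double-bond count")

    @property
    def n_chains(self) -> int:
        return _CLASS_TRAITS[self.lipid_class][0]

    @property
    def hexose_count(self) -> int:
        return _CLASS_TRAITS[self.lipid_class][1]

    @property
    def ala_count(self) -> int:
        return _CLASS_TRAITS[self.lipid_class][2]

    @property
    def has_phosphoglycerol_head(self) -> bool:
        return _CLASS_TRAITS[self.lipid_class][3]

    def resolved_chains(self) -> tuple[AcylChain, ...]:
        """Resolved acyl chains; unresolved sum compositions default to the
        dominant *B. subtilis* split ((30:0) -> 15:0/15:0, (32:0) -> 15:0/17:0)
        or, failing that, a near-equal split.  The choice is mass-invariant."""
        if self.chains is not None:
            return self.chains
        key = (self.total_carbons, self.total_double_bonds)
        if self.n_chains == 2 and key in _PREFERRED_PAIRS:
            return _PREFERRED_PAIRS[key]
        n = self.n_chains
        base_c, rem_c = divmod(self.total_carbons, n)
        base_d, rem_d = divmod(self.total_double_bonds, n)
        chains = []
        for i in range(n):
            c = base_c + (1 if i < rem_c else 0)
            d = base_d + (1 if i < rem_d else 0)
            chains.append(AcylChain(c, d))
        return tuple(chains)

    def formula(self) -> ElementComposition:
        return species_formula(self)

    def shorthand(self, resolved: bool = False) -> str:
        if resolved or (self.chains is not None):
            chains = self.chains if self.chains is not None else self.resolved_chains()
            comp = "/".join(f"{c.carbons}:{c.double_bonds}" for c in chains)
        else:
            comp = f"{self.total_carbons}:{self.total_double_bonds}"
        return f"({comp}) {self.lipid_class.value}"

    def __str__(self) -> str:
        return self.shorthand()


_SHORTHAND = re.compile(r"^\s*\(([\d:/\s]+)\)\s+(.+?)\s*$")
_CLASS_BY_TOKEN = {cls.value: cls for cls in LipidClass}


def parse_species(text: str) -> LipidSpecies:
    """Parse shorthand such as ``"(30:0) DAG-Glc-Glc-P-Gro-Ala"``.

    A single ``(C:D)`` token gives an unresolved sum composition; a
    slash-separated list (one entry per chain) resolves the chains.
    """
    m = _SHORTHAND.match(text)
    if not m:
        raise ValueError(f"malformed species shorthand: {text!r}")
    comp_token, class_token = m.groups()
    lipid_class = _CLASS_BY_TOKEN.get(class_token)
    if lipid_class is None:
        raise ValueError(
            f"unknown lipid class {class_token!r}; expected one of "
            f"{sorted(_CLASS_BY_TOKEN)}"
        )
    parts = [p.strip() for p in comp_token.split("/")]
    pairs = []
    for part in parts:
        try:
            c_str, d_str = part.split(":")
            pairs.append((int(c_str), int(d_str)))
        except ValueError as exc:
            raise ValueError(f"malformed acyl composition {part!r} in {text!r}") from exc
    if len(pairs) == 1:
        total_c, total_d = pairs[0]
        return LipidSpecies(lipid_class, total_c, total_d)
    chains = tuple(AcylChain(c, d) for c, d in pairs)
    return LipidSpecies(
        lipid_class,
        sum(c for c, _ in pairs),
        sum(d for _, d in pairs),
        chains=chains,
    )


def species_formula(species: LipidSpecies) -> ElementComposition:
    """Neutral molecular formula by condensation of the residue graph.

    One water is lost per covalent linkage: each acyl ester, each glycosidic
    bond, each phosphoester flank of a phosphodiester, and each alanyl ester.
    """
    cls = species.lipid_class
    chains = species.resolved_chains()
    acyls = ElementComposition()
    for chain in chains:
        acyls = acyls + chain.free_acid

    if cls in (LipidClass.CARDIOLIPIN, LipidClass.LYSO_CARDIOLIPIN):
        # three glycerols bridged by two phosphodiesters, 4 (or 3) acyls
        n_acyl = len(chains)
        total = 3 * GLYCEROL + 2 * PHOSPHORIC_ACID + acyls
        n_bonds = n_acyl + 4
        return (total - n_bonds * WATER).validated()

    total = GLYCEROL + acyls
    n_bonds = len(chains)
    total = total + species.hexose_count * GLUCOSE
    n_bonds += species.hexose_count
    if species.has_phosphoglycerol_head:
        total = total + PHOSPHORIC_ACID + GLYCEROL
        n_bonds += 2
    total = total + species.ala_count * ALANINE
    n_bonds += species.ala_count
    return (total - n_bonds * WATER).validated()


def precursor_mz(species: LipidSpecies, adduct: Adduct | None = None) -> float:
    """Molecular-ion m/z for the class-compatible adduct.

    Default adducts: sodiated for the neutral diglucosyl anchor, deprotonated
    for phosphate-bearing lipids, doubly deprotonated for cardiolipin.
    """
    if adduct is None:
        adduct = default_adduct(species.lipid_class)
    if adduct not in COMPATIBLE_ADDUCTS[species.lipid_class]:
        raise AdductError(
            f"{adduct.value} is not formed by {species.lipid_class.value}"
        )
    return ion_mz(species_formula(species), adduct)
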