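"""Theoretical fragment-ion enumeration for glycolipid tandem MS.

The fragmenter cuts labelled scissile bonds of a residue graph and applies
the water/hydrogen bookkeeping characteristic of collision-induced
dissociation of these lipids:

* Every covalent linkage in the condensed structure "owes" one water.  When
  a bond is cut, the charge-retaining side either keeps that water
  (hydroxyl-retaining cut) or loses it (dehydrating cut).  Compounded over
  one to three cuts and the final deprotonation, this generates the
  ``- H`` / ``- H3O`` / ``- H5O2`` suffix family of negative-mode fragments
  without any per-ion hard-coding.
* Acyl ester cuts therefore emit both the free-fatty-acid-loss form and the
  ketene-loss form (one water apart).
* In positive mode an ester cut on the glycerol-retaining side may instead
  lose a hydroxyl group, producing allylic cations such as the sodiated
  CH2=CH-CH2-Glc-Glc ion of the glycolipid anchor.
* Positive-mode fragments ionise either by sodiation or by hydroxide
  abstraction ("MAG - OH" type acylium-like cations); negative-mode
  fragments by deprotonation.

Bond labels follow the alphabetic convention used for the di-alanylated
primer structure: ``a``/``b`` flank the acyl esters, ``c``/``d`` the
glycerol-glucose linkage, ``f`` the glycosidic bond, ``g``-``j`` the
phosphodiester flanks, and ``k``-``n`` the alanyl ester flanks.  For species
with two identical chains the a1/a2 (b1/b2) cuts collapse to single
deduplicated ions.

Cardiolipin and lyso-cardiolipin are modelled at the molecular-ion level
only (their fragmentation is outside the catalogue's scope).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .masses import (
    Adduct,
    AdductError,
    ALANINE,
    CARBON_DIOXIDE,
    ElementComposition,
    GLUCOSE,
    GLYCEROL,
    PHOSPHORIC_ACID,
    WATER,
    condense,
    ion_mz,
    nominal_mass,
)
from .species import LipidClass, LipidSpecies, default_polarity, species_formula

__all__ = [
    "FragmentIon",
    "FragmentGraph",
    "Residue",
    "Linkage",
    "enumerate_fragments",
    "enumerate_graph_fragments",
    "special_rearrangements",
    "full_catalog",
    "neutral_loss",
    "catalog_to_frame",
    "write_catalog_tsv",
    "MIN_FRAGMENT_MZ",
]

#: Fragments below this m/z are suppressed (below the useful scan range).
MIN_FRAGMENT_MZ = 50.0

_HYDROXYL = ElementComposition(H=1, O=1)

_LABEL_ORDER = {
    lab: i
    for i, lab in enumerate(
        ["a1", "a2", "b1", "b2", "c", "d", "f", "g", "h", "i", "j", "k", "l", "m", "n"]
    )
}


@dataclass(frozen=True)
class Residue:
    """A node of the residue graph."""

    key: str
    comp: ElementComposition
    kind: str  # 'acyl' | 'backbone' | 'hexose' | 'phosphate' | 'head_glycerol' | 'alanine'
    name: str  # rendering token, e.g. '(15:0)', 'Glc', 'P', 'Gro', 'Ala'


@dataclass(frozen=True)
class Linkage:
    """An edge of the residue graph with its scissile-bond label pair.

    ``labels`` maps each endpoint key to ``(hydroxyl_retaining_label,
    dehydrating_label)`` for the case where that endpoint's side retains the
    charge.
    """

    key: str
    a: str
    b: str
    kind: str  # 'ester' | 'glycosidic' | 'phosphoester' | 'ala_ester'
    labels: tuple[tuple[str, tuple[str, str]], ...]

    def label_for(self, retained_key: str, dehydrated: bool) -> str:
        for key, (full, dehyd) in self.labels:
            if key == retained_key:
                return dehyd if dehydrated else full
        raise KeyError(retained_key)  # pragma: no cover

    def other(self, key: str) -> str:
        return self.b if key == self.a else self.a


@dataclass(frozen=True)
class FragmentGraph:
    residues: tuple[Residue, ...]
    linkages: tuple[Linkage, ...]

    def residue(self, key: str) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(key)


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical ion: neutral composition, provenance, adduct and m/z."""

    neutral: ElementComposition
    adduct: Adduct
    mz: float
    cleavage: tuple[str, ...]
    n_cuts: int
    loss: ElementComposition  # removed from the condensed fragment (cut states)
    description: str

    @property
    def charge(self) -> int:
        return self.adduct.charge


def build_graph(species: LipidSpecies) -> FragmentGraph:
    """Residue graph with labelled scissile linkages for a fragmentable class."""
    cls = species.lipid_class
    if cls in (LipidClass.CARDIOLIPIN, LipidClass.LYSO_CARDIOLIPIN):
        raise ValueError(f"{cls.value} is modelled at the molecular-ion level only")
    chains = species.resolved_chains()
    residues = [
        Residue("FA1", chains[0].free_acid, "acyl", str(chains[0])),
        Residue("FA2", chains[1].free_acid, "acyl", str(chains[1])),
        Residue("GroB", GLYCEROL, "backbone", "Gro"),
    ]
    linkages = [
        Linkage(
            "est1", "FA1", "GroB", "ester",
            (("GroB", ("a1", "b1")), ("FA1", ("b1", "a1"))),
        ),
        Linkage(
            "est2", "FA2", "GroB", "ester",
            (("GroB", ("a2", "b2")), ("FA2", ("b2", "a2"))),
        ),
    ]
    if species.hexose_count == 2:
        residues += [
            Residue("Glc1", GLUCOSE, "hexose", "Glc"),
            Residue("Glc2", GLUCOSE, "hexose", "Glc"),
        ]
        linkages += [
            Linkage(
                "gro-glc", "GroB", "Glc1", "glycosidic",
                (("Glc1", ("c", "d")), ("GroB", ("c", "d"))),
            ),
            Linkage(
                "glc-glc", "Glc1", "Glc2", "glycosidic",
                (("Glc1", ("f", "f")), ("Glc2", ("f", "f"))),
            ),
        ]
        phosphate_anchor = "Glc2"
    else:
        phosphate_anchor = "GroB"
    if species.has_phosphoglycerol_head:
        residues += [
            Residue("P", PHOSPHORIC_ACID, "phosphate", "P"),
            Residue("GroH", GLYCEROL, "head_glycerol", "Gro"),
        ]
        linkages += [
            Linkage(
                "anchor-p", phosphate_anchor, "P", "phosphoester",
                (("P", ("g", "h")), (phosphate_anchor, ("h", "g"))),
            ),
            Linkage(
                "p-gro", "P", "GroH", "phosphoester",
                (("P", ("j", "i")), ("GroH", ("i", "j"))),
            ),
        ]
        ala_labels = [("l", "k"), ("n", "m")]
        for i in range(species.ala_count):
            key = f"Ala{i + 1}"
            residues.append(Residue(key, ALANINE, "alanine", "Ala"))
            full, dehyd = ala_labels[i]
            linkages.append(
                Linkage(
                    f"ala{i + 1}", "GroH", key, "ala_ester",
                    (("GroH", (full, dehyd)), (key, (dehyd, full))),
                )
            )
    return FragmentGraph(tuple(residues), tuple(linkages))


def _components(
    graph: FragmentGraph, removed: frozenset[str]
) -> list[frozenset[str]]:
    adjacency: dict[str, list[str]] = {r.key: [] for r in graph.residues}
    for link in graph.linkages:
        if link.key in removed:
            continue
        adjacency[link.a].append(link.b)
        adjacency[link.b].append(link.a)
    seen: set[str] = set()
    components = []
    for start in adjacency:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(n for n in adjacency[node] if n not in comp)
        seen |= comp
        components.append(frozenset(comp))
    return components


def _condensed(graph: FragmentGraph, component: frozenset[str]) -> ElementComposition:
    total = ElementComposition()
    for r in graph.residues:
        if r.key in component:
            total = total + r.comp
    n_internal = sum(
        1 for l in graph.linkages if l.a in component and l.b in component
    )
    return (total - n_internal * WATER).validated()


def _describe(
    species: LipidSpecies,
    graph: FragmentGraph,
    component: frozenset[str],
    loss: ElementComposition,
    adduct: Adduct,
) -> str:
    return _core_name(species, graph, component) + _suffix(loss, adduct)


def _core_name(
    species: LipidSpecies, graph: FragmentGraph, component: frozenset[str]
) -> str:
    acyl = [graph.residue(k) for k in sorted(component) if k.startswith("FA")]
    has_grob = "GroB" in component
    sugars = sum(1 for k in component if k.startswith("Glc"))
    has_p = "P" in component
    has_groh = "GroH" in component
    n_ala = sum(1 for k in component if k.startswith("Ala"))

    def chain_tag() -> str:
        if len(acyl) == len(species.resolved_chains()):
            return f"({species.total_carbons}:{species.total_double_bonds})"
        return " ".join(r.name for r in acyl)

    if has_grob:
        family_complete = (
            sugars == species.hexose_count
            and has_p == species.has_phosphoglycerol_head
            and has_groh == species.has_phosphoglycerol_head
        )
        if family_complete and has_p:
            base = {
                LipidClass.PG: "PG",
                LipidClass.ALANYL_PG: "PG",
                LipidClass.LTA_PRIMER: "LTAP",
                LipidClass.LTA_PRIMER_ALA: "LTAP",
                LipidClass.LTA_PRIMER_ALA2: "LTAP",
            }[species.lipid_class]
            if n_ala and base == "PG":
                base = "Ala-PG"
            elif n_ala:
                base = base + ("-Ala" if n_ala == 1 else "-Ala2")
            if len(acyl) == species.n_chains:
                return f"{chain_tag()} {base}"
            if len(acyl) == 1:
                return f"{acyl[0].name} lyso-{base}"
            return f"dilyso-{base}"
        # systematic chain of residue tokens
        head = "DAG" if len(acyl) == 2 else ("MAG" if len(acyl) == 1 else "Gro")
        parts = [head]
        if sugars == 2:
            parts.append("Glc2" if (has_p or has_groh) else "Glc-Glc")
        elif sugars == 1:
            parts.append("Glc")
        if has_p:
            parts.append("P")
        if has_groh:
            parts.append("Gro")
        if n_ala:
            parts.append("Ala" if n_ala == 1 else "Ala2")
        name = "-".join(parts)
        return f"{chain_tag()} {name}" if acyl else name
    if len(acyl) == 1 and len(component) == 1:
        return f"{acyl[0].name} FA"
    parts = []
    if sugars == 2:
        parts.append("Glc2" if (has_p or has_groh) else "Glc-Glc")
    elif sugars == 1:
        parts.append("Glc")
    if has_p:
        parts.append("P")
    if has_groh:
        parts.append("Gro")
    if n_ala:
        parts.append("Ala" if n_ala == 1 else "Ala2")
    return "-".join(parts) if parts else "?"


def _suffix(loss: ElementComposition, adduct: Adduct) -> str:
    """Render the hydration/adduct suffix in the conventional table style."""
    n_water, is_water = _as_waters(loss)
    if adduct is Adduct.DEPROTONATED:
        if is_water:
            # merged with the deprotonation: -H, -H3O, -H5O2, ...
            if n_water == 0:
                return " - H"
            return f" - H{2 * n_water + 1}O{n_water if n_water > 1 else ''}"
        return f" - {loss.hill()} - H"
    if adduct is Adduct.DOUBLY_DEPROTONATED:
        return " - 2H (2-)" if not loss else f" - {loss.hill()} - 2H (2-)"
    tail = " + Na+" if adduct is Adduct.SODIATED else " - OH+"
    if is_water:
        if n_water == 0:
            return tail
        return (" - H2O" if n_water == 1 else f" - {n_water}H2O") + tail
    return f" - {loss.hill()}{tail}"


def _as_waters(loss: ElementComposition) -> tuple[int, bool]:
    n = loss["O"]
    if loss == n * WATER:
        return n, True
    return 0, False


def _cut_state_options(
    linkage: Linkage, retained_key: str, graph_kind_positive: bool
) -> list[tuple[str, ElementComposition]]:
    """Allowed per-cut states: retain the linkage water, or lose it.

    Positive-mode ester cuts retaining the glycerol side may also lose a bare
    hydroxyl (allylic dehydration).
    """
    options = [("full", ElementComposition()), ("dehydrated", WATER)]
    if (
        graph_kind_positive
        and linkage.kind == "ester"
        and not retained_key.startswith("FA")
    ):
        options.append(("hydroxyl", _HYDROXYL))
    return options


def _molecular_ions(species: LipidSpecies, polarity: str) -> list[FragmentIon]:
    neutral = species_formula(species)
    ions = []
    from .species import COMPATIBLE_ADDUCTS  # local to avoid cycle at import

    for adduct in COMPATIBLE_ADDUCTS[species.lipid_class]:
        if adduct.polarity != polarity:
            continue
        mz = ion_mz(neutral, adduct)
        tag = f"({species.total_carbons}:{species.total_double_bonds})"
        core = {
            LipidClass.DAG_ANCHOR: f"{tag} DAG-Glc-Glc",
            LipidClass.LTA_PRIMER: f"{tag} LTAP",
            LipidClass.LTA_PRIMER_ALA: f"{tag} LTAP-Ala",
            LipidClass.LTA_PRIMER_ALA2: f"{tag} LTAP-Ala2",
            LipidClass.PG: f"{tag} PG",
            LipidClass.ALANYL_PG: f"{tag} Ala-PG",
            LipidClass.CARDIOLIPIN: f"{tag} CL",
            LipidClass.LYSO_CARDIOLIPIN: f"{tag} lyso-CL",
        }[species.lipid_class]
        ions.append(
            FragmentIon(
                neutral=neutral,
                adduct=adduct,
                mz=mz,
                cleavage=(),
                n_cuts=0,
                loss=ElementComposition(),
                description=core + _suffix(ElementComposition(), adduct),
            )
        )
    return ions


def enumerate_graph_fragments(
    species: LipidSpecies,
    graph: FragmentGraph,
    polarity: str,
    max_cuts: int,
    min_mz: float = MIN_FRAGMENT_MZ,
) -> list[FragmentIon]:
    """Enumerate ions over all <=max_cuts bond subsets of an explicit graph."""
    positive = polarity == "positive"
    adducts = (
        (Adduct.SODIATED, Adduct.HYDROXIDE_LOSS) if positive else (Adduct.DEPROTONATED,)
    )
    best: dict[tuple[ElementComposition, Adduct], FragmentIon] = {}

    def consider(ion: FragmentIon) -> None:
        key = (ion.neutral, ion.adduct)
        old = best.get(key)
        rank = (ion.n_cuts, ion.cleavage)
        if old is None or rank < (old.n_cuts, old.cleavage):
            best[key] = ion

    linkage_by_key = {l.key: l for l in graph.linkages}
    for n_cut in range(0, max_cuts + 1):
        for subset in itertools.combinations(sorted(linkage_by_key), n_cut):
            removed = frozenset(subset)
            for component in _components(graph, removed):
                boundary = [
                    linkage_by_key[k]
                    for k in subset
                    if (linkage_by_key[k].a in component)
                    != (linkage_by_key[k].b in component)
                ]
                if not boundary and removed:
                    continue
                condensed = _condensed(graph, component)
                state_sets = []
                for link in boundary:
                    retained = link.a if link.a in component else link.b
                    state_sets.append(
                        [
                            (link, retained, state, delta)
                            for state, delta in _cut_state_options(
                                link, retained, positive
                            )
                        ]
                    )
                for assignment in itertools.product(*state_sets):
                    loss = ElementComposition()
                    labels = []
                    for link, retained, state, delta in assignment:
                        loss = loss + delta
                        labels.append(
                            link.label_for(retained, state != "full")
                        )
                    neutral = condensed - loss
                    if not neutral.is_non_negative():
                        continue
                    cleavage = tuple(
                        sorted(labels, key=lambda l: _LABEL_ORDER.get(l, 99))
                    )
                    for adduct in adducts:
                        try:
                            mz = ion_mz(neutral, adduct)
                        except AdductError:
                            continue
                        if mz < min_mz:
                            continue
                        consider(
                            FragmentIon(
                                neutral=neutral,
                                adduct=adduct,
                                mz=mz,
                                cleavage=cleavage,
                                n_cuts=len(boundary),
                                loss=loss,
                                description=_describe(
                                    species, graph, component, loss, adduct
                                ),
                            )
                        )
    return sorted(best.values(), key=lambda i: (i.mz, i.adduct.value))


def enumerate_fragments(
    species: LipidSpecies,
    polarity: str | None = None,
    max_cuts: int | None = None,
    min_mz: float = MIN_FRAGMENT_MZ,
) -> list[FragmentIon]:
    """Theoretical fragment catalogue of *species*, sorted by m/z.

    ``max_cuts`` defaults to 3 for alanylated classes (whose spectra require
    triple cuts) and 2 otherwise; it must lie in 1..3.  Cardiolipin classes
    yield molecular ions only.
    """
    if polarity is None:
        polarity = default_polarity(species.lipid_class)
    if polarity not in ("positive", "negative"):
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    if polarity != default_polarity(species.lipid_class):
        raise ValueError(
            f"{species.lipid_class.value} is observed in "
            f"{default_polarity(species.lipid_class)} mode, not {polarity}"
        )
    if species.lipid_class in (LipidClass.CARDIOLIPIN, LipidClass.LYSO_CARDIOLIPIN):
        return _molecular_ions(species, polarity)
    if max_cuts is None:
        max_cuts = 3 if species.ala_count else 2
    if not 1 <= max_cuts <= 3:
        raise ValueError(f"max_cuts must be in 1..3, got {max_cuts}")
    graph = build_graph(species)
    return enumerate_graph_fragments(species, graph, polarity, max_cuts, min_mz)


def special_rearrangements(species: LipidSpecies) -> list[FragmentIon]:
    """Two-step rearrangement ions unique to the di-alanylated primer.

    A head-group rearrangement condenses the two ester-linked alanines into
    an alanyl-alanine dipeptide that leaves as the deprotonated anion; an
    alternative rearrangement exposes a terminal carboxyl which decarboxylates,
    so the molecular anion also appears minus CO2.  Other classes yield an
    empty list.
    """
    if species.lipid_class is not LipidClass.LTA_PRIMER_ALA2:
        return []
    dipeptide = condense(ALANINE, ALANINE, 1)
    m_minus_co2 = (species_formula(species) - CARBON_DIOXIDE).validated()
    tag = f"({species.total_carbons}:{species.total_double_bonds})"
    return [
        FragmentIon(
            neutral=dipeptide,
            adduct=Adduct.DEPROTONATED,
            mz=ion_mz(dipeptide, Adduct.DEPROTONATED),
            cleavage=("rearrangement",),
            n_cuts=0,
            loss=ElementComposition(),
            description="Ala-Ala - H",
        ),
        FragmentIon(
            neutral=m_minus_co2,
            adduct=Adduct.DEPROTONATED,
            mz=ion_mz(m_minus_co2, Adduct.DEPROTONATED),
            cleavage=("rearrangement",),
            n_cuts=0,
            loss=CARBON_DIOXIDE,
            description=f"{tag} LTAP-Ala2 - CO2 - H",
        ),
    ]


def full_catalog(
    species: LipidSpecies,
    polarity: str | None = None,
    max_cuts: int | None = None,
    min_mz: float = MIN_FRAGMENT_MZ,
) -> list[FragmentIon]:
    """Enumerated cleavage fragments plus the class-specific rearrangement
    ions, deduplicated by (composition, adduct) and sorted by m/z."""
    ions = enumerate_fragments(species, polarity, max_cuts, min_mz)
    by_key = {(i.neutral, i.adduct): i for i in ions}
    for extra in special_rearrangements(species):
        by_key.setdefault((extra.neutral, extra.adduct), extra)
    return sorted(by_key.values(), key=lambda i: (i.mz, i.adduct.value))


def neutral_loss(
    precursor: FragmentIon | ElementComposition,
    fragment: FragmentIon | ElementComposition,
) -> tuple[ElementComposition, int]:
    """Expelled neutral between a precursor and one of its fragments.

    Returns the element-wise composition difference and its nominal mass;
    raises if the fragment is not a sub-composition of the precursor.
    """
    pre = precursor.neutral if isinstance(precursor, FragmentIon) else precursor
    frag = fragment.neutral if isinstance(fragment, FragmentIon) else fragment
    if not pre.covers(frag):
        raise ValueError(
            f"fragment {frag.hill()} is not a sub-composition of {pre.hill()}"
        )
    diff = (pre - frag).validated()
    return diff, nominal_mass(diff)


def catalog_to_frame(ions: Iterable[FragmentIon]) -> pd.DataFrame:
    rows = []
    for ion in ions:
        rows.append(
            {
                "mz": round(ion.mz, 4),
                "polarity": ion.adduct.polarity,
                "adduct": ion.adduct.value,
                "cleavage": " & ".join(ion.cleavage) if ion.cleavage else "[M]",
                "n_cuts": ion.n_cuts,
                "loss": ion.loss.hill() if ion.loss else "",
                "formula": ion.neutral.hill(),
                "description": ion.description,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mz", "polarity", "adduct", "cleavage", "n_cuts", "loss",
            "formula", "description",
        ],
    )


def write_catalog_tsv(ions: Sequence[FragmentIon], path) -> None:
    """TSV export with 4-decimal m/z, sorted ascending."""
    frame = catalog_to_frame(ions)
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")
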