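"""Fragment enumeration: table reproduction, bookkeeping invariants, oracle."""

import pandas as pd
import pytest

from ltafrag.fragments import (
    FragmentGraph,
    Linkage,
    MIN_FRAGMENT_MZ,
    Residue,
    enumerate_fragments,
    enumerate_graph_fragments,
    full_catalog,
    neutral_loss,
    special_rearrangements,
    write_catalog_tsv,
)
from ltafrag.masses import (
    ElementComposition,
    GLUCOSE,
    GLYCEROL,
    PHOSPHORIC_ACID,
    parse_formula,
)
from ltafrag.reference import REFERENCE_TABLES, load_reference
from ltafrag.species import parse_species

from _oracles import brute_force_path_fragment_mzs

TABLE_KEYS = {
    "anchor_32_0": "anchor_32",
    "primer_30_0": "primer_30",
    "primer_ala_30_0": "primer_ala_30",
    "primer_ala2_30_0": "primer_ala2_30",
}


def _nearest_mz(catalog, target):
    return min(catalog, key=lambda ion: abs(ion.mz - target)).mz


class TestTableReproduction:
    @pytest.mark.parametrize("table", sorted(REFERENCE_TABLES))
    def test_reported_calculated_masses_in_catalog(self, table, catalogs):
        """Every consistent reported calculated mass appears in the
        enumerated catalogue within 0.002 amu."""
        catalog = catalogs[TABLE_KEYS[table]]
        frame = load_reference(table)
        for _, row in frame.iterrows():
            if {"contaminant", "reported_mz_inconsistent"} & row["flag_set"]:
                continue
            reported = float(row["reported_mz"])
            assert abs(_nearest_mz(catalog, reported) - reported) <= 0.002, row[
                "description"
            ]

    def test_misprinted_value_recomputed_from_neutral_loss_arithmetic(self, catalogs):
        """The one reported calculated mass that contradicts its own
        neutral-loss arithmetic: the acyl+head double-cut fragment of the
        primer must equal the head-cut fragment minus the 15:0 fatty acid
        (943.5399 - 242.2246), not the printed 701.3051."""
        catalog = catalogs["primer_30"]
        head_cut = _nearest_mz(catalog, 943.5399)
        fa15 = 242.2246
        ours = _nearest_mz(catalog, head_cut - fa15)
        assert ours == pytest.approx(head_cut - fa15, abs=0.002)
        assert abs(ours - 701.3051) > 0.005  # the printed value is inconsistent


class TestBookkeeping:
    def test_symmetric_chains_deduplicate(self, species, catalogs):
        """With two identical 15:0 chains, a1/a2 and b1/b2 cuts give one ion."""
        fa_ions = [
            ion
            for ion in catalogs["primer_30"]
            if ion.neutral == parse_formula("C15H30O2")
        ]
        assert len(fa_ions) == 1

    def test_conservation_of_composition(self, species, catalogs):
        """fragment + neutral loss = precursor, element-wise, for every
        fragment whose composition is contained in the molecular ion."""
        molecular = species["primer_30"].formula()
        for ion in catalogs["primer_30"]:
            if not molecular.covers(ion.neutral):
                continue
            loss, _ = neutral_loss(molecular, ion)
            assert (ion.neutral + loss) == molecular

    def test_named_neutral_losses(self, species, catalogs):
        """The expelled neutrals behind the published fragment walk-throughs."""
        anchor = species["anchor_32"].formula()
        cases = {
            645.3462: ("C17H34O2", 270),  # 17:0 fatty acid
            673.3775: ("C15H30O2", 242),  # 15:0 fatty acid
            753.5493: ("C6H10O5", 162),  # anhydroglucose
        }
        for target, (formula, nominal) in cases.items():
            ion = min(catalogs["anchor_32"], key=lambda i: abs(i.mz - target))
            loss, nom = neutral_loss(anchor, ion)
            assert loss == parse_formula(formula)
            assert nom == nominal

    def test_neutral_loss_requires_sub_composition(self):
        with pytest.raises(ValueError):
            neutral_loss(GLUCOSE, PHOSPHORIC_ACID)

    def test_neutral_loss_of_itself_is_empty(self):
        loss, nominal = neutral_loss(GLUCOSE, GLUCOSE)
        assert loss == ElementComposition() and nominal == 0

    def test_minimum_mz_filter(self, catalogs):
        for catalog in catalogs.values():
            assert all(ion.mz >= MIN_FRAGMENT_MZ for ion in catalog)

    @pytest.mark.parametrize("bad_cuts", [0, 4])
    def test_max_cuts_range(self, species, bad_cuts):
        with pytest.raises(ValueError):
            enumerate_fragments(species["primer_30"], max_cuts=bad_cuts)

    def test_polarity_mismatch_rejected(self, species):
        with pytest.raises(ValueError):
            enumerate_fragments(species["anchor_32"], polarity="negative")

    def test_cardiolipin_is_molecular_ion_only(self, species):
        ions = full_catalog(species["cl_62"])
        assert all(ion.n_cuts == 0 for ion in ions)
        assert any(ion.adduct.charge == -2 for ion in ions)


class TestRearrangements:
    def test_dialanylated_gains_exactly_two_ions(self, species):
        ions = special_rearrangements(species["primer_ala2_30"])
        assert len(ions) == 2
        mzs = sorted(ion.mz for ion in ions)
        assert mzs[0] == pytest.approx(159.0770, abs=0.002)  # Ala-Ala - H
        assert mzs[1] == pytest.approx(1115.6610, abs=0.002)  # M - CO2 - H

    @pytest.mark.parametrize("key", ["primer_30", "primer_ala_30", "pg_30"])
    def test_other_classes_get_none(self, species, key):
        assert special_rearrangements(species[key]) == []


class TestOracleEquivalence:
    def test_linear_chain_matches_brute_force(self, species):
        """On a 4-residue glucosyl-glucosyl-phosphoglycerol chain, the graph
        enumerator emits exactly the ions a brute-force generator finds by
        trying every contiguous segment with every water state."""
        residues = (
            Residue("Glc1", GLUCOSE, "hexose", "Glc"),
            Residue("Glc2", GLUCOSE, "hexose", "Glc"),
            Residue("P", PHOSPHORIC_ACID, "phosphate", "P"),
            Residue("GroH", GLYCEROL, "head_glycerol", "Gro"),
        )
        linkages = (
            Linkage("l1", "Glc1", "Glc2", "glycosidic", (("Glc1", ("f", "f")), ("Glc2", ("f", "f")))),
            Linkage("l2", "Glc2", "P", "phosphoester", (("P", ("g", "h")), ("Glc2", ("h", "g")))),
            Linkage("l3", "P", "GroH", "phosphoester", (("P", ("j", "i")), ("GroH", ("i", "j")))),
        )
        graph = FragmentGraph(residues, linkages)
        ions = enumerate_graph_fragments(
            species["primer_30"], graph, "negative", max_cuts=2
        )
        engine = {round(ion.mz, 6) for ion in ions}
        oracle = brute_force_path_fragment_mzs(
            [GLUCOSE, GLUCOSE, PHOSPHORIC_ACID, GLYCEROL]
        )
        assert engine == oracle


class TestExport:
    def test_tsv_round_trip(self, catalogs, tmp_path):
        path = tmp_path / "catalog.tsv"
        write_catalog_tsv(catalogs["primer_30"], path)
        frame = pd.read_csv(path, sep="\t")
        assert list(frame.columns[:4]) == ["mz", "polarity", "adduct", "cleavage"]
        assert len(frame) == len(catalogs["primer_30"])
        assert frame["mz"].is_monotonic_increasing
        assert f"{1017.5769:.4f}" in frame["mz"].map(lambda v: f"{v:.4f}").values
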