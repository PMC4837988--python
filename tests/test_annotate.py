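"""Peak annotation, diagnostic scans and species nomination."""

import pytest

from ltafrag.annotate import (
    DIAGNOSTIC_CLASSES,
    DIAGNOSTIC_IONS,
    annotate_spectrum,
    annotation_report,
    match_stats,
    nominate_species,
    precursor_scan,
)
from ltafrag.reference import load_reference, reference_spectrum
from ltafrag.simulate import NoiseModel, simulate_msms
from ltafrag.species import LipidSpecies, parse_species, precursor_mz
from ltafrag.spectra import Peak, Spectrum


class TestAnnotateSpectrum:
    def test_empty_spectrum(self, species):
        result = annotate_spectrum(Spectrum(polarity="negative"), species["primer_30"])
        assert result.annotations == () and result.unmatched == ()

    def test_zero_error_round_trip(self, species):
        noiseless = simulate_msms(
            species["primer_30"], noise=NoiseModel(mz_error_sd=0.0, seed=1)
        )
        result = annotate_spectrum(noiseless, species["primer_30"], tol=1e-6)
        assert not result.unmatched
        assert all(a.delta == 0.0 for a in result.annotations)

    def test_observed_primer_table_fully_annotated(self, species):
        """The 12 observed high-accuracy fragments of the (30:0) primer are
        all explained by its catalogue at 0.01 amu."""
        spectrum = reference_spectrum("primer_30_0")
        result = annotate_spectrum(spectrum, species["primer_30"], tol=0.01)
        assert result.n_matched == 12 and not result.unmatched
        assert match_stats(result.annotations).max_abs_delta <= 0.01

    def test_tolerance_monotonicity(self, species):
        spectrum = reference_spectrum("primer_ala2_30_0")
        counts = [
            annotate_spectrum(spectrum, species["primer_ala2_30"], tol=tol).n_matched
            for tol in (0.001, 0.005, 0.01, 0.05, 0.3)
        ]
        assert counts == sorted(counts)

    def test_far_peak_reported_unmatched(self, species):
        spectrum = Spectrum(polarity="negative", peaks=(Peak(10000.0, 5.0),))
        result = annotate_spectrum(spectrum, species["primer_30"], tol=0.01)
        assert result.n_matched == 0 and len(result.unmatched) == 1

    def test_polarity_mismatch_rejected(self, species):
        spectrum = Spectrum(polarity="positive", peaks=(Peak(100.0, 1.0),))
        with pytest.raises(ValueError):
            annotate_spectrum(spectrum, species["primer_30"])

    def test_report_mirrors_peak_order(self, species):
        spectrum = reference_spectrum("primer_30_0")
        result = annotate_spectrum(spectrum, species["primer_30"], tol=0.01)
        report = annotation_report(result)
        assert list(report["observed_mz"]) == sorted(report["observed_mz"])
        assert len(report) == len(spectrum)


class TestMatchStats:
    def test_empty(self):
        stats = match_stats([])
        assert (stats.n_matched, stats.max_abs_delta, stats.mean_abs_delta) == (0, 0.0, 0.0)

    def test_single_negative_delta(self, species, catalogs):
        ion = catalogs["primer_30"][0]
        from ltafrag.annotate import Annotation

        stats = match_stats([Annotation(Peak(ion.mz - 0.0015), ion, -0.0015)])
        assert stats.max_abs_delta == pytest.approx(0.0015)


@pytest.fixture(scope="module")
def msms_set():
    shorthands = [
        "(30:0) PG", "(32:0) PG",
        "(30:0) DAG-Glc-Glc-P-Gro", "(32:0) DAG-Glc-Glc-P-Gro",
        "(30:0) Ala-PG", "(32:0) Ala-PG",
        "(30:0) DAG-Glc-Glc-P-Gro-Ala", "(32:0) DAG-Glc-Glc-P-Gro-Ala",
    ]
    out = {}
    for i, text in enumerate(shorthands):
        sp = parse_species(text)
        out[precursor_mz(sp)] = simulate_msms(sp, noise=NoiseModel(seed=100 + i))
    return out


class TestPrecursorScan:
    def test_phosphoglycerol_scan_hits_terminal_emitters_only(self, msms_set):
        """The 153 channel lights up PG and LTA primer but not lipids whose
        phosphoglycerol is esterified or embedded."""
        hits = precursor_scan(
            msms_set, DIAGNOSTIC_IONS["phosphoglycerol_153"], tol=0.01, min_intensity=150.0
        )
        assert sorted(round(h.precursor_mz) for h in hits) == [693, 722, 1018, 1046]

    def test_alaninate_scan_hits_alanylated_lipids(self, msms_set):
        hits = precursor_scan(
            msms_set, DIAGNOSTIC_IONS["alaninate_88"], tol=0.01, min_intensity=150.0
        )
        assert sorted(round(h.precursor_mz) for h in hits) == [765, 793, 1089, 1117]
        for hit in hits:
            assert hit.species  # candidates explaining precursor + diagnostic

    def test_out_of_range_diagnostic_is_empty(self, msms_set):
        assert precursor_scan(msms_set, 10000.0, tol=0.01) == []

    def test_mixed_polarity_rejected(self, msms_set):
        mixed = dict(msms_set)
        mixed[1.0] = Spectrum(polarity="positive", peaks=(Peak(100.0, 1.0),))
        with pytest.raises(ValueError):
            precursor_scan(mixed, 88.0)


class TestNomination:
    @pytest.mark.parametrize(
        "mz,diagnostic,expected",
        [
            (1017.58, "phosphoglycerol_153", "(30:0) DAG-Glc-Glc-P-Gro"),
            (1159.65, "alaninate_88", "(30:0) DAG-Glc-Glc-P-Gro-(Ala)2"),
            (915.60, "dihexose_347", "(32:0) DAG-Glc-Glc"),
            (693.47, "phosphoglycerol_153", "(30:0) PG"),
            (764.51, "alaninate_88", "(30:0) Ala-PG"),
        ],
    )
    def test_published_precursors_nominate_correctly(self, mz, diagnostic, expected):
        hits = nominate_species(mz, diagnostic, tol=0.02)
        assert hits and hits[0][0].shorthand() == expected

    def test_self_consistency_over_search_grid(self):
        """Every supported species is ranked first for its own precursor."""
        for diagnostic, classes in DIAGNOSTIC_CLASSES.items():
            for lipid_class in classes:
                for carbons in (24, 28, 31, 35, 40):
                    for dbs in (0, 2, 4):
                        sp = LipidSpecies(lipid_class, carbons, dbs)
                        hits = nominate_species(precursor_mz(sp), diagnostic, tol=0.01)
                        assert hits, sp
                        top = hits[0][0]
                        assert (
                            top.lipid_class,
                            top.total_carbons,
                            top.total_double_bonds,
                        ) == (lipid_class, carbons, dbs)

    def test_unknown_887_species_has_no_candidate(self):
        assert nominate_species(887.0, "phosphoglycerol_153", tol=0.02) == []

    def test_unknown_diagnostic_rejected(self):
        with pytest.raises(ValueError):
            nominate_species(1000.0, "nonesuch")
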