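import pytest

from ltafrag import full_catalog, parse_species

SPECIES_SHORTHAND = {
    "anchor_32": "(32:0) DAG-Glc-Glc",
    "anchor_30": "(30:0) DAG-Glc-Glc",
    "primer_30": "(30:0) DAG-Glc-Glc-P-Gro",
    "primer_32": "(32:0) DAG-Glc-Glc-P-Gro",
    "primer_ala_30": "(30:0) DAG-Glc-Glc-P-Gro-Ala",
    "primer_ala2_30": "(30:0) DAG-Glc-Glc-P-Gro-(Ala)2",
    "pg_30": "(30:0) PG",
    "pg_32": "(32:0) PG",
    "ala_pg_30": "(30:0) Ala-PG",
    "cl_62": "(62:0) CL",
    "lyso_cl_47": "(47:0) lyso-CL",
}


@pytest.fixture(scope="session")
def species():
    return {key: parse_species(text) for key, text in SPECIES_SHORTHAND.items()}


@pytest.fixture(scope="session")
def catalogs(species):
    """Theoretical catalogues for the four table species, built once."""
    return {
        key: full_catalog(species[key])
        for key in ("anchor_32", "primer_30", "primer_ala_30", "primer_ala2_30")
    }
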