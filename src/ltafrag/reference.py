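"""Curated reference MS/MS peak lists for the four characterised species.

Each table transcribes the originally reported high-accuracy tandem-MS
fragment list for one lipid: the observed m/z, the reported calculated m/z,
the cleavage assignment and a description.  They are the package's
regression surface: the fragmenter must reproduce the reported values and
the annotator must explain the observed ones.

Row flags:

``qtrap_only``
    observed only on the unit-resolution instrument (one decimal digit);
    matched at the 0.3 amu unit-resolution tolerance.
``contaminant``
    a background free fatty acid, not a fragment of the species.
``reported_mz_inconsistent``
    the reported calculated value contradicts the neutral-loss arithmetic
    that accompanies it (a 0.0098 amu discrepancy consistent with a
    misprint); the arithmetically consistent value is recomputed in tests.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .spectra import Peak, Spectrum

__all__ = ["REFERENCE_TABLES", "load_reference", "reference_spectrum"]

#: table name -> (species shorthand, polarity)
REFERENCE_TABLES: dict[str, tuple[str, str]] = {
    "anchor_32_0": ("(32:0) DAG-Glc-Glc", "positive"),
    "primer_30_0": ("(30:0) DAG-Glc-Glc-P-Gro", "negative"),
    "primer_ala_30_0": ("(30:0) DAG-Glc-Glc-P-Gro-Ala", "negative"),
    "primer_ala2_30_0": ("(30:0) DAG-Glc-Glc-P-Gro-(Ala)2", "negative"),
}


def load_reference(name: str) -> pd.DataFrame:
    """Load one reference table as a DataFrame (flags parsed to a frozenset
    per row under the ``flag_set`` column)."""
    if name not in REFERENCE_TABLES:
        raise KeyError(f"unknown reference table {name!r}; have {sorted(REFERENCE_TABLES)}")
    with resources.files("ltafrag.data").joinpath(f"{name}.tsv").open() as handle:
        frame = pd.read_csv(handle, sep="\t", keep_default_na=False)
    frame["flags"] = frame["flags"].fillna("")
    frame["flag_set"] = [
        frozenset(f for f in str(flags).split(";") if f and f != "nan")
        for flags in frame["flags"]
    ]
    return frame


def reference_spectrum(name: str, include_flagged: bool = True) -> Spectrum:
    """The observed peaks of one reference table as a unit-intensity
    Spectrum (optionally excluding flagged rows)."""
    frame = load_reference(name)
    _, polarity = REFERENCE_TABLES[name]
    peaks = []
    for _, row in frame.iterrows():
        if not include_flagged and row["flag_set"]:
            continue
        peaks.append(Peak(float(row["observed_mz"]), 1.0))
    precursor = max(p.mz for p in peaks) if peaks else None
    return Spectrum(polarity=polarity, peaks=tuple(peaks), precursor_mz=precursor, title=name)
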