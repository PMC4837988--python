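"""Peak annotation, precursor-ion-scan emulation and species nomination.

Annotation matches observed peaks greedily against a theoretical fragment
catalogue: each peak is assigned the nearest catalogue ion within tolerance
(ties go to the ion reachable with the fewest cuts, then the
lexicographically smallest cleavage label set); unmatched peaks are reported
separately, never force-assigned.

The three diagnostic channels mirror the scans used to profile *B. subtilis*
lipid extracts:

* ``dihexose_347``        — sodiated dehydrated diglucose (positive mode),
  emitted by diglucosyl-DAG anchors;
* ``phosphoglycerol_153`` — cyclic glycerophosphate anion (negative mode),
  intense for lipids with a *terminal* phosphoglycerol (PG, LTA primer);
* ``alaninate_88``        — deprotonated alanine (negative mode), emitted by
  every lipid with an ester-linked alanine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fragments import FragmentIon, full_catalog
from .masses import Adduct, ALANINE, GLUCOSE, GLYCEROL, PHOSPHORIC_ACID, WATER, condense, ion_mz
from .species import LipidClass, LipidSpecies, default_polarity, precursor_mz
from .spectra import Peak, Spectrum

__all__ = [
    "Annotation",
    "AnnotationResult",
    "MatchStats",
    "ScanHit",
    "DIAGNOSTIC_IONS",
    "annotate_spectrum",
    "match_stats",
    "precursor_scan",
    "nominate_species",
    "annotation_report",
]

#: Default matching tolerances (amu): high mass accuracy vs unit resolution.
TOL_HIGH_ACCURACY = 0.005
TOL_UNIT_RESOLUTION = 0.3

#: Diagnostic-channel m/z values, recomputed from the formula engine.
DIAGNOSTIC_IONS: dict[str, float] = {
    "dihexose_347": ion_mz(condense(GLUCOSE, GLUCOSE, 1) - WATER, Adduct.SODIATED),
    "phosphoglycerol_153": ion_mz(
        condense(PHOSPHORIC_ACID, GLYCEROL, 1) - WATER, Adduct.DEPROTONATED
    ),
    "alaninate_88": ion_mz(ALANINE, Adduct.DEPROTONATED),
}

#: Lipid classes a diagnostic channel can nominate.  The 153 channel is
#: restricted to terminal-phosphoglycerol classes: lipids whose
#: phosphoglycerol is embedded or esterified (cardiolipin, aminoacyl-PGs,
#: alanylated primers) emit it only weakly.
DIAGNOSTIC_CLASSES: dict[str, tuple[LipidClass, ...]] = {
    "dihexose_347": (LipidClass.DAG_ANCHOR,),
    "phosphoglycerol_153": (LipidClass.PG, LipidClass.LTA_PRIMER),
    "alaninate_88": (
        LipidClass.ALANYL_PG,
        LipidClass.LTA_PRIMER_ALA,
        LipidClass.LTA_PRIMER_ALA2,
    ),
}

#: Acyl sum-composition search grid for nomination.
ACYL_CARBON_RANGE = range(24, 41)
ACYL_DOUBLE_BOND_RANGE = range(0, 5)


@dataclass(frozen=True)
class Annotation:
    peak: Peak
    fragment: FragmentIon
    delta: float  # observed - calculated, amu


@dataclass(frozen=True)
class AnnotationResult:
    species: LipidSpecies
    tol: float
    annotations: tuple[Annotation, ...]
    unmatched: tuple[Peak, ...]

    @property
    def n_matched(self) -> int:
        return len(self.annotations)


@dataclass(frozen=True)
class MatchStats:
    n_matched: int
    max_abs_delta: float
    mean_abs_delta: float


@dataclass(frozen=True)
class ScanHit:
    precursor_mz: float
    diagnostic_mz: float
    intensity: float
    species: tuple[LipidSpecies, ...] = ()


def annotate_spectrum(
    spectrum: Spectrum,
    species: LipidSpecies,
    tol: float = TOL_HIGH_ACCURACY,
    catalog: Sequence[FragmentIon] | None = None,
) -> AnnotationResult:
    """Greedily annotate each peak with the nearest catalogue ion within
    ``tol`` amu."""
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    if spectrum.polarity != default_polarity(species.lipid_class):
        raise ValueError(
            f"spectrum polarity {spectrum.polarity!r} incompatible with "
            f"{species.lipid_class.value}"
        )
    if catalog is None:
        catalog = full_catalog(species, spectrum.polarity)
    catalog = sorted(catalog, key=lambda i: i.mz)
    mz = np.array([ion.mz for ion in catalog])
    annotations: list[Annotation] = []
    unmatched: list[Peak] = []
    for peak in spectrum.peaks:
        if len(mz) == 0:
            unmatched.append(peak)
            continue
        idx = int(np.searchsorted(mz, peak.mz))
        candidates = [i for i in (idx - 1, idx) if 0 <= i < len(mz)]
        deltas = {i: peak.mz - mz[i] for i in candidates}
        within = {i: d for i, d in deltas.items() if abs(d) <= tol}
        if not within:
            unmatched.append(peak)
            continue
        best_abs = min(abs(d) for d in within.values())
        tied = [i for i, d in within.items() if abs(abs(d) - best_abs) < 1e-12]
        chosen = min(tied, key=lambda i: (catalog[i].n_cuts, catalog[i].cleavage))
        annotations.append(Annotation(peak, catalog[chosen], within[chosen]))
    return AnnotationResult(species, tol, tuple(annotations), tuple(unmatched))


def match_stats(annotations: Sequence[Annotation]) -> MatchStats:
    """Deterministic |delta| summary of a set of annotations."""
    if not annotations:
        return MatchStats(0, 0.0, 0.0)
    abs_deltas = [abs(a.delta) for a in annotations]
    return MatchStats(len(annotations), max(abs_deltas), sum(abs_deltas) / len(abs_deltas))


def precursor_scan(
    msms_set: Mapping[float, Spectrum],
    diagnostic_mz: float,
    tol: float = 0.01,
    min_intensity: float = 0.0,
    nominate: bool = True,
    nominate_tol: float = 0.02,
) -> list[ScanHit]:
    """Emulated precursor-ion scan over a set of tandem spectra.

    A precursor is a hit when its MS/MS spectrum contains a peak within
    ``tol`` of ``diagnostic_mz`` above ``min_intensity``; the trace intensity
    is that diagnostic peak's intensity.  If the diagnostic m/z corresponds
    to a known channel, species explaining both precursor and diagnostic are
    attached.
    """
    polarities = {s.polarity for s in msms_set.values()}
    if len(polarities) > 1:
        raise ValueError("precursor scan requires a single polarity")
    channel = _channel_for(diagnostic_mz)
    hits = []
    for precursor in sorted(msms_set):
        spectrum = msms_set[precursor]
        matches = [
            p
            for p in spectrum.peaks
            if abs(p.mz - diagnostic_mz) <= tol and p.intensity > min_intensity
        ]
        if not matches:
            continue
        intensity = max(p.intensity for p in matches)
        species: tuple[LipidSpecies, ...] = ()
        if nominate and channel is not None:
            species = tuple(
                s for s, _ in nominate_species(precursor, channel, nominate_tol)
            )
        hits.append(ScanHit(precursor, diagnostic_mz, intensity, species))
    return hits


def _channel_for(diagnostic_mz: float, tol: float = 0.05) -> str | None:
    for name, mz in DIAGNOSTIC_IONS.items():
        if abs(mz - diagnostic_mz) <= tol:
            return name
    return None


def nominate_species(
    precursor_mz_value: float,
    diagnostic: str | float,
    tol: float = 0.02,
) -> list[tuple[LipidSpecies, float]]:
    """Rank candidate species for a precursor seen in a diagnostic scan.

    Searches the classes compatible with the diagnostic channel over acyl sum
    compositions (C 24-40, 0-4 double bonds) and returns species whose
    molecular-ion m/z lies within ``tol``, ranked by |observed - calculated|.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    if isinstance(diagnostic, str):
        if diagnostic not in DIAGNOSTIC_CLASSES:
            raise ValueError(
                f"unknown diagnostic {diagnostic!r}; expected one of "
                f"{sorted(DIAGNOSTIC_CLASSES)}"
            )
        channel = diagnostic
    else:
        channel = _channel_for(float(diagnostic))
        if channel is None:
            raise ValueError(
                f"diagnostic m/z {diagnostic} does not match a known channel"
            )
    candidates: list[tuple[LipidSpecies, float]] = []
    for lipid_class in DIAGNOSTIC_CLASSES[channel]:
        for carbons in ACYL_CARBON_RANGE:
            for dbs in ACYL_DOUBLE_BOND_RANGE:
                species = LipidSpecies(lipid_class, carbons, dbs)
                delta = precursor_mz_value - precursor_mz(species)
                if abs(delta) <= tol:
                    candidates.append((species, delta))
    candidates.sort(key=lambda sd: abs(sd[1]))
    return candidates


def annotation_report(result: AnnotationResult) -> pd.DataFrame:
    """Tabular report mirroring the published table layout: observed,
    calculated, cleavage, description and signed deviation; unmatched peaks
    keep empty calculated fields.  Row order mirrors the input peak order."""
    rows = []
    all_peaks = sorted(
        list(result.annotations) + list(result.unmatched),
        key=lambda x: (x.peak.mz if isinstance(x, Annotation) else x.mz),
    )
    for item in all_peaks:
        if isinstance(item, Annotation):
            rows.append(
                {
                    "observed_mz": round(item.peak.mz, 4),
                    "intensity": item.peak.intensity,
                    "calculated_mz": round(item.fragment.mz, 4),
                    "delta": round(item.delta, 4),
                    "cleavage": " & ".join(item.fragment.cleavage) or "[M]",
                    "description": item.fragment.description,
                }
            )
        else:
            rows.append(
                {
                    "observed_mz": round(item.mz, 4),
                    "intensity": item.intensity,
                    "calculated_mz": None,
                    "delta": None,
                    "cleavage": "",
                    "description": "unmatched",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["observed_mz", "intensity", "calculated_mz", "delta", "cleavage", "description"],
    )
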