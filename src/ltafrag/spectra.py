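"""Spectrum containers and peak-list I/O (MGF and two-column CSV)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = ["Peak", "Spectrum", "read_mgf", "write_mgf", "read_peaks_csv", "write_peaks_csv"]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """A centroided peak list with fixed polarity, sorted by m/z."""

    polarity: str
    peaks: tuple[Peak, ...] = field(default_factory=tuple)
    precursor_mz: float | None = None
    title: str = ""

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be 'positive'/'negative', got {self.polarity!r}")
        ordered = tuple(sorted(self.peaks, key=lambda p: p.mz))
        object.__setattr__(self, "peaks", ordered)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def base_peak(self) -> Peak | None:
        return max(self.peaks, key=lambda p: p.intensity) if self.peaks else None


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF peak-list file; polarity is taken from the charge sign."""
    spectra = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry.get("params", {})
            charges = params.get("charge")
            polarity = "positive"
            if charges:
                polarity = "negative" if int(charges[0]) < 0 else "positive"
            pepmass = params.get("pepmass")
            precursor = float(pepmass[0]) if pepmass else None
            peaks = tuple(
                Peak(float(mz), float(it))
                for mz, it in zip(entry["m/z array"], entry["intensity array"])
            )
            spectra.append(
                Spectrum(
                    polarity=polarity,
                    peaks=peaks,
                    precursor_mz=precursor,
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    entries = []
    for i, spectrum in enumerate(spectra):
        params = {"title": spectrum.title or f"spectrum_{i}"}
        if spectrum.precursor_mz is not None:
            params["pepmass"] = round(spectrum.precursor_mz, 4)
        params["charge"] = "1-" if spectrum.polarity == "negative" else "1+"
        entries.append(
            {
                "m/z array": spectrum.mz_array,
                "intensity array": spectrum.intensity_array,
                "params": params,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_peaks_csv(
    path: str | Path,
    polarity: str,
    precursor_mz: float | None = None,
) -> Spectrum:
    """Read a two-column (m/z, intensity) CSV; a header row is optional and a
    missing intensity column defaults to 1."""
    try:
        frame = pd.read_csv(path, header=None, comment="#")
    except pd.errors.EmptyDataError:
        return Spectrum(polarity=polarity, precursor_mz=precursor_mz)
    if frame.empty:
        return Spectrum(polarity=polarity, precursor_mz=precursor_mz)
    # drop a header row if the first cell is not numeric
    try:
        float(frame.iloc[0, 0])
    except (TypeError, ValueError):
        frame = frame.iloc[1:]
    if frame.empty:
        return Spectrum(polarity=polarity, precursor_mz=precursor_mz)
    mz = frame.iloc[:, 0].astype(float)
    if frame.shape[1] > 1:
        intensity = frame.iloc[:, 1].astype(float)
    else:
        intensity = pd.Series(np.ones(len(frame)))
    peaks = tuple(Peak(m, i) for m, i in zip(mz, intensity))
    return Spectrum(polarity=polarity, peaks=peaks, precursor_mz=precursor_mz)


def write_peaks_csv(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"mz": [round(p.mz, 4) for p in spectrum.peaks],
         "intensity": [round(p.intensity, 4) for p in spectrum.peaks]}
    ).to_csv(path, index=False)
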