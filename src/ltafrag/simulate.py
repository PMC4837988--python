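"""Synthetic direct-infusion spectra with the cluster structure of
*B. subtilis* polar-lipid extracts.

The generator produces three artefacts, each deterministic under its seed:

``simulate_msms``
    One peak per theoretical catalogue ion with Gaussian m/z jitter and
    log-normal intensity, plus uniform background peaks.
``simulate_full_scan``
    One molecular-ion peak per mixture species (cardiolipin as its 2-
    dianion), abundance-scaled.
``simulate_precursor_scan``
    Composes per-species tandem spectra and keeps the precursors whose
    spectrum shows the diagnostic ion — the in-silico analogue of the
    347+/153-/88- precursor-ion scans.

A key qualitative feature of the real scans is reproduced: the 153 amu
cyclic glycerophosphate anion is intense only for lipids with a *terminal*
phosphoglycerol.  Species whose phosphoglycerol is embedded or esterified
(cardiolipin, lyso-cardiolipin, alanyl-PG, alanylated primers) emit it at
5% of the signal scale, below the default precursor-scan threshold.

Intensities are arbitrary units: signal peaks are log-normal around
``signal_scale`` (default 1000), noise peaks uniform on
(0, ``noise_intensity_max``] (default 50).  Relative abundances of the
default mixture are order-of-magnitude choices (PG dominant, cardiolipin
dianions in the 650-680 window, primer and alanylated clusters minor), not
quantitative fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .annotate import DIAGNOSTIC_IONS
from .fragments import full_catalog
from .species import (
    LipidClass,
    LipidSpecies,
    default_polarity,
    parse_species,
    precursor_mz,
)
from .spectra import Peak, Spectrum

__all__ = [
    "NoiseModel",
    "MixtureSpec",
    "QTOF_NOISE",
    "QTRAP_NOISE",
    "default_mixture",
    "load_mixture",
    "simulate_msms",
    "simulate_full_scan",
    "simulate_precursor_scan",
    "EMBEDDED_PHOSPHOGLYCEROL_CLASSES",
    "PRECURSOR_SCAN_MIN_INTENSITY",
]

#: Classes whose phosphoglycerol is embedded/esterified: weak 153 emitters.
EMBEDDED_PHOSPHOGLYCEROL_CLASSES = frozenset(
    {
        LipidClass.CARDIOLIPIN,
        LipidClass.LYSO_CARDIOLIPIN,
        LipidClass.ALANYL_PG,
        LipidClass.LTA_PRIMER_ALA,
        LipidClass.LTA_PRIMER_ALA2,
    }
)

#: Intensity damping applied to the 153 diagnostic for embedded emitters.
EMBEDDED_DIAGNOSTIC_SCALE = 0.05

#: Default absolute trace threshold for the emulated precursor scans; sits
#: between the damped-diagnostic band (~50) and the signal floor (~550).
PRECURSOR_SCAN_MIN_INTENSITY = 150.0


@dataclass(frozen=True)
class NoiseModel:
    """Instrument emulation parameters (reproducible given ``seed``)."""

    mz_error_sd: float = 0.0005  # amu, Gaussian per peak
    n_noise_peaks: int = 0
    signal_scale: float = 1000.0  # log-normal median of signal intensities
    signal_sigma: float = 0.2  # log-sd of signal intensities
    noise_intensity_max: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.mz_error_sd < 0:
            raise ValueError("mz_error_sd must be >= 0")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: High-accuracy (Q-TOF-like) and unit-resolution (QTRAP-like) presets.
QTOF_NOISE = NoiseModel(mz_error_sd=0.0005)
QTRAP_NOISE = NoiseModel(mz_error_sd=0.2)


@dataclass(frozen=True)
class MixtureSpec:
    """Lipid species with relative abundances plus the scan range."""

    components: tuple[tuple[LipidSpecies, float], ...]
    scan_range: tuple[float, float] = (400.0, 1700.0)

    def __post_init__(self):
        for species, abundance in self.components:
            if abundance <= 0:
                raise ValueError(f"abundance must be > 0 for {species}")
        lo, hi = self.scan_range
        if not lo < hi:
            raise ValueError("scan_range must be (low, high) with low < high")


# Relative abundances: PG dominant; CL dianions in the 650-680 window;
# primer, alanyl-PG and alanylated-primer clusters progressively weaker.
_DEFAULT_MIXTURE = (
    ("(30:0) PG", 100.0),
    ("(32:0) PG", 80.0),
    ("(62:0) CL", 35.0),
    ("(64:0) CL", 30.0),
    ("(47:0) lyso-CL", 10.0),
    ("(30:0) DAG-Glc-Glc-P-Gro", 40.0),
    ("(32:0) DAG-Glc-Glc-P-Gro", 30.0),
    ("(30:0) Ala-PG", 25.0),
    ("(32:0) Ala-PG", 20.0),
    ("(30:0) DAG-Glc-Glc-P-Gro-Ala", 15.0),
    ("(32:0) DAG-Glc-Glc-P-Gro-Ala", 12.0),
    ("(30:0) DAG-Glc-Glc-P-Gro-(Ala)2", 8.0),
    ("(32:0) DAG-Glc-Glc-P-Gro-(Ala)2", 6.0),
)


def default_mixture() -> MixtureSpec:
    """The default negative-mode *B. subtilis*-like membrane mixture."""
    return MixtureSpec(
        tuple((parse_species(s), a) for s, a in _DEFAULT_MIXTURE)
    )


def load_mixture(path: str | Path) -> MixtureSpec:
    """Load a mixture from a YAML file with ``species: {shorthand: abundance}``
    and optional ``scan_range: [low, high]``."""
    with open(path) as handle:
        config = yaml.safe_load(handle) or {}
    species_map = config.get("species")
    if not species_map:
        raise ValueError(f"mixture file {path} defines no species")
    components = tuple(
        (parse_species(name), float(abundance))
        for name, abundance in species_map.items()
    )
    scan_range = tuple(float(x) for x in config.get("scan_range", (400.0, 1700.0)))
    return MixtureSpec(components, scan_range)  # type: ignore[arg-type]


def _is_diagnostic_153(mz: float) -> bool:
    return abs(mz - DIAGNOSTIC_IONS["phosphoglycerol_153"]) <= 0.02


def simulate_msms(
    species: LipidSpecies,
    polarity: str | None = None,
    noise: NoiseModel = NoiseModel(),
) -> Spectrum:
    """Synthetic tandem spectrum: one jittered peak per catalogue ion plus
    background noise peaks; deterministic per seed."""
    if polarity is None:
        polarity = default_polarity(species.lipid_class)
    catalog = full_catalog(species, polarity)
    rng = noise.rng()
    damped = species.lipid_class in EMBEDDED_PHOSPHOGLYCEROL_CLASSES
    peaks = []
    for ion in catalog:
        mz = ion.mz + (rng.normal(0.0, noise.mz_error_sd) if noise.mz_error_sd else 0.0)
        intensity = rng.lognormal(math.log(noise.signal_scale), noise.signal_sigma)
        if damped and _is_diagnostic_153(ion.mz):
            intensity *= EMBEDDED_DIAGNOSTIC_SCALE
        peaks.append(Peak(mz, intensity))
    precursor = max(catalog, key=lambda i: i.mz).mz if catalog else None
    hi = (precursor or 1000.0) + 10.0
    for _ in range(noise.n_noise_peaks):
        peaks.append(
            Peak(rng.uniform(50.0, hi), rng.uniform(0.0, noise.noise_intensity_max) + 1e-9)
        )
    return Spectrum(
        polarity=polarity,
        peaks=tuple(peaks),
        precursor_mz=precursor,
        title=f"MSMS {species.shorthand()}",
    )


def simulate_full_scan(
    mixture: MixtureSpec,
    polarity: str = "negative",
    noise: NoiseModel = NoiseModel(),
) -> Spectrum:
    """Synthetic survey scan: abundance-scaled molecular ions of the mixture
    (skipping species that do not ionise in the requested polarity) plus
    uniform noise over the scan range."""
    rng = noise.rng()
    peaks = []
    for species, abundance in mixture.components:
        if default_polarity(species.lipid_class) != polarity:
            continue
        mz = precursor_mz(species)
        if not mixture.scan_range[0] <= mz <= mixture.scan_range[1]:
            continue
        jitter = rng.normal(0.0, noise.mz_error_sd) if noise.mz_error_sd else 0.0
        intensity = abundance * rng.lognormal(
            math.log(noise.signal_scale), noise.signal_sigma
        )
        peaks.append(Peak(mz + jitter, intensity))
    lo, hi = mixture.scan_range
    for _ in range(noise.n_noise_peaks):
        peaks.append(
            Peak(rng.uniform(lo, hi), rng.uniform(0.0, noise.noise_intensity_max) + 1e-9)
        )
    return Spectrum(polarity=polarity, peaks=tuple(peaks), title="full scan")


def simulate_precursor_scan(
    mixture: MixtureSpec,
    diagnostic_mz: float,
    polarity: str = "negative",
    noise: NoiseModel = NoiseModel(),
    tol: float = 0.01,
    min_intensity: float = PRECURSOR_SCAN_MIN_INTENSITY,
) -> Spectrum:
    """Emulated precursor-ion-scan trace for one diagnostic channel.

    Each mixture species is fragmented in silico (its own derived seed); the
    species is retained when its spectrum shows the diagnostic ion above
    ``min_intensity``, and contributes a trace point at its molecular-ion m/z
    with the diagnostic peak's abundance-scaled intensity.
    """
    points = []
    for index, (species, abundance) in enumerate(mixture.components):
        if default_polarity(species.lipid_class) != polarity:
            continue
        sub_noise = replace(noise, seed=(noise.seed + 7919 * (index + 1)) % (2**31))
        msms = simulate_msms(species, polarity, sub_noise)
        matches = [
            p
            for p in msms.peaks
            if abs(p.mz - diagnostic_mz) <= tol and p.intensity >= min_intensity
        ]
        if not matches:
            continue
        mz = precursor_mz(species)
        if not mixture.scan_range[0] <= mz <= mixture.scan_range[1]:
            continue
        intensity = abundance * max(p.intensity for p in matches) / noise.signal_scale
        points.append(Peak(mz, intensity))
    return Spectrum(
        polarity=polarity,
        peaks=tuple(points),
        title=f"precursor scan {diagnostic_mz:.4f}",
    )
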