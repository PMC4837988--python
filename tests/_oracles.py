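"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's enumeration machinery: fragments of a
linear residue chain are generated by trying every contiguous segment with
every water-retention state at its cut boundaries.
"""

from __future__ import annotations

from ltafrag.masses import (
    Adduct,
    ElementComposition,
    WATER,
    ion_mz,
)


def brute_force_path_fragment_mzs(
    residues: list[ElementComposition],
    min_mz: float = 50.0,
) -> set[float]:
    """All deprotonated-fragment m/z values of a linear condensed chain.

    Every contiguous segment is a candidate fragment; each cut boundary
    (left and/or right) independently retains or loses one water.  Returns
    m/z rounded to 6 decimals for robust set comparison.
    """
    n = len(residues)
    mzs: set[float] = set()
    for i in range(n):
        for j in range(i, n):
            segment = residues[i : j + 1]
            condensed = ElementComposition()
            for comp in segment:
                condensed = condensed + comp
            condensed = condensed - (len(segment) - 1) * WATER
            n_boundaries = (1 if i > 0 else 0) + (1 if j < n - 1 else 0)
            for lost_waters in range(n_boundaries + 1):
                neutral = condensed - lost_waters * WATER
                if not neutral.is_non_negative() or neutral["H"] < 1:
                    continue
                mz = ion_mz(neutral, Adduct.DEPROTONATED)
                if mz >= min_mz:
                    mzs.add(round(mz, 6))
    return mzs
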