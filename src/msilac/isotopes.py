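"""Unit-mass isotopomer distributions for natural and 15N-enriched peptides.

A peptide's isotopomer envelope at unit (nominal-mass) resolution is the
convolution of the per-element isotope distributions: each element with n
atoms contributes its single-atom nominal-offset distribution convolved with
itself n times, and elements combine by further convolution.  Bin 0 is
anchored at the monoisotopic (all-light) mass; bin k sits one nominal mass
unit higher per step.  This is the envelope a MALDI-TOF reflector spectrum
shows — fine structure within a nominal mass is deliberately aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import ElementalFormula, monoisotopic_mass
from .constants import ISOTOPE_ABUNDANCE
from .errors import InvalidInputError

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class IsotopePattern:
    """Relative isotopomer abundances on a +1 Da nominal grid.

    ``abundances[k]`` is the relative abundance of the isotopomer k nominal
    mass units above ``monoisotopic_mass``; the vector is normalized to sum
    to one.
    """

    monoisotopic_mass: float
    abundances: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.abundances, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidInputError("abundances must be a non-empty 1-D vector")
        if np.any(arr < 0):
            raise InvalidInputError("abundances must be non-negative")
        if abs(arr.sum() - 1.0) > _SUM_TOL:
            raise InvalidInputError("abundances must sum to 1 within 1e-9")
        arr.flags.writeable = False
        object.__setattr__(self, "abundances", arr)

    @property
    def n_bins(self) -> int:
        return int(self.abundances.size)

    def mean_offset(self) -> float:
        """Mean nominal-mass offset above monoisotopic, in bins (~Da)."""
        return float(np.dot(np.arange(self.n_bins), self.abundances))

    def same_grid(self, other: "IsotopePattern", tol: float = 1e-6) -> bool:
        return (
            self.n_bins == other.n_bins
            and abs(self.monoisotopic_mass - other.monoisotopic_mass) <= tol
        )


def default_n_bins(formula: ElementalFormula) -> int:
    """N_count + 6: room for a fully 15N-shifted envelope plus natural tail."""
    return formula["N"] + 6


def _convolve_power(dist: np.ndarray, n: int, n_bins: int) -> np.ndarray:
    """``dist`` convolved with itself n times, truncated to ``n_bins``.

    Truncation commutes with convolution here because offsets only grow, so
    the first ``n_bins`` coefficients are exact.
    """
    result = np.zeros(n_bins)
    result[0] = 1.0
    base = dist[:n_bins].copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[:n_bins]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:n_bins]
    return result


def raw_distribution(
    formula: ElementalFormula,
    n_bins: int,
    n15_fraction: float | None = None,
) -> np.ndarray:
    """Unnormalized (truncated) isotopomer vector of a formula.

    With ``n15_fraction=None`` every element follows natural abundance;
    otherwise nitrogen atoms are independently heavy with that probability (a
    binomial) and all other elements stay natural.  The sum of the returned
    vector is <= 1, the deficit being the truncated tail.  Used internally so
    mixtures can be formed before the final normalization.
    """
    if n_bins < 1:
        raise InvalidInputError("n_bins must be >= 1")
    out = np.zeros(n_bins)
    out[0] = 1.0
    for element, count in formula.counts.items():
        if element == "N" and n15_fraction is not None:
            single = np.array([1.0 - n15_fraction, n15_fraction])
        else:
            single = np.asarray(ISOTOPE_ABUNDANCE[element])
        out = np.convolve(out, _convolve_power(single, count, n_bins))[:n_bins]
    return out


def _normalized(formula: ElementalFormula, raw: np.ndarray) -> IsotopePattern:
    total = raw.sum()
    if total <= 0:
        raise InvalidInputError("truncated distribution has zero mass")
    return IsotopePattern(monoisotopic_mass(formula), raw / total)


def natural_pattern(formula: ElementalFormula, n_bins: int | None = None) -> IsotopePattern:
    """Isotopomer distribution at natural isotope abundance.

    Bins beyond ``n_bins`` are truncated and the remainder renormalized.
    """
    if n_bins is None:
        n_bins = default_n_bins(formula)
    return _normalized(formula, raw_distribution(formula, n_bins))


def enriched_pattern(
    formula: ElementalFormula,
    n15_fraction: float,
    n_bins: int | None = None,
) -> IsotopePattern:
    """Isotopomer distribution with nitrogen at a set 15N fraction.

    Models material built from an amino-acid supply enriched to
    ``n15_fraction`` heavy nitrogen (0.98 for the 98%-enriched algal mixture);
    C, H, O and S remain at natural abundance.
    """
    if not 0.0 <= n15_fraction <= 1.0:
        raise InvalidInputError("n15_fraction must lie in [0, 1]")
    if n_bins is None:
        n_bins = default_n_bins(formula)
    return _normalized(formula, raw_distribution(formula, n_bins, n15_fraction))
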