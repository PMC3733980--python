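"""Peptide chemistry: elemental formulas, sequences, tryptic digestion.

Everything downstream of this module (isotope patterns, labeling models,
turnover fits) works on :class:`ElementalFormula` objects produced here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

from .constants import (
    MODIFICATION_FORMULA,
    MODIFICATION_TARGET,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    RESIDUE_FORMULA,
    WATER,
)
from .errors import InvalidInputError

ELEMENTS = ("C", "H", "N", "O", "S")

#: Sentinel modification position meaning "every Cys residue" (the usual
#: database-search convention for a fixed modification).
FIXED_CYS = "fixed-Cys"

ModificationKey = Union[int, str]


@dataclass(frozen=True)
class ElementalFormula:
    """Atom counts per element (C, H, N, O, S) of a peptide or fragment."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for element, n in self.counts.items():
            if element not in ELEMENTS:
                raise InvalidInputError(f"unsupported element {element!r}")
            if not isinstance(n, int) or n < 0:
                raise InvalidInputError(
                    f"atom count for {element} must be a non-negative integer, got {n!r}"
                )
            if n:
                clean[element] = n
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return ElementalFormula(merged)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula({e: n * k for e, n in self.counts.items()})

    __rmul__ = __mul__

    @property
    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def hill(self) -> str:
        """Hill-order formula string, e.g. ``C2H5NO2`` for glycine."""
        parts = []
        for element in ("C", "H", "N", "O", "S"):
            n = self[element]
            if n == 0:
                continue
            parts.append(element if n == 1 else f"{element}{n}")
        return "".join(parts) or "(empty)"

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string like ``C4H8N2O3``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z])(\d*)", text):
            if m.start() != pos:
                raise InvalidInputError(f"cannot parse formula {text!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(text):
            raise InvalidInputError(f"cannot parse formula {text!r}")
        return cls(counts)


WATER_FORMULA = ElementalFormula(WATER)


@dataclass(frozen=True)
class PeptideSequence:
    """An amino-acid sequence with optional modifications.

    ``modifications`` holds ``(position, name)`` pairs where ``position`` is a
    0-based residue index, or the string ``"fixed-Cys"`` to apply
    carbamidomethylation to every cysteine (the fixed-modification convention
    of database searches).
    """

    sequence: str
    modifications: frozenset[tuple[ModificationKey, str]] = frozenset()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError("empty peptide sequence")
        bad = set(self.sequence) - set(RESIDUE_FORMULA)
        if bad:
            raise InvalidInputError(
                f"unknown residue code(s) {sorted(bad)}; standard 20 letters only"
            )
        object.__setattr__(self, "modifications", frozenset(self.modifications))
        for key, name in self.modifications:
            if name not in MODIFICATION_FORMULA:
                raise InvalidInputError(f"unknown modification {name!r}")
            if key == FIXED_CYS:
                if name != "carbamidomethyl":
                    raise InvalidInputError(
                        f"{FIXED_CYS} applies only to carbamidomethyl, got {name!r}"
                    )
                continue
            if not isinstance(key, int) or not 0 <= key < len(self.sequence):
                raise InvalidInputError(f"modification position {key!r} out of range")
            if self.sequence[key] != MODIFICATION_TARGET[name]:
                raise InvalidInputError(
                    f"{name} applies to {MODIFICATION_TARGET[name]} residues, "
                    f"but position {key} is {self.sequence[key]}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def as_peptide(peptide: Union[str, PeptideSequence]) -> PeptideSequence:
    return peptide if isinstance(peptide, PeptideSequence) else PeptideSequence(peptide)


def composition(peptide: Union[str, PeptideSequence]) -> ElementalFormula:
    """Elemental composition of a (modified) peptide.

    The formula is the sum of residue formulas plus one water for the free
    termini, plus the delta of every modification (carbamidomethyl +C2H3NO on
    each Cys when the fixed modification is enabled, +O on each oxidized Met).
    """
    pep = as_peptide(peptide)
    formula = WATER_FORMULA
    for residue in pep.sequence:
        formula = formula + ElementalFormula(RESIDUE_FORMULA[residue])
    for key, name in pep.modifications:
        delta = ElementalFormula(MODIFICATION_FORMULA[name])
        if key == FIXED_CYS:
            formula = formula + delta * pep.sequence.count("C")
        else:
            formula = formula + delta
    return formula


def residue_formula(residue: str) -> ElementalFormula:
    """Formula of a single residue as incorporated in a chain (no water)."""
    try:
        return ElementalFormula(RESIDUE_FORMULA[residue])
    except KeyError:
        raise InvalidInputError(f"unknown residue code {residue!r}") from None


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in Da (all atoms at their lightest isotope)."""
    return sum(n * MONOISOTOPIC_MASS[e] for e, n in formula.counts.items())


def protonated_mass(formula: ElementalFormula, charge: int = 1) -> float:
    """m/z of the [M+zH]^z+ ion; MALDI spectra are singly charged (z=1)."""
    if charge < 1:
        raise InvalidInputError("charge must be >= 1")
    return (monoisotopic_mass(formula) + charge * PROTON_MASS) / charge


def peptide_mass(peptide: Union[str, PeptideSequence], charge: int = 0) -> float:
    """Convenience: neutral (charge=0) or protonated peptide mass."""
    formula = composition(peptide)
    if charge == 0:
        return monoisotopic_mass(formula)
    return protonated_mass(formula, charge)


def digest(
    protein: Union[str, PeptideSequence],
    max_missed_cleavages: int = 1,
) -> list[PeptideSequence]:
    """In-silico tryptic digest.

    Trypsin cleaves C-terminal to K or R except when the next residue is
    proline.  Returns every peptide with 0..``max_missed_cleavages`` internal
    missed cleavage sites, ordered N-terminus to C-terminus (by start
    position, shorter first at equal start).  A ``fixed-Cys`` modification on
    the protein is inherited by every peptide; positional modifications are
    not propagated through digestion.
    """
    prot = as_peptide(protein)
    if max_missed_cleavages < 0:
        raise InvalidInputError("max_missed_cleavages must be >= 0")
    seq = prot.sequence
    inherited = frozenset(m for m in prot.modifications if m[0] == FIXED_CYS)

    # Cleavage points: index i such that the bond after seq[i-1] is cut.
    cuts = [0]
    for i in range(1, len(seq)):
        if seq[i - 1] in "KR" and seq[i] != "P":
            cuts.append(i)
    cuts.append(len(seq))

    peptides = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + max_missed_cleavages, len(cuts))):
            peptides.append(
                PeptideSequence(seq[cuts[a]:cuts[b]], modifications=inherited)
            )
    return peptides


def digest_lookup(
    protein: Union[str, PeptideSequence],
    target_mz: float,
    tolerance: float = 1.2,
    max_missed_cleavages: int = 1,
    charge: int = 1,
) -> list[PeptideSequence]:
    """All tryptic peptides whose [M+zH]^z+ lies within ``tolerance`` of
    ``target_mz`` — the mass-fingerprint lookup used to attach an observed
    MALDI fragment (e.g. the 1702.5 m/z Annexin A1 peptide) to candidate
    sequences.  Every candidate within tolerance is returned; choosing among
    them is the caller's problem, as it would be for a search engine.
    """
    if tolerance <= 0:
        raise InvalidInputError("tolerance must be positive")
    hits = []
    for pep in digest(protein, max_missed_cleavages):
        if abs(peptide_mass(pep, charge=charge) - target_mz) <= tolerance:
            hits.append(pep)
    return hits
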