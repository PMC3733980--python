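"""Physical constants for peptide isotope calculations.

Atomic masses and isotope abundances are the IUPAC/CIAAW recommended values
rounded to six significant figures.  Each element entry lists its isotopes as
``(nominal mass offset from the lightest isotope, relative abundance)``; the
offsets are what the unit-mass (aggregated) isotopomer convolution operates
on.  Only C, H, N, O and S occur in unmodified peptides and in the two
modifications supported here (carbamidomethyl, Met oxidation).
"""

from __future__ import annotations

CONSTANTS_VERSION = "2021-iupac-6sf"

#: Monoisotopic (lightest isotope) atomic masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00783,
    "C": 12.0,
    "N": 14.0031,
    "O": 15.9949,
    "S": 31.9721,
}

#: Isotope abundance by nominal mass offset.  Index k of each tuple is the
#: abundance of the isotope k Da above the lightest (zeros fill gaps, e.g.
#: 35S is absent and 36S sits at offset +4).
ISOTOPE_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),                 # 1H, 2H
    "C": (0.989300, 0.010700),                 # 12C, 13C
    "N": (0.996360, 0.003640),                 # 14N, 15N
    "O": (0.997570, 0.000380, 0.002050),       # 16O, 17O, 18O
    "S": (0.949900, 0.007500, 0.042500, 0.0, 0.000100),  # 32S..36S
}

#: Natural abundance of 15N, used for the enriched-vs-natural identity check
#: and the mean-mass-shift relation.
NATURAL_N15 = ISOTOPE_ABUNDANCE["N"][1]

#: Mass of a proton, Da — protonation for singly charged MALDI ions [M+H]+.
PROTON_MASS = 1.00728

#: Average spacing of successive unit-mass isotopomer peaks, Da.  Lies between
#: the 13C-12C (1.00336) and 15N-14N (1.00011) spacings weighted toward carbon,
#: the convention for unit-resolution envelope grids.
BIN_SPACING = 1.00335

#: Monoisotopic elemental composition of the 20 standard amino-acid residues
#: (as incorporated in a chain, i.e. minus water).
RESIDUE_FORMULA: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

WATER: dict[str, int] = {"H": 2, "O": 1}

#: Mass deltas of the supported modifications, as elemental compositions.
#: Carbamidomethylation (iodoacetamide alkylation of Cys) adds C2H3NO; its
#: nitrogen is reagent-derived, never metabolically labeled.  Oxidation of
#: Met adds one oxygen.
MODIFICATION_FORMULA: dict[str, dict[str, int]] = {
    "carbamidomethyl": {"C": 2, "H": 3, "N": 1, "O": 1},
    "oxidation": {"O": 1},
}

MODIFICATION_TARGET: dict[str, str] = {
    "carbamidomethyl": "C",
    "oxidation": "M",
}
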