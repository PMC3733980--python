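"""Loaders for the packaged reference tables and sequences.

The three CSV fixtures are verbatim transcriptions of the published dose,
time-course and synthesis-rate tables of the oxythiamine / MIA PaCa-2 study
this package reimplements (``--`` entries become empty cells; one obvious
dropped decimal point, 025 -> 0.25, is repaired).  The FASTA fixture is the
canonical human Annexin A1 sequence (UniProt P04083), the protein whose
1702.5 m/z tryptic fragment anchors the turnover example.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .chem import PeptideSequence
from .io import read_fasta, read_spot_table
from .spots import SpotTable

_DATA = files("msilac.data")

#: Condition labels of the dose table, control first, doses ascending (uM).
DOSE_CONDITIONS = ("ratio_0uM", "ratio_5uM", "ratio_50uM", "ratio_500uM")

#: Total-protein and phospho ratio columns of the time-course table (h).
TOTAL_CONDITIONS = ("total_0h", "total_24h", "total_48h")
PHOSPHO_CONDITIONS = ("phospho_0h", "phospho_24h", "phospho_48h")


def load_dose_table() -> SpotTable:
    """The 18-spot dose-response table (ratios vs untreated control)."""
    with _DATA.joinpath("table1_dose.csv").open() as fh:
        df = pd.read_csv(fh)
    return SpotTable(df, mode="ratio")


def load_time_table() -> pd.DataFrame:
    """The 48-row time-course table: 46 total-protein profiles (with the
    printed cluster letter d/e/f) plus 2 phospho-only rows; 14 rows carry
    phospho profiles."""
    with _DATA.joinpath("table2_time.csv").open() as fh:
        return pd.read_csv(fh)


def load_turnover_table() -> pd.DataFrame:
    """Per-protein percent new synthesis at 48 h: labeled-only control column
    and 50 uM oxythiamine columns (12 h column empty: no detectable shift)."""
    with _DATA.joinpath("table3_turnover.csv").open() as fh:
        return pd.read_csv(fh)


def load_annexin_a1(fixed_carbamidomethyl: bool = True) -> PeptideSequence:
    """Human Annexin A1 (P04083) as a digestible protein sequence."""
    path = _DATA.joinpath("annexin_a1_P04083.fasta")
    return read_fasta(str(path), fixed_carbamidomethyl)[0][1]
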