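"""File formats: FASTA proteins, two-column peak lists, spot-table CSV/TSV."""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chem import FIXED_CYS, PeptideSequence
from .errors import InvalidInputError
from .spots import META_COLUMNS, SpotTable
from .turnover import SpectrumObservation

PathLike = Union[str, Path]


def read_fasta(
    path: PathLike,
    fixed_carbamidomethyl: bool = True,
) -> list[tuple[str, PeptideSequence]]:
    """Read protein records from FASTA.

    Returns (description, sequence) pairs; with ``fixed_carbamidomethyl``
    every record carries the fixed Cys modification, matching the standard
    iodoacetamide sample preparation.
    """
    mods = frozenset({(FIXED_CYS, "carbamidomethyl")}) if fixed_carbamidomethyl else frozenset()
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.description, PeptideSequence(str(rec.seq), mods)))
    if not records:
        raise InvalidInputError(f"no FASTA records in {path}")
    return records


def read_peak_list(path: PathLike, label: str | None = None) -> SpectrumObservation:
    """Read a centroided spectrum from two-column text (m/z, intensity).

    Columns may be separated by whitespace or commas; blank lines and lines
    starting with ``#`` are ignored.  One spectrum per file.
    """
    peaks = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\s]+", line)
        if len(parts) < 2:
            raise InvalidInputError(f"{path}:{lineno}: expected 'm/z intensity'")
        peaks.append((float(parts[0]), float(parts[1])))
    return SpectrumObservation(tuple(peaks), label=label or Path(path).stem)


def write_peak_list(obs: SpectrumObservation, path: PathLike) -> None:
    """Write a spectrum in the same two-column dialect the reader accepts."""
    with open(path, "w") as fh:
        for mz, inten in obs.peaks:
            fh.write(f"{mz:.5f}\t{inten:.6f}\n")


def read_spot_table(path: PathLike, mode: str = "ratio") -> SpotTable:
    """Read a spot table from CSV/TSV (delimiter sniffed from the header).

    Layout: ``spot_id, protein_name, accession`` then one column per
    condition.  Empty cells in condition columns mean "absent" (the printed
    tables' ``--`` for proteins without a phospho signal) and load as NaN.
    """
    text = Path(path).read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(_io.StringIO(text), sep=sep)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {missing}")
    return SpotTable(df, mode=mode)


def write_spot_table(table: SpotTable, path: PathLike) -> None:
    table.data.to_csv(path, index=False)


def write_fit_report(report: pd.DataFrame, path: PathLike) -> None:
    """Write turnover fit results as CSV with a stable column order."""
    preferred = [
        "sample", "peptide", "condition", "fraction_new", "percent_new",
        "a_old", "b_new", "residual_norm", "flag", "direction",
    ]
    cols = [c for c in preferred if c in report.columns] + [
        c for c in report.columns if c not in preferred
    ]
    report[cols].to_csv(path, index=False)
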