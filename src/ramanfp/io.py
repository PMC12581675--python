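"""Plain-text readers and writers for spectra and cohort metadata.

Two spectral dialects are supported:

``two_column``
    One spectrum per file: wavenumber, intensity.
``wide_matrix``
    One sample per file: first column is the wavenumber, every remaining
    column is one replicate; the header row carries replicate labels.

Delimiters (comma, tab, semicolon) are auto-detected, headers are optional,
and rows are re-sorted so the axis is always strictly ascending on return.
Floats are written with ``repr`` so that a write/read round trip reproduces
values exactly.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MANDATORY_COLUMNS, CohortTable
from .spectra import Spectrum, SpectrumSet

__all__ = [
    "read_spectrum_table",
    "write_spectrum_table",
    "read_cohort_table",
    "write_cohort_table",
    "read_metadata_sidecar",
    "write_metadata_sidecar",
]

_DELIMITERS = (",", "\t", ";")


class SpectrumParseError(ValueError):
    """Raised when a spectral text file cannot be parsed; names the line."""


def _sniff_delimiter(line: str) -> str:
    counts = {d: line.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise SpectrumParseError(f"no delimiter (comma/tab/semicolon) found in {line!r}")
    return best


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _read_rows(path: Path) -> tuple[list[list[str]], list[str] | None, int]:
    """Return (data rows, optional header, 1-based line number of first data row)."""
    with open(path, newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise SpectrumParseError(f"{path}: file is empty")
    delim = _sniff_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    first = [t.strip() for t in rows[0]]
    header = None
    start = 1
    if not all(_is_float(t) for t in first):
        header = first
        rows = rows[1:]
        start = 2
        if not rows:
            raise SpectrumParseError(f"{path}: header but no data rows")
    return [[t.strip() for t in r] for r in rows], header, start


def _parse_float(tok: str, path: Path, line_no: int) -> float:
    try:
        return float(tok)
    except ValueError:
        raise SpectrumParseError(
            f"{path}: non-numeric value {tok!r} on line {line_no}"
        ) from None


def read_spectrum_table(
    path: str | Path, dialect: str = "two_column", sample_id: str | None = None
):
    """Read a spectral table.

    Parameters
    ----------
    path
        Delimited text file (UTF-8, '.' decimal separator).
    dialect
        ``two_column`` returns a :class:`Spectrum`; ``wide_matrix`` returns a
        :class:`SpectrumSet` whose replicates share the file's axis.
    sample_id
        Sample identifier for ``wide_matrix``; defaults to the file stem.

    Raises
    ------
    SpectrumParseError
        Non-numeric cell (citing the line number) or duplicate wavenumber.
    """
    path = Path(path)
    if dialect not in ("two_column", "wide_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows, header, start = _read_rows(path)

    ncol = len(rows[0])
    parsed = np.empty((len(rows), ncol), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != ncol:
            raise SpectrumParseError(
                f"{path}: expected {ncol} fields on line {start + i}, got {len(row)}"
            )
        for j, tok in enumerate(row):
            parsed[i, j] = _parse_float(tok, path, start + i)

    wn = parsed[:, 0]
    if len(np.unique(wn)) != len(wn):
        dup = wn[pd.Index(wn).duplicated()][0]
        raise SpectrumParseError(f"{path}: duplicate wavenumber {dup:g}")
    order = np.argsort(wn)
    wn = wn[order]
    parsed = parsed[order]

    if dialect == "two_column":
        if ncol != 2:
            raise SpectrumParseError(
                f"{path}: two_column dialect expects 2 columns, found {ncol}"
            )
        return Spectrum(wn, parsed[:, 1], label=path.stem)

    if ncol < 2:
        raise SpectrumParseError(f"{path}: wide_matrix needs at least one replicate column")
    labels = header[1:] if header else [f"rep{j}" for j in range(1, ncol)]
    reps = [Spectrum(wn, parsed[:, j + 1], label=labels[j]) for j in range(ncol - 1)]
    return SpectrumSet(sample_id or path.stem, reps)


def write_spectrum_table(obj, path: str | Path, dialect: str = "two_column") -> None:
    """Write a Spectrum (two_column) or SpectrumSet (wide_matrix) as CSV.

    Uses full-precision float ``repr`` so the round trip is exact. For the
    wide dialect all replicates must already share one axis.
    """
    path = Path(path)
    if dialect == "two_column":
        if not isinstance(obj, Spectrum):
            raise TypeError("two_column dialect writes a single Spectrum")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("wavenumber,intensity\n")
            for w, y in zip(obj.wavenumbers, obj.intensities):
                fh.write(f"{float(w)!r},{float(y)!r}\n")
        return
    if dialect != "wide_matrix":
        raise ValueError(f"unknown dialect {dialect!r}")
    if not isinstance(obj, SpectrumSet):
        raise TypeError("wide_matrix dialect writes a SpectrumSet")
    if len(obj.replicates) == 0:  # unreachable via the validated constructor
        raise ValueError("cannot write an empty SpectrumSet")
    axis = obj.replicates[0].wavenumbers
    for r in obj.replicates[1:]:
        if len(r.wavenumbers) != len(axis) or not np.array_equal(r.wavenumbers, axis):
            raise ValueError(
                "wide_matrix requires all replicates on a common axis; "
                "resample first (see ramanfp.preprocess)"
            )
    labels = [r.label or f"rep{i + 1}" for i, r in enumerate(obj.replicates)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("wavenumber," + ",".join(labels) + "\n")
        for i, w in enumerate(axis):
            vals = ",".join(repr(float(r.intensities[i])) for r in obj.replicates)
            fh.write(f"{float(w)!r},{vals}\n")


def read_cohort_table(path: str | Path) -> CohortTable:
    """Read the per-sample metadata CSV.

    Mandatory columns: sample_id, group, timepoint. Every extra column is
    taken as a numeric phenotype; blank cells become missing values.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={c: str for c in MANDATORY_COLUMNS}, skipinitialspace=True)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    return CohortTable(df)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def write_metadata_sidecar(path: str | Path, metadata: dict) -> Path:
    """Write a free-form JSON sidecar next to a spectral file."""
    side = Path(str(path) + ".json")
    with open(side, "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return side


def read_metadata_sidecar(path: str | Path) -> dict | None:
    side = Path(str(path) + ".json")
    if not side.exists():
        return None
    with open(side, encoding="utf-8") as fh:
        return json.load(fh)
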