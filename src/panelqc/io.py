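"""Readers and writers for count tables, control detection and annotations.

Two input dialects are supported:

``delimited``
    A plain CSV/TSV (or .xlsx) table: first column probe ids, header row
    sample ids, body read counts.  This is the primary supported format.

``instrument-export``
    An instrument-style export in which zero or more metadata rows precede
    the counts block.  Rows are skipped until the first row whose first cell
    equals a sentinel (default ``"Sample Name"``); that row is taken as the
    header and everything below as the counts block.  This is a documented
    stand-in layout for vendor exports, not a claim about any proprietary
    format.

All delimited output is UTF-8 CSV with RFC-4180 quoting (pandas defaults).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import AnnotationTable, ControlSpec, ExpressionMatrix, PanelQCError

logger = logging.getLogger(__name__)

DEFAULT_SENTINEL = "Sample Name"
DEFAULT_POSITIVE_PREFIX = "POS"
DEFAULT_NEGATIVE_PREFIX = "ANT"

_EXCEL_SUFFIXES = {".xlsx", ".xlsm", ".xls"}


def _read_raw_table(path: Path, header: int | None) -> pd.DataFrame:
    """Read a delimited or spreadsheet file into a raw string-ish DataFrame.

    With ``header=None`` rows may be ragged (metadata lines above the counts
    block), so text files are tokenized row-wise and padded.
    """
    if path.suffix.lower() in _EXCEL_SUFFIXES:
        return pd.read_excel(path, header=header, dtype=object)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    if header is not None:
        return pd.read_csv(path, header=header, sep=sep, dtype=object)
    import csv

    with open(path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    width = max((len(r) for r in rows), default=0)
    padded = [r + [None] * (width - len(r)) for r in rows]
    frame = pd.DataFrame(padded, dtype=object)
    return frame.mask(frame == "")


def _counts_block_to_matrix(block: pd.DataFrame, path: Path) -> ExpressionMatrix:
    """Validate and convert a header-ed counts block (probe id first column)."""
    if block.shape[1] < 2:
        raise PanelQCError(f"{path}: counts table needs a probe-id column plus >=1 sample column")
    probe_col = block.columns[0]
    probe_ids = [str(p) for p in block[probe_col]]
    sample_ids = [str(c) for c in block.columns[1:]]
    body = block.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise PanelQCError(
            f"{path}: non-numeric count {body.iat[r, c]!r} at probe "
            f"{probe_ids[r]!r}, sample {sample_ids[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise PanelQCError(
            f"{path}: missing count at probe {probe_ids[r]!r}, sample {sample_ids[c]!r}"
        )
    try:
        return ExpressionMatrix(
            probe_ids=tuple(probe_ids),
            sample_ids=tuple(sample_ids),
            counts=numeric.to_numpy(dtype=float),
        )
    except PanelQCError as exc:
        raise PanelQCError(f"{path}: {exc}") from None


def _find_sentinel_row(raw: pd.DataFrame, sentinel: str, path: Path) -> int:
    first = raw.iloc[:, 0].astype(str).str.strip()
    hits = np.flatnonzero(first.str.casefold() == sentinel.strip().casefold())
    if hits.size == 0:
        raise PanelQCError(
            f"{path}: counts block not found — no row whose first cell is "
            f"{sentinel!r} (instrument-export dialect)"
        )
    return int(hits[0])


def read_counts_table(
    path,
    dialect: str = "delimited",
    sentinel: str = DEFAULT_SENTINEL,
) -> ExpressionMatrix:
    """Read a probe x sample counts table.

    Parameters
    ----------
    path : str or Path
        CSV (``,``), TSV/TXT (tab) or .xlsx file.
    dialect : {"delimited", "instrument-export"}
        ``delimited``: row 0 is the header.  ``instrument-export``: leading
        metadata rows are skipped until the sentinel header row.
    sentinel : str
        First cell of the header row in the instrument-export dialect.

    Returns
    -------
    ExpressionMatrix
        Row and column order exactly as in the file.
    """
    path = Path(path)
    if not path.is_file():
        raise PanelQCError(f"input file not found: {path}")
    if dialect == "delimited":
        block = _read_raw_table(path, header=0)
    elif dialect == "instrument-export":
        raw = _read_raw_table(path, header=None)
        if raw.shape[0] == 0:
            raise PanelQCError(f"{path}: file is empty")
        hrow = _find_sentinel_row(raw, sentinel, path)
        header = [str(v) for v in raw.iloc[hrow]]
        block = raw.iloc[hrow + 1 :].reset_index(drop=True)
        block.columns = header
        block = block.dropna(how="all")
    else:
        raise PanelQCError(f"unknown dialect {dialect!r} (expected delimited or instrument-export)")
    if block.shape[0] == 0:
        raise PanelQCError(f"{path}: no count rows found")
    return _counts_block_to_matrix(block, path)


def detect_controls(
    matrix: ExpressionMatrix,
    positive_prefix: str = DEFAULT_POSITIVE_PREFIX,
    negative_prefix: str = DEFAULT_NEGATIVE_PREFIX,
    positive_ids=None,
    negative_ids=None,
) -> ControlSpec:
    """Identify control probes by id prefix (case-insensitive) or explicit lists.

    Explicit id lists take precedence over prefixes for the respective set.
    Defaults follow the common panel convention of ``POS*`` spike-ins and
    ``ANT*`` negative (non-human) probes.
    """
    def by_prefix(prefix: str, kind: str) -> frozenset[str]:
        if not prefix:
            raise PanelQCError(f"{kind} control prefix must be non-empty")
        hits = frozenset(
            p for p in matrix.probe_ids if p.casefold().startswith(prefix.casefold())
        )
        if not hits:
            preview = ", ".join(matrix.probe_ids[:20])
            more = "" if matrix.n_probes <= 20 else f", … ({matrix.n_probes} total)"
            raise PanelQCError(
                f"no probe id starts with {prefix!r} ({kind} controls); "
                f"available probes: {preview}{more}"
            )
        return hits

    def explicit(ids, kind: str) -> frozenset[str]:
        ids = frozenset(str(i) for i in ids)
        missing = ids - set(matrix.probe_ids)
        if missing:
            raise PanelQCError(
                f"{kind} control id(s) not in matrix: {', '.join(sorted(missing))}"
            )
        return ids

    pos = explicit(positive_ids, "positive") if positive_ids else by_prefix(positive_prefix, "positive")
    neg = explicit(negative_ids, "negative") if negative_ids else by_prefix(negative_prefix, "negative")
    return ControlSpec(positive_ids=pos, negative_ids=neg)


def write_counts_table(matrix: ExpressionMatrix, path) -> Path:
    """Write a matrix as CSV (probe ids first column, sample ids header)."""
    path = Path(path)
    matrix.to_frame().to_csv(path)
    return path


def write_clean_matrix(matrix: ExpressionMatrix, controls: ControlSpec, path) -> Path:
    """Write the matrix with all control probes removed ("cleaned data").

    The output round-trips through :func:`read_counts_table` to a matrix
    identical to ``matrix`` minus the control rows.
    """
    non_control = [p for p in matrix.probe_ids if p not in controls.all_ids]
    if not non_control:
        raise PanelQCError("nothing to export: every probe is a control probe")
    cleaned = matrix.drop_probes(controls.all_ids)
    return write_counts_table(cleaned, path)


def write_instrument_export(
    matrix: ExpressionMatrix,
    path,
    metadata_rows: list[list[str]] | None = None,
    sentinel: str = DEFAULT_SENTINEL,
) -> Path:
    """Write the instrument-export dialect: metadata rows, sentinel header, counts."""
    path = Path(path)
    if metadata_rows is None:
        metadata_rows = [
            ["Panel", "Synthetic Panel"],
            ["Instrument", "synthetic"],
            ["Total Samples", str(matrix.n_samples)],
            [],
        ]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        import csv

        writer = csv.writer(fh)
        for row in metadata_rows:
            writer.writerow(row)
        writer.writerow([sentinel, *matrix.sample_ids])
        for i, probe in enumerate(matrix.probe_ids):
            writer.writerow([probe, *matrix.counts[i, :].tolist()])
    return path


def read_annotation(path) -> AnnotationTable:
    """Read a sample annotation table (first column sample id, header required)."""
    path = Path(path)
    if not path.is_file():
        raise PanelQCError(f"annotation file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, index_col=0)
    except pd.errors.EmptyDataError:
        raise PanelQCError(f"{path}: annotation file is empty") from None
    try:
        return AnnotationTable(frame=frame)
    except PanelQCError as exc:
        raise PanelQCError(f"{path}: {exc}") from None
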