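"""Optional validation against published supplementary differential tables.

The study's differential lists are distributed as XLSX workbooks (one row
per transcript, one sheet or status column per direction).  These helpers
count rows by regulation status so published summary counts (e.g. numbers of
hyper-up / hypo-down transcripts) can be checked against a local copy of the
workbooks.  The files themselves are not bundled.
"""

from __future__ import annotations

import re

import pandas as pd

from .exceptions import ValidationError

# column headers that typically carry the regulation / mode label
_STATUS_PATTERNS = (
    r"regulat",  # "Regulation", "regulated"
    r"\bmode\b",
    r"status",
    r"methyl.*direction",
)


def _find_status_column(df: pd.DataFrame) -> str | None:
    for col in df.columns:
        name = str(col).lower()
        if any(re.search(p, name) for p in _STATUS_PATTERNS):
            return col
    return None


def count_rows_by(path, column: str | None = None, sheet=None) -> dict:
    """Count data rows of an XLSX sheet grouped by a status column.

    When ``column`` is None the first header matching a regulation/mode
    pattern is used; when no such column exists the total row count is
    returned under the key ``"total"``.
    """
    sheets = pd.read_excel(path, sheet_name=sheet)
    if isinstance(sheets, pd.DataFrame):
        sheets = {sheet or 0: sheets}
    counts: dict = {}
    for sheet_name, df in sheets.items():
        col = column or _find_status_column(df)
        if col is None:
            counts[str(sheet_name)] = {"total": int(len(df))}
            continue
        if col not in df.columns:
            raise ValidationError(
                f"{path}[{sheet_name}]: no column '{col}'"
            )
        by = (
            df[col]
            .astype(str)
            .str.strip()
            .str.lower()
            .value_counts()
            .to_dict()
        )
        counts[str(sheet_name)] = {k: int(v) for k, v in by.items()}
    return counts


def count_supplementary_modes(path, column: str | None = None) -> dict:
    """Flattened status counts over all sheets of a supplementary workbook."""
    per_sheet = count_rows_by(path, column=column)
    flat: dict = {}
    for sheet_counts in per_sheet.values():
        for status, n in sheet_counts.items():
            flat[status] = flat.get(status, 0) + n
    return flat
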