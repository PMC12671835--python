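"""Reading and writing one-column numeric series.

Accepts CSV or whitespace-delimited text, with optional header row,
blank lines and '#' comments.  Decimal points only (locale-independent).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_series", "write_series"]


def _split(line: str) -> list[str]:
    return [c.strip() for c in (line.split(",") if "," in line else line.split())]


def read_series(path, column: int | str | None = None) -> np.ndarray:
    """Parse one numeric column from a text file.

    ``column`` may be an integer position (default 0) or a header name.
    A header row is auto-detected (first non-comment row that does not
    parse as numbers).  Malformed numeric cells raise with the 1-based
    line number.
    """
    lines = Path(path).read_text().splitlines()
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(lines, start=1):
        s = raw.strip()
        if not s or s.startswith("#"):
            continue
        rows.append((lineno, _split(s)))
    if not rows:
        raise ValueError(f"{path}: no data rows")

    header: list[str] | None = None
    first_cells = rows[0][1]
    try:
        [float(c) for c in first_cells if c]
    except ValueError:
        header = first_cells
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header but no data rows")

    if isinstance(column, str):
        if header is None or column not in header:
            raise ValueError(f"{path}: no column named {column!r}")
        idx = header.index(column)
    else:
        idx = int(column or 0)

    out = []
    for lineno, cells in rows:
        if idx >= len(cells):
            raise ValueError(f"{path}: line {lineno}: missing column {idx}")
        try:
            out.append(float(cells[idx]))
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: non-numeric value {cells[idx]!r}"
            ) from None
    return np.asarray(out)


def write_series(path, values, header: str | None = None) -> None:
    """Write values as a one-column text file (optionally with a header)."""
    lines = ([header] if header else []) + [repr(float(v)) for v in values]
    Path(path).write_text("\n".join(lines) + "\n")
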