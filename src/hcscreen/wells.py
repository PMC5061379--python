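"""Well-name utilities for 96- and 384-well plates.

Canonical form is a row letter plus a zero-padded two-digit column
("A01".."H12" for 96-well, "A01".."P24" for 384-well); the parser also
accepts unpadded names such as "A1".
"""

from __future__ import annotations

import re

from .errors import ParameterError

PLATE_DIMS = {96: (8, 12), 384: (16, 24)}

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


def normalize_well(well: str) -> str:
    """Return the canonical zero-padded form of a well name.

    >>> normalize_well("a1")
    'A01'
    """
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ParameterError(f"unparseable well name: {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if col < 1:
        raise ParameterError(f"well column must be >= 1: {well!r}")
    return f"{row}{col:02d}"


def parse_well(well: str) -> tuple[int, int]:
    """Return 0-based (row, column) indices for a well name."""
    w = normalize_well(well)
    return ord(w[0]) - ord("A"), int(w[1:]) - 1


def well_name(row: int, col: int) -> str:
    """Canonical well name for 0-based (row, column) indices."""
    if row < 0 or row > 15 or col < 0 or col > 23:
        raise ParameterError(f"row/column ({row}, {col}) outside plate bounds")
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def well_names(plate_format: int) -> list[str]:
    """All well names of a plate format in row-major order."""
    try:
        n_rows, n_cols = PLATE_DIMS[int(plate_format)]
    except (KeyError, ValueError):
        raise ParameterError(
            f"unsupported plate format {plate_format!r}; expected 96 or 384"
        ) from None
    return [well_name(r, c) for r in range(n_rows) for c in range(n_cols)]


def check_well_in_format(well: str, plate_format: int) -> str:
    """Normalize a well name and verify it exists on the given plate format."""
    n_rows, n_cols = PLATE_DIMS[int(plate_format)]
    r, c = parse_well(well)
    if r >= n_rows or c >= n_cols:
        raise ParameterError(
            f"well {normalize_well(well)} outside {plate_format}-well plate"
        )
    return normalize_well(well)
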