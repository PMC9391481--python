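"""Plain (P1, ASCII) PBM bitmap reading and writing.

Network states and stored patterns are ±1 vectors arranged on small
grids; they are persisted as plain PBM so that every artifact stays
human-readable text.  Pillow reads plain PBM but cannot write the P1
variant (it always emits binary P4), so the few lines of P1 encoding
live here.  Convention: +1 (active) maps to bit 1, -1 (quiet) to bit 0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError


def write_pbm(path: str | Path, grid: np.ndarray) -> None:
    """Write a 2-D ±1 array as a plain P1 PBM file (+1 -> 1, -1 -> 0)."""
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise FormatError(f"expected a 2-D grid, got shape {grid.shape}")
    bits = (grid > 0).astype(np.uint8)
    rows, cols = bits.shape
    with open(path, "w") as fh:
        fh.write(f"P1\n{cols} {rows}\n")
        for row in bits:
            fh.write(" ".join(str(int(b)) for b in row) + "\n")


def read_pbm(path: str | Path) -> np.ndarray:
    """Read a plain P1 PBM file into a ±1 int8 array (1 -> +1, 0 -> -1)."""
    text = Path(path).read_text()
    # Strip comments (allowed anywhere after '#' up to end of line).
    tokens: list[str] = []
    for line in text.splitlines():
        body = line.split("#", 1)[0]
        tokens.extend(body.split())
    if not tokens or tokens[0] != "P1":
        raise FormatError(f"{path}: not a plain PBM (P1) file")
    try:
        cols, rows = int(tokens[1]), int(tokens[2])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed PBM header") from exc
    bits = tokens[3:]
    if len(bits) != rows * cols:
        raise FormatError(
            f"{path}: expected {rows * cols} pixels, found {len(bits)}"
        )
    try:
        arr = np.array([int(b) for b in bits], dtype=np.int8)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric pixel token") from exc
    if not np.isin(arr, (0, 1)).all():
        raise FormatError(f"{path}: PBM pixels must be 0 or 1")
    return (2 * arr - 1).reshape(rows, cols)
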