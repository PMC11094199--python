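"""Deterministic CSV output for record-style results."""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

__all__ = ["write_table"]

logger = logging.getLogger(__name__)


def _format(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if not math.isfinite(value):
            logger.warning("non-finite value %r written as an empty cell", value)
            return ""
        return f"{value:.12g}"
    return str(value)


def write_table(
    records: Sequence[Mapping],
    path: str | Path,
    format: str = "csv",
    columns: Sequence[str] | None = None,
) -> Path:
    """Write homogeneous records as CSV with a deterministic column order.

    Columns default to the key order of the first record (extras appended in
    sorted order); floats are rendered at 12 significant digits and
    non-finite values become empty cells with a logged warning.  An empty
    record list yields a header-only file (header requires ``columns``).
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if columns is None:
        if records:
            columns = list(records[0].keys())
            extra = sorted({k for rec in records for k in rec} - set(columns))
            columns = columns + extra
        else:
            columns = []
    lines = [",".join(columns)]
    for rec in records:
        lines.append(",".join(_format(rec.get(col, "")) for col in columns))
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path
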