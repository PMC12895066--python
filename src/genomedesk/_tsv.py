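"""Small shared reader for the package's tab-separated exchange files.

All TSV contracts in genomedesk share the same dialect: UTF-8, tab-separated,
one required header row, lines starting with ``#`` ignored.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterator

from .errors import ValidationError


def read_tsv(path, required_columns=None, optional_columns=()) -> Iterator[tuple[int, dict]]:
    """Yield ``(line_number, row_dict)`` for each data row of a TSV file.

    ``line_number`` is 1-based and counts every physical line, so diagnostics
    can point at the file. Raises :class:`ValidationError` if the header is
    missing a required column. Rows with fewer cells than the header are
    padded with empty strings; extra cells raise per-row ValueError entries
    handled by callers.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ValidationError(f"cannot read {path}: {exc}") from exc
    yield from read_tsv_text(text, required_columns, optional_columns, name=str(path))


def read_tsv_text(text, required_columns=None, optional_columns=(), name="<tsv>"):
    lines = io.StringIO(text).read().splitlines()
    header = None
    header_line = 0
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        header = [c.strip() for c in line.rstrip("\n").split("\t")]
        header_line = i
        break
    if header is None:
        return
    if required_columns is not None:
        missing = [c for c in required_columns if c not in header]
        if missing:
            raise ValidationError(
                f"{name}: header missing required column(s): {', '.join(missing)}"
            )
    for i, line in enumerate(lines[header_line:], start=header_line + 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) < len(header):
            cells = cells + [""] * (len(header) - len(cells))
        row = {h: cells[j].strip() for j, h in enumerate(header)}
        yield i, row
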