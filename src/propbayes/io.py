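"""TSV readers/writers for count data, plus JSON result records.

Dialect: tab-separated, UTF-8, ``#`` comment lines, header row required on
output and optional on input.  Bivariate tables have columns
``x_label  n0  n1``; univariate tables have ``state_label  count``.
Malformed lines raise with the offending line number.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .counts import BinaryConditionalCounts, CountVector

__all__ = [
    "read_bivariate_tsv",
    "write_bivariate_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_json_record",
]

logger = logging.getLogger(__name__)


class TsvFormatError(ValueError):
    """A TSV line could not be parsed; the message names the line number."""


def _data_lines(path, meta: dict | None = None):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip().lstrip("#").strip()
                if meta is not None and "=" in body:
                    key, _, value = body.partition("=")
                    try:
                        meta[key.strip()] = int(value.strip())
                    except ValueError:
                        pass
                continue
            yield lineno, line.split("\t")


def _is_header(fields: list[str]) -> bool:
    try:
        [int(f) for f in fields[1:]]
    except ValueError:
        return True
    return False


def read_bivariate_tsv(path, kx: int | None = None) -> BinaryConditionalCounts:
    """Read per-x-state pairs (n0, n1).

    ``kx`` falls back to a ``# kx=K`` comment line if present, else to the
    number of rows (with a logged warning, since unsampled states cannot be
    inferred from data).
    """
    meta: dict = {}
    pairs = []
    first = True
    for lineno, fields in _data_lines(path, meta):
        if first and _is_header(fields):
            first = False
            continue
        first = False
        if len(fields) != 3:
            raise TsvFormatError(
                f"{path}:{lineno}: expected 3 tab-separated columns "
                f"(x_label, n0, n1), got {len(fields)}"
            )
        try:
            pairs.append((int(fields[1]), int(fields[2])))
        except ValueError as exc:
            raise TsvFormatError(f"{path}:{lineno}: non-integer count: {exc}") from exc
    if kx is None:
        kx = meta.get("kx")
    if kx is None:
        kx = len(pairs)
        logger.warning(
            "kx not supplied; inferred kx=%d from the number of rows in %s "
            "(unsampled states cannot be inferred from data)", kx, path,
        )
    return BinaryConditionalCounts(pairs, kx)


def write_bivariate_tsv(path, counts: BinaryConditionalCounts) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kx={counts.kx}\n")
        fh.write("x_label\tn0\tn1\n")
        for i, (n0, n1) in enumerate(counts.pairs):
            fh.write(f"x{i}\t{n0}\t{n1}\n")


def read_counts_tsv(path, k: int | None = None) -> CountVector:
    """Read per-state counts; k falls back to a ``# k=K`` comment, else #rows."""
    meta: dict = {}
    counts = []
    first = True
    for lineno, fields in _data_lines(path, meta):
        if first and _is_header(fields):
            first = False
            continue
        first = False
        if len(fields) != 2:
            raise TsvFormatError(
                f"{path}:{lineno}: expected 2 tab-separated columns "
                f"(state_label, count), got {len(fields)}"
            )
        try:
            counts.append(int(fields[1]))
        except ValueError as exc:
            raise TsvFormatError(f"{path}:{lineno}: non-integer count: {exc}") from exc
    if k is None:
        k = meta.get("k")
    return CountVector(counts, k)


def write_counts_tsv(path, counts: CountVector) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# k={counts.k}\n")
        fh.write("state_label\tcount\n")
        for i, c in enumerate(counts.counts):
            fh.write(f"s{i}\t{c}\n")


def write_json_record(path, record: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
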