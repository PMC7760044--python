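"""Count-table file formats.

TSV dialect: header ``x<TAB>y<TAB>z<TAB>count``, 0-based integer symbols,
UTF-8, LF or CRLF; duplicate cells are summed.  JSON dialect: an object
with ``alphabet_sizes`` and a dense nested ``counts`` array.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .distribution import CountTable

__all__ = ["read_counts", "write_counts"]

_TSV_HEADER = ("x", "y", "z", "count")


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "tsv"


def read_counts(
    path: str | Path, fmt: str | None = None
) -> tuple[CountTable, tuple[int, int, int] | None]:
    """Read a count table; returns (table, declared alphabet sizes or None).

    Only the JSON dialect declares alphabet sizes; for TSV they must be
    inferred by the caller (e.g. max symbol + 1).
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "tsv":
        lines = path.read_text(encoding="utf-8").splitlines()
        if not lines:
            raise ValueError(f"{path}: empty file")
        header = tuple(h.strip() for h in lines[0].split("\t"))
        if header != _TSV_HEADER:
            raise ValueError(
                f"{path}: malformed header {header!r}; expected "
                + "\\t".join(_TSV_HEADER)
            )
        merged: dict[tuple[int, int, int], int] = {}
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 fields")
            try:
                x, y, z, c = (int(v) for v in fields)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer field") from exc
            if c < 0:
                raise ValueError(f"{path}:{ln}: negative count")
            merged[(x, y, z)] = merged.get((x, y, z), 0) + c
        return CountTable.from_mapping(merged), None
    if fmt == "json":
        obj = json.loads(path.read_text(encoding="utf-8"))
        counts = np.asarray(obj["counts"])
        if counts.ndim != 3:
            raise ValueError(f"{path}: counts array must be 3-dimensional")
        sizes = tuple(int(s) for s in obj.get("alphabet_sizes", counts.shape))
        if tuple(counts.shape) != sizes:
            raise ValueError(
                f"{path}: counts shape {counts.shape} != alphabet_sizes {sizes}"
            )
        if np.any(counts < 0):
            raise ValueError(f"{path}: negative count")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError(f"{path}: non-integer count")
        xs, ys, zs = np.nonzero(counts)
        table = CountTable(
            tuple(
                (int(x), int(y), int(z), int(counts[x, y, z]))
                for x, y, z in zip(xs, ys, zs)
            )
        )
        return table, sizes  # type: ignore[return-value]
    raise ValueError(f"unknown format {fmt!r}")


def write_counts(
    table: CountTable,
    path: str | Path,
    fmt: str | None = None,
    alphabet_sizes: tuple[int, int, int] | None = None,
) -> None:
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "tsv":
        lines = ["\t".join(_TSV_HEADER)]
        for x, y, z, c in table.records:
            lines.append(f"{x}\t{y}\t{z}\t{c}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return
    if fmt == "json":
        if alphabet_sizes is None:
            alphabet_sizes = tuple(
                max((rec[i] for rec in table.records), default=0) + 1
                for i in range(3)
            )  # type: ignore[assignment]
        arr = np.zeros(alphabet_sizes, dtype=np.int64)
        for x, y, z, c in table.records:
            arr[x, y, z] += c
        path.write_text(
            json.dumps(
                {"alphabet_sizes": list(alphabet_sizes), "counts": arr.tolist()}
            )
        )
        return
    raise ValueError(f"unknown format {fmt!r}")
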