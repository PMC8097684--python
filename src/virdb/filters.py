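"""Complete-genome restriction by family length bounds or title keywords.

Virus families have characteristic genome (or segment) sizes, so a cheap
and annotation-independent way to keep only complete genomes is a length
window around the known extremes: 10% below the shortest known genome to
10% above the largest.  The alternative trusts the submitter: keep
entries whose title contains "genome" together with "complete" (or,
optionally, "partial").  Family length tables are user-supplied
configuration, loaded from a simple TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .records import SequenceRecord

__all__ = [
    "compute_length_bounds",
    "load_length_criteria",
    "filter_by_length",
    "filter_by_title",
    "write_filter_report",
]


def compute_length_bounds(shortest: int, largest: int) -> tuple[int, int]:
    """10%-buffered inclusive bounds around the known genome-length extremes.

    ``min_len = round(0.9 * shortest)``, ``max_len = round(1.1 * largest)``.
    """
    if not 0 < shortest <= largest:
        raise ValueError(f"need 0 < shortest <= largest, got ({shortest}, {largest})")
    return round(0.9 * shortest), round(1.1 * largest)


def load_length_criteria(source: str | Path | TextIO) -> dict[str, tuple[int, int]]:
    """Read a family length table: ``family<TAB>shortest<TAB>largest``.

    Returns family -> 10%-buffered (min_len, max_len).  ``#`` comment
    lines and blank lines are skipped.
    """
    own = isinstance(source, (str, Path))
    handle = open(source) if own else source
    try:
        bounds: dict[str, tuple[int, int]] = {}
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) != 3:
                raise ValueError(f"expected 3 tab-separated columns, got {row!r}")
            family, shortest, largest = row[0].strip(), int(row[1]), int(row[2])
            if family in bounds:
                raise ValueError(f"duplicate family {family!r} in length criteria")
            bounds[family] = compute_length_bounds(shortest, largest)
        return bounds
    finally:
        if own:
            handle.close()


def filter_by_length(
    records: Iterable[SequenceRecord], bounds: tuple[int, int]
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Keep records with min_len <= length <= max_len (inclusive), order preserved."""
    min_len, max_len = bounds
    if not 0 < min_len <= max_len:
        raise ValueError(f"invalid bounds ({min_len}, {max_len})")
    kept, removed = [], []
    for rec in records:
        (kept if min_len <= len(rec) <= max_len else removed).append(rec)
    return kept, removed


def filter_by_title(
    records: Iterable[SequenceRecord], allow_partial: bool = False
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Keep records whose title claims a (complete, optionally partial) genome.

    Case-insensitive: the description must contain "genome" and either
    "complete" or -- when ``allow_partial`` -- "partial".
    """
    kept, removed = [], []
    for rec in records:
        title = rec.description.lower()
        ok = "genome" in title and (
            "complete" in title or (allow_partial and "partial" in title)
        )
        (kept if ok else removed).append(rec)
    return kept, removed


def write_filter_report(
    removed: Sequence[SequenceRecord], path: str | Path, reason: str
) -> None:
    """TSV of removed entries: accession, sub-database, length, reason."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["accession", "subdb", "length", "reason"])
        for rec in removed:
            writer.writerow([rec.accession, rec.subdb, len(rec), reason])
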