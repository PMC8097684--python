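"""Canonical k-mer extraction, indexing and reference coverage.

This is the shared primitive behind both contamination screening and read
classification.  K-mers are *canonical* (the lexicographically smaller of
a window and its reverse complement), so matches are strand-insensitive
-- a vector insert or host fragment on either strand is caught.  Windows
containing ambiguity codes (N, R, ...) are skipped rather than expanded.

Coverage of a reference by a query counts covered *bases*: the union of
the k-wide intervals of every reference position whose canonical k-mer
also occurs in the query, divided by the reference length.  A set of
k-mers can be masked (e.g. everything shared with a host genome); masked
k-mers never match anything.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

DEFAULT_K = 16

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

__all__ = [
    "DEFAULT_K",
    "revcomp",
    "canonical",
    "canonical_kmers",
    "KmerIndex",
    "build_index",
    "reference_coverage",
    "mask_kmers",
    "save_index",
    "load_index",
]


def revcomp(sequence: str) -> str:
    """Reverse complement of an A/C/G/T sequence."""
    return sequence.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Strand-collapsed form: min(kmer, reverse complement)."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def canonical_kmers(sequence: str, k: int) -> list[tuple[int, str]]:
    """All (start, canonical k-mer) windows of ``sequence``.

    Windows containing any character outside A/C/G/T are skipped.  A
    sequence shorter than k yields an empty list.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = sequence.upper()
    n = len(seq)
    if n < k:
        return []
    # invalid[i..] prefix sums let each window's cleanliness be checked in O(1)
    prefix_bad = [0] * (n + 1)
    for i, base in enumerate(seq):
        prefix_bad[i + 1] = prefix_bad[i] + (base not in _VALID)
    out: list[tuple[int, str]] = []
    for i in range(n - k + 1):
        if prefix_bad[i + k] - prefix_bad[i]:
            continue
        out.append((i, canonical(seq[i : i + k])))
    return out


class KmerIndex:
    """Canonical-kmer index over a set of reference sequences.

    Attributes
    ----------
    k : word length.
    inventories : reference id -> ordered list of (position, canonical kmer).
    global_map : canonical kmer -> set of reference ids carrying it.
    ref_lengths : reference id -> sequence length.
    masked : set of canonical kmers excluded from all matching.
    """

    def __init__(self, k: int = DEFAULT_K):
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        self.k = k
        self.inventories: dict[str, list[tuple[int, str]]] = {}
        self.global_map: dict[str, set[str]] = {}
        self.ref_lengths: dict[str, int] = {}
        self.masked: set[str] = set()
        self._distinct_cache: dict[str, frozenset[str]] = {}

    def add_reference(self, ref_id: str, sequence: str) -> None:
        if ref_id in self.inventories:
            raise ValueError(f"duplicate reference id {ref_id!r}")
        inventory = canonical_kmers(sequence, self.k)
        self.inventories[ref_id] = inventory
        self.ref_lengths[ref_id] = len(sequence)
        for _, km in inventory:
            self.global_map.setdefault(km, set()).add(ref_id)

    def distinct_kmers(self, ref_id: str) -> frozenset[str]:
        """Distinct canonical k-mers of one reference (masked ones included)."""
        cached = self._distinct_cache.get(ref_id)
        if cached is None:
            cached = frozenset(km for _, km in self.inventories[ref_id])
            self._distinct_cache[ref_id] = cached
        return cached

    def unmasked_distinct(self, ref_id: str) -> frozenset[str]:
        return self.distinct_kmers(ref_id) - self.masked

    def references_sharing(self, kmers: Iterable[str]) -> set[str]:
        """Reference ids sharing at least one unmasked k-mer with ``kmers``."""
        refs: set[str] = set()
        for km in kmers:
            if km in self.masked:
                continue
            refs.update(self.global_map.get(km, ()))
        return refs

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self.inventories

    def __len__(self) -> int:
        return len(self.inventories)


def build_index(references: Iterable[tuple[str, str]], k: int = DEFAULT_K) -> KmerIndex:
    """Index labelled sequences; reference ids must be unique."""
    index = KmerIndex(k=k)
    for ref_id, sequence in references:
        index.add_reference(ref_id, sequence)
    return index


def _interval_union_length(positions: list[int], k: int) -> int:
    """Total bases covered by the union of [p, p+k-1] over sorted positions."""
    total = 0
    run_start = run_end = None
    for p in positions:
        if run_end is None or p > run_end + 1:
            if run_end is not None:
                total += run_end - run_start + 1
            run_start = p
            run_end = p + k - 1
        else:
            run_end = max(run_end, p + k - 1)
    if run_end is not None:
        total += run_end - run_start + 1
    return total


def reference_coverage(query_sequence: str, index: KmerIndex, ref_id: str) -> float:
    """Fraction of ``ref_id``'s bases covered by k-mers shared with the query.

    A reference position counts as matched when its canonical k-mer is
    unmasked and occurs anywhere in the query (either strand, by
    canonicalisation); coverage is the union of the matched k-wide
    intervals over the reference length.
    """
    if ref_id not in index:
        raise KeyError(f"unknown reference {ref_id!r}")
    query_kmers = {km for _, km in canonical_kmers(query_sequence, index.k)}
    matched = [
        p
        for p, km in index.inventories[ref_id]
        if km not in index.masked and km in query_kmers
    ]
    if not matched:
        return 0.0
    return _interval_union_length(matched, index.k) / index.ref_lengths[ref_id]


def mask_kmers(index: KmerIndex, mask_sequences: Iterable[tuple[str, str] | str]) -> float:
    """Add the canonical k-mers of ``mask_sequences`` to the index's mask.

    Mutates the index in place.  Returns the *masked fraction*: the share
    of the index's distinct k-mers that is now masked (0 by convention for
    an empty index).
    """
    for item in mask_sequences:
        seq = item[1] if isinstance(item, tuple) else item
        index.masked.update(km for _, km in canonical_kmers(seq, index.k))
    if not index.global_map:
        return 0.0
    return len(index.masked & index.global_map.keys()) / len(index.global_map)


# ---------------------------------------------------------------------------
# serialization (versioned JSON container)

_FORMAT_VERSION = 1


def save_index(index: KmerIndex, path: str | Path) -> None:
    payload = {
        "format_version": _FORMAT_VERSION,
        "k": index.k,
        "masked": sorted(index.masked),
        "references": {
            ref: {"length": index.ref_lengths[ref], "inventory": inv}
            for ref, inv in index.inventories.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_index(path: str | Path) -> KmerIndex:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported index format: {payload.get('format_version')}")
    index = KmerIndex(k=payload["k"])
    for ref, data in payload["references"].items():
        index.inventories[ref] = [(p, km) for p, km in data["inventory"]]
        index.ref_lengths[ref] = data["length"]
        for _, km in index.inventories[ref]:
            index.global_map.setdefault(km, set()).add(ref)
    index.masked = set(payload["masked"])
    return index
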