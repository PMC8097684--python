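"""Database cleaning: blocklist, contamination screen, dereplication, clustering.

The fixed pipeline order is blocklist -> contamination screen -> exact
dereplication -> (optional) greedy clustering; each stage feeds the next
and every removed entry gets exactly one primary reason.

The contamination screen indexes the contaminant FASTA with canonical
k-mers and removes a database entry when its k-mer matches cover at least
a threshold fraction of *the contaminant's* bases (default 0.5).  The
screen is nucleotide-only; protein records pass through untouched.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO

from .kmers import DEFAULT_K, build_index, canonical_kmers, reference_coverage
from .records import SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5

__all__ = [
    "Removal",
    "CleaningReport",
    "load_blocklist",
    "load_contaminants",
    "apply_blocklist",
    "screen_contamination",
    "dedup_exact",
    "cluster_greedy",
    "clean_pipeline",
]


@dataclass
class Removal:
    accession: str
    subdb: str
    reason: str  # blocklist | contamination | duplicate | cluster-member
    contaminant: str = ""
    coverage: float = 0.0
    retained: str = ""  # for duplicates/cluster members: the kept representative


@dataclass
class CleaningReport:
    removals: list[Removal] = field(default_factory=list)

    def by_reason(self, reason: str) -> list[Removal]:
        return [r for r in self.removals if r.reason == reason]

    def removed_fraction(self, subdb: str, n_input: int) -> float:
        if n_input == 0:
            return 0.0
        return sum(1 for r in self.removals if r.subdb == subdb) / n_input

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(
                ["accession", "subdb", "reason", "contaminant", "coverage", "retained"]
            )
            for r in self.removals:
                writer.writerow(
                    [r.accession, r.subdb, r.reason, r.contaminant,
                     f"{r.coverage:.4f}" if r.reason == "contamination" else "",
                     r.retained]
                )


def load_blocklist(source: str | Path | TextIO) -> list[str]:
    """One accession per line (bare or versioned); ``#`` comments allowed."""
    own = isinstance(source, (str, Path))
    handle = open(source) if own else source
    try:
        entries = []
        for line in handle:
            entry = line.split("#", 1)[0].strip()
            if entry:
                entries.append(entry)
        return entries
    finally:
        if own:
            handle.close()


def load_contaminants(path: str | Path) -> list[tuple[str, str]]:
    """Plain-FASTA contamination database as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def apply_blocklist(
    records: Sequence[SequenceRecord], blocklist: Iterable[str]
) -> tuple[list[SequenceRecord], CleaningReport]:
    """Remove entries whose accession (versioned or bare) is blocklisted."""
    listed = set(blocklist)
    report = CleaningReport()
    kept = []
    hit: set[str] = set()
    for rec in records:
        match = next(
            (b for b in (rec.accession, rec.bare_accession) if b in listed), None
        )
        if match is not None:
            hit.add(match)
            report.removals.append(Removal(rec.accession, rec.subdb, "blocklist"))
        else:
            kept.append(rec)
    for unused in sorted(listed - hit):
        logger.warning("blocklist entry %s matched no record", unused)
    return kept, report


def screen_contamination(
    records: Sequence[SequenceRecord],
    contaminants: Sequence[tuple[str, str]],
    threshold: float = DEFAULT_THRESHOLD,
    k: int = DEFAULT_K,
) -> tuple[list[SequenceRecord], CleaningReport]:
    """Remove entries covering >= ``threshold`` of any contaminant's bases.

    Coverage is the canonical-kmer base coverage of the contaminant by
    the entry (see :func:`virdb.kmers.reference_coverage`).  Contaminants
    shorter than k are ignored with a warning; protein records pass
    through with a notice.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    usable = [(cid, seq) for cid, seq in contaminants if len(seq) >= k]
    for cid, seq in contaminants:
        if len(seq) < k:
            logger.warning("contaminant %s shorter than k=%d: ignored", cid, k)
    report = CleaningReport()
    if not usable:
        if not contaminants:
            logger.warning("empty contamination database: nothing screened")
        return list(records), report
    index = build_index(usable, k=k)
    kept = []
    for rec in records:
        if rec.moltype != "nucleotide":
            logger.info("%s: protein record, contamination screen skipped", rec.accession)
            kept.append(rec)
            continue
        rec_kmers = {km for _, km in canonical_kmers(rec.sequence, k)}
        best_id, best_cov = "", 0.0
        for cid in sorted(index.references_sharing(rec_kmers)):
            cov = reference_coverage(rec.sequence, index, cid)
            if cov > best_cov:
                best_id, best_cov = cid, cov
        if best_cov >= threshold:
            report.removals.append(
                Removal(rec.accession, rec.subdb, "contamination",
                        contaminant=best_id, coverage=best_cov)
            )
        else:
            kept.append(rec)
    return kept, report


def dedup_exact(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], CleaningReport]:
    """Drop exact sequence duplicates (case-insensitive, forward strand only).

    The first occurrence in input order is retained; each removal points
    at its retained representative.
    """
    seen: dict[str, str] = {}
    kept, report = [], CleaningReport()
    for rec in records:
        key = rec.sequence.upper()
        if key in seen:
            report.removals.append(
                Removal(rec.accession, rec.subdb, "duplicate", retained=seen[key])
            )
        else:
            seen[key] = rec.accession
            kept.append(rec)
    return kept, report


def cluster_greedy(
    records: Sequence[SequenceRecord],
    identity_threshold: float,
    k: int = DEFAULT_K,
) -> tuple[list[SequenceRecord], dict[str, str], CleaningReport]:
    """Greedy length-sorted centroid clustering on shared canonical k-mers.

    Records are visited longest first (stable); a record joins the first
    centroid with which its shared-kmer identity -- shared distinct
    k-mers over the distinct k-mers of the shorter sequence -- reaches
    the threshold, else it founds a new centroid.  Returns (centroids,
    member -> centroid accession, report).
    """
    if not 0.0 <= identity_threshold <= 1.0:
        raise ValueError(f"identity threshold must be in [0, 1], got {identity_threshold}")
    ordered = sorted(records, key=len, reverse=True)
    centroids: list[SequenceRecord] = []
    centroid_kmers: list[frozenset[str]] = []
    membership: dict[str, str] = {}
    report = CleaningReport()
    for rec in ordered:
        rec_kmers = frozenset(km for _, km in canonical_kmers(rec.sequence, k))
        assigned = None
        for centroid, ckmers in zip(centroids, centroid_kmers):
            if rec.sequence.upper() == centroid.sequence.upper():
                identity = 1.0  # identical sequences cluster even below k
            else:
                denom_kmers = rec_kmers if len(rec) <= len(centroid) else ckmers
                identity = (
                    len(rec_kmers & ckmers) / len(denom_kmers) if denom_kmers else 0.0
                )
            if identity >= identity_threshold:
                assigned = centroid
                break
        if assigned is None:
            centroids.append(rec)
            centroid_kmers.append(rec_kmers)
            membership[rec.accession] = rec.accession
        else:
            membership[rec.accession] = assigned.accession
            report.removals.append(
                Removal(rec.accession, rec.subdb, "cluster-member",
                        retained=assigned.accession)
            )
    return centroids, membership, report


def clean_pipeline(
    records: Sequence[SequenceRecord],
    blocklist: Iterable[str] = (),
    contaminants: Sequence[tuple[str, str]] = (),
    threshold: float = DEFAULT_THRESHOLD,
    k: int = DEFAULT_K,
    cluster_identity: float | None = None,
) -> tuple[list[SequenceRecord], CleaningReport]:
    """Run the full cleaning pipeline in its fixed stage order."""
    kept, report = apply_blocklist(records, blocklist)
    if contaminants:
        kept, r2 = screen_contamination(kept, contaminants, threshold=threshold, k=k)
        report.removals.extend(r2.removals)
    kept, r3 = dedup_exact(kept)
    report.removals.extend(r3.removals)
    if cluster_identity is not None:
        kept, _, r4 = cluster_greedy(kept, cluster_identity, k=k)
        report.removals.extend(r4.removals)
    return kept, report
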