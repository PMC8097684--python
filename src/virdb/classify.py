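"""Kmer-based read/contig classification against a curated database.

Each query (FASTQ read or FASTA contig) is assigned to the template whose
inventory contains the most of the query's canonical k-mers (counted with
multiplicity); ties go to the template with fewer distinct k-mers, then
the lexicographically smaller accession.  Per-template hits aggregate the
assigned reads: *template coverage* is the fraction of the template's
distinct unmasked k-mers seen in at least one assigned read, *template
identity* the matched/total k-mer ratio pooled over its reads.  A hit
passes when both clear the user thresholds (defaults: coverage 0.8,
identity 0).  Host k-mers can be masked out of the index beforehand so
host-derived reads can no longer drive false-positive hits.

Composition reports give the share of assigned reads per virus family
(= sub-database) or species (= organism).
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .kmers import DEFAULT_K, KmerIndex, build_index, canonical_kmers, mask_kmers
from .records import SequenceRecord, read_annotated_fasta
from .versioning import CONCAT_FASTA

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 0.8

__all__ = [
    "ReadAssignment",
    "TemplateHit",
    "CompositionReport",
    "TemplateInfo",
    "assign_read",
    "call_hits",
    "compose",
    "classify_run",
]


@dataclass
class ReadAssignment:
    read_id: str
    template: str | None  # accession, or None when unassigned
    matched: int  # kmers (with multiplicity) found in the assigned template
    total: int  # valid kmer windows in the read
    tie: bool = False
    matched_kmers: frozenset[str] = frozenset()  # supports coverage aggregation

    @property
    def identity(self) -> float:
        return self.matched / self.total if self.total else 0.0

    @property
    def assigned(self) -> bool:
        return self.template is not None


@dataclass
class TemplateInfo:
    subdb: str = ""
    organism: str = ""
    taxid: int = 0


@dataclass
class TemplateHit:
    template: str
    subdb: str
    organism: str
    taxid: int
    read_count: int
    coverage: float
    identity: float
    passed: bool


@dataclass
class CompositionReport:
    level: str  # "family" or "species"
    fractions: dict[str, float] = field(default_factory=dict)
    assigned: int = 0
    unassigned: int = 0


def assign_read(sequence: str, index: KmerIndex) -> ReadAssignment:
    """Best-template assignment of one read by unmasked canonical-kmer count."""
    kmer_list = [km for _, km in canonical_kmers(sequence, index.k)]
    total = len(kmer_list)
    if total == 0:
        return ReadAssignment("", None, 0, 0)
    candidates = index.references_sharing(kmer_list)
    if not candidates:
        return ReadAssignment("", None, 0, total)
    best_ref, best_count, best_kmers, tie = None, 0, frozenset(), False
    for ref in candidates:
        template_kmers = index.unmasked_distinct(ref)
        hits = [km for km in kmer_list if km in template_kmers]
        count = len(hits)
        if count == 0:
            continue
        if best_ref is None or count > best_count:
            best_ref, best_count, best_kmers, tie = ref, count, frozenset(hits), False
        elif count == best_count:
            tie = True
            challenger = (len(index.distinct_kmers(ref)), ref)
            incumbent = (len(index.distinct_kmers(best_ref)), best_ref)
            if challenger < incumbent:
                best_ref, best_kmers = ref, frozenset(hits)
    if best_ref is None:
        return ReadAssignment("", None, 0, total)
    return ReadAssignment("", best_ref, best_count, total, tie=tie, matched_kmers=best_kmers)


def call_hits(
    assignments: Iterable[ReadAssignment],
    index: KmerIndex,
    metadata: Mapping[str, TemplateInfo] | None = None,
    min_identity: float = 0.0,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[TemplateHit]:
    """Aggregate read assignments into per-template hits.

    Both passing and failing templates are reported (flagged), sorted by
    mapped read count descending, then accession.
    """
    metadata = metadata or {}
    per_template: dict[str, list[ReadAssignment]] = {}
    for a in assignments:
        if a.assigned:
            per_template.setdefault(a.template, []).append(a)
    hits = []
    for template, reads in per_template.items():
        template_kmers = index.unmasked_distinct(template)
        seen: set[str] = set()
        for a in reads:
            seen.update(a.matched_kmers)
        coverage = len(seen & template_kmers) / len(template_kmers) if template_kmers else 0.0
        matched = sum(a.matched for a in reads)
        total = sum(a.total for a in reads)
        identity = matched / total if total else 0.0
        info = metadata.get(template, TemplateInfo())
        hits.append(
            TemplateHit(
                template=template,
                subdb=info.subdb,
                organism=info.organism,
                taxid=info.taxid,
                read_count=len(reads),
                coverage=coverage,
                identity=identity,
                passed=coverage >= min_coverage and identity >= min_identity,
            )
        )
    hits.sort(key=lambda h: (-h.read_count, h.template))
    return hits


def compose(
    assignments: Iterable[ReadAssignment],
    metadata: Mapping[str, TemplateInfo],
    level: str = "family",
) -> CompositionReport:
    """Fraction of assigned reads per family (sub-database) or species."""
    if level not in {"family", "species"}:
        raise ValueError(f"level must be 'family' or 'species', got {level!r}")
    counts: dict[str, int] = {}
    assigned = unassigned = 0
    for a in assignments:
        if not a.assigned:
            unassigned += 1
            continue
        info = metadata.get(a.template)
        if info is None:
            raise KeyError(f"assigned template {a.template} missing from manifest metadata")
        label = info.subdb if level == "family" else info.organism
        counts[label] = counts.get(label, 0) + 1
        assigned += 1
    fractions = {k: v / assigned for k, v in counts.items()} if assigned else {}
    return CompositionReport(level=level, fractions=fractions,
                             assigned=assigned, unassigned=unassigned)


# ---------------------------------------------------------------------------
# file-level run


def template_metadata(records: Iterable[SequenceRecord]) -> dict[str, TemplateInfo]:
    return {
        rec.accession: TemplateInfo(subdb=rec.subdb, organism=rec.organism, taxid=rec.taxid)
        for rec in records
    }


def _read_queries(path: Path) -> Iterable[tuple[str, str]]:
    name = path.name
    opener = gzip.open if name.endswith(".gz") else open
    stem = name[:-3] if name.endswith(".gz") else name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, fmt):
            yield rec.id, str(rec.seq).upper()


def classify_run(
    db_dir: str | Path,
    query_path: str | Path,
    out_dir: str | Path,
    k: int = DEFAULT_K,
    host_mask: str | Path | None = None,
    min_identity: float = 0.0,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> tuple[list[TemplateHit], dict[str, CompositionReport]]:
    """Classify a FASTQ/FASTA query file against a database directory.

    Builds the index from the concatenated database FASTA, applies the
    optional host mask (logging the masked-kmer fraction), assigns every
    query, and writes ``hits.tsv``, ``composition_family.tsv``,
    ``composition_species.tsv`` and ``run.log`` under ``out_dir``.
    """
    db_dir, query_path, out_dir = Path(db_dir), Path(query_path), Path(out_dir)
    concat = db_dir / CONCAT_FASTA
    if not concat.exists():
        raise FileNotFoundError(f"no {CONCAT_FASTA} in {db_dir}; build the database first")
    templates = read_annotated_fasta(concat)
    index = build_index(((r.accession, r.sequence) for r in templates), k=k)
    masked_fraction = 0.0
    if host_mask is not None:
        mask_seqs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(host_mask), "fasta")]
        masked_fraction = mask_kmers(index, mask_seqs)
        logger.info("masked %.2f%% of database kmers", 100 * masked_fraction)
    metadata = template_metadata(templates)
    assignments = []
    n_queries = 0
    for read_id, seq in _read_queries(query_path):
        n_queries += 1
        a = assign_read(seq, index)
        a.read_id = read_id
        assignments.append(a)
    if n_queries == 0:
        logger.warning("query file %s is empty", query_path)
    hits = call_hits(assignments, index, metadata,
                     min_identity=min_identity, min_coverage=min_coverage)
    compositions = {
        level: compose(assignments, metadata, level) for level in ("family", "species")
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "hits.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["template", "subdb", "organism", "taxid",
                         "reads", "coverage", "identity", "pass"])
        for h in hits:
            writer.writerow([h.template, h.subdb, h.organism, h.taxid, h.read_count,
                             f"{h.coverage:.4f}", f"{h.identity:.4f}",
                             "yes" if h.passed else "no"])
    for level, report in compositions.items():
        with open(out_dir / f"composition_{level}.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow([level, "fraction"])
            for label, frac in sorted(report.fractions.items()):
                writer.writerow([label, f"{frac:.4f}"])
            writer.writerow(["unassigned_reads", report.unassigned])
    with open(out_dir / "run.log", "a") as fh:
        fh.write(
            f"queries={n_queries}\tassigned={sum(1 for a in assignments if a.assigned)}\t"
            f"masked_kmer_fraction={masked_fraction:.4f}\t"
            f"min_coverage={min_coverage}\tmin_identity={min_identity}\tk={k}\n"
        )
    return hits, compositions
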