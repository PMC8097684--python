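"""Domain types and on-disk formats for annotated sequence databases.

A database is organised as named *sub-databases* (typically one virus
family each), defined by a Boolean search string.  Every entry is carried
in memory as a :class:`SequenceRecord` and on disk in an annotated-FASTA
dialect whose header encodes accession, sub-database, taxonomy ID and
organism.  Membership over time is tracked by a :class:`DatabaseManifest`
with an append-only history log, so any past version can be reconstructed.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import UndefinedSequenceError

logger = logging.getLogger(__name__)

NUCLEOTIDE_CODES = set("ACGTURYSWKMBDHVN")
PROTEIN_CODES = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

__all__ = [
    "SequenceRecord",
    "SubDatabaseSpec",
    "DatabaseManifest",
    "ParseError",
    "FormatError",
    "parse_input_spec",
    "parse_genbank_records",
    "write_annotated_fasta",
    "read_annotated_fasta",
    "concatenate_unique",
    "save_manifest",
    "load_manifest",
]


class ParseError(ValueError):
    """Raised for malformed input files (spec files, GenBank streams)."""


class FormatError(ValueError):
    """Raised when an on-disk record does not follow the expected dialect."""


@dataclass
class SequenceRecord:
    """One annotated database entry.

    ``taxid`` 0 means unknown; ``lineage`` is the ordered list of taxonomy
    rank names (possibly empty).  ``subdb`` is the sub-database label the
    entry was downloaded into.
    """

    accession: str
    sequence: str
    description: str = ""
    organism: str = ""
    taxid: int = 0
    lineage: list[str] = field(default_factory=list)
    moltype: str = "nucleotide"
    subdb: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.taxid < 0:
            raise ValueError(f"{self.accession}: negative taxid")
        self.sequence = self.sequence.upper()
        codes = NUCLEOTIDE_CODES if self.moltype == "nucleotide" else PROTEIN_CODES
        bad = set(self.sequence) - codes
        if bad:
            raise ValueError(
                f"{self.accession}: invalid {self.moltype} codes {sorted(bad)!r}"
            )

    @property
    def bare_accession(self) -> str:
        """Accession without the trailing ``.N`` version suffix."""
        return self.accession.rsplit(".", 1)[0]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SubDatabaseSpec:
    """A named Boolean query defining one sub-database."""

    name: str
    query: str
    length_bounds: tuple[int, int] | None = None
    moltype: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.name or any(c.isspace() for c in self.name):
            raise ValueError(f"sub-database name must be non-empty, no whitespace: {self.name!r}")
        if self.length_bounds is not None:
            lo, hi = self.length_bounds
            if not (0 < lo <= hi):
                raise ValueError(f"{self.name}: invalid length bounds ({lo}, {hi})")


@dataclass
class DatabaseManifest:
    """Versioned membership of a database plus its append-only history.

    ``membership`` maps sub-database name to the ordered accession list of
    the *current* version.  ``history`` holds one event dict per change
    (``timestamp``, ``version``, ``action``, ``accession``, ``subdb``);
    rollbacks additionally record a marker event with
    ``action == "rollback"``.  ``prior_versions`` keeps the full accession
    lists of every past version so membership can be restored without
    replaying history.
    """

    version: int = 1
    membership: dict[str, list[str]] = field(default_factory=dict)
    history: list[dict] = field(default_factory=list)
    prior_versions: dict[int, dict[str, list[str]]] = field(default_factory=dict)

    def all_accessions(self) -> set[str]:
        return {a for accs in self.membership.values() for a in accs}

    def replay(self, upto_version: int | None = None) -> dict[str, list[str]]:
        """Reconstruct membership by replaying the history log from scratch."""
        upto = self.version if upto_version is None else upto_version
        m: dict[str, list[str]] = {}
        for ev in self.history:
            if ev["version"] > upto:
                break
            if ev["action"] == "add":
                m.setdefault(ev["subdb"], []).append(ev["accession"])
            elif ev["action"] == "remove":
                m[ev["subdb"]].remove(ev["accession"])
        return {k: v for k, v in m.items() if v}


# ---------------------------------------------------------------------------
# input spec file


def parse_input_spec(stream: TextIO | str) -> list[SubDatabaseSpec]:
    """Parse a sub-database input file: ``name<TAB>Boolean query`` per line.

    Blank lines and ``#`` comments are ignored.  Duplicate names and lines
    without a tab separator are rejected.
    """
    if isinstance(stream, str):
        stream = StringIO(stream)
    specs: list[SubDatabaseSpec] = []
    seen: set[str] = set()
    for lineno, line in enumerate(stream, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "\t" not in stripped:
            raise ParseError(f"line {lineno}: expected 'name<TAB>query', got {stripped!r}")
        name, query = stripped.split("\t", 1)
        name, query = name.strip(), query.strip()
        if not query:
            raise ParseError(f"line {lineno}: empty query for {name!r}")
        if name in seen:
            raise ParseError(f"line {lineno}: duplicate sub-database name {name!r}")
        seen.add(name)
        specs.append(SubDatabaseSpec(name=name, query=query))
    return specs


# ---------------------------------------------------------------------------
# GenBank flat files


def _taxid_from_features(seqrec) -> int:
    for feat in seqrec.features:
        if feat.type == "source":
            for xref in feat.qualifiers.get("db_xref", []):
                m = re.match(r"taxon:(\d+)$", xref)
                if m:
                    return int(m.group(1))
    return 0


def parse_genbank_records(
    stream: TextIO | str,
    subdb: str = "",
    moltype: str = "nucleotide",
    strict: bool = False,
) -> tuple[list[SequenceRecord], int]:
    """Parse GenBank flat-file entries into :class:`SequenceRecord` objects.

    Entries missing their sequence (no ORIGIN data) or a versioned
    accession are skipped with a warning (raised instead under
    ``strict=True``).  A truncated final entry -- trailing content after
    the last ``//`` terminator -- is always a :class:`ParseError`.

    Returns ``(records, skipped_count)``.
    """
    text = stream if isinstance(stream, str) else stream.read()
    stripped = text.strip()
    if stripped:
        tail = stripped.rsplit("//", 1)[-1].strip()
        if tail or not stripped.endswith("//"):
            raise ParseError("truncated final entry: stream does not end with '//'")
    records: list[SequenceRecord] = []
    skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate Biopython format nits
        for seqrec in SeqIO.parse(StringIO(text), "genbank"):
            problem = None
            try:
                sequence = str(seqrec.seq)
            except UndefinedSequenceError:
                problem = "missing ORIGIN sequence"
                sequence = ""
            if not problem and "." not in seqrec.id:
                problem = "missing VERSION"
            if not problem and not sequence:
                problem = "empty sequence"
            if problem:
                msg = f"skipping entry {seqrec.id or seqrec.name}: {problem}"
                if strict:
                    raise ParseError(msg)
                logger.warning(msg)
                skipped += 1
                continue
            records.append(
                SequenceRecord(
                    accession=seqrec.id,
                    sequence=sequence,
                    description=seqrec.description,
                    organism=seqrec.annotations.get("organism", ""),
                    taxid=_taxid_from_features(seqrec),
                    lineage=list(seqrec.annotations.get("taxonomy", [])),
                    moltype=moltype,
                    subdb=subdb,
                )
            )
    return records, skipped


# ---------------------------------------------------------------------------
# annotated FASTA dialect

_WRAP = 70


def annotated_header(rec: SequenceRecord) -> str:
    organism = rec.organism.replace(" ", "_") if rec.organism else "unknown"
    return f"{rec.accession}|{rec.subdb}|{rec.taxid}|{organism}"


def write_annotated_fasta(records: Iterable[SequenceRecord], sink: TextIO | str | Path) -> None:
    """Write records in the 4-field annotated header dialect.

    Header: ``>{accession}|{subdb}|{taxid}|{organism}`` with spaces in the
    organism name replaced by underscores; sequence wrapped at 70 columns.
    """
    own = isinstance(sink, (str, Path))
    handle = open(sink, "w") if own else sink
    try:
        for rec in records:
            handle.write(f">{annotated_header(rec)}\n")
            for i in range(0, len(rec.sequence), _WRAP):
                handle.write(rec.sequence[i : i + _WRAP] + "\n")
    finally:
        if own:
            handle.close()


def read_annotated_fasta(source: TextIO | str | Path, moltype: str = "nucleotide") -> list[SequenceRecord]:
    """Read records written by :func:`write_annotated_fasta`.

    Description and lineage are not encoded in the header and come back
    empty.  A header without exactly four pipe-separated fields is a
    :class:`FormatError`.
    """
    own = isinstance(source, (str, Path))
    handle = open(source) if own else source
    try:
        records = []
        for seqrec in SeqIO.parse(handle, "fasta"):
            header = seqrec.description  # full header line after '>'
            fields = header.split("|")
            if len(fields) != 4:
                raise FormatError(
                    f"header {header!r}: expected 4 pipe-separated fields, got {len(fields)}"
                )
            accession, subdb, taxid, organism = fields
            records.append(
                SequenceRecord(
                    accession=accession,
                    sequence=str(seqrec.seq),
                    organism=organism.replace("_", " "),
                    taxid=int(taxid),
                    moltype=moltype,
                    subdb=subdb,
                )
            )
        return records
    finally:
        if own:
            handle.close()


def concatenate_unique(records: Iterable[SequenceRecord]) -> list[SequenceRecord]:
    """Drop repeated accessions, keeping the first occurrence.

    Sub-database queries may overlap; the concatenated database must carry
    each accession once, attributed to the first sub-database in input
    order.
    """
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.accession in seen:
            continue
        seen.add(rec.accession)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# manifest serialization

SUMMARY_FILE = "summary.tsv"
HISTORY_FILE = "history.jsonl"
VERSIONS_DIR = "versions"


def save_manifest(manifest: DatabaseManifest, directory: str | Path) -> None:
    """Persist a manifest: summary TSV, JSON-lines history, per-version lists."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / SUMMARY_FILE, "w") as fh:
        for subdb, accs in manifest.membership.items():
            for acc in accs:
                fh.write(f"{subdb}\t{acc}\n")
    with open(directory / HISTORY_FILE, "w") as fh:
        for event in manifest.history:
            fh.write(json.dumps(event) + "\n")
    vdir = directory / VERSIONS_DIR
    vdir.mkdir(exist_ok=True)
    snapshots = dict(manifest.prior_versions)
    snapshots[manifest.version] = manifest.membership
    for version, membership in snapshots.items():
        with open(vdir / f"v{version}.json", "w") as fh:
            json.dump({"version": version, "membership": membership}, fh, indent=1)


def load_manifest(directory: str | Path) -> DatabaseManifest:
    """Load a manifest saved by :func:`save_manifest`.

    Raises if the summary file is missing or the stored version files are
    not the contiguous range 1..N.
    """
    directory = Path(directory)
    summary = directory / SUMMARY_FILE
    if not summary.exists():
        raise FileNotFoundError(f"no {SUMMARY_FILE} in {directory}")
    history = []
    hfile = directory / HISTORY_FILE
    if hfile.exists():
        with open(hfile) as fh:
            history = [json.loads(line) for line in fh if line.strip()]
    vdir = directory / VERSIONS_DIR
    snapshots: dict[int, dict[str, list[str]]] = {}
    if vdir.is_dir():
        for vfile in vdir.glob("v*.json"):
            with open(vfile) as fh:
                data = json.load(fh)
            snapshots[data["version"]] = data["membership"]
    if not snapshots:
        raise FileNotFoundError(f"no version snapshots under {vdir}")
    versions = sorted(snapshots)
    if versions != list(range(1, versions[-1] + 1)):
        raise ValueError(f"version gap in stored snapshots: {versions}")
    current = versions[-1]
    return DatabaseManifest(
        version=current,
        membership=snapshots[current],
        history=history,
        prior_versions={v: m for v, m in snapshots.items() if v != current},
    )
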