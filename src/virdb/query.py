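"""Search-string augmentation and batched, verified entry downloads.

Downloads go through the :class:`EntryFetcher` contract: ``search`` turns
a Boolean query into an accession list and ``fetch_batch`` returns
GenBank flat-file text for requested accessions.  Two implementations are
provided: :class:`FixtureFetcher`, backed by in-memory records or a
directory of flat files (with a deliberately simplified query matcher:
taxonomy-ID and title-keyword terms only), and :class:`EntrezFetcher`,
a thin client for NCBI's E-utilities.  Only the fixture fetcher is part
of the tested surface; network behaviour is not exercised by the suite.
"""

from __future__ import annotations

import logging
import re
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from .records import ParseError, SequenceRecord, SubDatabaseSpec, parse_genbank_records

logger = logging.getLogger(__name__)

DEFAULT_BATCH_SIZE = 100
DEFAULT_DELAY = 0.4  # seconds between batches, to go easy on the remote server
DEFAULT_RETRIES = 3

__all__ = [
    "QueryFlags",
    "EntryFetcher",
    "FixtureFetcher",
    "EntrezFetcher",
    "DownloadError",
    "VerificationReport",
    "augment_query",
    "download_subdatabase",
    "verify_download",
]


@dataclass
class QueryFlags:
    """Standard search-string augmentations applied to every sub-database."""

    exclude_patents: bool = False
    exclude_human: bool = False
    complete_keyword: bool = False
    length_bounds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.length_bounds is not None and self.length_bounds[0] > self.length_bounds[1]:
            raise ValueError(f"invalid length bounds {self.length_bounds}")


def augment_query(spec: SubDatabaseSpec, flags: QueryFlags) -> str:
    """Append the enabled standard clauses to a sub-database query.

    Fixed order: patent exclusion, human exclusion, 'complete' keyword,
    sequence-length (SLEN) range.  With all flags off the base query is
    returned unchanged.
    """
    if not spec.query:
        raise ValueError(f"{spec.name}: empty base query")
    query = spec.query
    if flags.exclude_patents:
        query += " NOT gbdiv_pat[Properties]"
    if flags.exclude_human:
        query += " NOT txid9606[Organism]"
    if flags.complete_keyword:
        query += " AND complete"
    bounds = flags.length_bounds or spec.length_bounds
    if bounds is not None:
        query += f' AND ("{bounds[0]}"[SLEN] : "{bounds[1]}"[SLEN])'
    return query


class EntryFetcher(Protocol):
    """Contract every download backend satisfies."""

    def search(self, query: str) -> list[str]:
        """Accessions matching a Boolean query, in a deterministic order."""
        ...

    def fetch_batch(self, accessions: Sequence[str]) -> str:
        """GenBank flat-file text for exactly the requested accessions."""
        ...


# ---------------------------------------------------------------------------
# fixture fetcher (offline)

_TAXID_TERM = re.compile(r"txid(\d+)\[Organism[^\]]*\]")
_SLEN_TERM = re.compile(r'\(\s*"(\d+)"\[SLEN\]\s*:\s*"(\d+)"\[SLEN\]\s*\)')
_FIELD_TERM = re.compile(r"\S+\[[^\]]+\]")


class FixtureFetcher:
    """Offline :class:`EntryFetcher` over a fixed archive of entries.

    Query matching is intentionally a small subset of NCBI semantics:
    ``txidN[Organism...]`` terms match records whose taxid is N or one of
    its registered children (``taxid_children`` emulates the ``:exp``
    expansion); ``NOT txidN[...]`` excludes; a ``NOT gbdiv_pat[Properties]``
    clause excludes accessions registered as patents; bare keywords must
    all appear (case-insensitively) in the entry title; an SLEN range
    restricts sequence length.  Boolean grouping beyond this is not
    emulated.
    """

    def __init__(
        self,
        records: Iterable[SequenceRecord],
        taxid_children: dict[int, set[int]] | None = None,
        patent_accessions: set[str] | None = None,
    ):
        self._records: dict[str, SequenceRecord] = {}
        for rec in records:
            if rec.accession in self._records:
                raise ValueError(f"duplicate fixture accession {rec.accession}")
            self._records[rec.accession] = rec
        self.taxid_children = taxid_children or {}
        self.patent_accessions = patent_accessions or set()

    @classmethod
    def from_directory(
        cls, directory: str | Path, taxid_children: dict[int, set[int]] | None = None
    ) -> "FixtureFetcher":
        """Build the archive by parsing every ``*.gb``/``*.gbk`` flat file."""
        records: list[SequenceRecord] = []
        for path in sorted(Path(directory).iterdir()):
            if path.suffix in {".gb", ".gbk", ".genbank"}:
                recs, _ = parse_genbank_records(path.read_text())
                records.extend(recs)
        return cls(records, taxid_children=taxid_children)

    def _taxid_matches(self, record_taxid: int, taxid: int) -> bool:
        return record_taxid == taxid or record_taxid in self.taxid_children.get(taxid, ())

    def _matches(self, rec: SequenceRecord, query: str) -> bool:
        exclude_patents = "NOT gbdiv_pat[Properties]" in query
        query = query.replace("NOT gbdiv_pat[Properties]", " ")
        if exclude_patents and (
            rec.accession in self.patent_accessions
            or rec.bare_accession in self.patent_accessions
        ):
            return False
        slen = _SLEN_TERM.search(query)
        if slen:
            lo, hi = int(slen.group(1)), int(slen.group(2))
            if not lo <= len(rec.sequence) <= hi:
                return False
            query = _SLEN_TERM.sub(" ", query)
        # taxid terms, honouring a preceding NOT; multiple positive taxid
        # terms are treated as alternatives (the common "A OR B" pattern)
        positives: list[bool] = []
        for match in _TAXID_TERM.finditer(query):
            taxid = int(match.group(1))
            negated = query[: match.start()].rstrip().endswith("NOT")
            hit = self._taxid_matches(rec.taxid, taxid)
            if negated:
                if hit:
                    return False
            else:
                positives.append(hit)
        if positives and not any(positives):
            return False
        query = _TAXID_TERM.sub(" ", query)
        query = _FIELD_TERM.sub(" ", query)  # any remaining field terms: ignored
        title = rec.description.lower()
        for token in query.split():
            if token in {"AND", "OR", "NOT"}:
                continue
            if token.strip('"').lower() not in title:
                return False
        return True

    def search(self, query: str) -> list[str]:
        return [acc for acc, rec in self._records.items() if self._matches(rec, query)]

    def fetch_batch(self, accessions: Sequence[str]) -> str:
        from .simulate import emit_genbank_fixture  # local import avoids a cycle

        missing = [a for a in accessions if a not in self._records]
        if missing:
            raise KeyError(f"fixture archive has no entries for {missing}")
        return emit_genbank_fixture(self._records[a] for a in accessions)


# ---------------------------------------------------------------------------
# live E-utilities fetcher (not exercised by the test suite)

_EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"


class EntrezFetcher:
    """Minimal E-utilities client (esearch + efetch) for live downloads.

    Network behaviour is intentionally untested; use
    :class:`FixtureFetcher` everywhere reproducibility matters.
    """

    def __init__(self, db: str = "nuccore", email: str = "", retmax: int = 100000):
        self.db = db
        self.email = email
        self.retmax = retmax

    def _get(self, endpoint: str, params: dict) -> str:
        if self.email:
            params = {**params, "email": self.email}
        url = f"{_EUTILS}/{endpoint}?{urllib.parse.urlencode(params)}"
        with urllib.request.urlopen(url, timeout=60) as resp:
            return resp.read().decode()

    def search(self, query: str) -> list[str]:
        text = self._get(
            "esearch.fcgi",
            {"db": self.db, "term": query, "retmax": self.retmax, "idtype": "acc"},
        )
        return re.findall(r"<Id>([^<]+)</Id>", text)

    def fetch_batch(self, accessions: Sequence[str]) -> str:
        return self._get(
            "efetch.fcgi",
            {"db": self.db, "id": ",".join(accessions), "rettype": "gb", "retmode": "text"},
        )


# ---------------------------------------------------------------------------
# batched verified download


class DownloadError(RuntimeError):
    def __init__(self, message: str, missing: Sequence[str] = ()):
        super().__init__(message)
        self.missing = list(missing)


@dataclass
class VerificationReport:
    missing: list[str] = field(default_factory=list)
    unexpected: list[str] = field(default_factory=list)

    @property
    def count_ok(self) -> bool:
        return not self.missing and not self.unexpected


def verify_download(
    records: Iterable[SequenceRecord], expected_accessions: Iterable[str]
) -> VerificationReport:
    """Compare parsed records against the accession list the search returned."""
    parsed = {rec.accession for rec in records}
    expected = set(expected_accessions)
    return VerificationReport(
        missing=sorted(expected - parsed), unexpected=sorted(parsed - expected)
    )


def download_subdatabase(
    spec: SubDatabaseSpec,
    fetcher: EntryFetcher,
    flags: QueryFlags | None = None,
    batch_size: int = DEFAULT_BATCH_SIZE,
    retries: int = DEFAULT_RETRIES,
    delay: float = 0.0,
) -> tuple[list[SequenceRecord], list[str]]:
    """Search and download one sub-database in verified batches.

    Each batch is re-fetched (up to ``retries`` extra attempts) whenever
    fetching raises or the parsed accessions differ from the requested
    ones, so transient truncations are recovered.  Returns the records
    (tagged with ``spec.name``) and the accession list the search yielded.
    """
    if batch_size < 1:
        raise ValueError(f"batch_size must be >= 1, got {batch_size}")
    flags = flags or QueryFlags()
    accessions = fetcher.search(augment_query(spec, flags))
    records: list[SequenceRecord] = []
    for i in range(0, len(accessions), batch_size):
        batch = accessions[i : i + batch_size]
        if i and delay:
            time.sleep(delay)
        last_error: Exception | None = None
        for attempt in range(retries + 1):
            try:
                text = fetcher.fetch_batch(batch)
                parsed, _ = parse_genbank_records(text, subdb=spec.name, moltype=spec.moltype)
            except (ParseError, OSError, KeyError) as exc:
                last_error = exc
                continue
            report = verify_download(parsed, batch)
            if report.count_ok:
                records.extend(parsed)
                break
            last_error = DownloadError(
                f"batch mismatch: missing {report.missing}, unexpected {report.unexpected}",
                missing=report.missing,
            )
        else:
            missing = getattr(last_error, "missing", batch)
            raise DownloadError(
                f"{spec.name}: batch failed after {retries + 1} attempts "
                f"({last_error}); missing accessions: {missing}",
                missing=missing,
            )
    return records, accessions
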