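"""Versioned database directories: build, diff-based update, rollback.

On-disk layout of a database directory::

    summary.tsv          current membership (subdb <TAB> accession)
    history.jsonl        append-only event log
    versions/vN.json     full membership snapshot of every version
    store/<acc>.fasta    every sequence ever downloaded (archive)
    <subdb>.fasta        per-sub-database FASTA, current version
    database.fasta       concatenated FASTA, each accession once

Updates download only accessions not already held; entries removed from a
version stay archived in ``store/`` so rolling back never re-downloads.
A rollback is itself a new version whose membership equals the target's,
so history remains strictly append-only.  ``purge`` reclaims the archive
space for accessions outside the current membership.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

from .query import DownloadError, EntryFetcher, QueryFlags, augment_query, download_subdatabase
from .records import (
    DatabaseManifest,
    SequenceRecord,
    SubDatabaseSpec,
    concatenate_unique,
    load_manifest,
    read_annotated_fasta,
    save_manifest,
    write_annotated_fasta,
)

logger = logging.getLogger(__name__)

STORE_DIR = "store"
CONCAT_FASTA = "database.fasta"

__all__ = [
    "UpdatePlan",
    "compute_update_plan",
    "build_database",
    "apply_update",
    "update_database",
    "rollback",
    "purge",
    "load_store_record",
]


@dataclass
class UpdatePlan:
    to_add: list[str] = field(default_factory=list)
    to_remove: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.to_add and not self.to_remove


def compute_update_plan(old_accessions, new_accessions) -> UpdatePlan:
    """Set difference between the current and freshly searched accession lists."""
    old, new = set(old_accessions), set(new_accessions)
    return UpdatePlan(to_add=sorted(new - old), to_remove=sorted(old - new))


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def _event(version: int, action: str, accession: str, subdb: str) -> dict:
    return {
        "timestamp": _now(),
        "version": version,
        "action": action,
        "accession": accession,
        "subdb": subdb,
    }


def _store_path(db_dir: Path, accession: str) -> Path:
    return db_dir / STORE_DIR / f"{accession}.fasta"


def load_store_record(db_dir: str | Path, accession: str) -> SequenceRecord:
    path = _store_path(Path(db_dir), accession)
    if not path.exists():
        raise FileNotFoundError(f"accession {accession} not in store {path.parent}")
    return read_annotated_fasta(path)[0]


def _write_store(db_dir: Path, records: Sequence[SequenceRecord]) -> None:
    store = db_dir / STORE_DIR
    store.mkdir(parents=True, exist_ok=True)
    for rec in records:
        path = _store_path(db_dir, rec.accession)
        if not path.exists():
            write_annotated_fasta([rec], path)


def _write_fastas(db_dir: Path, manifest: DatabaseManifest) -> None:
    """Rewrite per-subdb and concatenated FASTA from the store + membership."""
    ordered: list[SequenceRecord] = []
    for subdb, accessions in manifest.membership.items():
        subdb_records = [
            dataclasses.replace(load_store_record(db_dir, acc), subdb=subdb)
            for acc in accessions
        ]
        write_annotated_fasta(subdb_records, db_dir / f"{subdb}.fasta")
        ordered.extend(subdb_records)
    write_annotated_fasta(concatenate_unique(ordered), db_dir / CONCAT_FASTA)


def build_database(
    db_dir: str | Path,
    specs: Sequence[SubDatabaseSpec],
    fetcher: EntryFetcher,
    flags: QueryFlags | None = None,
    batch_size: int = 100,
    retries: int = 3,
    delay: float = 0.0,
) -> DatabaseManifest:
    """Initial download of every sub-database into a fresh directory."""
    db_dir = Path(db_dir)
    db_dir.mkdir(parents=True, exist_ok=True)
    manifest = DatabaseManifest(version=1)
    for spec in specs:
        records, accessions = download_subdatabase(
            spec, fetcher, flags=flags, batch_size=batch_size, retries=retries, delay=delay
        )
        manifest.membership[spec.name] = list(accessions)
        manifest.history.extend(
            _event(1, "add", acc, spec.name) for acc in accessions
        )
        _write_store(db_dir, records)
    _write_fastas(db_dir, manifest)
    save_manifest(manifest, db_dir)
    return manifest


def apply_update(
    db_dir: str | Path,
    plans: Mapping[str, UpdatePlan],
    fetcher: EntryFetcher,
    batch_size: int = 100,
    retries: int = 3,
    delay: float = 0.0,
) -> DatabaseManifest:
    """Apply per-sub-database add/remove plans as one new version.

    Only accessions absent from the local store are fetched; an empty
    overall plan leaves the manifest untouched.  All fetching happens
    before any file is rewritten, so a download failure leaves the
    directory unchanged.
    """
    db_dir = Path(db_dir)
    manifest = load_manifest(db_dir)
    # effective changes relative to the current membership; a plan that is
    # already applied (or empty) must be a no-op, not a new version
    effective: dict[str, UpdatePlan] = {}
    for subdb, plan in plans.items():
        current = set(manifest.membership.get(subdb, []))
        eff = UpdatePlan(
            to_add=[a for a in plan.to_add if a not in current],
            to_remove=[a for a in plan.to_remove if a in current],
        )
        if not eff.empty:
            effective[subdb] = eff
    plans = effective
    if not plans:
        return manifest
    held = manifest.all_accessions() | {
        p.stem for p in (db_dir / STORE_DIR).glob("*.fasta")
    }
    need: dict[str, str] = {}  # accession -> subdb to tag it with
    for subdb, plan in plans.items():
        for acc in plan.to_add:
            if acc not in held:
                need.setdefault(acc, subdb)
    fetched: list[SequenceRecord] = []
    accs = sorted(need)
    for i in range(0, len(accs), batch_size):
        batch = accs[i : i + batch_size]
        from .records import parse_genbank_records

        last_error: Exception | None = None
        for _ in range(retries + 1):
            try:
                parsed, _ = parse_genbank_records(fetcher.fetch_batch(batch))
                if {r.accession for r in parsed} == set(batch):
                    break
                last_error = DownloadError(f"batch mismatch for {batch}")
            except Exception as exc:  # noqa: BLE001 - retried, re-raised below
                last_error = exc
        else:
            raise DownloadError(f"update fetch failed: {last_error}", missing=batch)
        for rec in parsed:
            fetched.append(dataclasses.replace(rec, subdb=need[rec.accession]))
    # commit
    new_version = manifest.version + 1
    manifest.prior_versions[manifest.version] = {
        k: list(v) for k, v in manifest.membership.items()
    }
    for subdb, plan in plans.items():
        current = list(manifest.membership.get(subdb, []))
        for acc in plan.to_remove:
            if acc in current:
                current.remove(acc)
                manifest.history.append(_event(new_version, "remove", acc, subdb))
        for acc in plan.to_add:
            if acc not in current:
                current.append(acc)
                manifest.history.append(_event(new_version, "add", acc, subdb))
        manifest.membership[subdb] = current
    manifest.membership = {k: v for k, v in manifest.membership.items() if v}
    manifest.version = new_version
    _write_store(db_dir, fetched)
    _write_fastas(db_dir, manifest)
    save_manifest(manifest, db_dir)
    return manifest


def update_database(
    db_dir: str | Path,
    specs: Sequence[SubDatabaseSpec],
    fetcher: EntryFetcher,
    flags: QueryFlags | None = None,
    **kwargs,
) -> tuple[DatabaseManifest, dict[str, UpdatePlan]]:
    """Re-run every search and apply the resulting diff plans."""
    flags = flags or QueryFlags()
    manifest = load_manifest(db_dir)
    plans = {
        spec.name: compute_update_plan(
            manifest.membership.get(spec.name, []),
            fetcher.search(augment_query(spec, flags)),
        )
        for spec in specs
    }
    return apply_update(db_dir, plans, fetcher, **kwargs), plans


def rollback(db_dir: str | Path, target_version: int) -> DatabaseManifest:
    """Restore a prior version's membership as a new version.

    All of the target's sequences must still be archived; otherwise an
    error lists the missing accessions (a purge may have removed them).
    """
    db_dir = Path(db_dir)
    manifest = load_manifest(db_dir)
    snapshots = dict(manifest.prior_versions)
    snapshots[manifest.version] = manifest.membership
    if target_version not in snapshots:
        raise KeyError(f"unknown version {target_version} (have {sorted(snapshots)})")
    target = {k: list(v) for k, v in snapshots[target_version].items()}
    missing = [
        acc
        for accs in target.values()
        for acc in accs
        if not _store_path(db_dir, acc).exists()
    ]
    if missing:
        raise FileNotFoundError(f"archived sequences missing for rollback: {sorted(missing)}")
    new_version = manifest.version + 1
    manifest.prior_versions[manifest.version] = {
        k: list(v) for k, v in manifest.membership.items()
    }
    # diff events keep history replayable; the marker records intent
    for subdb in sorted(set(manifest.membership) | set(target)):
        old = manifest.membership.get(subdb, [])
        new = target.get(subdb, [])
        for acc in old:
            if acc not in new:
                manifest.history.append(_event(new_version, "remove", acc, subdb))
        for acc in new:
            if acc not in old:
                manifest.history.append(_event(new_version, "add", acc, subdb))
    manifest.history.append(
        {
            "timestamp": _now(),
            "version": new_version,
            "action": "rollback",
            "accession": None,
            "subdb": None,
            "target_version": target_version,
        }
    )
    manifest.membership = target
    manifest.version = new_version
    _write_fastas(db_dir, manifest)
    save_manifest(manifest, db_dir)
    return manifest


def purge(db_dir: str | Path) -> list[str]:
    """Delete archived sequences not in the current membership.

    Returns the purged accessions.  Rolling back to a version that needed
    them will fail afterwards, by design.
    """
    db_dir = Path(db_dir)
    manifest = load_manifest(db_dir)
    current = manifest.all_accessions()
    purged = []
    for path in sorted((db_dir / STORE_DIR).glob("*.fasta")):
        if path.stem not in current:
            path.unlink()
            purged.append(path.stem)
    return purged
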