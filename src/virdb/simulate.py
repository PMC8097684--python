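"""Synthetic fixtures: random genomes, GenBank flat files, chimeras and reads.

Everything the pipeline consumes from the outside world -- GenBank
entries, contaminated (chimeric) submissions, sequencing reads -- can be
generated here deterministically from a seed, so the full download /
clean / classify workflow is exercisable with no network access.

The read simulator follows the common shotgun-simulation model: uniform
start positions, uniform strand, independent per-base substitutions at a
fixed error rate, optional paired-end mode with a fixed outer insert
size.  Indels and position-dependent quality profiles are deliberately
not modelled; constant quality 'I' is written in FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .kmers import revcomp
from .records import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")

__all__ = [
    "random_genome",
    "make_chimera",
    "SimulatedRead",
    "simulate_reads",
    "write_fastq",
    "emit_genbank_fixture",
    "MockCommunity",
    "mock_community",
]


def random_genome(length: int, seed: int | np.random.Generator) -> str:
    """Uniform i.i.d. A/C/G/T sequence; deterministic per (length, seed)."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_chimera(genome: str, insert: str, position: int) -> str:
    """Splice ``insert`` into ``genome`` at ``position`` (0..len(genome))."""
    if not 0 <= position <= len(genome):
        raise ValueError(f"position {position} out of range 0..{len(genome)}")
    return genome[:position] + insert + genome[position:]


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    mate: int = 0  # 0 = single end, 1/2 for pairs


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(
    genome: str,
    n: int,
    read_length: int,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    paired: bool = False,
    insert_size: int = 500,
    genome_id: str = "g",
) -> list[SimulatedRead]:
    """Simulate shotgun reads from one genome.

    Start positions are uniform on [0, len-L]; strand is uniform; each
    base substitutes with probability ``error_rate`` to a uniformly chosen
    different base.  Paired mode emits the mate from the opposite strand
    at the outer ``insert_size`` distance (clipped to the genome).  Read
    ids encode genome id, start and strand.
    """
    if read_length > len(genome):
        raise ValueError(f"read length {read_length} exceeds genome length {len(genome)}")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error rate must be in [0, 1), got {error_rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for i in range(n):
        start = int(rng.integers(0, len(genome) - read_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = genome[start : start + read_length]
        if strand == "-":
            fragment = revcomp(fragment)
        base_id = f"{genome_id}:{start}:{strand}:{i}"
        if not paired:
            reads.append(SimulatedRead(base_id, _mutate(fragment, error_rate, rng)))
            continue
        mate_start = min(max(start + insert_size - read_length, 0), len(genome) - read_length)
        mate = genome[mate_start : mate_start + read_length]
        if strand == "+":
            mate = revcomp(mate)
        reads.append(SimulatedRead(base_id + "/1", _mutate(fragment, error_rate, rng), mate=1))
        reads.append(SimulatedRead(base_id + "/2", _mutate(mate, error_rate, rng), mate=2))
    return reads


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


# ---------------------------------------------------------------------------
# GenBank flat-file fixtures


def emit_genbank_fixture(records: Iterable[SequenceRecord]) -> str:
    """Render records as minimal well-formed GenBank flat-file entries.

    Entries carry LOCUS, DEFINITION, ACCESSION, VERSION, ORGANISM with
    lineage, a source feature with a taxon db_xref (when taxid > 0) and
    the ORIGIN sequence block, each terminated by ``//`` -- enough for the
    flat-file parser to recover every field losslessly.
    """
    out = StringIO()
    for rec in records:
        bare, _, version = rec.accession.partition(".")
        bio = BioSeqRecord(
            Seq(rec.sequence),
            id=rec.accession,
            name=bare[:16],
            description=rec.description.rstrip("."),
        )
        bio.annotations.update(
            {
                "molecule_type": "DNA" if rec.moltype == "nucleotide" else "protein",
                "organism": rec.organism,
                "source": rec.organism,
                "taxonomy": list(rec.lineage),
                "accessions": [bare],
                "sequence_version": int(version) if version else 1,
                "topology": "linear",
                "data_file_division": "VRL",
            }
        )
        qualifiers = {"organism": [rec.organism]}
        if rec.taxid:
            qualifiers["db_xref"] = [f"taxon:{rec.taxid}"]
        bio.features.append(
            SeqFeature(SimpleLocation(0, len(rec.sequence)), type="source", qualifiers=qualifiers)
        )
        SeqIO.write([bio], out, "genbank")
    return out.getvalue()


# ---------------------------------------------------------------------------
# the standard mock community used by end-to-end tests

FAMILY_NAMES = ["Alphasynviridae", "Betasynviridae", "Gammasynviridae",
                "Deltasynviridae", "Epsilonsynviridae"]
FAMILY_TAXIDS = {name: 110 + 10 * i for i, name in enumerate(FAMILY_NAMES)}
FAMILY_GENOME_LENGTHS = {name: length for name, length in
                         zip(FAMILY_NAMES, [3000, 4500, 6000, 8000, 10000])}
HOST_TAXID = 9606
HOST_LENGTH = 12000
VECTOR_LENGTH = 600
GENOMES_PER_FAMILY = 3


@dataclass
class MockCommunity:
    """A miniature curated-download scenario.

    Five synthetic virus families with three complete genomes each, a
    host genome, two cloning-vector contaminants, one vector-spiked
    chimeric submission and one host-fragment chimeric submission, plus
    short partial-gene fragments per family.  All sequences derive
    deterministically from one seed.
    """

    genomes: list[SequenceRecord]
    fragments: list[SequenceRecord]
    vector_chimera: SequenceRecord
    host_chimera: SequenceRecord
    host: SequenceRecord
    vectors: list[tuple[str, str]]
    taxid_children: dict[int, set[int]] = field(default_factory=dict)

    @property
    def family_names(self) -> list[str]:
        return list(FAMILY_NAMES)

    def all_genbank_entries(self) -> list[SequenceRecord]:
        """Every entry a search against the fixture archive could return."""
        return [*self.genomes, *self.fragments, self.vector_chimera,
                self.host_chimera, self.host]

    def input_spec_text(self) -> str:
        lines = [
            f"{name}\ttxid{FAMILY_TAXIDS[name]}[Organism:exp]" for name in FAMILY_NAMES
        ]
        return "\n".join(lines) + "\n"


def mock_community(seed: int = 0) -> MockCommunity:
    rng = np.random.default_rng(seed)
    genomes: list[SequenceRecord] = []
    fragments: list[SequenceRecord] = []
    taxid_children: dict[int, set[int]] = {}
    for fi, family in enumerate(FAMILY_NAMES):
        family_taxid = FAMILY_TAXIDS[family]
        taxid_children[family_taxid] = set()
        for gi in range(GENOMES_PER_FAMILY):
            taxid = family_taxid * 1000 + gi
            taxid_children[family_taxid].add(taxid)
            organism = f"Synthvirus {family[:-7].lower()} {gi + 1}"
            accession = f"SYN{fi + 1:02d}{gi + 1:03d}.1"
            genome = random_genome(FAMILY_GENOME_LENGTHS[family], rng)
            genomes.append(
                SequenceRecord(
                    accession=accession,
                    sequence=genome,
                    description=f"{organism}, complete genome",
                    organism=organism,
                    taxid=taxid,
                    lineage=["Viruses", family],
                    subdb=family,
                )
            )
            # one short partial-gene submission per genome
            frag_len = int(rng.integers(200, 400))
            start = int(rng.integers(0, len(genome) - frag_len))
            fragments.append(
                SequenceRecord(
                    accession=f"FRG{fi + 1:02d}{gi + 1:03d}.1",
                    sequence=genome[start : start + frag_len],
                    description=f"{organism} polymerase gene, partial cds",
                    organism=organism,
                    taxid=taxid,
                    lineage=["Viruses", family],
                    subdb=family,
                )
            )
    host_seq = random_genome(HOST_LENGTH, rng)
    host = SequenceRecord(
        accession="HST00001.1",
        sequence=host_seq,
        description="Synthetic host chromosome fragment",
        organism="Homo sapiens synthetic",
        taxid=HOST_TAXID,
        lineage=["Eukaryota", "Metazoa"],
        subdb="",
    )
    vectors = [(f"VEC{i + 1:03d}", random_genome(VECTOR_LENGTH, rng)) for i in range(2)]
    # a genome submission that still carries a full cloning vector
    base = genomes[0]
    vector_chimera = SequenceRecord(
        accession="CHM00001.1",
        sequence=make_chimera(base.sequence, vectors[0][1], len(base.sequence) // 2),
        description=f"{base.organism} clone, complete genome",
        organism=base.organism,
        taxid=base.taxid,
        lineage=list(base.lineage),
        subdb=base.subdb,
    )
    # a mostly-host misassembly submitted under a viral family; its short
    # non-host part is novel sequence, not a copy of any real genome
    base2 = genomes[3]
    host_fragment = host_seq[2000:5000]
    novel_insert = random_genome(200, rng)
    host_chimera = SequenceRecord(
        accession="CHM00002.1",
        sequence=make_chimera(host_fragment, novel_insert, 0),
        description=f"{base2.organism} unverified misassembly, complete genome",
        organism=base2.organism,
        taxid=base2.taxid,
        lineage=list(base2.lineage),
        subdb=base2.subdb,
    )
    return MockCommunity(
        genomes=genomes,
        fragments=fragments,
        vector_chimera=vector_chimera,
        host_chimera=host_chimera,
        host=host,
        vectors=vectors,
        taxid_children=taxid_children,
    )
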