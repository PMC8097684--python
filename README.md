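# virdb

Curated, family-partitioned viral sequence databases — automated download,
cleaning, versioned updating — plus k-mer based classification of reads and
contigs against them.

## The problem

Viral metagenomics (virome sequencing, surveillance, diagnostics) needs
reference databases that are both *comprehensive* (public archives grow by
thousands of viral entries per month) and *clean* (public entries routinely
carry cloning vectors, host DNA, misassemblies and heavy redundancy, all of
which drive false-positive classifications from short reads). `virdb`
automates the whole loop:

* **Download** — a plain input file maps each sub-database (typically one
  virus family) to a Boolean search string; entries are fetched in verified
  batches through a pluggable fetcher (a live NCBI E-utilities client, or an
  offline archive-backed fetcher for reproducible work). Standard query
  augmentations (patent/human exclusion, the `complete` keyword, a
  sequence-length window) are one flag each.
* **Complete-genome restriction** — per-family length windows with a 10%
  buffer: keep entries with `round(0.9·shortest) ≤ L ≤ round(1.1·largest)`,
  where *shortest*/*largest* are the known genome (or segment) length
  extremes for the family; or, alternatively, title-keyword rules
  (`complete`/`partial` + `genome`).
* **Cleaning** — blocklist of known-bad accessions; removal of any entry
  whose k-mer matches cover ≥ a threshold fraction (default 0.5) of a
  contaminant sequence (vectors, rRNA, marker genes…); exact dereplication;
  optional greedy clustering.
* **Versioning** — updates download only new accessions, removals and
  additions are logged append-only, every prior version can be restored
  offline (removed sequences stay archived until an explicit purge).
* **Classification** — queries are assigned to the template sharing the most
  canonical 16-mers; per-template hits aggregate assigned reads into
  *coverage* (fraction of the template's distinct unmasked k-mers observed)
  and *identity* (matched/total k-mer ratio), with a default passing
  threshold of 80% coverage. Host k-mers can be masked out of the index so
  host-contaminated database entries cannot produce passing hits from host
  reads. Composition reports give per-family and per-species read fractions.

All matching is on canonical k-mers — `min(w, revcomp(w))` over clean
A/C/G/T windows `w` — so both strands are handled; contaminant coverage is
the interval union of matched k-mer positions over the contaminant length.

## Worked example

Everything is runnable offline: `virdb.simulate` generates a mock community
(5 synthetic virus families × 3 genomes, gene fragments, a host genome, two
vector contaminants, a vector-spiked chimera and a mostly-host misassembly)
and an archive-backed fetcher serves it as GenBank flat files. From
`examples/classify_sample.py` — build the database, simulate an even
five-family read sample plus host reads, classify with and without host
masking:

```
$ python examples/classify_sample.py
without host mask: 29 passing hits, 1 from chimeric entries
  family composition: {'Alphasynviridae': 0.19, 'Betasynviridae': 0.241, ...}
  unassigned reads: 872
with host mask: 28 passing hits, 0 from chimeric entries
  family composition: {'Alphasynviridae': 0.2, 'Betasynviridae': 0.2, ...}
  unassigned reads: 1200
```

Without masking, the 1 200 host reads pile onto the host-fragment chimera in
the database and push it over the 80% coverage threshold (a false-positive
hit, and an inflated fraction for its family). With the host mask the
chimera receives no reads, all host reads are unassigned, and the family
composition is uniform at 0.20 — the ground truth of the simulated sample.

The other examples cover the download (`build_database.py`), the cleaning
threshold sweep (`clean_database.py`, the full-length vector chimera is
removed at coverage 1.0 under every threshold) and versioned
update/rollback (`update_and_rollback.py`, only the two new accessions are
fetched, and rollback restores version 1 from the local archive).

The same workflow is available as a CLI for shell use:

```
virdb download input.tsv db/ --standard-exclusions --length-criteria lengths.tsv
virdb clean db/ --contamination univec.fasta --threshold 0.5
virdb classify --db db/ --query sample.fastq --host human.fasta --out results/
```

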