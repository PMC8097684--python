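# Methods

## Database model

A database is a set of named *sub-databases*, each defined by one Boolean
search string (in practice: one virus family per line of the input file).
Entries are stored with their annotations in a fixed FASTA header dialect,

```
>{accession}|{subdb}|{taxid}|{organism_with_underscores}
```

chosen so a classifier can recover taxonomy and family from the header
alone. The entry description and lineage are kept in memory and in the
GenBank source but deliberately not encoded in the header. Unknown taxonomy
is encoded as taxid 0 and an empty lineage; taxonomy is never invented.
When sub-database queries overlap, the accession is listed in every
sub-database's manifest but emitted once in the concatenated FASTA,
attributed to the first sub-database in input-file order, because a
classification index needs unique template ids.

Membership over time is a monotone version counter plus an append-only
JSON-lines event log (`add`/`remove` per accession, plus a `rollback`
marker event recording intent). Invariant: the membership of any version is
reconstructible by replaying the log, and full per-version snapshots are
stored as well so restoration does not depend on replay. Removed sequences
are archived rather than deleted — rollback therefore never touches the
network — and an explicit purge reclaims the space, after which rollbacks
needing the purged entries fail loudly with the missing accessions.

## Downloads

Fetching goes through a two-method contract (`search`, `fetch_batch`).
Batches (default 100 accessions, 0.4 s inter-batch delay, 3 retries) are
*verified*: the parsed accession set must equal the requested set, else the
batch is retried; a batch that still fails raises with the missing
accessions. The live E-utilities client implements the contract with
stdlib HTTP but is excluded from the automated test surface; all tests use
the archive-backed fixture fetcher. That fetcher's query matcher is an
intentional subset of NCBI semantics — taxid terms (with an explicit
parent→children expansion standing in for `:exp`), `NOT` exclusions for
taxids and the patent division, bare title keywords (all must occur), and
an SLEN length range. Multiple positive taxid terms act as alternatives
(`A OR B`); arbitrary Boolean grouping is not emulated.

Standard query augmentations are appended in a fixed order: `NOT
gbdiv_pat[Properties]`, `NOT txid9606[Organism]`, `AND complete`, `AND
("min"[SLEN] : "max"[SLEN])`. Exclusions default to off; a convenience
flag enables the patent+human pair.

## Complete-genome filters

The length criterion keeps entries within `[round(0.9·shortest),
round(1.1·largest)]` nt, inclusive at both ends, where the extremes are the
user-supplied known genome/segment lengths per family (TSV config; these
are curation inputs, not shipped facts). Segmented families get a single
(shortest-segment, largest-segment) window per family by default; listing
one spec per segment gives per-segment sub-databases. The same window can
be applied either inside the search string (SLEN) or locally after
download; on the fixture archive both routes agree by construction. The
title criterion keeps entries whose description contains "genome" together
with "complete", optionally also "partial" — case-insensitive substring
matching.

## K-mer engine

All matching uses canonical k-mers, `min(w, revcomp(w))`, k = 16 by
default everywhere (configurable). Windows containing any non-A/C/G/T code
are skipped, not expanded: deterministic, cheap, and a 16-wide loss around
each ambiguity code is negligible at genome scale.

*Contaminant coverage* (the cleaning statistic) counts covered bases: the
positions of the contaminant whose canonical k-mer also occurs in the
database entry mark k-wide intervals, and coverage is the length of their
union divided by the contaminant length. Split matches therefore
accumulate; no single contiguous alignment is required. This definition is
cross-checked in the tests against an independent brute-force oracle that
substring-searches every contaminant window in the entry and its reverse
complement.

*Masking*: the canonical k-mers of a mask FASTA (e.g. a host genome) are
added to a masked set that every lookup ignores. The reported masked
fraction is the share of the index's distinct k-mers that is masked.
Masking is monotone: no coverage or read count can increase.

## Classification

Each read (or contig) is assigned to the template whose unmasked k-mer set
contains the most of the read's canonical k-mers, counted with
multiplicity. Ties are broken deterministically: fewer distinct template
k-mers first (preferring the more specific template), then the smaller
accession; tied assignments are flagged. Reads with no valid k-mers or no
matches are unassigned. Paired reads are classified independently.

Per-template hits aggregate assigned reads. *Template coverage* is the
fraction of the template's distinct unmasked k-mers seen in at least one
assigned read — defined over distinct k-mers rather than base intervals so
aggregation across overlapping reads needs no positional alignment and
behaves sensibly under masking. *Template identity* pools matched/total
k-mer counts over the template's reads. A hit passes when coverage ≥ 0.8
(default) and identity ≥ 0 (default; settable). Composition reports are
fractions of assigned reads per family (= sub-database) or species
(= organism); unassigned reads are counted separately.

This is a deliberate simplification of full alignment-based mapping (no
consensus calling, no alignment extension, no fractional assignment of
multi-mapping reads); it preserves the decision structure — best-template
assignment, coverage/identity thresholds, host masking — that the
surrounding pipeline exercises.

## Cleaning defaults

Stage order is fixed: blocklist → contamination screen → exact
dereplication → optional clustering. The default contaminant-coverage
threshold is 0.5. Dereplication is exact, case-insensitive, forward-strand
only (reverse-complement duplicates are left to clustering), first
occurrence retained. Greedy clustering visits records longest-first; a
record joins the first centroid whose shared distinct-k-mer fraction —
normalised by the shorter sequence's k-mer count — reaches the identity
threshold. Contaminants shorter than k are ignored with a warning; protein
records pass the (nucleotide-only) screen untouched.

## Synthetic data

The fixture generator emulates the study conditions in miniature: five
virus families with three complete genomes each (3 000–10 000 nt, i.i.d.
uniform bases), one short partial-gene fragment per genome (200–400 nt,
titled "partial cds"), one 12 000 nt host genome registered under the
human taxid, two 600 nt vector contaminants, one genome carrying a
full-length spiked vector, and one mostly-host misassembly (3 000 nt host
fragment plus 200 nt of novel sequence) filed under a viral family. Reads
follow a substitution-only error model with uniform starts and strands;
indels and realistic quality profiles are not modelled, and constant 'I'
qualities are written. i.i.d. genomes have no shared ancestry, repeats or
compositional bias, so passing tests demonstrate the decision logic
(thresholds, masking, bookkeeping) rather than sensitivity/specificity on
real viral diversity; k-mer collisions between unrelated synthetic
sequences are vanishingly rare at k = 16, which makes recovery tests
sharper than real data would be.

Test and acceptance problem sizes: ~30-entry databases, 50-chimera
threshold sweeps, 200+ random oracle pairs at k ∈ {3, 5, 16}, 1 200 host
reads and 800 error-free reads per genome (depth ≥ 8× on the largest
genome, enough that the probability of an uncovered k-mer window is
negligible, so every source genome clears the 80% coverage bar).

## Numerical and edge-case choices

* Length bounds round half-to-even via Python `round`; bounds inclusive.
* Coverage of an empty match set is 0.0; the masked fraction of an empty
  index is 0 by convention.
* Blocklist entries match both bare and versioned accessions; unmatched
  entries warn.
* Identical sequences always cluster together even when shorter than k.
* GenBank parsing is tolerant by default (entries missing ORIGIN data or a
  versioned accession are skipped and counted, with a strict mode that
  raises); trailing content after the last `//` is always an error, since
  it indicates a truncated transfer.
* Updates are idempotent at two levels: an unchanged remote yields empty
  plans, and re-applying an already-applied plan is a no-op (no version
  bump). Accessions already in the membership or the archive are never
  re-fetched.

## Known limitations

* The classifier is k-mer exact: sequences diverged beyond ~1 mismatch per
  k bases lose most matches, so sensitivity to distant homologs is limited
  by design (protein-level search is out of scope).
* Contamination screening removes whole entries; partial masking of a
  contaminated region is not attempted.
* The fixture fetcher's query matcher is not a Boolean query engine; live
  NCBI behaviour is untested.
* Whole-index JSON serialization is simple and lossless but not
  space-efficient for large databases.
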