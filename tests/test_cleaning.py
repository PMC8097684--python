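import random

import pytest

from _oracles import oracle_coverage
from virdb.cleaning import (
    apply_blocklist,
    clean_pipeline,
    cluster_greedy,
    dedup_exact,
    load_blocklist,
    screen_contamination,
)
from virdb.records import SequenceRecord
from virdb.simulate import make_chimera, random_genome

THRESHOLDS = [0.5, 0.6, 0.75, 0.95]


def _rec(acc, seq, **kw):
    return SequenceRecord(accession=acc, sequence=seq, **kw)


class TestBlocklist:
    def test_bare_entry_matches_versioned_accession(self):
        records = [_rec("MF468140.1", "ACGT" * 10), _rec("OK000001.1", "AAAA")]
        kept, report = apply_blocklist(records, ["MF468140"])
        assert [r.accession for r in kept] == ["OK000001.1"]
        assert report.removals[0].reason == "blocklist"

    def test_empty_blocklist_keeps_all(self):
        records = [_rec("A.1", "ACGT")]
        kept, report = apply_blocklist(records, [])
        assert kept == records and report.removals == []

    def test_unmatched_entry_keeps_all(self, caplog):
        records = [_rec("A.1", "ACGT")]
        with caplog.at_level("WARNING"):
            kept, _ = apply_blocklist(records, ["NOPE"])
        assert kept == records
        assert "NOPE" in caplog.text

    def test_load_blocklist_comments(self, tmp_path):
        path = tmp_path / "block.txt"
        path.write_text("# known bad\nMF468140\nKX689266.1  # misassembly\n\n")
        assert load_blocklist(path) == ["MF468140", "KX689266.1"]


class TestContaminationScreen:
    def test_full_vector_insert_removed(self):
        vector = random_genome(60, 1)
        genome = random_genome(500, 2)
        records = [_rec("CHM.1", make_chimera(genome, vector, 250))]
        kept, report = screen_contamination(records, [("vec", vector)], threshold=0.5)
        assert kept == []
        (removal,) = report.removals
        assert removal.reason == "contamination"
        assert removal.contaminant == "vec"
        assert removal.coverage == pytest.approx(1.0)

    def test_disjoint_record_kept_at_every_threshold(self):
        clean = _rec("OK.1", random_genome(400, 3))
        vector = random_genome(100, 4)
        for threshold in THRESHOLDS:
            kept, _ = screen_contamination([clean], [("vec", vector)], threshold=threshold)
            assert kept == [clean]

    def test_half_contaminant_flips_between_50_and_60(self):
        vector = random_genome(600, 5)
        genome = random_genome(1000, 6)
        chimera = _rec("CHM.1", make_chimera(genome, vector[:300], 500))
        cov = oracle_coverage(chimera.sequence, vector, 16)
        assert cov == pytest.approx(0.5)
        removed_at = {
            t: not screen_contamination([chimera], [("vec", vector)], threshold=t)[0]
            for t in THRESHOLDS
        }
        assert removed_at == {0.5: True, 0.6: False, 0.75: False, 0.95: False}

    def test_removal_monotone_in_threshold(self):
        rng = random.Random(7)
        vector = random_genome(600, 8)
        records = []
        for i in range(30):
            genome = random_genome(800, 100 + i)
            fraction = rng.uniform(0.1, 1.0)
            piece = vector[: int(len(vector) * fraction)]
            records.append(_rec(f"CHM{i:03d}.1", make_chimera(genome, piece, 400)))
        removed_counts = [
            len(screen_contamination(records, [("vec", vector)], threshold=t)[1].removals)
            for t in THRESHOLDS
        ]
        assert removed_counts == sorted(removed_counts, reverse=True)

    def test_empty_contamination_database_keeps_all(self, caplog):
        records = [_rec("A.1", random_genome(100, 9))]
        with caplog.at_level("WARNING"):
            kept, _ = screen_contamination(records, [], threshold=0.5)
        assert kept == records

    def test_protein_records_pass_through(self):
        prot = SequenceRecord(accession="P.1", sequence="MKV" * 30, moltype="protein")
        kept, _ = screen_contamination([prot], [("vec", random_genome(100, 10))])
        assert kept == [prot]

    def test_short_contaminant_ignored(self):
        records = [_rec("A.1", "ACGTACGTACGTACGTACGT")]
        kept, _ = screen_contamination(records, [("tiny", "ACGTA")], threshold=0.5, k=16)
        assert kept == records


class TestDedup:
    def test_later_duplicates_removed(self):
        records = [_rec("X.1", "ACGT"), _rec("Y.1", "acgt"), _rec("Z.1", "ACGG")]
        kept, report = dedup_exact(records)
        assert [r.accession for r in kept] == ["X.1", "Z.1"]
        (removal,) = report.removals
        assert removal.accession == "Y.1" and removal.retained == "X.1"
        assert removal.reason == "duplicate"

    def test_all_distinct_unchanged(self):
        records = [_rec(f"R{i}.1", random_genome(50, i)) for i in range(5)]
        kept, report = dedup_exact(records)
        assert kept == records and report.removals == []

    def test_idempotent(self):
        records = [_rec("X.1", "ACGT"), _rec("Y.1", "ACGT")]
        once, _ = dedup_exact(records)
        twice, report = dedup_exact(once)
        assert twice == once and report.removals == []

    def test_reverse_complement_not_a_duplicate(self):
        # forward-strand-only semantics: revcomp duplicates are left alone
        records = [_rec("X.1", "AACCGGTA"), _rec("Y.1", "TACCGGTT")]
        kept, _ = dedup_exact(records)
        assert len(kept) == 2


class TestClustering:
    def test_threshold_one_all_distinct_records_own_centroids(self):
        records = [_rec(f"R{i}.1", random_genome(100, 50 + i)) for i in range(4)]
        centroids, membership, _ = cluster_greedy(records, 1.0)
        assert len(centroids) == 4
        assert all(membership[r.accession] == r.accession for r in records)

    def test_identical_sequences_single_centroid(self):
        seq = random_genome(80, 60)
        for threshold in [0.0, 0.5, 1.0]:
            centroids, membership, _ = cluster_greedy(
                [_rec("A.1", seq), _rec("B.1", seq)], threshold
            )
            assert len(centroids) == 1
            assert membership["B.1"] == membership["A.1"]

    def test_threshold_zero_single_centroid_longest(self):
        records = [_rec("S.1", random_genome(50, 61)), _rec("L.1", random_genome(200, 62))]
        centroids, _, _ = cluster_greedy(records, 0.0)
        assert [c.accession for c in centroids] == ["L.1"]

    def test_subsequence_joins_centroid(self):
        genome = random_genome(400, 63)
        records = [_rec("L.1", genome), _rec("S.1", genome[100:200])]
        centroids, membership, _ = cluster_greedy(records, 0.9)
        assert [c.accession for c in centroids] == ["L.1"]
        assert membership["S.1"] == "L.1"


class TestPipeline:
    def test_stage_order_and_partition(self, community):
        vector = community.vectors[0]
        records = [
            community.genomes[0],
            community.vector_chimera,
            _rec("DUP.1", community.genomes[0].sequence),
            _rec("BAD.1", random_genome(100, 70)),
        ]
        kept, report = clean_pipeline(
            records, blocklist=["BAD"], contaminants=community.vectors, threshold=0.5
        )
        reasons = {r.accession: r.reason for r in report.removals}
        assert reasons == {
            "BAD.1": "blocklist",
            community.vector_chimera.accession: "contamination",
            "DUP.1": "duplicate",
        }
        assert [r.accession for r in kept] == [community.genomes[0].accession]

    def test_clean_genome_never_removed(self, community):
        clean = community.genomes[1]
        for threshold in THRESHOLDS:
            kept, _ = clean_pipeline(
                [clean], contaminants=community.vectors, threshold=threshold
            )
            assert kept == [clean]
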