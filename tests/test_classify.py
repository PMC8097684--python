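import pytest

from virdb.classify import (
    TemplateInfo,
    assign_read,
    call_hits,
    classify_run,
    compose,
    template_metadata,
)
from virdb.kmers import build_index, mask_kmers
from virdb.simulate import mock_community, random_genome, simulate_reads, write_fastq


class TestAssignRead:
    def test_exact_submatch_full_identity(self):
        idx = build_index([("R1", "A" * 10)], k=3)
        a = assign_read("AAAA", idx)
        assert a.template == "R1" and (a.matched, a.total) == (2, 2)
        assert a.identity == 1.0

    def test_no_shared_kmers_unassigned(self):
        idx = build_index([("R1", "A" * 10)], k=3)
        a = assign_read("CCCC", idx)  # canonical CCC -> GGG... still not AAA
        assert not a.assigned and a.total == 2

    def test_tie_broken_by_accession(self):
        seq = random_genome(60, 1)
        idx = build_index([("B.1", seq), ("A.1", seq)], k=16)
        a = assign_read(seq[10:40], idx)
        assert a.template == "A.1" and a.tie

    def test_read_shorter_than_k_unassigned(self):
        idx = build_index([("R1", random_genome(50, 2))], k=16)
        a = assign_read("ACGTACGT", idx)
        assert not a.assigned and a.total == 0

    def test_reads_land_on_source_template(self):
        genomes = [(f"G{i}.1", random_genome(500, 10 + i)) for i in range(4)]
        idx = build_index(genomes, k=16)
        for gid, seq in genomes:
            for read in simulate_reads(seq, 20, 80, seed=3, genome_id=gid):
                assert assign_read(read.sequence, idx).template == gid


class TestCallHits:
    def test_full_tiling_passes(self):
        seq = random_genome(500, 20)
        idx = build_index([("T.1", seq)], k=16)
        reads = [seq[i : i + 50] for i in range(0, 500 - 50 + 1, 25)]
        assignments = [assign_read(r, idx) for r in reads]
        (hit,) = call_hits(assignments, idx, min_coverage=0.8)
        assert hit.coverage == pytest.approx(1.0)
        assert hit.identity == pytest.approx(1.0)
        assert hit.passed

    def test_half_coverage_fails_at_80(self):
        seq = random_genome(600, 21)
        idx = build_index([("T.1", seq)], k=16)
        half = seq[:300]
        reads = [half[i : i + 60] for i in range(0, 300 - 60 + 1, 20)]
        assignments = [assign_read(r, idx) for r in reads]
        (hit,) = call_hits(assignments, idx, min_coverage=0.8)
        # distinct kmers of the first half over the whole template
        expected = (300 - 15) / (600 - 15)
        assert hit.coverage == pytest.approx(expected, abs=0.01)
        assert not hit.passed

    def test_zero_assignments_empty(self):
        idx = build_index([("T.1", random_genome(100, 22))], k=16)
        assert call_hits([], idx) == []

    def test_sorted_by_read_count(self):
        a, b = random_genome(300, 23), random_genome(300, 24)
        idx = build_index([("A.1", a), ("B.1", b)], k=16)
        assignments = [assign_read(a[i : i + 50], idx) for i in range(0, 250, 10)]
        assignments += [assign_read(b[:50], idx)]
        hits = call_hits(assignments, idx)
        assert [h.template for h in hits] == ["A.1", "B.1"]


class TestCompose:
    def test_family_fractions(self):
        meta = {"X.1": TemplateInfo(subdb="X"), "Y.1": TemplateInfo(subdb="Y")}
        idx = build_index([("X.1", random_genome(100, 25)), ("Y.1", random_genome(100, 26))], k=16)
        assignments = [assign_read(random_genome(100, 25)[:40], idx) for _ in range(4)]
        from virdb.classify import ReadAssignment

        assignments = [ReadAssignment("r", "X.1", 1, 1)] * 8 + [
            ReadAssignment("r", "Y.1", 1, 1)
        ] * 2
        report = compose(assignments, meta, level="family")
        assert report.fractions == {"X": 0.8, "Y": 0.2}
        assert abs(sum(report.fractions.values()) - 1.0) < 1e-9

    def test_all_unassigned(self):
        from virdb.classify import ReadAssignment

        assignments = [ReadAssignment("r", None, 0, 0)] * 5
        report = compose(assignments, {}, level="family")
        assert report.fractions == {} and report.unassigned == 5

    def test_missing_template_metadata_errors(self):
        from virdb.classify import ReadAssignment

        with pytest.raises(KeyError, match="GHOST.1"):
            compose([ReadAssignment("r", "GHOST.1", 1, 1)], {}, level="family")

    def test_even_families_near_uniform(self, community):
        genomes = community.genomes
        idx = build_index([(g.accession, g.sequence) for g in genomes], k=16)
        meta = template_metadata(genomes)
        assignments = []
        for g in genomes:
            for read in simulate_reads(g.sequence, 100, 100, seed=5, genome_id=g.accession):
                assignments.append(assign_read(read.sequence, idx))
        report = compose(assignments, meta, level="family")
        assert set(report.fractions) == set(community.family_names)
        for fraction in report.fractions.values():
            assert fraction == pytest.approx(0.2, abs=0.02)


class TestErrorRateIdentity:
    def test_mean_identity_decreases_with_error_rate(self):
        genome = random_genome(2000, 30)
        idx = build_index([("G.1", genome)], k=16)
        means = []
        for e in [0.0, 0.01, 0.05]:
            reads = simulate_reads(genome, 150, 100, error_rate=e, seed=31)
            ids = [assign_read(r.sequence, idx).identity for r in reads]
            means.append(sum(ids) / len(ids))
        assert means[0] > means[1] > means[2]


class TestClassifyRun:
    def test_fasta_verbatim_template_full_coverage(self, built_db, community, tmp_path):
        db_dir, _, _ = built_db
        contig = tmp_path / "contig.fasta"
        genome = community.genomes[2]
        contig.write_text(f">{genome.accession}_contig\n{genome.sequence}\n")
        hits, _ = classify_run(db_dir, contig, tmp_path / "out")
        best = hits[0]
        assert best.template == genome.accession
        assert best.coverage == pytest.approx(1.0)
        assert (tmp_path / "out" / "hits.tsv").exists()

    def test_empty_query_file_warns_not_fails(self, built_db, tmp_path, caplog):
        db_dir, _, _ = built_db
        empty = tmp_path / "empty.fastq"
        empty.write_text("")
        with caplog.at_level("WARNING"):
            hits, compositions = classify_run(db_dir, empty, tmp_path / "out")
        assert hits == []
        assert compositions["family"].fractions == {}

    def test_host_mask_suppresses_false_positive(self, built_db, community, tmp_path):
        db_dir, _, _ = built_db
        host_reads = simulate_reads(
            community.host.sequence, 1200, 100, seed=8, genome_id="host"
        )
        fq = tmp_path / "host.fastq"
        write_fastq(host_reads, fq)
        host_fa = tmp_path / "host.fasta"
        host_fa.write_text(f">host\n{community.host.sequence}\n")
        unmasked_hits, _ = classify_run(db_dir, fq, tmp_path / "raw")
        fp = [h for h in unmasked_hits if h.passed]
        assert any(h.template == community.host_chimera.accession for h in fp)
        masked_hits, _ = classify_run(db_dir, fq, tmp_path / "decon", host_mask=host_fa)
        assert [h for h in masked_hits if h.passed] == []

    def test_masking_never_increases_read_counts(self, built_db, community, tmp_path):
        db_dir, _, _ = built_db
        reads = simulate_reads(community.host.sequence, 300, 100, seed=9, genome_id="host")
        for g in community.genomes[:3]:
            reads += simulate_reads(g.sequence, 50, 100, seed=9, genome_id=g.accession)
        fq = tmp_path / "mix.fastq"
        write_fastq(reads, fq)
        host_fa = tmp_path / "host.fasta"
        host_fa.write_text(f">host\n{community.host.sequence}\n")
        raw_hits, _ = classify_run(db_dir, fq, tmp_path / "raw")
        masked_hits, _ = classify_run(db_dir, fq, tmp_path / "decon", host_mask=host_fa)
        raw_counts = {h.template: h.read_count for h in raw_hits}
        for h in masked_hits:
            assert h.read_count <= raw_counts.get(h.template, 0)
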