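import numpy as np
import pytest

from natseek.genome_io import (
    GenomicInterval,
    TranscriptModel,
    extract_sequence,
    read_expression,
    read_gff3_genes,
    read_gtf_transcripts,
    reverse_complement,
    write_gff3_genes,
    write_gtf_transcripts,
)

from _oracles import random_dna


def _model(tid, scaffold, strand, exon_coords, source="assembled"):
    exons = [GenomicInterval(scaffold, s, e, strand) for s, e in exon_coords]
    iv = GenomicInterval(scaffold, exon_coords[0][0], exon_coords[-1][1], strand)
    return TranscriptModel(tid, iv, exons, source=source)


def _random_models(rng, n, source="assembled"):
    models = []
    for i in range(n):
        scaffold = f"scaf{int(rng.integers(1, 4))}"
        strand = "+-"[int(rng.integers(0, 2))]
        start = int(rng.integers(0, 5000))
        n_exons = int(rng.integers(1, 4))
        coords = []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(50, 400))
            coords.append((pos, pos + length))
            pos += length + int(rng.integers(30, 120))
        models.append(_model(f"m{i}", scaffold, strand, coords, source=source))
    return models


class TestGff3:
    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.gff3"
        path.write_text("##gff-version 3\n")
        assert read_gff3_genes(path) == []

    def test_one_based_closed_converted_to_zero_based_half_open(self, tmp_path):
        path = tmp_path / "one.gff3"
        path.write_text("scaf1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n")
        (gene,) = read_gff3_genes(path)
        assert (gene.interval.start, gene.interval.end, gene.strand) == (100, 200, "+")
        assert len(gene.exons) == 1 and gene.exons[0].start == 100

    def test_roundtrip_multi_exon_models(self, tmp_path):
        rng = np.random.default_rng(0)
        models = _random_models(rng, 30, source="predicted_gene")
        path = tmp_path / "rt.gff3"
        write_gff3_genes(models, path)
        back = read_gff3_genes(path)
        orig = {m.id: [(e.start, e.end) for e in m.exons] for m in models}
        reread = {m.id: [(e.start, e.end) for e in m.exons] for m in back}
        assert orig == reread
        assert all(m.strand == dict((x.id, x.strand) for x in models)[m.id] for m in back)

    def test_duplicate_id_is_hard_error(self, tmp_path):
        path = tmp_path / "dup.gff3"
        path.write_text(
            "scaf1\t.\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "scaf1\t.\tgene\t200\t300\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(Exception):
            read_gff3_genes(path)

    def test_unstranded_gene_rejected_with_warning(self, tmp_path, caplog):
        path = tmp_path / "uns.gff3"
        path.write_text(
            "scaf1\t.\tgene\t1\t100\t.\t.\t.\tID=g1\n"
            "scaf1\t.\tgene\t200\t300\t.\t-\t.\tID=g2\n"
        )
        with caplog.at_level("WARNING", logger="natseek.genome_io"):
            genes = read_gff3_genes(path)
        assert [g.id for g in genes] == ["g2"]
        assert any("no strand" in r.message for r in caplog.records)


class TestGtf:
    def test_exons_grouped_by_transcript_and_sorted(self, tmp_path):
        path = tmp_path / "t.gtf"
        # exons deliberately out of order
        path.write_text(
            'scaf1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
            'scaf1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
        )
        (model,) = read_gtf_transcripts(path)
        assert [(e.start, e.end) for e in model.exons] == [(100, 200), (300, 400)]
        assert model.interval.start == 100 and model.interval.end == 400

    def test_strand_disagreement_is_hard_error(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'scaf1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
            'scaf1\tx\texon\t301\t400\t.\t-\t.\tgene_id "g"; transcript_id "t1";\n'
        )
        with pytest.raises(ValueError, match="strands disagree"):
            read_gtf_transcripts(path)

    def test_roundtrip_random_model_set(self, tmp_path):
        rng = np.random.default_rng(1)
        models = _random_models(rng, 100)
        path = tmp_path / "rt.gtf"
        write_gtf_transcripts(models, path)
        back = read_gtf_transcripts(path)
        orig = {m.id: (m.scaffold, m.strand, tuple((e.start, e.end) for e in m.exons))
                for m in models}
        reread = {m.id: (m.scaffold, m.strand, tuple((e.start, e.end) for e in m.exons))
                  for m in back}
        assert orig == reread


class TestExtractSequence:
    def test_plus_strand_single_exon(self):
        m = _model("t", "s", "+", [(0, 4)])
        assert extract_sequence(m, {"s": "ACGTTT"}) == "ACGT"

    def test_minus_strand_is_reverse_complement(self):
        m = _model("t", "s", "-", [(0, 4)])
        assert extract_sequence(m, {"s": "AAGTTT"}) == "ACTT"

    def test_spliced_minus_strand_matches_string_oracle(self):
        rng = np.random.default_rng(2)
        genome = {"s": random_dna(rng, 600)}
        m = _model("t", "s", "-", [(50, 150), (220, 330)])
        expected = reverse_complement(genome["s"][50:150] + genome["s"][220:330])
        assert extract_sequence(m, genome) == expected

    def test_plus_and_minus_are_exact_reverse_complements(self):
        rng = np.random.default_rng(3)
        genome = {"s": random_dna(rng, 1000)}
        for _ in range(20):
            coords = sorted(map(int, rng.choice(900, 4, replace=False)))
            exons = [(coords[0], coords[1] + 1), (coords[2] + 2, coords[3] + 3)]
            plus = extract_sequence(_model("p", "s", "+", exons), genome)
            minus = extract_sequence(_model("m", "s", "-", exons), genome)
            assert minus == reverse_complement(plus)

    def test_exon_out_of_bounds_is_hard_error(self):
        m = _model("t", "s", "+", [(0, 10)])
        with pytest.raises(ValueError, match="bounds"):
            extract_sequence(m, {"s": "ACGT"})


class TestExpression:
    def test_zero_matrix_is_valid(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("transcript_id\tM\tP\tFB\nt1\t0\t0\t0\nt2\t0\t0\t0\n")
        m = read_expression(path)
        assert m.stages == ["M", "P", "FB"]
        assert m.value("t1", "FB") == 0.0

    def test_values_retrievable_by_id_and_stage(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("transcript_id\tM\tP\tFB\nt1\t5\t2\t0\n")
        m = read_expression(path)
        assert (m.value("t1", "M"), m.value("t1", "P"), m.value("t1", "FB")) == (5, 2, 0)

    def test_write_read_roundtrip(self, tmp_path):
        from natseek.genome_io import ExpressionMatrix, write_expression
        import pandas as pd

        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            rng.uniform(0, 50, (50, 3)),
            index=[f"t{i}" for i in range(50)],
            columns=["M", "P", "FB"],
        )
        path = tmp_path / "e.tsv"
        write_expression(ExpressionMatrix(df), path)
        back = read_expression(path)
        assert np.allclose(back.values.values, df.values, rtol=1e-4)

    @pytest.mark.parametrize(
        "body", ["t1\t-1\t2\t3\n", "t1\t1\t2\t3\nt1\t4\t5\t6\n", "t1\t1\t\t3\n"],
        ids=["negative", "duplicate-row", "missing-cell"],
    )
    def test_malformed_tables_are_hard_errors(self, tmp_path, body):
        path = tmp_path / "e.tsv"
        path.write_text("transcript_id\tM\tP\tFB\n" + body)
        with pytest.raises(ValueError):
            read_expression(path)


class TestInvariants:
    def test_interval_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("s", 10, 10, "+")
        with pytest.raises(ValueError):
            GenomicInterval("s", 0, 10, ".")

    def test_transcript_model_rejects_inconsistent_exons(self):
        iv = GenomicInterval("s", 0, 100, "+")
        with pytest.raises(ValueError, match="span"):
            TranscriptModel("t", iv, [GenomicInterval("s", 10, 90, "+")])
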