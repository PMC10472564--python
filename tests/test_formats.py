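"""I/O contracts: coordinate conventions, round-trips, dialect parsing."""

import numpy as np
import pytest

from exonweave import formats
from exonweave.formats import (
    AlignmentChain,
    FormatError,
    GeneModel,
    GenomeSequence,
    Hint,
    parse_alignments,
    read_fasta,
    read_gene_models,
    read_hints_gff,
    read_training_genbank,
    write_alignments_compact,
    write_fasta,
    write_gene_models,
    write_hints_gff,
    write_training_genbank,
)
from exonweave.training_genes import TrainingGene


# ---------------------------------------------------------------- FASTA


def test_read_fasta_single_record(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">s1\nACGT\n")
    (rec,) = read_fasta(p)
    assert (rec.seq_id, rec.length, rec.residues) == ("s1", 4, "ACGT")


def test_read_fasta_folds_case_and_keeps_mask(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">s1\nacgT\n")
    (rec,) = read_fasta(p)
    assert rec.residues == "ACGT"
    assert rec.mask.tolist() == [True, True, True, False]
    # mask restored on write
    out = tmp_path / "b.fa"
    write_fasta([rec], out)
    assert "acgT" in out.read_text()


@pytest.mark.parametrize(
    "content,msg",
    [(">a\nAC\n>a\nGG\n", "duplicate seq_id a"), (">a\nAC\n>b\n", "empty sequence")],
)
def test_read_fasta_errors(tmp_path, content, msg):
    p = tmp_path / "bad.fa"
    p.write_text(content)
    with pytest.raises(FormatError, match=msg):
        read_fasta(p)


# ---------------------------------------------------------- gene models


def test_gtf_coordinates_become_half_open(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(
        's1\tx\tCDS\t101\t200\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
    )
    (m,) = read_gene_models(p, "gtf")
    assert m.cds_exons == [(100, 200)]


def test_multi_cds_lines_grouped_and_sorted(tmp_path):
    p = tmp_path / "a.gtf"
    lines = [
        f's1\tx\tCDS\t{a}\t{b}\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
        for a, b in [(501, 600), (101, 200), (301, 400)]
    ]
    p.write_text("".join(lines))
    (m,) = read_gene_models(p, "gtf")
    assert m.cds_exons == [(100, 200), (300, 400), (500, 600)]


def test_mixed_strands_rejected(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(
        's1\tx\tCDS\t101\t200\t.\t+\t0\tgene_id "g"; transcript_id "t";\n'
        's1\tx\tCDS\t301\t400\t.\t-\t0\tgene_id "g"; transcript_id "t";\n'
    )
    with pytest.raises(FormatError, match="mixed strands"):
        read_gene_models(p, "gtf")


def test_stop_codon_merged_into_terminal_cds(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(
        's1\tx\tCDS\t101\t200\t.\t+\t0\tgene_id "g"; transcript_id "t";\n'
        's1\tx\tstop_codon\t201\t203\t.\t+\t0\tgene_id "g"; transcript_id "t";\n'
        's1\tx\tstart_codon\t101\t103\t.\t+\t0\tgene_id "g"; transcript_id "t";\n'
    )
    (m,) = read_gene_models(p, "gtf")
    assert m.cds_exons == [(100, 203)]
    assert m.completeness == "complete"


def test_codon_features_drive_completeness(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(
        's1\tx\tCDS\t101\t200\t.\t+\t0\tgene_id "g"; transcript_id "t1";\n'
        's1\tx\tstart_codon\t101\t103\t.\t+\t0\tgene_id "g"; transcript_id "t1";\n'
        's1\tx\tCDS\t301\t400\t.\t+\t0\tgene_id "g2"; transcript_id "t2";\n'
    )
    models = {m.transcript_id: m for m in read_gene_models(p, "gtf")}
    assert models["t1"].completeness == "missing_stop"
    assert models["t2"].completeness == "missing_both"


@pytest.mark.parametrize("dialect", ["gff3", "gtf"])
def test_gene_model_round_trip(tmp_path, dialect):
    models = [
        GeneModel("gA", "tA1", "s1", "+", [(100, 250), (400, 550)]),
        GeneModel("gA", "tA2", "s1", "+", [(100, 250), (480, 550)]),
        GeneModel("gB", "tB1", "s1", "-", [(1000, 1150)], completeness="missing_start"),
        GeneModel("gC", "tC1", "s2", "-", [(10, 70), (200, 380), (500, 620)]),
    ]
    path = tmp_path / f"m.{dialect}"
    write_gene_models(models, path, dialect)
    back = read_gene_models(path, dialect)
    key = lambda m: (m.transcript_id,)
    for orig, rt in zip(sorted(models, key=key), sorted(back, key=key)):
        assert (
            orig.gene_id,
            orig.transcript_id,
            orig.seq_id,
            orig.strand,
            orig.cds_exons,
            orig.completeness,
        ) == (rt.gene_id, rt.transcript_id, rt.seq_id, rt.strand, rt.cds_exons, rt.completeness)


# ------------------------------------------------------------ alignments


def test_compact_two_block_chain_yields_one_intron(tmp_path):
    p = tmp_path / "a.aln"
    p.write_text(
        "chain\tp1\ts1\t+\t50\t1\t20\t20\n"
        "block\t901\t1000\tM30S2M1\t.\n"
        "block\t1101\t1130\tM10\t.\n"
    )
    (c,) = parse_alignments(p, "compact")
    assert c.intron_intervals == [(1000, 1100)]
    assert c.block_summaries[0].identical == 31
    assert c.block_summaries[0].positive == 2


def test_compact_runstring_decoding_counts():
    cols = formats._decode_runstring("M10S2M8")
    assert cols.count(formats.IDENTICAL) == 18
    assert cols.count(formats.SUBSTITUTION) == 2


def test_compact_event_positions(tmp_path):
    p = tmp_path / "a.aln"
    p.write_text(
        "chain\tp1\ts1\t+\t50\t.\t.\t.\n" "block\t1201\t1260\tM20\t*@1234,F@1240\n"
    )
    (c,) = parse_alignments(p, "compact")
    assert c.inframe_stops == [1233]  # 1-based on disk, 0-based internally
    assert c.frameshifts == [1239]


def test_out_of_order_blocks_rejected_with_warning(tmp_path, caplog):
    p = tmp_path / "a.aln"
    p.write_text(
        "chain\tbad\ts1\t+\t5\t.\t.\t.\n"
        "block\t1101\t1130\tM10\t.\n"
        "block\t901\t1000\tM30\t.\n"
        "chain\tgood\ts1\t+\t5\t.\t.\t.\n"
        "block\t901\t1000\tM30\t.\n"
    )
    chains = parse_alignments(p, "compact")
    assert [c.protein_id for c in chains] == ["good"]


def test_compact_round_trip(tiny_fixture, tmp_path):
    path = tmp_path / "rt.aln"
    write_alignments_compact(tiny_fixture.chains, path)
    back = parse_alignments(path, "compact")
    assert len(back) == len(tiny_fixture.chains)
    for a, b in zip(tiny_fixture.chains, back):
        assert a.blocks == b.blocks
        assert a.frameshifts == b.frameshifts and a.inframe_stops == b.inframe_stops
        assert a.junctions == b.junctions
        assert a.identity == pytest.approx(b.identity)


def test_aligner_gff_chains_lack_residue_detail(tmp_path):
    p = tmp_path / "a.gff"
    p.write_text(
        "##gff-version 3\n"
        "s1\taln\tmRNA\t901\t1130\t77\t+\t.\tID=c1;Target=p1 1 40 40;Identity=0.95\n"
        "s1\taln\tCDS\t901\t1000\t50\t+\t0\tParent=c1\n"
        "s1\taln\tCDS\t1101\t1130\t27\t+\t0\tParent=c1\n"
    )
    (c,) = parse_alignments(p, "miniprot_gff")
    assert c.junctions is None
    assert c.intron_intervals == [(1000, 1100)]
    assert c.identity == pytest.approx(0.95)
    assert c.covers_protein_start


# ----------------------------------------------------------------- hints


def test_hints_gff_column9_contract(tmp_path):
    h = Hint("s1", "intron", 1000, 1100, "+", 0.91, 3, "high")
    path = tmp_path / "h.gff"
    write_hints_gff([h], path)
    data_lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert data_lines == ["s1\texonweave\tintron\t1001\t1100\t0.91\t+\t.\tsrc=M;mult=3;pri=4"]


def test_low_confidence_hint_gets_src_p(tmp_path):
    h = Hint("s1", "CDSpart", 10, 50, "-", 0.5, 1, "low")
    path = tmp_path / "h.gff"
    write_hints_gff([h], path)
    assert "src=P;mult=1;pri=4" in path.read_text()


def test_empty_hint_list_writes_header_only(tmp_path):
    path = tmp_path / "h.gff"
    write_hints_gff([], path)
    assert path.read_text().startswith("#")
    assert read_hints_gff(path) == []


def test_hints_round_trip_bit_exact(tmp_path):
    hints = [
        Hint("s2", "intron", 500, 700, "-", 0.25, 2, "high"),
        Hint("s1", "CDSpart", 9, 91, "+", 0.8, 1, "low"),
        Hint("s1", "start", 0, 3, "+", 1.0, 1, "low"),
        Hint("s1", "stop", 97, 100, "+", 1.0, 1, "low"),
    ]
    p1, p2 = tmp_path / "a.gff", tmp_path / "b.gff"
    write_hints_gff(hints, p1)
    back = read_hints_gff(p1)
    assert sorted(back, key=lambda h: (h.seq_id, h.start, h.end, h.feature)) == sorted(
        hints, key=lambda h: (h.seq_id, h.start, h.end, h.feature)
    )
    write_hints_gff(back, p2)
    assert p1.read_text() == p2.read_text()


# --------------------------------------------------------------- GenBank


def _training_gene(model, window):
    g = TrainingGene(source="alignment", model=model, score=1.0)
    g.excised_window = window
    return g


def test_genbank_window_and_local_coordinates(tmp_path):
    seq = GenomeSequence("s1", "A" * 1000)
    m = GeneModel("g1", "t1", "s1", "+", [(100, 250), (300, 400)])
    gb = tmp_path / "t.gb"
    write_training_genbank([_training_gene(m, (50, 450))], [seq], gb)
    text = gb.read_text()
    assert "400 bp" in text  # excised length 450-50
    assert "join(51..200,251..350)" in text
    (back,) = read_training_genbank(gb)
    assert back.cds_exons == [(50, 200), (250, 350)]


def test_genbank_minus_strand_uses_complement_join(tmp_path):
    seq = GenomeSequence("s1", "ACGT" * 300)
    m = GeneModel("g1", "t1", "s1", "-", [(100, 220), (400, 520)])
    gb = tmp_path / "t.gb"
    write_training_genbank([_training_gene(m, (0, 600))], [seq], gb)
    assert "complement(join(" in gb.read_text()


def test_genbank_window_clamped_to_sequence(tmp_path, caplog):
    seq = GenomeSequence("s1", "ACGT" * 100)
    m = GeneModel("g1", "t1", "s1", "+", [(10, 70)])
    gb = tmp_path / "t.gb"
    with caplog.at_level("WARNING"):
        write_training_genbank([_training_gene(m, (-40, 120))], [seq], gb)
    assert any("clamp" in r.message for r in caplog.records)
    assert "120 bp" in gb.read_text()  # clamped to [0, 120)
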