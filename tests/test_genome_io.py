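"""GenBank / FASTA+GFF ingestion and coordinate conventions."""

import pytest

from cbestop.genome_io import (
    CdsFeature,
    GenomeIOError,
    GenomeRecord,
    extract_cds,
    read_fasta,
    read_fasta_gff,
    read_genbank,
    write_fasta,
)

def _locus_line(name, length):
    # canonical column layout: name+length span columns 12..40
    return "LOCUS       " + name + str(length).rjust(28 - len(name)) + \
        " bp    DNA     linear   BCT 01-JAN-2024\n"


GENBANK_HEADER = """DEFINITION  synthetic test record.
ACCESSION   testlocus
VERSION     testlocus
FEATURES             Location/Qualifiers
"""


def _genbank(tmp_path, seq, feature_lines):
    text = _locus_line("testlocus", len(seq)) + GENBANK_HEADER
    text += feature_lines
    text += "ORIGIN\n"
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        text += f"{i + 1:>9} {blocks}\n"
    text += "//\n"
    path = tmp_path / "test.gbk"
    path.write_text(text)
    return path


def test_read_genbank_plus_strand_cds(tmp_path):
    """1-based inclusive 1..9 becomes 0-based half-open [0, 9) on +."""
    path = _genbank(
        tmp_path,
        "ATGCAGTAAGGG",
        "     CDS             1..9\n                     /locus_tag=\"geneA\"\n",
    )
    genomes, features = read_genbank(path)
    assert len(genomes) == 1 and genomes[0].seq == "ATGCAGTAAGGG"
    (f,) = features
    assert (f.gene_id, f.start, f.end, f.strand, f.partial) == ("geneA", 0, 9, "+", False)


def test_read_genbank_complement_cds(tmp_path):
    """complement(4..12) becomes [3, 12) on the minus strand."""
    path = _genbank(
        tmp_path,
        "AAATTACTGCATAAA",
        "     CDS             complement(4..12)\n                     /locus_tag=\"geneB\"\n",
    )
    _, features = read_genbank(path)
    (f,) = features
    assert (f.start, f.end, f.strand) == (3, 12, "-")


def test_read_genbank_length_not_multiple_of_three_flagged_partial(tmp_path):
    path = _genbank(
        tmp_path,
        "ATGCAGTAAGGG",
        "     CDS             1..10\n                     /locus_tag=\"geneC\"\n",
    )
    with pytest.warns(UserWarning, match="not divisible by 3"):
        _, features = read_genbank(path)
    assert features[0].partial is True


def test_read_genbank_cds_without_identifier_skipped(tmp_path):
    path = _genbank(
        tmp_path,
        "ATGCAGTAAGGG",
        "     CDS             1..9\n                     /product=\"anonymous\"\n",
    )
    with pytest.warns(UserWarning, match="skipped"):
        _, features = read_genbank(path)
    assert features == []


def test_read_genbank_unreadable_file_fatal(tmp_path):
    path = tmp_path / "broken.gbk"
    path.write_text("this is not a genbank file\n")
    with pytest.raises(GenomeIOError):
        read_genbank(path)


def test_read_fasta_gff_coordinates(tmp_path):
    """GFF 1-based row 7..15 becomes [6, 15)."""
    fasta = tmp_path / "g.fasta"
    fasta.write_text(">contig1\n" + "ATGCAGTAA" * 4 + "\n")
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "contig1\tsrc\tCDS\t7\t15\t.\t+\t0\tID=cds1;locus_tag=geneD\n"
    )
    genomes, features = read_fasta_gff(fasta, gff)
    (f,) = features
    assert (f.gene_id, f.start, f.end, f.strand, f.partial) == ("geneD", 6, 15, "+", False)


def test_read_fasta_gff_empty_gff(tmp_path):
    fasta = tmp_path / "g.fasta"
    fasta.write_text(">contig1\nATGCAGTAA\n")
    gff = tmp_path / "empty.gff3"
    gff.write_text("##gff-version 3\n")
    _, features = read_fasta_gff(fasta, gff)
    assert features == []


def test_read_fasta_gff_multipart_cds_flagged_partial(tmp_path):
    fasta = tmp_path / "g.fasta"
    fasta.write_text(">contig1\n" + "ATGCAGTAA" * 5 + "\n")
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "contig1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=cds2;locus_tag=geneE\n"
        "contig1\tsrc\tCDS\t19\t27\t.\t+\t0\tID=cds2;locus_tag=geneE\n"
    )
    _, features = read_fasta_gff(fasta, gff)
    (f,) = features
    assert f.partial is True
    assert (f.start, f.end) == (0, 27)


def test_read_fasta_gff_unknown_seqid_fatal(tmp_path):
    fasta = tmp_path / "g.fasta"
    fasta.write_text(">contig1\nATGCAGTAA\n")
    gff = tmp_path / "g.gff3"
    gff.write_text("##gff-version 3\nother\tsrc\tCDS\t1\t9\t.\t+\t0\tID=x;locus_tag=g\n")
    with pytest.raises(GenomeIOError, match="not present in FASTA"):
        read_fasta_gff(fasta, gff)


def test_lowercase_and_ambiguity_cleaning(tmp_path):
    fasta = tmp_path / "g.fasta"
    fasta.write_text(">c\natgcRgtaa\n")
    with pytest.warns(UserWarning, match="converted to N"):
        (g,) = read_fasta(fasta)
    assert g.seq == "ATGCNGTAA"


@pytest.mark.parametrize(
    "seq, strand, expected",
    [
        ("ATGCAGTGA", "+", "ATGCAGTGA"),
        ("TCACTGCAT", "-", "ATGCAGTGA"),
    ],
)
def test_extract_cds(seq, strand, expected):
    genome = GenomeRecord("c", seq)
    cds = CdsFeature("g", "c", 0, 9, strand)
    assert extract_cds(genome, cds) == expected


def test_extract_cds_out_of_bounds():
    genome = GenomeRecord("c", "ATGCAGTGA")
    with pytest.raises(GenomeIOError):
        extract_cds(genome, CdsFeature("g", "c", 0, 12, "+", partial=True))


def test_fasta_round_trip(tmp_path):
    genome = GenomeRecord("roundtrip", "ACGTN" * 100)
    path = tmp_path / "rt.fasta"
    write_fasta([genome], path)
    (back,) = read_fasta(path)
    assert back.seq == genome.seq and back.contig_id == genome.contig_id


def test_extract_cds_length_and_strand_symmetry(planted_genome):
    """extract length equals end-start; minus-strand extraction is the
    reverse complement of the plus-strand slice."""
    from cbestop.scanner import revcomp

    genome, cds_list, _ = planted_genome
    for cds in cds_list:
        s = extract_cds(genome, cds)
        assert len(s) == cds.end - cds.start
        plus = genome.seq[cds.start : cds.end]
        assert s == (plus if cds.strand == "+" else revcomp(plus))
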