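import warnings

import pytest
from hypothesis import given, settings, strategies as st

from gatafam.genome_io import (GeneModel, ParseError, SequenceRecord,
                               StructuralError, TranscriptModel,
                               TranslationError, extract_cds, read_fasta,
                               read_gff3, translate_ambiguous, write_fasta,
                               write_gff3)
from _oracles import oracle_codon_sets

NT = "ACGT"
AMBIG = "RYSWKMBDHVN"


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">g1\nATGC\n")
        recs = read_fasta(p)
        assert [(r.id, r.seq) for r in recs] == [("g1", "ATGC")]

    def test_line_folding_and_order(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nAT\nGC\n>b\nTTT\n")
        recs = read_fasta(p)
        assert [(r.id, r.seq) for r in recs] == [("a", "ATGC"), ("b", "TTT")]

    def test_iupac_ambiguity_accepted(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nAKGTRY\n")
        assert read_fasta(p)[0].seq == "AKGTRY"

    def test_illegal_character_names_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">bad\nAT!C\n")
        with pytest.raises(ParseError, match="bad"):
            read_fasta(p)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(
        st.tuples(st.from_regex(r"[A-Za-z0-9_]{1,10}", fullmatch=True),
                  st.text(alphabet=NT + AMBIG, min_size=1, max_size=200)),
        min_size=1, max_size=5, unique_by=lambda t: t[0]))
    def test_round_trip(self, tmp_path_factory, records):
        p = tmp_path_factory.mktemp("fa") / "r.fa"
        recs = [SequenceRecord(i, s) for i, s in records]
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.seq) for r in back] == \
            [(r.id, r.seq) for r in recs]


GFF = """##gff-version 3
chr1\tsrc\tgene\t1\t500\t.\t{strand}\t.\tID=g1;ortholog=GATA9
chr1\tsrc\tmRNA\t1\t500\t.\t{strand}\t.\tID=g1.a;Parent=g1;isoform=a
chr1\tsrc\texon\t1\t100\t.\t{strand}\t.\tParent=g1.a
chr1\tsrc\texon\t201\t500\t.\t{strand}\t.\tParent=g1.a
chr1\tsrc\tCDS\t201\t440\t.\t{strand}\t0\tParent=g1.a
"""


class TestGff3:
    def test_utr_lengths_plus_strand(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF.format(strand="+"))
        g = read_gff3(p)[0]
        tx = g.transcripts[0]
        # exon1 (100) entirely 5'UTR; exon2 pre-CDS part absent here
        assert (tx.utr5_len, tx.utr3_len, tx.cds_len) == (100, 60, 240)
        assert g.ortholog_key == "GATA9"

    def test_utr_lengths_minus_strand(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF.format(strand="-"))
        tx = read_gff3(p)[0].transcripts[0]
        # 5'UTR now measured from the high-coordinate end
        assert (tx.utr5_len, tx.utr3_len) == (60, 100)

    def test_orphan_mrna_is_structural_error(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("##gff-version 3\n"
                     "chr1\ts\tmRNA\t1\t10\t.\t+\t.\tID=m1;Parent=nope\n"
                     "chr1\ts\texon\t1\t10\t.\t+\t.\tParent=m1\n")
        with pytest.raises(StructuralError, match="m1"):
            read_gff3(p)

    def test_cds_outside_exon_rejected(self):
        with pytest.raises(StructuralError, match="outside exon"):
            TranscriptModel("t", "a", [(1, 100)], [(50, 150)])

    def test_round_trip(self, tmp_path, panel):
        genes = panel.genes["Col0"][:5]
        p = tmp_path / "rt.gff3"
        write_gff3(genes, p)
        back = read_gff3(p)
        orig = sorted(genes, key=lambda g: (g.chromosome, g.start))
        assert len(back) == len(orig)
        for a, b in zip(orig, back):
            assert (a.gene_id, a.ortholog_key, a.strand) == \
                (b.gene_id, b.ortholog_key, b.strand)
            for ta, tb in zip(a.transcripts, b.transcripts):
                assert ta.exons == tb.exons and ta.cds == tb.cds
                assert ta.isoform_label == tb.isoform_label


class TestExtractCds:
    def test_plus_strand(self):
        tx = TranscriptModel("t", "a", [(1, 9)], [(4, 6)], "+")
        assert extract_cds(tx, SequenceRecord("g", "AAAATGCCC")) == "ATG"

    def test_minus_strand_revcomp(self):
        tx = TranscriptModel("t", "a", [(1, 9)], [(4, 6)], "-")
        assert extract_cds(tx, SequenceRecord("g", "AAACATCCC")) == "ATG"

    def test_ambiguity_preserved(self):
        tx = TranscriptModel("t", "a", [(1, 6)], [(1, 3)], "+")
        assert extract_cds(tx, SequenceRecord("g", "KGTAAA")) == "KGT"

    def test_out_of_bounds(self):
        tx = TranscriptModel("t", "a", [(1, 30)], [(10, 30)], "+")
        with pytest.raises(ValueError, match="outside genome"):
            extract_cds(tx, SequenceRecord("g", "AAAAA"))


class TestTranslateAmbiguous:
    @pytest.mark.parametrize("codon,expected,het", [
        ("KGT", {"C", "G"}, True),     # heterozygous C/G
        ("GGM", {"G"}, False),         # silent ambiguity
        ("TTY", {"F"}, False),
        ("ACY", {"T"}, False),
        ("AAY", {"N"}, False),
        ("ATG", {"M"}, False),
    ])
    def test_known_codons(self, codon, expected, het):
        (state,) = translate_ambiguous(codon)
        assert state.amino_set == frozenset(expected)
        assert state.heterozygous is het

    def test_matches_bruteforce_over_all_two_ambiguous_codons(self):
        import itertools
        bases = "ACGT" + AMBIG
        checked = 0
        for codon in itertools.product(bases, repeat=3):
            codon = "".join(codon)
            n_amb = sum(c in AMBIG for c in codon)
            if n_amb > 2:
                continue
            aminos, stops = oracle_codon_sets(codon)
            if stops and aminos:
                with pytest.raises(TranslationError):
                    translate_ambiguous("ATG" + codon + "TAA")
            elif stops:
                assert translate_ambiguous(codon) == []
            else:
                (state,) = translate_ambiguous(codon)
                assert state.amino_set == frozenset(aminos), codon
            checked += 1
        assert checked == 2044   # 4^3 + 3*16*11 + 3*4*121

    def test_unambiguous_equals_standard_translation(self):
        import numpy as np
        from Bio.Seq import Seq
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 40))
            cds = "".join(rng.choice(list("ACGT"), size=3 * n))
            ref = str(Seq(cds).translate(to_stop=True))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                states = translate_ambiguous(cds)
            assert "".join(s.consensus for s in states) == ref

    def test_internal_stop_warns_and_truncates(self):
        with pytest.warns(UserWarning, match="internal stop"):
            states = translate_ambiguous("ATGTAAATG")
        assert len(states) == 1

    def test_three_ambiguous_positions_rejected(self):
        with pytest.raises(TranslationError, match="ambiguous positions"):
            translate_ambiguous("NNN")

    def test_length_not_multiple_of_three(self):
        with pytest.raises(TranslationError):
            translate_ambiguous("ATGA")
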