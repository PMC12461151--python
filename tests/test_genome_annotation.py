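"""Genome access, canonical selection and mature-transcript assembly."""

import pytest

from splice2nmd.genome_annotation import (
    AnnotationError,
    GenomeSequence,
    TranscriptModel,
    assemble_mature,
    load_canonical_annotation,
)

from conftest import TOY_CHROM, TOY_EXON1, TOY_EXON2, TOY_EXON3, toy_exon_intervals

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_rc(s):
    # independent per-base reverse complement used as the oracle here
    return "".join(COMP[b] for b in reversed(s))


class TestGenomeSequence:
    def test_fetch_plus(self):
        g = GenomeSequence({"chr1": "ACGT"})
        assert g.fetch("chr1", 0, 4, "+") == "ACGT"

    def test_fetch_minus_palindrome(self):
        g = GenomeSequence({"chr1": "ACGT"})
        assert g.fetch("chr1", 0, 4, "-") == "ACGT"

    def test_out_of_bounds(self):
        g = GenomeSequence({"chr1": "ACGT"})
        with pytest.raises(IndexError):
            g.fetch("chr1", 2, 6)

    def test_missing_chromosome(self):
        g = GenomeSequence({"chr1": "ACGT"})
        with pytest.raises(KeyError):
            g.fetch("chr2", 0, 1)

    def test_revcomp_involution(self):
        g = GenomeSequence({"c": "ACGTTTGCAN"})
        rc = g.fetch("c", 0, 10, "-")
        assert GenomeSequence({"c": rc}).fetch("c", 0, 10, "-") == "ACGTTTGCAN"
        assert rc == naive_rc("ACGTTTGCAN")

    def test_from_fasta(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chr1 description\nACGTAC\nGTAA\n")
        g = GenomeSequence.from_fasta(path)
        assert g.fetch("chr1", 0, 10) == "ACGTACGTAA"


GTF_TWO_TX = """\
chr1\tx\tgene\t1\t300\t.\t+\t.\tgene_id "G1";
chr1\tx\ttranscript\t1\t300\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; tag "Ensembl_canonical";
chr1\tx\texon\t1\t90\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; tag "Ensembl_canonical";
chr1\tx\texon\t151\t300\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; tag "Ensembl_canonical";
chr1\tx\tCDS\t10\t90\t.\t+\t0\tgene_id "G1"; transcript_id "T1"; tag "Ensembl_canonical";
chr1\tx\tCDS\t151\t219\t.\t+\t0\tgene_id "G1"; transcript_id "T1"; tag "Ensembl_canonical";
chr1\tx\tstop_codon\t220\t222\t.\t+\t0\tgene_id "G1"; transcript_id "T1"; tag "Ensembl_canonical";
chr1\tx\ttranscript\t1\t300\t.\t+\t.\tgene_id "G1"; transcript_id "T0";
chr1\tx\texon\t1\t300\t.\t+\t.\tgene_id "G1"; transcript_id "T0";
chr1\tx\tCDS\t10\t240\t.\t+\t0\tgene_id "G1"; transcript_id "T0";
"""


class TestCanonicalSelection:
    def test_tagged_transcript_wins(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(GTF_TWO_TX)
        models, skipped = load_canonical_annotation(path)
        assert models["G1"].transcript_id == "T1"
        # 1-based inclusive converted to 0-based half-open, stop normalised in
        assert models["G1"].cds_lo == 9
        assert models["G1"].cds_hi == 222

    def test_fallback_longest_cds(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(GTF_TWO_TX.replace(' tag "Ensembl_canonical";', ""))
        models, _ = load_canonical_annotation(path)
        assert models["G1"].transcript_id == "T0"  # 231 nt CDS > 154

    def test_tie_broken_lexicographically(self, tmp_path):
        lines = []
        for tx in ("TB", "TA"):
            lines += [
                f'chr1\tx\ttranscript\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "{tx}";',
                f'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "{tx}";',
                f'chr1\tx\tCDS\t10\t60\t.\t+\t0\tgene_id "G"; transcript_id "{tx}";',
            ]
        path = tmp_path / "a.gtf"
        path.write_text("\n".join(lines) + "\n")
        models, _ = load_canonical_annotation(path)
        assert models["G"].transcript_id == "TA"

    def test_no_cds_gene_is_skipped(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(
            'chr1\tx\ttranscript\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "T";\n')
        models, skipped = load_canonical_annotation(path)
        assert models == {}
        assert skipped == {"G": "no_cds"}

    def test_stop_included_dialect(self, tmp_path):
        # CDS records already contain the stop codon, no stop_codon feature
        text = GTF_TWO_TX.replace(
            'chr1\tx\tCDS\t151\t219\t.\t+\t0\tgene_id "G1"; transcript_id "T1"; tag "Ensembl_canonical";\n'
            'chr1\tx\tstop_codon\t220\t222\t.\t+\t0\tgene_id "G1"; transcript_id "T1"; tag "Ensembl_canonical";\n',
            'chr1\tx\tCDS\t151\t222\t.\t+\t0\tgene_id "G1"; transcript_id "T1"; tag "Ensembl_canonical";\n')
        path = tmp_path / "a.gtf"
        path.write_text(text)
        models, _ = load_canonical_annotation(path)
        assert (models["G1"].cds_lo, models["G1"].cds_hi) == (9, 222)

    def test_minus_strand_exons_in_transcription_order(self, tmp_path):
        lines = [
            'chr1\tx\ttranscript\t1001\t1300\t.\t-\t.\tgene_id "G"; transcript_id "T";',
            'chr1\tx\texon\t1001\t1100\t.\t-\t.\tgene_id "G"; transcript_id "T";',
            'chr1\tx\texon\t1201\t1300\t.\t-\t.\tgene_id "G"; transcript_id "T";',
            'chr1\tx\tCDS\t1023\t1100\t.\t-\t0\tgene_id "G"; transcript_id "T";',
            'chr1\tx\tCDS\t1210\t1290\t.\t-\t0\tgene_id "G"; transcript_id "T";',
        ]
        path = tmp_path / "a.gtf"
        path.write_text("\n".join(lines) + "\n")
        models, skipped = load_canonical_annotation(path)
        assert models["G"].exons == [(1200, 1300), (1000, 1100)]


class TestTranscriptModel:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(AnnotationError):
            TranscriptModel("G", "T", "c", "+", [(0, 100), (50, 150)], 10, 120)

    def test_cds_outside_exons_rejected(self):
        with pytest.raises(AnnotationError):
            TranscriptModel("G", "T", "c", "+", [(0, 100)], 10, 150)

    def test_introns(self, toy_tx):
        ivs = toy_exon_intervals()
        assert toy_tx.introns() == [(ivs[0][1], ivs[1][0]), (ivs[1][1], ivs[2][0])]


class TestAssembleMature:
    def test_toy_plus_strand(self, toy_genome, toy_tx):
        mature = assemble_mature(toy_genome, toy_tx)
        assert mature.sequence == TOY_EXON1 + TOY_EXON2 + TOY_EXON3
        assert mature.junctions == [13, 19]
        assert mature.cds_offset == 4
        assert mature.stop_offset == 19
        # CDS length is a codon multiple including the stop
        assert (mature.stop_offset + 3 - mature.cds_offset) % 3 == 0

    def test_single_exon_has_no_junction(self):
        genome = GenomeSequence({"c": "GGATG" + "AAA" * 5 + "TAATT"})
        tx = TranscriptModel("G", "T", "c", "+", [(0, 25)], 2, 23)
        mature = assemble_mature(genome, tx)
        assert mature.junctions == []

    def test_minus_strand_matches_base_oracle(self, toy_genome, toy_tx):
        # mirror the toy gene onto the minus strand and re-assemble
        n = len(TOY_CHROM)
        mirrored = GenomeSequence({"chrT": naive_rc(TOY_CHROM)})
        exons = [(n - e, n - s) for s, e in toy_tx.exons]
        tx = TranscriptModel("TOYG1", "TOYT1", "chrT", "-", exons,
                             cds_lo=n - toy_tx.cds_hi, cds_hi=n - toy_tx.cds_lo)
        mature = assemble_mature(mirrored, tx)
        expected = assemble_mature(toy_genome, toy_tx)
        assert mature.sequence == expected.sequence
        assert mature.junctions == expected.junctions
        assert mature.cds_offset == expected.cds_offset
        assert mature.stop_offset == expected.stop_offset

    def test_length_equals_sum_of_exons(self, cohort100, cohort100_loaded):
        genome, annotation, _ = cohort100_loaded
        for tx in annotation.values():
            mature = assemble_mature(genome, tx)
            assert len(mature.sequence) == tx.exonic_length
            assert len(mature.junctions) == tx.n_exons - 1
            assert mature.cds_offset < mature.stop_offset
            assert (mature.stop_offset + 3 - mature.cds_offset) % 3 == 0
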