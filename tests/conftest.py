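"""Shared fixtures: a hand-built toy gene pair and generated cohorts."""

import pytest

from splice2nmd.genome_annotation import (
    GenomeSequence,
    TranscriptModel,
    load_canonical_annotation,
    load_genome,
)
from splice2nmd.nmd_core import NMDConfig, run_pipeline
from splice2nmd.synthetic_data import GeneratorSpec, make_toy_genes


# A deterministic three-exon plus-strand toy gene, small enough to verify by
# eye.  Mature transcript: GGGG ATG AAA CCC | GGG TTT | TAA TTTT
# (exon boundaries marked |): cds_offset 4, junctions [13, 19], stop at 19.
TOY_EXON1 = "GGGGATGAAACCC"          # 4 nt 5'UTR + 3 codons
TOY_INTRON1 = "GTAAGTATAG"           # 10 nt
TOY_EXON2 = "GGGTTT"                 # 2 codons
TOY_INTRON2 = "GTXXAG".replace("X", "C")  # 6 nt
TOY_EXON3 = "TAATTTT"                # stop + 4 nt 3'UTR
TOY_CHROM = TOY_EXON1 + TOY_INTRON1 + TOY_EXON2 + TOY_INTRON2 + TOY_EXON3


def toy_exon_intervals():
    s1 = 0
    s2 = len(TOY_EXON1) + len(TOY_INTRON1)
    s3 = s2 + len(TOY_EXON2) + len(TOY_INTRON2)
    return [(s1, s1 + len(TOY_EXON1)),
            (s2, s2 + len(TOY_EXON2)),
            (s3, s3 + len(TOY_EXON3))]


@pytest.fixture
def toy_genome():
    return GenomeSequence({"chrT": TOY_CHROM})


@pytest.fixture
def toy_tx():
    exons = toy_exon_intervals()
    return TranscriptModel(
        gene_id="TOYG1", transcript_id="TOYT1", chrom="chrT", strand="+",
        exons=exons, cds_lo=4, cds_hi=exons[2][0] + 3, canonical=True)


@pytest.fixture(scope="session")
def cohort100():
    """Mixed synthetic cohort used across modules (seed-fixed)."""
    return make_toy_genes(100, seed=11)


@pytest.fixture(scope="session")
def cohort100_files(cohort100, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort100")
    return cohort100.write(outdir)


@pytest.fixture(scope="session")
def cohort100_loaded(cohort100_files):
    genome = load_genome(cohort100_files["fasta"])
    annotation, skipped = load_canonical_annotation(cohort100_files["gtf"])
    return genome, annotation, skipped


@pytest.fixture(scope="session")
def cohort100_results(cohort100, cohort100_loaded):
    genome, annotation, _ = cohort100_loaded
    return run_pipeline(cohort100.events, annotation, genome, NMDConfig())
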