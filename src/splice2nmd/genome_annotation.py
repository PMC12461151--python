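"""Genome access, canonical-transcript selection and mature-transcript assembly.

All coordinates are 0-based half-open internally; the GTF's 1-based inclusive
convention is converted at the parse boundary.  Exons of a transcript are kept
in transcription order (descending genomic coordinates on the minus strand).
The CDS extent is normalised to *include* the stop codon whether or not the
GTF records stop_codon features separately from CDS records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pyfaidx
from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Inconsistent transcript annotation (CDS outside exons, etc.)."""


class GenomeSequence:
    """Random access to genomic intervals with optional reverse complement.

    Wraps either an in-memory ``{chrom: sequence}`` mapping or a pyfaidx
    FASTA handle; intervals are 0-based half-open and must lie within the
    chromosome.
    """

    def __init__(self, seqs: dict[str, str]):
        self._seqs = {c: s.upper() for c, s in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on ``chrom``; minus strand returns the
        reverse complement."""
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        seq = self._seqs[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"{chrom}:{start}-{end} outside chromosome of length {len(seq)}")
        sub = seq[start:end]
        return sub if strand == "+" else reverse_complement(sub)


def load_genome(path: str | Path) -> GenomeSequence:
    """Load a FASTA file (indexed on the fly if needed)."""
    return GenomeSequence.from_fasta(path)


@dataclass
class TranscriptModel:
    """Canonical transcript structure in genomic coordinates.

    ``exons`` are in transcription order.  ``cds_lo``/``cds_hi`` delimit the
    CDS *including* the stop codon as a 0-based half-open genomic interval,
    regardless of strand; on the plus strand the start codon begins at
    ``cds_lo`` and the stop codon ends at ``cds_hi``, mirrored on minus.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds_lo: int
    cds_hi: int
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r}")
        srt = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(srt, srt[1:]):
            if e1 > s2:
                raise AnnotationError(f"overlapping exons in {self.transcript_id}")
        expected = srt if self.strand == "+" else srt[::-1]
        if self.exons != expected:
            raise AnnotationError(
                f"exons of {self.transcript_id} not in transcription order")
        if not any(s <= self.cds_lo < e for s, e in self.exons) or \
           not any(s < self.cds_hi <= e for s, e in self.exons):
            raise AnnotationError(
                f"CDS boundary outside exons in {self.transcript_id}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_exonic_length(self) -> int:
        """Number of exonic bases in the CDS interval (stop codon included)."""
        return sum(max(0, min(e, self.cds_hi) - max(s, self.cds_lo))
                   for s, e in self.exons)

    def introns(self) -> list[Interval]:
        """Intron intervals between consecutive exons (genomic, sorted pairs)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return out

    @property
    def start_codon_first_base(self) -> int:
        """Genomic position of the start codon's first base."""
        return self.cds_lo if self.strand == "+" else self.cds_hi - 1

    @property
    def stop_codon_first_base(self) -> int:
        """Genomic position of the stop codon's first base (transcript sense)."""
        return self.cds_hi - 3 if self.strand == "+" else self.cds_lo + 2


@dataclass
class MatureTranscript:
    """A spliced transcript: sense-strand sequence plus junction/CDS offsets.

    ``junctions`` are transcript coordinates of the first base of each
    downstream exon block, strictly increasing.  ``cds_offset`` is the start
    codon's first base; ``stop_offset`` the terminating stop codon's first
    base (``None`` when surgery removed the start, or no in-frame stop
    remains).  ``stop_recomputed`` marks a stop relocated by surgery.
    """

    sequence: str
    junctions: list[int]
    cds_offset: int | None
    stop_offset: int | None
    gene_id: str = ""
    transcript_id: str = ""
    event_id: str = ""
    stop_recomputed: bool = False

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if any(not 0 < j < n for j in self.junctions):
            raise ValueError("junction outside (0, len(sequence))")
        if any(a >= b for a, b in zip(self.junctions, self.junctions[1:])):
            raise ValueError("junctions not strictly increasing")

    @property
    def last_junction(self) -> int | None:
        return self.junctions[-1] if self.junctions else None


def _select_canonical(transcripts: list[tuple[str, bool, int]]) -> str:
    """Pick the canonical transcript id.

    Prefers the Ensembl_canonical tag; otherwise the longest CDS, ties broken
    by lexicographic transcript id.  ``transcripts`` holds
    (transcript_id, tagged, cds_length) triples.
    """
    tagged = [t for t in transcripts if t[1]]
    pool = tagged if tagged else transcripts
    return min(pool, key=lambda t: (-t[2], t[0]))[0]


def load_canonical_annotation(
    path: str | Path,
) -> tuple[dict[str, TranscriptModel], dict[str, str]]:
    """Load a GTF and return one canonical TranscriptModel per gene.

    Returns ``(models, skipped)`` where ``skipped`` maps gene_id to a reason
    for genes that cannot be processed (no CDS on the canonical transcript,
    CDS length not a multiple of three, no exons).
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    # Collect per-transcript structure keyed by (gene_id, transcript_id).
    tx_exons: dict[tuple[str, str], list[Interval]] = {}
    tx_cds: dict[tuple[str, str], list[Interval]] = {}
    tx_stop: dict[tuple[str, str], list[Interval]] = {}
    tx_meta: dict[tuple[str, str], tuple[str, str, bool]] = {}  # chrom, strand, tagged

    def _key(feat) -> tuple[str, str]:
        return (feat.attributes["gene_id"][0], feat.attributes["transcript_id"][0])

    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon", "transcript"):
            continue
        if "transcript_id" not in feat.attributes:
            continue
        key = _key(feat)
        iv = (feat.start - 1, feat.end)  # to 0-based half-open
        tagged = "Ensembl_canonical" in feat.attributes.get("tag", [])
        prev = tx_meta.get(key)
        tx_meta[key] = (feat.seqid, feat.strand, tagged or (prev[2] if prev else False))
        if feat.featuretype == "exon":
            tx_exons.setdefault(key, []).append(iv)
        elif feat.featuretype == "CDS":
            tx_cds.setdefault(key, []).append(iv)
        elif feat.featuretype == "stop_codon":
            tx_stop.setdefault(key, []).append(iv)

    by_gene: dict[str, list[tuple[str, bool, int]]] = {}
    for (gene_id, tx_id), (chrom, strand, tagged) in tx_meta.items():
        cds_len = sum(e - s for s, e in tx_cds.get((gene_id, tx_id), []))
        by_gene.setdefault(gene_id, []).append((tx_id, tagged, cds_len))

    models: dict[str, TranscriptModel] = {}
    skipped: dict[str, str] = {}
    for gene_id, transcripts in sorted(by_gene.items()):
        tx_id = _select_canonical(transcripts)
        key = (gene_id, tx_id)
        chrom, strand, _ = tx_meta[key]
        exons = tx_exons.get(key, [])
        if not exons:
            skipped[gene_id] = "no_exons"
            log.warning("gene %s: canonical transcript %s has no exons", gene_id, tx_id)
            continue
        cds = tx_cds.get(key, [])
        if not cds:
            skipped[gene_id] = "no_cds"
            continue
        # Normalise CDS extent to include the stop codon.
        pieces = cds + tx_stop.get(key, [])
        cds_lo = min(s for s, _ in pieces)
        cds_hi = max(e for _, e in pieces)
        exons_sorted = sorted(exons)
        if strand == "-":
            exons_sorted = exons_sorted[::-1]
        try:
            model = TranscriptModel(
                gene_id=gene_id, transcript_id=tx_id, chrom=chrom,
                strand=strand, exons=exons_sorted,
                cds_lo=cds_lo, cds_hi=cds_hi, canonical=True,
            )
        except AnnotationError as exc:
            skipped[gene_id] = f"bad_annotation: {exc}"
            continue
        cds_len = model.cds_exonic_length()
        if cds_len % 3 != 0:
            skipped[gene_id] = "cds_not_multiple_of_3"
            continue
        models[gene_id] = model
    return models, skipped


def splice_blocks(
    genome: GenomeSequence,
    chrom: str,
    strand: str,
    blocks: list[Interval],
) -> tuple[str, list[int]]:
    """Concatenate genomic blocks (transcription order) into a sense-strand
    sequence with junction positions at block boundaries."""
    parts = [genome.fetch(chrom, s, e, strand) for s, e in blocks]
    junctions: list[int] = []
    pos = 0
    for part in parts[:-1]:
        pos += len(part)
        junctions.append(pos)
    return "".join(parts), junctions


def genomic_to_transcript(
    blocks: list[Interval], strand: str, gpos: int
) -> int | None:
    """Map a genomic position to a transcript coordinate, or None if it falls
    outside the blocks.  Blocks must be in transcription order."""
    offset = 0
    for s, e in blocks:
        if s <= gpos < e:
            return offset + (gpos - s if strand == "+" else e - 1 - gpos)
        offset += e - s
    return None


STOP_CODONS = ("TAA", "TAG", "TGA")


def first_inframe_stop(sequence: str, cds_offset: int,
                       stop_codons=STOP_CODONS) -> int | None:
    """First stop-codon position in the reading frame anchored at cds_offset."""
    for p in range(cds_offset, len(sequence) - 2, 3):
        if sequence[p:p + 3] in stop_codons:
            return p
    return None


def assemble_transcript_from_blocks(
    genome: GenomeSequence,
    tx: TranscriptModel,
    blocks: list[Interval],
    event_id: str = "",
) -> MatureTranscript:
    """Assemble a MatureTranscript from an (optionally modified) exon chain.

    ``cds_offset`` maps the annotated start codon into the chain (None when
    the surgery removed it).  ``stop_offset`` is the annotated stop codon's
    position when it survives *in the translation frame*; after a frameshift
    or a stop-exon removal it is None — the annotated termination no longer
    exists in the frame being read, so every downstream in-frame stop is
    premature — and ``stop_recomputed`` is set.
    """
    sequence, junctions = splice_blocks(genome, tx.chrom, tx.strand, blocks)
    cds_offset = genomic_to_transcript(blocks, tx.strand, tx.start_codon_first_base)
    if cds_offset is not None and sequence[cds_offset:cds_offset + 3] != "ATG":
        # Surgery may truncate the start codon mid-triplet.
        cds_offset = None
    stop_offset: int | None = None
    recomputed = False
    if cds_offset is not None:
        p = genomic_to_transcript(blocks, tx.strand, tx.stop_codon_first_base)
        if (p is not None and (p - cds_offset) % 3 == 0
                and sequence[p:p + 3] in STOP_CODONS):
            stop_offset = p
        else:
            recomputed = True
    return MatureTranscript(
        sequence=sequence,
        junctions=junctions,
        cds_offset=cds_offset,
        stop_offset=stop_offset,
        gene_id=tx.gene_id,
        transcript_id=tx.transcript_id,
        event_id=event_id,
        stop_recomputed=recomputed,
    )


def assemble_mature(genome: GenomeSequence, tx: TranscriptModel) -> MatureTranscript:
    """Assemble the unmodified mature transcript of a canonical model."""
    mature = assemble_transcript_from_blocks(genome, tx, list(tx.exons))
    if mature.cds_offset is None:
        raise AnnotationError(
            f"{tx.transcript_id}: annotated start codon is not ATG or lies "
            "outside the exons")
    return mature
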