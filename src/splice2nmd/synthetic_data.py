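"""Synthetic genomes, annotations and event tables with known NMD truth.

The generator designs one splicing event per toy gene and *constructs the
genome around the designed outcome*: the terminating stop codon of the
event-modified transcript is planted at a chosen distance from the final
exon junction, competing stop codons in the reading path are scrubbed, and
the finished gene is verified against the independent brute-force oracle
(:func:`oracle_nmd`) before it is accepted.  Truth labels therefore come
from the oracle, not from the pipeline under test.

Genes are designed in transcript space on the plus strand; minus-strand
genes are produced by mirroring the whole chromosome (reverse complement +
coordinate reflection), which makes strand handling exactly symmetric.

The oracle at the bottom of this module deliberately shares no code with
the pipeline: it re-parses the GTF with regexes, does its own string
surgery on ascending exon lists, reverse-complements with a lookup table
and translates codon-by-codon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .whippet_io import SpliceEvent

NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
STOPS = ("TAA", "TAG", "TGA")

PROCESSED_OUTCOMES = ("true", "no_ptc", "too_close", "in_last_exon",
                      "no_junction", "no_cds_change")
OUTCOME_REASON = {
    "true": "PTC_UPSTREAM_RULE",
    "no_ptc": "NO_PTC",
    "too_close": "PTC_TOO_CLOSE",
    "in_last_exon": "PTC_IN_LAST_EXON",
    "no_junction": "NO_JUNCTION",
    "no_cds_change": "NO_CDS_CHANGE",
    "start_lost": "START_LOST",
    "not_on_canonical": "NOT_ON_CANONICAL",
    "transcription_related": "NOT_ON_CANONICAL",
}

TRUTH_COLUMNS = [
    "gene_id", "node", "event_type", "strand", "designed_outcome",
    "designed_net", "designed_frame", "designed_distance",
    "expected_nmd", "expected_reason", "processed", "significant",
]


class GenerationError(RuntimeError):
    """The requested design could not be satisfied."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions emulated by the generator.

    Outcome weights follow the cohort structure the pipeline is meant to
    summarise: ~90% of processed splicing events trigger NMD, the remainder
    split over the non-NMD branches.  Event-type weights approximate the
    observed frequency order in whole-blood splicing tables (exon skipping
    dominant, then retained introns, then alternative acceptor/donor).
    """

    nmd_true_fraction: float = 0.90
    false_outcome_weights: tuple[tuple[str, float], ...] = (
        ("no_ptc", 0.40), ("too_close", 0.20), ("in_last_exon", 0.20),
        ("no_junction", 0.10), ("no_cds_change", 0.10),
    )
    event_type_weights: tuple[tuple[str, float], ...] = (
        ("CE", 0.76), ("RI", 0.10), ("AA", 0.08), ("AD", 0.06),
    )
    #: extra (skipped) events, as fractions of n_genes
    start_lost_fraction: float = 0.02
    unknown_gene_fraction: float = 0.02
    transcription_related_fraction: float = 0.06
    #: fraction of events passing the significance filter
    significant_fraction: float = 0.7
    #: designed PTC-to-junction distance for NMD-true events
    true_distance_range: tuple[int, int] = (60, 240)
    too_close_distance_range: tuple[int, int] = (5, 45)
    minus_strand_fraction: float = 0.5
    threshold: int = 50
    exon_count_range: tuple[int, int] = (4, 6)
    exon_len_range: tuple[int, int] = (70, 160)
    intron_len_range: tuple[int, int] = (60, 120)
    ri_triple_span_fraction: float = 0.3
    decoy_transcript_fraction: float = 0.15
    max_tries: int = 40


@dataclass
class SyntheticCohort:
    """In-memory bundle: genome, annotation, events and truth labels."""

    genome: dict[str, str]
    gtf_text: str
    events: list[SpliceEvent]
    truth: pd.DataFrame

    def gtf_by_gene(self) -> dict[str, str]:
        """Split the GTF text into per-gene chunks (keyed by gene_id)."""
        out: dict[str, list[str]] = {}
        for line in self.gtf_text.splitlines():
            m = re.search(r'gene_id "([^"]+)"', line)
            if m:
                out.setdefault(m.group(1), []).append(line)
        return {g: "\n".join(lines) + "\n" for g, lines in out.items()}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write fasta/gtf/diff/truth files; returns the paths."""
        from .whippet_io import write_diff_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "diff": outdir / "events.diff",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for chrom in self.genome:
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        paths["gtf"].write_text(self.gtf_text)
        write_diff_table(self.events, paths["diff"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False, na_rep="NA")
        return paths


# ----------------------------------------------------------------------
# gene construction
# ----------------------------------------------------------------------

@dataclass
class _Layout:
    """Arithmetic skeleton of one gene before any sequence is drawn."""

    n_exons: int
    exon_lens: list[int]
    intron_lens: list[int]
    utr5: int                      # transcript offset of the start codon
    event_type: str                # CE | RI | AA | AD
    site: int                      # exon index (CE/AA/AD) or intron index (RI)
    mode: str                      # skip | retain | ext | trunc
    shift: int = 0                 # AA/AD shift amount
    stop_exon: int = -1            # exon holding the annotated stop
    stop_gap: int = 40             # 3'UTR length after the stop in its exon

    @property
    def net(self) -> int:
        if self.mode == "skip":
            return -self.exon_lens[self.site]
        if self.mode == "retain":
            return self.intron_lens[self.site]
        return self.shift if self.mode == "ext" else -self.shift

    def pieces(self) -> list[tuple[str, int, int, int]]:
        """Modified-transcript pieces as (kind, index, lo, hi) segment slices.

        kind is 'e' (exon) or 'i' (intron); lo/hi are offsets within the
        segment.  Pieces are in transcription order.
        """
        out: list[tuple[str, int, int, int]] = []
        for i in range(self.n_exons):
            lo, hi = 0, self.exon_lens[i]
            if self.mode == "skip" and i == self.site:
                continue
            if self.mode == "trunc" and i == self.site:
                if self.event_type == "AA":
                    lo = self.shift
                else:
                    hi -= self.shift
            if self.mode == "ext" and i == self.site and self.event_type == "AA":
                ilen = self.intron_lens[i - 1]
                out.append(("i", i - 1, ilen - self.shift, ilen))
            out.append(("e", i, lo, hi))
            if self.mode == "retain" and i == self.site:
                out.append(("i", i, 0, self.intron_lens[i]))
            if self.mode == "ext" and i == self.site and self.event_type == "AD":
                out.append(("i", i, 0, self.shift))
        return out

    def exon_starts(self) -> list[int]:
        """Gene-local genomic start of each exon (plus orientation)."""
        starts, pos = [], 0
        for i in range(self.n_exons):
            starts.append(pos)
            pos += self.exon_lens[i]
            if i < self.n_exons - 1:
                pos += self.intron_lens[i]
        return starts

    def _seg_start(self, kind: str, idx: int) -> int:
        starts = self.exon_starts()
        if kind == "e":
            return starts[idx]
        return starts[idx] + self.exon_lens[idx]

    def modified_blocks(self) -> list[tuple[int, int]]:
        """Gene-local genomic blocks of the modified transcript, with
        genomically contiguous pieces merged."""
        blocks: list[tuple[int, int]] = []
        for kind, idx, lo, hi in self.pieces():
            s = self._seg_start(kind, idx) + lo
            e = self._seg_start(kind, idx) + hi
            if blocks and blocks[-1][1] == s:
                blocks[-1] = (blocks[-1][0], e)
            else:
                blocks.append((s, e))
        return blocks

    def modified_length(self) -> int:
        return sum(hi - lo for _, _, lo, hi in self.pieces())

    def junctions(self) -> list[int]:
        blocks = self.modified_blocks()
        out, pos = [], 0
        for s, e in blocks[:-1]:
            pos += e - s
            out.append(pos)
        return out

    def insert_start(self) -> int:
        """Modified-transcript position where inserted/changed reading begins."""
        pos = 0
        for kind, idx, lo, hi in self.pieces():
            if self.mode == "skip":
                if kind == "e" and idx > self.site:
                    return pos
            elif self.mode == "retain":
                if kind == "i" and idx == self.site:
                    return pos
            elif self.mode == "ext":
                if kind == "i":
                    return pos
            else:  # trunc
                if kind == "e" and idx == self.site:
                    return pos if self.event_type == "AA" else pos + (hi - lo)
            pos += hi - lo
        return pos

    def to_transcript_original(self, kind: str, idx: int, off: int) -> int | None:
        """Map a segment offset into original-transcript coordinates."""
        if kind != "e":
            return None
        return sum(self.exon_lens[:idx]) + off

    def map_modified(self, tpos: int) -> tuple[str, int, int]:
        """Map a modified-transcript position to (kind, index, offset)."""
        pos = 0
        for kind, idx, lo, hi in self.pieces():
            if pos <= tpos < pos + (hi - lo):
                return kind, idx, lo + (tpos - pos)
            pos += hi - lo
        raise IndexError(tpos)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n > 0 else ""


def _rand_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(NON_STOP_CODONS), size=n_codons)
    return "".join(NON_STOP_CODONS[i] for i in idx)


def _adjust_parity(length: int, want_mod3: int, lo: int) -> int:
    """Smallest tweak of ``length`` (>= lo) to the wanted residue mod 3."""
    delta = (want_mod3 - length) % 3
    length += delta
    while length < lo:
        length += 3
    return length


@dataclass
class _Design:
    outcome: str
    event_type: str
    strand: str
    distance: int | None
    significant: bool


class _GeneBuilder:
    """Build one gene satisfying a design; raises GenerationError on failure."""

    def __init__(self, rng: np.random.Generator, spec: GeneratorSpec):
        self.rng = rng
        self.spec = spec

    # -- layout ---------------------------------------------------------

    def _base_layout(self, design: _Design) -> _Layout:
        rng, spec = self.rng, self.spec
        if design.outcome == "no_junction":
            n_exons = 2
        else:
            n_exons = int(rng.integers(*spec.exon_count_range, endpoint=True))
        exon_lens = [int(rng.integers(*spec.exon_len_range, endpoint=True))
                     for _ in range(n_exons)]
        intron_lens = [int(rng.integers(*spec.intron_len_range, endpoint=True))
                       for _ in range(max(0, n_exons - 1))]
        utr5 = int(rng.integers(12, 40))
        lay = _Layout(n_exons=n_exons, exon_lens=exon_lens,
                      intron_lens=intron_lens, utr5=utr5,
                      event_type=design.event_type, site=0, mode="skip",
                      stop_exon=n_exons - 1)
        return lay

    def _place_event(self, lay: _Layout, design: _Design) -> _Layout:
        rng = self.rng
        et, outcome = design.event_type, design.outcome
        frame0 = outcome in ("no_ptc", "no_cds_change")
        if et == "CE":
            lay.mode = "skip"
            hi = lay.n_exons - 3 if outcome in ("true", "too_close",
                                                "in_last_exon") else lay.n_exons - 2
            lay.site = int(rng.integers(1, max(2, hi + 1)))
            want = 0 if frame0 else (3 - int(rng.integers(1, 3))) % 3
            if outcome == "start_lost":
                lay.site = 1
                want = lay.exon_lens[lay.site] % 3  # parity irrelevant
            lay.exon_lens[lay.site] = _adjust_parity(
                lay.exon_lens[lay.site], want, self.spec.exon_len_range[0])
        elif et == "RI":
            lay.mode = "retain"
            if outcome == "no_junction":
                lay.site = 0
            elif outcome == "no_cds_change":
                lay.site = lay.n_exons - 2  # the 3'UTR intron
                lay.stop_exon = lay.n_exons - 2
            else:
                hi = lay.n_exons - 3 if outcome in ("true", "too_close",
                                                    "in_last_exon") else lay.n_exons - 2
                lay.site = int(rng.integers(0, max(1, hi)))
            if frame0 or outcome == "no_junction":
                want = 0
            elif outcome == "true" and design.distance is not None \
                    and design.distance >= 40 and rng.random() < 0.5:
                want = int(rng.integers(0, 3))  # insert-planted: any frame
            else:
                want = int(rng.integers(1, 3))
            lay.intron_lens[lay.site] = _adjust_parity(
                lay.intron_lens[lay.site], want, self.spec.intron_len_range[0])
        else:  # AA / AD
            ext = bool(rng.random() < 0.5)
            if outcome in ("true",) and design.distance is not None \
                    and design.distance < 40:
                ext = False
            lay.mode = "ext" if ext else "trunc"
            hi = lay.n_exons - 3 if outcome in ("true", "too_close",
                                                "in_last_exon") else lay.n_exons - 2
            lo = 1 if et == "AA" else (1 if hi >= 1 else 0)
            lay.site = int(rng.integers(lo, max(lo + 1, hi + 1)))
            s = int(rng.integers(9, 45))
            if frame0:
                s = _adjust_parity(s, 0, 9)
            elif lay.mode == "ext" and outcome == "true":
                s = _adjust_parity(s, int(rng.integers(0, 3)), 12)
            else:
                want_net = int(rng.integers(1, 3))
                want = want_net if lay.mode == "ext" else (3 - want_net) % 3
                s = _adjust_parity(s, want, 4)
            flank = lay.intron_lens[lay.site - 1] if et == "AA" else \
                lay.intron_lens[lay.site]
            if lay.mode == "ext" and s > flank - 10:
                idx = lay.site - 1 if et == "AA" else lay.site
                lay.intron_lens[idx] = s + 12
            if lay.mode == "trunc" and s > lay.exon_lens[lay.site] - 10:
                lay.exon_lens[lay.site] = _adjust_parity(
                    lay.exon_lens[lay.site], lay.exon_lens[lay.site] % 3, s + 12)
            lay.shift = s
        return lay

    # -- distance solving ------------------------------------------------

    def _solve_distance(self, lay: _Layout, design: _Design) -> int | None:
        """Pick the planted-stop position (modified-transcript coords) and
        stretch the penultimate exon so the distance to the final junction is
        exactly the designed one.  Returns the plant position, or None when
        no stop is planted."""
        outcome = design.outcome
        if outcome not in ("true", "too_close", "in_last_exon"):
            return None
        cds = lay.utr5
        adjustable = lay.n_exons - 2
        if outcome == "in_last_exon":
            # plant just downstream of the final junction, phase-aligned
            j0 = lay.junctions()[-1]
            p = j0 + 3 + ((cds - (j0 + 3)) % 3)
            lay.exon_lens[-1] = max(lay.exon_lens[-1], (p - j0) + 70)
            return p
        insert_mode = lay.mode in ("retain", "ext") and outcome == "true"
        a = lay.insert_start()
        if insert_mode:
            b = a
            ins_len = lay.shift if lay.mode == "ext" else lay.intron_lens[lay.site]
            p = b + 3 + ((cds - (b + 3)) % 3)
            if p + 2 >= b + ins_len - 3:
                insert_mode = False
        d = design.distance
        if insert_mode:
            j0 = lay.junctions()[-1]
            need = (p + 2 + d) - j0
            new_len = lay.exon_lens[adjustable] + need
            if new_len < 25 or new_len > 500:
                insert_mode = False
            else:
                lay.exon_lens[adjustable] = new_len
                return p
        # downstream-plant mode: p = j - 2 - d, phase-fixed via the
        # penultimate exon.
        j0 = lay.junctions()[-1]
        p0 = j0 - 2 - d
        delta = (cds - p0) % 3
        if p0 + delta < a + 3:
            delta += 3 * ((a + 3 - (p0 + delta) + 2) // 3)
        lay.exon_lens[adjustable] += delta
        j = lay.junctions()[-1]
        return j - 2 - d

    # -- sequence generation ---------------------------------------------

    def _fill_sequences(self, lay: _Layout, design: _Design
                        ) -> tuple[list[bytearray], list[bytearray], int]:
        """Draw exon/intron sequences; returns (exon_segs, intron_segs,
        stop_first) with the annotated stop placed in ``lay.stop_exon``."""
        rng = self.rng
        total = sum(lay.exon_lens)
        cds = lay.utr5
        # annotated stop near the end of its exon
        stop_exon_start_t = sum(lay.exon_lens[:lay.stop_exon])
        if design.outcome == "no_cds_change":
            # stop close to the following junction (gap << threshold)
            gap = 18
            stop_first = stop_exon_start_t + lay.exon_lens[lay.stop_exon] - 2 - gap
        else:
            utr3 = min(lay.stop_gap, lay.exon_lens[lay.stop_exon] - 12)
            stop_first = stop_exon_start_t + lay.exon_lens[lay.stop_exon] - 3 - utr3
        stop_first -= (stop_first - cds) % 3
        if stop_first < stop_exon_start_t + 3:
            raise GenerationError("stop codon does not fit in its exon")
        n_codons = (stop_first - cds) // 3
        mature = (_rand_seq(rng, cds) + "ATG" + _rand_cds(rng, n_codons - 1)
                  + str(rng.choice(STOPS)) + _rand_seq(rng, total - stop_first - 3))
        assert len(mature) == total
        exon_segs, pos = [], 0
        for L in lay.exon_lens:
            exon_segs.append(bytearray(mature[pos:pos + L], "ascii"))
            pos += L
        intron_segs = [bytearray(_rand_seq(rng, L), "ascii")
                       for L in lay.intron_lens]
        return exon_segs, intron_segs, stop_first

    def _modified_seq(self, lay: _Layout, exon_segs, intron_segs) -> str:
        parts = []
        for kind, idx, lo, hi in lay.pieces():
            seg = exon_segs[idx] if kind == "e" else intron_segs[idx]
            parts.append(seg[lo:hi].decode())
        return "".join(parts)

    def _set_base(self, lay: _Layout, exon_segs, intron_segs,
                  tpos: int, base: str) -> None:
        kind, idx, off = lay.map_modified(tpos)
        seg = exon_segs[idx] if kind == "e" else intron_segs[idx]
        seg[off] = ord(base)

    def _scrub_and_plant(self, lay: _Layout, design: _Design,
                         exon_segs, intron_segs, plant_at: int | None) -> None:
        """Remove frame-0 stops in the reading path and plant the designed
        terminator."""
        rng = self.rng
        cds = lay.utr5
        a = lay.insert_start()
        if design.outcome in ("true", "too_close", "in_last_exon"):
            scrub_hi = plant_at
        elif design.outcome == "no_ptc":
            ins = lay.net if lay.net > 0 else 0
            scrub_hi = a + ins + 3
        else:
            return
        seq = self._modified_seq(lay, exon_segs, intron_segs)
        start = cds + 3 * max(0, (a - 3 - cds) // 3)
        for p in range(start, min(scrub_hi, len(seq) - 2), 3):
            if seq[p:p + 3] in STOPS:
                repl = NON_STOP_CODONS[int(rng.integers(0, len(NON_STOP_CODONS)))]
                for i, b in enumerate(repl):
                    self._set_base(lay, exon_segs, intron_segs, p + i, b)
        if plant_at is not None:
            stop = str(rng.choice(STOPS))
            for i, b in enumerate(stop):
                self._set_base(lay, exon_segs, intron_segs, plant_at + i, b)

    # -- assembly ---------------------------------------------------------

    def build(self, gene_id: str, tx_id: str, chrom: str, node: int,
              design: _Design) -> dict | None:
        """One attempt; returns the gene record or None on a failed check."""
        rng, spec = self.rng, self.spec
        try:
            lay = self._base_layout(design)
            if design.outcome == "start_lost":
                lay.utr5 = lay.exon_lens[0] + int(rng.integers(3, 12))
            lay = self._place_event(lay, design)
            plant_at = self._solve_distance(lay, design)
            exon_segs, intron_segs, stop_first = self._fill_sequences(lay, design)
            if design.outcome not in ("start_lost",):
                self._scrub_and_plant(lay, design, exon_segs, intron_segs, plant_at)
        except (GenerationError, IndexError, ValueError):
            return None

        pad = 25
        gene_seq_parts = []
        for i in range(lay.n_exons):
            gene_seq_parts.append(exon_segs[i].decode())
            if i < lay.n_exons - 1:
                gene_seq_parts.append(intron_segs[i].decode())
        body = "".join(gene_seq_parts)
        chrom_seq = _rand_seq(rng, pad) + body + _rand_seq(rng, pad)

        starts = [s + pad for s in lay.exon_starts()]
        exon_ivs = [(starts[i], starts[i] + lay.exon_lens[i])
                    for i in range(lay.n_exons)]
        # genomic CDS interval (stop included), from transcript offsets
        cds_lo_t, cds_hi_t = lay.utr5, stop_first + 3

        def t2g(tpos: int) -> int:
            off = 0
            for i, (s, e) in enumerate(exon_ivs):
                L = e - s
                if off <= tpos < off + L:
                    return s + (tpos - off)
                off += L
            raise IndexError(tpos)

        cds_lo_g = t2g(cds_lo_t)
        cds_hi_g = t2g(cds_hi_t - 1) + 1
        stop_g = (t2g(stop_first), t2g(stop_first + 2) + 1)

        # event coordinate (gene-local plus orientation)
        ei = lay.site
        if lay.mode == "skip":
            ev_iv = exon_ivs[ei]
        elif lay.mode == "retain":
            intron_iv = (exon_ivs[ei][1], exon_ivs[ei + 1][0])
            if rng.random() < spec.ri_triple_span_fraction:
                ev_iv = (exon_ivs[ei][0], exon_ivs[ei + 1][1])
            else:
                ev_iv = intron_iv
        elif lay.mode == "ext":
            s, e = exon_ivs[ei]
            ev_iv = (s - lay.shift, e) if design.event_type == "AA" \
                else (s, e + lay.shift)
        else:
            s, e = exon_ivs[ei]
            ev_iv = (s + lay.shift, e) if design.event_type == "AA" \
                else (s, e - lay.shift)

        strand = design.strand
        n = len(chrom_seq)
        if strand == "-":
            chrom_seq = _naive_revcomp(chrom_seq)
            refl = lambda iv: (n - iv[1], n - iv[0])
            exon_ivs = [refl(iv) for iv in exon_ivs][::-1]
            cds_lo_g, cds_hi_g = n - cds_hi_g, n - cds_lo_g
            stop_g = refl(stop_g)
            ev_iv = refl(ev_iv)
        gtf = _gtf_lines(chrom, gene_id, tx_id, strand, exon_ivs,
                         (cds_lo_g, cds_hi_g), stop_g, canonical=True)
        if rng.random() < spec.decoy_transcript_fraction and lay.n_exons >= 4:
            decoy_exons = [iv for k, iv in enumerate(exon_ivs) if k != 1]
            gtf += _gtf_lines(chrom, gene_id, tx_id + "decoy", strand,
                              decoy_exons, (cds_lo_g, cds_hi_g), None,
                              canonical=False)

        event = self._make_event(gene_id, node, chrom, ev_iv, strand, design)
        truth = self._truth_row(gene_id, node, design, lay, plant_at)

        record = {
            "chrom": chrom, "seq": chrom_seq, "gtf": gtf,
            "event": event, "truth": truth,
        }
        if not self._verify(record, design, lay, plant_at):
            return None
        return record

    def _make_event(self, gene_id, node, chrom, ev_iv, strand,
                    design: _Design) -> SpliceEvent:
        rng = self.rng
        if design.significant:
            prob = float(0.9 + 0.1 * rng.random())
            dpsi = float(rng.uniform(0.12, 0.6)) * (1 if rng.random() < 0.5 else -1)
        elif rng.random() < 0.5:
            prob = float(rng.uniform(0.2, 0.89))
            dpsi = float(rng.uniform(0.12, 0.6)) * (1 if rng.random() < 0.5 else -1)
        else:
            prob = float(0.9 + 0.1 * rng.random())
            dpsi = float(rng.uniform(0.01, 0.099)) * (1 if rng.random() < 0.5 else -1)
        lo = max(0.0, -dpsi) + 0.01
        hi = min(1.0, 1.0 - dpsi) - 0.01
        psi_a = float(rng.uniform(lo, hi))
        return SpliceEvent(
            gene_id=gene_id, node=node, chrom=chrom,
            start=ev_iv[0], end=ev_iv[1], strand=strand,
            event_type=design.event_type,
            psi_a=round(psi_a, 5), psi_b=round(psi_a + dpsi, 5),
            delta_psi=round(dpsi, 5), probability=round(prob, 5),
            complexity="K1", entropy=round(float(rng.uniform(0, 2)), 4),
        )

    def _truth_row(self, gene_id, node, design: _Design, lay: _Layout,
                   plant_at: int | None) -> dict:
        outcome = design.outcome
        cds_changed = outcome not in ("no_cds_change",)
        frame = (lay.net % 3) if cds_changed else 0
        if outcome == "in_last_exon":
            distance = lay.junctions()[-1] - (plant_at + 2)
        else:
            distance = design.distance
        expected_nmd = outcome == "true"
        return {
            "gene_id": gene_id, "node": node,
            "event_type": design.event_type, "strand": design.strand,
            "designed_outcome": outcome,
            "designed_net": lay.net if outcome in PROCESSED_OUTCOMES else None,
            "designed_frame": frame if outcome in PROCESSED_OUTCOMES else None,
            "designed_distance": distance,
            "expected_nmd": expected_nmd,
            "expected_reason": OUTCOME_REASON[outcome],
            "processed": outcome in PROCESSED_OUTCOMES,
            "significant": design.significant,
        }

    def _verify(self, record, design: _Design, lay: _Layout,
                plant_at: int | None) -> bool:
        """Check the finished gene against the independent oracle."""
        res = oracle_nmd({record["chrom"]: record["seq"]}, record["gtf"],
                         record["event"], threshold=self.spec.threshold)
        truth = record["truth"]
        if design.outcome == "start_lost":
            return res.skip_reason == "start_lost"
        if design.outcome not in PROCESSED_OUTCOMES:
            return True
        if res.skip_reason is not None:
            return False
        if bool(res.nmd) != bool(truth["expected_nmd"]):
            return False
        if design.outcome in ("true", "too_close") and \
                res.distance != truth["designed_distance"]:
            return False
        if design.outcome == "no_junction" and res.last_junction is not None:
            return False
        return True


def _gtf_lines(chrom, gene_id, tx_id, strand, exon_ivs, cds_iv, stop_iv,
               canonical: bool) -> str:
    """Emit Ensembl-dialect GTF for one transcript (CDS excludes the stop
    codon, which gets its own stop_codon feature)."""
    tag = ' tag "Ensembl_canonical";' if canonical else ""
    attrs_tx = f'gene_id "{gene_id}"; transcript_id "{tx_id}";{tag}'
    lines = [
        f"{chrom}\tsynth\tgene\t{min(s for s, _ in exon_ivs) + 1}\t"
        f"{max(e for _, e in exon_ivs)}\t.\t{strand}\t.\tgene_id \"{gene_id}\";",
        f"{chrom}\tsynth\ttranscript\t{min(s for s, _ in exon_ivs) + 1}\t"
        f"{max(e for _, e in exon_ivs)}\t.\t{strand}\t.\t{attrs_tx}",
    ]
    cds_lo, cds_hi = cds_iv
    if stop_iv is not None:
        # CDS excludes the stop codon
        if strand == "+":
            cds_hi = stop_iv[0]
        else:
            cds_lo = stop_iv[1]
    for s, e in sorted(exon_ivs):
        lines.append(f"{chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs_tx}")
        cs, ce = max(s, cds_lo), min(e, cds_hi)
        if cs < ce:
            lines.append(
                f"{chrom}\tsynth\tCDS\t{cs + 1}\t{ce}\t.\t{strand}\t0\t{attrs_tx}")
    if stop_iv is not None:
        lines.append(
            f"{chrom}\tsynth\tstop_codon\t{stop_iv[0] + 1}\t{stop_iv[1]}\t.\t"
            f"{strand}\t0\t{attrs_tx}")
    return "\n".join(lines) + "\n"


def make_toy_genes(
    n_genes: int,
    seed: int,
    spec: GeneratorSpec | None = None,
    outdir: str | Path | None = None,
) -> SyntheticCohort:
    """Generate a synthetic cohort of single-event toy genes.

    Deterministic for a fixed seed.  ``n_genes`` is the number of processed
    (in-scope) events; skipped designs (start-lost, unknown genes,
    transcription-related events) are added on top at the spec's fractions.
    Every gene is verified against the brute-force oracle before acceptance;
    an unsatisfiable design raises :class:`GenerationError`.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(seed)
    builder = _GeneBuilder(rng, spec)

    designs: list[_Design] = []
    fw = dict(spec.false_outcome_weights)
    tw = dict(spec.event_type_weights)
    t_names, t_probs = zip(*tw.items())
    t_probs = np.array(t_probs) / sum(t_probs)
    f_names, f_probs = zip(*fw.items())
    f_probs = np.array(f_probs) / sum(f_probs)
    for _ in range(n_genes):
        if rng.random() < spec.nmd_true_fraction:
            outcome = "true"
        else:
            outcome = str(f_names[int(rng.choice(len(f_names), p=f_probs))])
        if outcome == "no_junction" or outcome == "no_cds_change":
            etype = "RI"
        else:
            etype = str(t_names[int(rng.choice(len(t_names), p=t_probs))])
        if outcome == "true":
            d = int(rng.integers(*spec.true_distance_range, endpoint=True))
        elif outcome == "too_close":
            d = int(rng.integers(*spec.too_close_distance_range, endpoint=True))
        else:
            d = None
        designs.append(_Design(
            outcome=outcome, event_type=etype,
            strand="-" if rng.random() < spec.minus_strand_fraction else "+",
            distance=d,
            significant=bool(rng.random() < spec.significant_fraction)))
    for _ in range(round(spec.start_lost_fraction * n_genes)):
        designs.append(_Design("start_lost", "CE",
                               "-" if rng.random() < 0.5 else "+",
                               None, bool(rng.random() < spec.significant_fraction)))

    genome: dict[str, str] = {}
    gtf_parts: list[str] = []
    events: list[SpliceEvent] = []
    truth_rows: list[dict] = []
    node = 0
    for gi, design in enumerate(designs):
        gene_id = f"SYNG{gi:05d}"
        tx_id = f"SYNT{gi:05d}"
        chrom = f"chr_{gene_id}"
        node += 1
        record = None
        for _ in range(spec.max_tries):
            record = builder.build(gene_id, tx_id, chrom, node, design)
            if record is not None:
                break
        if record is None:
            raise GenerationError(
                f"could not satisfy design {design} for {gene_id}")
        genome[chrom] = record["seq"]
        gtf_parts.append(record["gtf"])
        events.append(record["event"])
        truth_rows.append(record["truth"])

    # skipped extras: transcription-related events on real genes, plus
    # events for genes absent from the annotation
    n_tr = round(spec.transcription_related_fraction * n_genes)
    for i in range(n_tr):
        host = events[int(rng.integers(0, n_genes))]
        node += 1
        etype = str(rng.choice(["TS", "TE", "AF", "AL"]))
        ev = replace(host, node=node, event_type=etype)
        events.append(ev)
        truth_rows.append({
            "gene_id": ev.gene_id, "node": node, "event_type": etype,
            "strand": ev.strand, "designed_outcome": "transcription_related",
            "designed_net": None, "designed_frame": None,
            "designed_distance": None, "expected_nmd": False,
            "expected_reason": "NOT_ON_CANONICAL", "processed": False,
            "significant": False,
        })
    n_unk = round(spec.unknown_gene_fraction * n_genes)
    for i in range(n_unk):
        node += 1
        gid = f"SYNGUNKNOWN{i:03d}"
        host = events[int(rng.integers(0, n_genes))]
        ev = replace(host, node=node, gene_id=gid)
        events.append(ev)
        truth_rows.append({
            "gene_id": gid, "node": node, "event_type": ev.event_type,
            "strand": ev.strand, "designed_outcome": "not_on_canonical",
            "designed_net": None, "designed_frame": None,
            "designed_distance": None, "expected_nmd": False,
            "expected_reason": "NOT_ON_CANONICAL", "processed": False,
            "significant": False,
        })

    cohort = SyntheticCohort(
        genome=genome,
        gtf_text="".join(gtf_parts),
        events=events,
        truth=pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS),
    )
    if outdir is not None:
        cohort.write(outdir)
    return cohort


def make_boundary_genes(
    seed: int,
    distances: tuple[int, ...] = (49, 50, 51, 54, 55, 56),
    strand: str = "+",
) -> SyntheticCohort:
    """Fixture genes whose planted PTC sits at exact distances from the
    final exon junction — the flip points of the 50-55 nt rule."""
    spec = GeneratorSpec(
        nmd_true_fraction=1.0, minus_strand_fraction=0.0,
        start_lost_fraction=0.0, unknown_gene_fraction=0.0,
        transcription_related_fraction=0.0, decoy_transcript_fraction=0.0,
        significant_fraction=1.0)
    rng = np.random.default_rng(seed)
    builder = _GeneBuilder(rng, spec)
    genome, gtf_parts, events, rows = {}, [], [], []
    for gi, d in enumerate(distances):
        design = _Design("true" if d >= 50 else "too_close", "CE",
                         strand, int(d), True)
        gene_id, tx_id = f"SYNB{gi:05d}", f"SYNTB{gi:05d}"
        chrom = f"chr_{gene_id}"
        record = None
        for _ in range(spec.max_tries):
            record = builder.build(gene_id, tx_id, chrom, gi + 1, design)
            if record is not None:
                break
        if record is None:
            raise GenerationError(f"boundary gene at distance {d} unsatisfiable")
        genome[chrom] = record["seq"]
        gtf_parts.append(record["gtf"])
        events.append(record["event"])
        rows.append(record["truth"])
    return SyntheticCohort(genome, "".join(gtf_parts), events,
                           pd.DataFrame(rows, columns=TRUTH_COLUMNS))


def mirror_cohort(cohort: SyntheticCohort) -> SyntheticCohort:
    """Reverse-complement every chromosome and reflect all coordinates.

    The mirrored cohort encodes the identical transcripts on the opposite
    strand; a strand-correct pipeline must produce identical transcript-space
    results on both.
    """
    lengths = {c: len(s) for c, s in cohort.genome.items()}
    genome = {c: _naive_revcomp(s) for c, s in cohort.genome.items()}
    flip = {"+": "-", "-": "+"}
    gtf_lines = []
    for line in cohort.gtf_text.splitlines():
        f = line.split("\t")
        n = lengths[f[0]]
        s1, e1 = int(f[3]), int(f[4])
        f[3], f[4] = str(n - e1 + 1), str(n - s1 + 1)
        f[6] = flip[f[6]]
        gtf_lines.append("\t".join(f))
    events = [replace(ev, start=lengths[ev.chrom] - ev.end,
                      end=lengths[ev.chrom] - ev.start,
                      strand=flip[ev.strand])
              for ev in cohort.events]
    truth = cohort.truth.copy()
    truth["strand"] = truth["strand"].map(flip)
    return SyntheticCohort(genome, "\n".join(gtf_lines) + "\n", events, truth)


# ----------------------------------------------------------------------
# the independent brute-force oracle
# ----------------------------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def _naive_revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


@dataclass
class OracleResult:
    nmd: bool
    first_stop: int | None
    last_junction: int | None
    distance: int | None
    skip_reason: str | None = None
    #: independent count of premature stops in the translation frame
    n_ptc_frame0: int | None = None


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _oracle_read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name, chunks = None, []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def oracle_nmd(genome, gtf, event: SpliceEvent, threshold: int = 50
               ) -> OracleResult:
    """Literal, naive NMD call for one event: re-parse the annotation, do
    string surgery on the ascending exon list, translate codon by codon from
    the start codon and measure the stop-to-last-junction distance.

    Shares no code with the pipeline modules; used to verify generated truth
    labels and as the independent reference in equivalence tests.
    """
    if isinstance(genome, (str, Path)):
        genome = _oracle_read_fasta(genome)
    if isinstance(gtf, Path) or (
            isinstance(gtf, str) and "\t" not in gtf and "\n" not in gtf
            and gtf and Path(gtf).is_file()):
        gtf = Path(gtf).read_text()

    # gather annotation lines for this gene
    by_tx: dict[str, dict] = {}
    for line in str(gtf).splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(_ATTR_RE.findall(f[8]))
        if attrs.get("gene_id") != event.gene_id:
            continue
        tx = attrs.get("transcript_id")
        if tx is None:
            continue
        rec = by_tx.setdefault(tx, {
            "chrom": f[0], "strand": f[6], "exons": [], "cds": [],
            "stop": [], "canonical": False})
        iv = (int(f[3]) - 1, int(f[4]))
        if f[2] == "exon":
            rec["exons"].append(iv)
        elif f[2] == "CDS":
            rec["cds"].append(iv)
        elif f[2] == "stop_codon":
            rec["stop"].append(iv)
        if "Ensembl_canonical" in f[8]:
            rec["canonical"] = True
    if not by_tx:
        return OracleResult(False, None, None, None, "no_gene")
    tagged = {t: r for t, r in by_tx.items() if r["canonical"]}
    pool = tagged or by_tx
    tx = sorted(pool, key=lambda t: (-sum(e - s for s, e in pool[t]["cds"]), t))[0]
    rec = by_tx[tx]
    if event.event_type not in ("CE", "RI", "AA", "AD"):
        return OracleResult(False, None, None, None, "out_of_scope")
    exons = sorted(rec["exons"])
    strand = rec["strand"]
    coord = (event.start, event.end)
    cds_pieces = rec["cds"] + rec["stop"]
    g_lo = min(s for s, _ in cds_pieces)
    g_hi = max(e for _, e in cds_pieces)

    # naive surgery on the ascending exon list
    if event.event_type == "CE":
        if coord not in exons:
            return OracleResult(False, None, None, None, "no_match")
        i = exons.index(coord)
        if i == 0 or i == len(exons) - 1:
            return OracleResult(False, None, None, None, "terminal_exon")
        new_exons = exons[:i] + exons[i + 1:]
    elif event.event_type == "RI":
        new_exons = None
        for i in range(len(exons) - 1):
            gap = (exons[i][1], exons[i + 1][0])
            span = (exons[i][0], exons[i + 1][1])
            if coord == gap or coord == span:
                new_exons = exons[:i] + [(exons[i][0], exons[i + 1][1])] \
                    + exons[i + 2:]
                break
        if new_exons is None:
            return OracleResult(False, None, None, None, "no_match")
    else:
        retain_end = (event.event_type == "AA") == (strand == "+")
        new_exons = None
        for i, (s, e) in enumerate(exons):
            if retain_end and e == coord[1] and s != coord[0]:
                new_exons = exons[:i] + [coord] + exons[i + 1:]
                break
            if not retain_end and s == coord[0] and e != coord[1]:
                new_exons = exons[:i] + [coord] + exons[i + 1:]
                break
            if (s, e) == coord:
                new_exons = list(exons)
                break
        if new_exons is None:
            return OracleResult(False, None, None, None, "no_match")
        new_exons.sort()

    chrom_seq = genome[rec["chrom"]]
    plus_seq = "".join(chrom_seq[s:e] for s, e in new_exons)
    L = len(plus_seq)
    boundaries = []
    pos = 0
    for s, e in new_exons[:-1]:
        pos += e - s
        boundaries.append(pos)

    def plus_index(gpos: int) -> int | None:
        off = 0
        for s, e in new_exons:
            if s <= gpos < e:
                return off + (gpos - s)
            off += e - s
        return None

    if strand == "+":
        mature = plus_seq
        junctions = boundaries
        start_g = g_lo
        to_t = plus_index
    else:
        mature = _naive_revcomp(plus_seq)
        junctions = sorted(L - b for b in boundaries)
        start_g = g_hi - 1

        def to_t(gpos: int):
            i = plus_index(gpos)
            return None if i is None else L - 1 - i

    t_start = to_t(start_g)
    if t_start is None or mature[t_start:t_start + 3] != "ATG":
        return OracleResult(False, None, None, None, "start_lost")
    first_stop = None
    for p in range(t_start, len(mature) - 2, 3):
        if mature[p:p + 3] in ("TAA", "TAG", "TGA"):
            first_stop = p
            break
    # premature-stop census in the translation frame: everything upstream of
    # the annotated stop when it is still readable in frame, else all stops
    if rec["stop"]:
        anno_stop_g = min(s for s, _ in rec["stop"]) if strand == "+" \
            else max(e for _, e in rec["stop"]) - 1
    else:
        anno_stop_g = None
    t_anno = to_t(anno_stop_g) if anno_stop_g is not None else None
    if t_anno is not None and ((t_anno - t_start) % 3 != 0
                               or mature[t_anno:t_anno + 3] not in
                               ("TAA", "TAG", "TGA")):
        t_anno = None
    n_ptc = 0
    for p in range(t_start, len(mature) - 2, 3):
        if t_anno is not None and p >= t_anno:
            break
        if mature[p:p + 3] in ("TAA", "TAG", "TGA"):
            n_ptc += 1
    last_j = junctions[-1] if junctions else None
    if first_stop is None or last_j is None:
        return OracleResult(False, first_stop, last_j, None,
                            n_ptc_frame0=n_ptc)
    dist = last_j - (first_stop + 2)
    return OracleResult(dist >= threshold, first_stop, last_j, dist,
                        n_ptc_frame0=n_ptc)
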