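"""Apply a single splicing event to a canonical transcript.

Each event type maps to one edit of the exon chain:

* ES (Whippet CE) — remove one internal exon; the event coordinate must match
  that exon exactly.
* RI — fuse the intron between two consecutive exons into one block; the
  event coordinate is either the bare intron interval or the
  exon-intron-exon span (both dialects occur in the wild).
* AA — move the acceptor (3' splice-site) edge of an exon; the coordinate is
  the modified exon interval, sharing the donor-side edge with the
  annotation.
* AD — move the donor (5' splice-site) edge, symmetric to AA.

The pipeline always models the non-canonical isoform (exon skipped, intron
retained, shifted site used): that is the PTC-generating form whose NMD fate
is being predicted, whichever direction the psi change points.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_annotation import (
    GenomeSequence,
    Interval,
    MatureTranscript,
    TranscriptModel,
    assemble_transcript_from_blocks,
)
from .whippet_io import SpliceEvent


class SurgeryError(ValueError):
    """Base class for event-placement and surgery failures."""


class NotOnCanonical(SurgeryError):
    """Event coordinates match no edit site on the canonical transcript."""


class TerminalExonEvent(SurgeryError):
    """A CE/ES call on a first or last exon (AF/AL/TS/TE territory)."""


class StartLost(SurgeryError):
    """Surgery removed or truncated the start codon."""


class DegenerateTranscript(SurgeryError):
    """Surgery produced an empty or single-base transcript."""


@dataclass(frozen=True)
class EventPlacement:
    """Where an event lands on the canonical transcript and what it changes.

    Exactly one of ``exon_index``/``intron_index`` is set (indices are in
    transcription order).  ``new_interval`` holds the modified exon interval
    for AA/AD.  ``net_length_change`` is signed nucleotides added to the
    mature transcript.
    """

    event: SpliceEvent
    overlap_kind: str  # exact_exon | intron_between_exons | acceptor_shift | donor_shift
    net_length_change: int
    exon_index: int | None = None
    intron_index: int | None = None
    new_interval: Interval | None = None

    def __post_init__(self) -> None:
        if (self.exon_index is None) == (self.intron_index is None):
            raise SurgeryError("exactly one of exon/intron index must be set")

    def affected_genomic_interval(self, tx: TranscriptModel) -> Interval:
        """Genomic interval whose bases are added or removed by the event."""
        if self.overlap_kind == "exact_exon":
            return tx.exons[self.exon_index]
        if self.overlap_kind == "intron_between_exons":
            return tx.introns()[self.intron_index]
        old_s, old_e = tx.exons[self.exon_index]
        new_s, new_e = self.new_interval
        if old_s != new_s:
            return (min(old_s, new_s), max(old_s, new_s))
        return (min(old_e, new_e), max(old_e, new_e))


def _shifted_edge(tx: TranscriptModel, event_type: str) -> str:
    """Which genomic edge of the exon an AA/AD event moves.

    The acceptor is the transcription-5' edge of an exon, the donor the
    transcription-3' edge; on the minus strand these swap in genomic terms.
    """
    if event_type == "AA":
        return "start" if tx.strand == "+" else "end"
    return "end" if tx.strand == "+" else "start"


def locate_event(event: SpliceEvent, tx: TranscriptModel) -> EventPlacement:
    """Match an event's coordinates against the canonical transcript.

    Raises :class:`NotOnCanonical` when nothing matches, and
    :class:`TerminalExonEvent` for an ES call on a first/last exon.
    """
    if event.gene_id != tx.gene_id:
        raise SurgeryError(
            f"event gene {event.gene_id} != transcript gene {tx.gene_id}")
    if event.chrom != tx.chrom:
        raise NotOnCanonical(f"event on {event.chrom}, gene on {tx.chrom}")
    coord = (event.start, event.end)
    etype = event.event_type

    if etype == "CE":
        for i, exon in enumerate(tx.exons):
            if exon == coord:
                if i == 0 or i == tx.n_exons - 1:
                    raise TerminalExonEvent(
                        f"CE/ES on terminal exon {i} of {tx.transcript_id}")
                return EventPlacement(
                    event=event, overlap_kind="exact_exon",
                    net_length_change=-(exon[1] - exon[0]), exon_index=i)
        raise NotOnCanonical(f"CE coord {coord} matches no exon")

    if etype == "RI":
        introns = tx.introns()
        for i, intron in enumerate(introns):
            span_lo = min(tx.exons[i][0], tx.exons[i + 1][0])
            span_hi = max(tx.exons[i][1], tx.exons[i + 1][1])
            if coord == intron or coord == (span_lo, span_hi):
                return EventPlacement(
                    event=event, overlap_kind="intron_between_exons",
                    net_length_change=intron[1] - intron[0], intron_index=i)
        raise NotOnCanonical(f"RI coord {coord} matches no intron")

    if etype in ("AA", "AD"):
        edge = _shifted_edge(tx, etype)
        lo = 0 if etype == "AA" else tx.n_exons - 1
        for i, (s, e) in enumerate(tx.exons):
            # the unchanged boundary must match the annotated exon
            if edge == "start" and e == coord[1] and s != coord[0]:
                pass
            elif edge == "end" and s == coord[0] and e != coord[1]:
                pass
            elif (s, e) == coord:
                # zero-shift degenerate call: identity surgery
                pass
            else:
                continue
            if etype == "AA" and i == 0:
                raise NotOnCanonical("AA on the first exon (no upstream intron)")
            if etype == "AD" and i == tx.n_exons - 1:
                raise NotOnCanonical("AD on the last exon (no downstream intron)")
            _validate_shift(tx, i, coord)
            net = (coord[1] - coord[0]) - (e - s)
            kind = "acceptor_shift" if etype == "AA" else "donor_shift"
            return EventPlacement(
                event=event, overlap_kind=kind, net_length_change=net,
                exon_index=i, new_interval=coord)
        raise NotOnCanonical(f"{etype} coord {coord} shares no exon edge")

    raise NotOnCanonical(f"event type {etype} is outside surgery scope")


def _validate_shift(tx: TranscriptModel, i: int, new_iv: Interval) -> None:
    """A shifted splice site must stay within the flanking intron and leave a
    non-empty exon."""
    new_s, new_e = new_iv
    if new_e - new_s < 1:
        raise NotOnCanonical(f"shifted exon {new_iv} is empty")
    neighbours = sorted(tx.exons)
    j = neighbours.index(tx.exons[i]) if tx.exons[i] in neighbours else None
    lo_bound = neighbours[j - 1][1] if j and j > 0 else 0
    hi_bound = neighbours[j + 1][0] if j is not None and j + 1 < len(neighbours) else None
    if new_s < lo_bound or (hi_bound is not None and new_e > hi_bound):
        raise NotOnCanonical(
            f"shifted exon {new_iv} crosses a neighbouring exon")


def modified_exon_chain(tx: TranscriptModel, placement: EventPlacement) -> list[Interval]:
    """Exon chain (transcription order) after applying the event."""
    exons = list(tx.exons)
    kind = placement.overlap_kind
    if kind == "exact_exon":
        del exons[placement.exon_index]
    elif kind == "intron_between_exons":
        i = placement.intron_index
        a, b = exons[i], exons[i + 1]
        fused = (min(a[0], b[0]), max(a[1], b[1]))
        exons[i:i + 2] = [fused]
    else:  # acceptor/donor shift
        exons[placement.exon_index] = placement.new_interval
    return exons


def apply_event(
    genome: GenomeSequence,
    tx: TranscriptModel,
    placement: EventPlacement,
) -> MatureTranscript:
    """Produce the event-modified mature transcript.

    Raises :class:`StartLost` when the surgery removes or truncates the start
    codon, and :class:`DegenerateTranscript` for an empty result.
    """
    chain = modified_exon_chain(tx, placement)
    if not chain or sum(e - s for s, e in chain) < 3:
        raise DegenerateTranscript(f"surgery on {tx.transcript_id} left no sequence")
    ev = placement.event
    mature = assemble_transcript_from_blocks(
        genome, tx, chain, event_id=f"{ev.gene_id}:{ev.node}:{ev.event_type}")
    if mature.cds_offset is None:
        raise StartLost(f"event removed the start codon of {tx.transcript_id}")
    return mature
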