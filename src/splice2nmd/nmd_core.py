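"""Reading-frame prediction, PTC enumeration and the NMD exon-junction rule.

The biological rule: after a splicing event, the ribosome initiates at the
annotated start codon and reads triplets until the first in-frame stop.  When
that termination site lies at least 50-55 nt upstream of the final exon-exon
junction, the retained exon-junction complex downstream of the terminating
ribosome marks the transcript for nonsense-mediated decay.

Frames here are anchored at the start codon of the *modified* transcript:
frame 0 is the frame the ribosome actually reads.  ``predicted_frame`` is the
frameshift class of the event — ``net_length_change mod 3`` — i.e. the frame
in which the original annotated codons appear downstream of the event; it is
reported per the pipeline's output contract but the NMD call itself always
follows the translation frame, which is what the event makes the ribosome
read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_annotation import (
    GenomeSequence,
    MatureTranscript,
    TranscriptModel,
    STOP_CODONS,
)
from .transcript_surgery import (
    EventPlacement,
    NotOnCanonical,
    StartLost,
    SurgeryError,
    apply_event,
    locate_event,
)
from .whippet_io import SpliceEvent, SPLICING_TYPES

# Reason codes attached to every NMD call.
PTC_UPSTREAM_RULE = "PTC_UPSTREAM_RULE"
NO_PTC = "NO_PTC"
PTC_IN_LAST_EXON = "PTC_IN_LAST_EXON"
PTC_TOO_CLOSE = "PTC_TOO_CLOSE"
NO_JUNCTION = "NO_JUNCTION"
START_LOST = "START_LOST"
NOT_ON_CANONICAL = "NOT_ON_CANONICAL"
NO_CDS_CHANGE = "NO_CDS_CHANGE"

#: Reasons that mean the event was processed (enters NMD-rate denominators).
PROCESSED_REASONS = frozenset(
    {PTC_UPSTREAM_RULE, NO_PTC, PTC_IN_LAST_EXON, PTC_TOO_CLOSE,
     NO_JUNCTION, NO_CDS_CHANGE})

#: Reasons that mean the event was skipped (excluded from denominators).
SKIP_REASONS = frozenset({START_LOST, NOT_ON_CANONICAL})

RESULT_COLUMNS = [
    "gene_id", "node", "event_type", "predicted_frame",
    "ptc_count_f0", "ptc_count_f1", "ptc_count_f2",
    "first_ptc", "last_junction", "distance_nt", "nmd", "reason",
]


@dataclass(frozen=True)
class NMDConfig:
    """Tunable parameters of the NMD call.

    ``ptc_junction_threshold_nt`` is the minimum distance from the last base
    of the terminating codon to the final exon junction for NMD to fire; the
    literature gives a 50-55 nt band and 50 (the conservative edge) is the
    default.  Values outside [50, 55] are allowed only with ``strict=False``.
    """

    ptc_junction_threshold_nt: int = 50
    stop_codons: tuple[str, ...] = STOP_CODONS
    strict: bool = True

    def __post_init__(self) -> None:
        if self.strict and not 50 <= self.ptc_junction_threshold_nt <= 55:
            raise ValueError(
                "ptc_junction_threshold_nt outside the canonical 50-55 band "
                "(pass strict=False to override)")


@dataclass
class NMDResult:
    """Outcome of the NMD prediction for one splicing event."""

    gene_id: str
    node: int
    event_type: str  # report label (ES, RI, AA, AD, ...)
    predicted_frame: int | None
    ptc_positions_per_frame: dict[int, list[int]] = field(default_factory=dict)
    first_ptc: int | None = None
    last_junction: int | None = None
    ptc_to_junction_nt: int | None = None
    nmd: bool = False
    reason: str = NOT_ON_CANONICAL

    @property
    def ptc_count_per_frame(self) -> dict[int, int]:
        return {f: len(v) for f, v in self.ptc_positions_per_frame.items()}

    @property
    def processed(self) -> bool:
        return self.reason in PROCESSED_REASONS

    def to_row(self) -> dict:
        counts = self.ptc_count_per_frame
        return {
            "gene_id": self.gene_id,
            "node": self.node,
            "event_type": self.event_type,
            "predicted_frame": self.predicted_frame,
            "ptc_count_f0": counts.get(0, 0),
            "ptc_count_f1": counts.get(1, 0),
            "ptc_count_f2": counts.get(2, 0),
            "first_ptc": self.first_ptc,
            "last_junction": self.last_junction,
            "distance_nt": self.ptc_to_junction_nt,
            "nmd": self.nmd,
            "reason": self.reason,
        }


def event_changes_cds(placement: EventPlacement, tx: TranscriptModel) -> bool:
    """True when the event adds or removes bases inside the CDS interval
    (stop codon included)."""
    lo, hi = placement.affected_genomic_interval(tx)
    return lo < tx.cds_hi and hi > tx.cds_lo


def predicted_frame(placement: EventPlacement, tx: TranscriptModel) -> int:
    """Frameshift class of the event: net length change mod 3 when the event
    touches the CDS, else 0 (no coding change)."""
    if not event_changes_cds(placement, tx):
        return 0
    return ((placement.net_length_change % 3) + 3) % 3


def scan_ptcs(mature: MatureTranscript, config: NMDConfig | None = None
              ) -> dict[int, list[int]]:
    """Stop-codon positions per frame, anchored at the start codon.

    Frame ``f`` holds positions ``p >= cds_offset`` with
    ``(p - cds_offset) % 3 == f`` whose triplet is a stop codon.  In frame 0
    — the translation frame — positions at or beyond the normal (possibly
    surgery-relocated) stop are excluded, so frame 0 lists only premature
    stops.  Codons containing N are never stops.
    """
    config = config or NMDConfig()
    if mature.cds_offset is None:
        raise ValueError("transcript has no start codon (cds_offset is None)")
    seq = mature.sequence
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    out: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for p in range(mature.cds_offset, len(seq) - 2):
        if seq[p:p + 3] in config.stop_codons:
            f = (p - mature.cds_offset) % 3
            if f == 0 and mature.stop_offset is not None and p >= mature.stop_offset:
                continue
            out[f].append(p)
    return out


def _skip_result(event: SpliceEvent, reason: str) -> NMDResult:
    return NMDResult(
        gene_id=event.gene_id, node=event.node,
        event_type=event.report_label, predicted_frame=None,
        nmd=False, reason=reason)


def classify_nmd(
    mature: MatureTranscript,
    frame: int,
    ptcs: dict[int, list[int]],
    config: NMDConfig | None = None,
    event: SpliceEvent | None = None,
    cds_changed: bool = True,
) -> NMDResult:
    """Apply the exon-junction rule to a modified transcript.

    Translation terminates at the first frame-0 stop (a premature one from
    ``ptcs[0]`` when present, else the normal stop).  NMD is called true when
    that termination site has at least ``ptc_junction_threshold_nt``
    nucleotides between the last base of its codon and the final exon
    junction; the distance is ``last_junction - (stop + 2)``.
    """
    config = config or NMDConfig()
    gene_id = event.gene_id if event else mature.gene_id
    node = event.node if event else -1
    etype = event.report_label if event else ""

    first_ptc = ptcs[0][0] if ptcs.get(0) else None
    # Where translation actually terminates.
    term = first_ptc if first_ptc is not None else mature.stop_offset
    last_junction = mature.last_junction

    result = NMDResult(
        gene_id=gene_id, node=node, event_type=etype,
        predicted_frame=frame, ptc_positions_per_frame=ptcs,
        first_ptc=first_ptc, last_junction=last_junction)

    if last_junction is None:
        result.reason = NO_JUNCTION
        return result
    if term is None:
        # no stop anywhere in the translation frame
        result.reason = NO_PTC
        return result

    distance = last_junction - (term + 2)
    result.ptc_to_junction_nt = distance
    if distance >= config.ptc_junction_threshold_nt:
        result.nmd = True
        result.reason = PTC_UPSTREAM_RULE
    elif not cds_changed:
        result.reason = NO_CDS_CHANGE
    elif first_ptc is None:
        result.reason = NO_PTC
    elif term + 2 >= last_junction:
        result.reason = PTC_IN_LAST_EXON
    else:
        result.reason = PTC_TOO_CLOSE
    return result


def predict_event(
    event: SpliceEvent,
    tx: TranscriptModel | None,
    genome: GenomeSequence,
    config: NMDConfig | None = None,
) -> NMDResult:
    """Full prediction for one event; degenerate cases become reason codes."""
    config = config or NMDConfig()
    if event.event_type not in SPLICING_TYPES or tx is None:
        return _skip_result(event, NOT_ON_CANONICAL)
    try:
        placement = locate_event(event, tx)
    except SurgeryError:
        return _skip_result(event, NOT_ON_CANONICAL)
    try:
        mature = apply_event(genome, tx, placement)
    except StartLost:
        return _skip_result(event, START_LOST)
    except SurgeryError:
        return _skip_result(event, NOT_ON_CANONICAL)
    frame = predicted_frame(placement, tx)
    ptcs = scan_ptcs(mature, config)
    return classify_nmd(
        mature, frame, ptcs, config, event=event,
        cds_changed=event_changes_cds(placement, tx))


def run_pipeline(
    events: list[SpliceEvent],
    annotation: dict[str, TranscriptModel],
    genome: GenomeSequence,
    config: NMDConfig | None = None,
) -> pd.DataFrame:
    """Predict NMD for every event; one row per input event.

    In-scope events (ES/RI/AA/AD placed on a canonical transcript) carry a
    processed reason; everything else carries a skip reason and is excluded
    from NMD-rate denominators downstream.  Deterministic for fixed inputs.
    """
    config = config or NMDConfig()
    rows = []
    for event in events:
        tx = annotation.get(event.gene_id)
        if tx is not None and tx.chrom not in genome:
            raise ValueError(
                f"chromosome {tx.chrom!r} of gene {tx.gene_id} absent from "
                "genome — annotation/genome naming mismatch (chr prefix?)")
        rows.append(predict_event(event, tx, genome, config).to_row())
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return df.astype({"nmd": bool}) if len(df) else df


def write_results(df: pd.DataFrame, path) -> None:
    """Write an NMD results table as TSV with a stable column order."""
    out = df[RESULT_COLUMNS].copy()
    out["nmd"] = out["nmd"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    df["nmd"] = df["nmd"].map({"true": True, "false": False, True: True, False: False})
    return df
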