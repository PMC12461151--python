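"""Parsing and filtering of Whippet differential-splicing tables.

Whippet reports per-node percent-spliced-in (psi) for two sample groups plus a
Bayesian probability that the node is differentially spliced.  Coordinates in
the ``.diff`` table are 1-based inclusive (``chrom:start-end``); internally the
package uses 0-based half-open intervals, converted here at the parse boundary.

Event-type codes follow Whippet: CE (core exon; reported to users as ES, exon
skipping), RI (retained intron), AA (alternative acceptor), AD (alternative
donor), plus the transcription-related codes TS, TE, AF, AL which are outside
the scope of NMD prediction.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

log = logging.getLogger(__name__)

#: Whippet event-type codes.
EVENT_TYPES = frozenset({"CE", "AA", "AD", "RI", "TS", "TE", "AF", "AL"})

#: Codes that modify the splicing pattern of an existing transcript body.
SPLICING_TYPES = ("CE", "RI", "AA", "AD")

#: Codes tied to transcription start/end choice rather than splicing proper.
TRANSCRIPTION_TYPES = ("TS", "TE", "AF", "AL")

#: User-facing label for each internal code (CE is reported as ES).
REPORT_LABELS = {"CE": "ES", "RI": "RI", "AA": "AA", "AD": "AD",
                 "TS": "TS", "TE": "TE", "AF": "AF", "AL": "AL"}

DIFF_COLUMNS = ["Gene", "Node", "Coord", "Strand", "Type", "Psi_A", "Psi_B",
                "DeltaPsi", "Probability", "Complexity", "Entropy"]

_COORD_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


class DiffParseError(ValueError):
    """A malformed row in a Whippet ``.diff`` table."""


@dataclass(frozen=True)
class SpliceEvent:
    """One Whippet differential-splicing record.

    ``start``/``end`` are 0-based half-open genomic coordinates.  ``delta_psi``
    is psi_b - psi_a, i.e. the second-listed group minus the first.
    """

    gene_id: str
    node: int
    chrom: str
    start: int
    end: int
    strand: str
    event_type: str
    psi_a: float
    psi_b: float
    delta_psi: float
    probability: float
    complexity: str = ""
    entropy: float = float("nan")

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise DiffParseError(f"unknown event type {self.event_type!r}")
        if not self.start < self.end:
            raise DiffParseError(
                f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise DiffParseError(f"bad strand {self.strand!r}")
        for name in ("psi_a", "psi_b", "probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DiffParseError(f"{name}={v} outside [0, 1]")
        if not -1.0 <= self.delta_psi <= 1.0:
            raise DiffParseError(f"delta_psi={self.delta_psi} outside [-1, 1]")

    @property
    def coord(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def report_label(self) -> str:
        """Event type as reported to users (CE -> ES)."""
        return REPORT_LABELS[self.event_type]

    @property
    def coord_1based(self) -> str:
        """Coordinate string in Whippet's 1-based inclusive dialect."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class DGERecord:
    """One differential-gene-expression record (DESeq2-style output row)."""

    gene_id: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"padj={self.padj} outside [0, 1]")

    def is_significant(self, alpha: float = 0.05, min_abs_log2fc: float = 2.0) -> bool:
        """Significance rule for DGE: adjusted P < alpha and |log2FC| > cutoff."""
        return self.padj < alpha and abs(self.log2fc) > min_abs_log2fc


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_coord(coord: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive) to 0-based half-open."""
    m = _COORD_RE.match(coord)
    if not m:
        raise DiffParseError(f"malformed coordinate {coord!r}")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    return chrom, start - 1, end


def parse_diff_table(path: str | Path) -> list[SpliceEvent]:
    """Parse a Whippet ``.diff`` table (plain or gzipped) into events.

    Rows whose psi columns are ``NA`` (unquantifiable nodes) are dropped and
    counted in a log message rather than raising.  Malformed coordinates or
    unknown type codes raise :class:`DiffParseError` naming the line.
    """
    events: list[SpliceEvent] = []
    n_na = 0
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != DIFF_COLUMNS[:5]:
            raise DiffParseError(
                f"unexpected header {header[:5]} (want {DIFF_COLUMNS[:5]})")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise DiffParseError(f"line {lineno}: expected >=9 columns")
            (gene, node, coord, strand, etype,
             psi_a, psi_b, dpsi, prob) = fields[:9]
            if "NA" in (psi_a, psi_b, dpsi):
                n_na += 1
                continue
            try:
                chrom, start, end = parse_coord(coord)
                ev = SpliceEvent(
                    gene_id=gene,
                    node=int(node),
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    event_type=etype,
                    psi_a=float(psi_a),
                    psi_b=float(psi_b),
                    delta_psi=float(dpsi),
                    probability=float(prob),
                    complexity=fields[9] if len(fields) > 9 else "",
                    entropy=float(fields[10]) if len(fields) > 10 else float("nan"),
                )
            except (DiffParseError, ValueError) as exc:
                raise DiffParseError(f"line {lineno}: {exc}") from exc
            events.append(ev)
    if n_na:
        log.info("dropped %d rows with NA psi values", n_na)
    return events


def write_diff_table(events: Iterable[SpliceEvent], path: str | Path) -> None:
    """Write events back in Whippet ``.diff`` format (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("\t".join(DIFF_COLUMNS) + "\n")
        for ev in events:
            entropy = "NA" if ev.entropy != ev.entropy else repr(ev.entropy)
            fh.write("\t".join([
                ev.gene_id, str(ev.node), ev.coord_1based, ev.strand,
                ev.event_type, repr(ev.psi_a), repr(ev.psi_b),
                repr(ev.delta_psi), repr(ev.probability),
                ev.complexity, entropy,
            ]) + "\n")


def parse_dge_table(path: str | Path) -> list[DGERecord]:
    """Parse a DGE table with columns gene_id, log2FoldChange, padj.

    DESeq2 column names (``log2FoldChange``, ``padj``) and generic names
    (``log2fc``) are both accepted; rows with NA padj are dropped.
    """
    records: list[DGERecord] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c.lower(): i for i, c in enumerate(header)}
        try:
            i_gene = cols.get("gene_id", cols.get("gene"))
            i_fc = cols.get("log2foldchange", cols.get("log2fc"))
            i_p = cols["padj"]
            if i_gene is None or i_fc is None:
                raise KeyError
        except KeyError:
            raise ValueError(f"DGE table missing required columns in {header}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or fields == [""]:
                continue
            if "NA" in (fields[i_fc], fields[i_p]):
                continue
            records.append(DGERecord(
                gene_id=fields[i_gene],
                log2fc=float(fields[i_fc]),
                padj=float(fields[i_p]),
            ))
    return records


def filter_significant(events: list[SpliceEvent],
                       prob_min: float = 0.9,
                       abs_dpsi_min: float = 0.1) -> list[SpliceEvent]:
    """Keep events with probability >= prob_min and |delta psi| > abs_dpsi_min.

    The probability bound is inclusive, the delta-psi bound strict, matching
    the significance rule recommended by the Whippet documentation.  Order is
    preserved and the operation is idempotent.
    """
    if not (0.0 <= prob_min <= 1.0 and 0.0 <= abs_dpsi_min <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    return [ev for ev in events
            if ev.probability >= prob_min and abs(ev.delta_psi) > abs_dpsi_min]


def categorize_events(events: list[SpliceEvent]) -> dict[str, dict[str, int]]:
    """Partition events into splicing vs transcription-related counts by type.

    Splicing: ES (CE), RI, AA, AD.  Transcription-related: TS, TE, AF, AL.
    Counts are keyed by report label (CE appears as ES).
    """
    splicing = {REPORT_LABELS[t]: 0 for t in SPLICING_TYPES}
    transcription = {t: 0 for t in TRANSCRIPTION_TYPES}
    for ev in events:
        if ev.event_type in SPLICING_TYPES:
            splicing[ev.report_label] += 1
        else:
            transcription[ev.event_type] += 1
    return {"splicing": splicing, "transcription_related": transcription}


def splicing_type_frequencies(events: list[SpliceEvent]) -> dict[str, float]:
    """Percentage of each splicing-group type among splicing-group events only.

    Transcription-related events are excluded from the denominator.  Returns
    an all-zero mapping for an input with no splicing-group events.
    """
    counts = categorize_events(events)["splicing"]
    total = sum(counts.values())
    if total == 0:
        return {label: 0.0 for label in counts}
    return {label: 100.0 * n / total for label, n in counts.items()}
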