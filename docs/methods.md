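# Methods

## Model

`splice2nmd` implements positional, exon-junction-complex (EJC) dependent
NMD prediction. The assumptions, in order of application:

1. **One event, one transcript.** Each differential-splicing event is
   applied in isolation to the gene's canonical transcript. Combinatorial
   application of several simultaneous events to one isoform is out of
   scope, as are the transcription-related event classes (TS/TE/AF/AL),
   which change transcript ends rather than the splicing of a fixed body.
2. **The non-canonical isoform is the object of interest.** Surgery always
   produces the event isoform — exon skipped, intron retained, shifted
   splice site used — regardless of which direction the ΔΨ change points.
   The ΔΨ sign matters later, in the protein-direction rule, not during
   reconstruction.
3. **Translation initiates at the annotated start codon** and proceeds in
   triplets to the first stop codon. Frame is therefore anchored at
   `cds_offset` of the *modified* transcript: frame 0 is what the ribosome
   reads. The reported `predicted_frame` is the event's frameshift class,
   `((net_length_change mod 3) + 3) mod 3` — the frame in which the original
   annotated codons appear downstream of the event. For frame-preserving
   events the two coincide; for frameshifts the NMD call follows the
   ribosome, i.e. frame 0, which is the frame the event makes it read. This
   is also exactly what the package's independent oracle computes, so the
   two routes are comparable event-for-event.
4. **The junction rule.** With the terminating codon's first base at `p` and
   the final exon–exon junction at `j` (position of the first base of the
   last exon block), the transcript is an NMD substrate iff
   `j − (p + 2) ≥ T`. The distance is measured from the *last* base of the
   terminating codon — the EJC deposition reference point. `T` defaults to
   50 nt, the conservative edge of the 50–55 nt band quoted in the NMD
   literature; values in [50, 55] are accepted without question
   (`--ptc-rule-nt`), anything else requires an explicit non-strict flag.
5. **Premature vs normal stops.** The annotated stop codon is not a PTC:
   frame-0 stop positions at or beyond it are excluded from the PTC census.
   When surgery removes the annotated stop or shifts it out of frame, no
   normal termination exists in the frame being read, so every downstream
   in-frame stop is premature and translation ends at the first of them.
   Stop codons containing N are never stops. A codon spanning an exon–exon
   junction is positioned by its first base.

Degenerate cases map to reason codes rather than errors: `START_LOST`
(surgery removed or truncated the start codon; excluded from NMD
denominators), `NO_JUNCTION` (single-block transcript after surgery, e.g.
retention of the only intron), `NO_PTC`, `PTC_TOO_CLOSE`,
`PTC_IN_LAST_EXON`, `NO_CDS_CHANGE` (event entirely outside the CDS and the
call is negative), `NOT_ON_CANONICAL` (out-of-scope type, unannotated gene,
or coordinates matching no canonical exon/intron boundary; excluded from
denominators).

## Event placement conventions

* **ES/CE** — the event coordinate must equal one *internal* exon exactly; a
  match on a first or last exon is rejected (that geometry belongs to
  AF/AL/TS/TE).
* **RI** — the coordinate is accepted as either the bare intron interval or
  the exon–intron–exon span; both dialects occur in Whippet output. Both
  are detected by boundary matching against the annotation.
* **AA/AD** — the coordinate is the modified exon interval: it shares the
  unchanged edge (the donor side for AA, the acceptor side for AD) with the
  annotated exon, and its other edge defines the shifted splice site.
  Shifts must stay within the flanking intron and leave a non-empty exon.
  A zero-shift coordinate is accepted as identity surgery.

All internal coordinates are 0-based half-open; the 1-based inclusive
conventions of GTF and of Whippet's `Coord` column are converted at the
parse boundaries. CDS extent is normalised to *include* the stop codon
whether the GTF records `stop_codon` features separately (Ensembl dialect)
or folds the stop into the CDS records. Canonical-transcript selection
prefers the `Ensembl_canonical` tag, falling back to the longest CDS with
lexicographic transcript-id tie-break — deterministic and close to
Ensembl's own definition. Genes whose canonical transcript has no CDS, or a
CDS length that is not a codon multiple, are recorded as non-processable.

## Statistical layer

* Proportions (NMD rates, subtype shares): 2×2 chi-square via
  `scipy.stats.chi2_contingency`; Yates' continuity correction is applied
  automatically when any expected cell count is below 5 (the conventional
  small-sample rule), and both corrected/uncorrected variants are available.
* |ΔΨ| magnitudes: Anderson–Darling normality is computed and reported for
  context; the comparison itself is the Wilcoxon rank-sum test
  (`scipy.stats.mannwhitneyu`), exact for tie-free samples of ≤ 50,
  normal-approximated with continuity correction otherwise.
* Continuous two-group comparisons (PTC-count medians): Shapiro–Wilk gating
  at α = 0.05 selects Welch's t test when both groups look normal and the
  Wilcoxon rank-sum test otherwise.
* The cohort summary treats "all quantified events" as the baseline
  population and "significant events" as the contrast, mirroring the study
  design the summary emulates; skip-reason rows never enter a denominator.

The protein-direction rule is only informative when transcription is
unchanged and degradation is predicted: DGE non-significant (adjusted
P ≥ 0.05 or |log2FC| ≤ 2) **and** the event NMD-true. Then ΔΨ < 0 (event
rarer in the contrast group) predicts a *higher* protein level there —
fewer transcripts routed to decay — and ΔΨ > 0 the opposite. Every other
combination is `indeterminate`.

## Synthetic data generator

The generator emulates the structure of a Whippet differential-splicing
cohort at desk scale, with ground truth built in:

* One designed event per toy gene; each gene on its own short chromosome
  (a few kb), padded with random sequence. Genes are designed in transcript
  space on the plus strand; minus-strand genes are produced by mirroring the
  chromosome (reverse complement + coordinate reflection), which makes
  strand handling exactly symmetric by construction.
* Gene anatomy: 4–6 exons of 70–160 nt (2 exons for the no-junction branch),
  introns of 60–120 nt, 12–40 nt 5'UTR, CDS drawn from non-stop codons with
  the annotated stop placed in the last exon.
* Outcome design: the terminating stop of the modified transcript is
  *planted* at a chosen distance from the final junction (inside the
  retained/extended intron sequence for frame-preserving designs, in the
  frameshifted downstream frame otherwise); competing in-frame stops along
  the reading path are scrubbed by codon resampling; the penultimate exon is
  stretched to make the designed distance exact. Designed distances: 60–240
  nt for NMD-true events, 5–45 nt for the too-close branch, and the exact
  boundary set {49, 50, 51, 54, 55, 56} for the flip fixtures.
* Default study conditions: 90% of processed events NMD-true; event types
  at ES 76% / RI 10% / AA 8% / AD 6%, approximating the frequency order of
  whole-blood splicing tables; 70% of events significant (probability drawn
  from [0.9, 1), |ΔΨ| from (0.12, 0.6), the remainder failing one of the
  two thresholds); half of the genes on each strand; plus small fractions
  of start-lost designs, unknown-gene events and transcription-related
  events to exercise every skip path.
* **Verification, not trust:** every generated gene is checked against the
  independent oracle before acceptance (up to 40 redraws, then a generation
  error). Truth labels therefore come from the oracle, never from the
  pipeline under test.

The oracle itself is deliberately naive and shares no code with the
pipeline: it re-parses the GTF with regular expressions, performs string
surgery on ascending exon lists, reverse-complements via a lookup table,
translates codon by codon from the start codon and measures the distance to
the last junction. It also counts premature stops in the translation frame
independently, which backs the dual-route check of the PTC-median summaries.

What the generator does *not* emulate: read-level noise in Ψ estimation,
Whippet's probabilistic model, overlapping genes, alternative TSS/polyA
structure, long-3'UTR or EJC-independent NMD branches, and NMD efficiency
(the call is binary). Passing tests therefore demonstrate correctness of
the reconstruction + rule machinery under clean annotations, not robustness
to noisy quantification or non-canonical decay triggers.

## Numerical and design choices

* Thresholds: probability ≥ 0.9 (inclusive) and |ΔΨ| > 0.1 (strict) for
  significance; adjusted P < 0.05 and |log2FC| > 2 (both strict) for DGE.
* The Whippet complexity/entropy columns are parsed and carried through but
  never filtered on.
* `CE` is relabelled `ES` only at the reporting surface; the internal code
  stays `CE`, faithful to the input format.
* Rows with `NA` Ψ values (unquantifiable nodes) are dropped with a logged
  count rather than raising.
* Results TSVs have a fixed column order
  (`gene_id … distance_nt, nmd, reason`) and are byte-stable across reruns
  for regression testing; `predict` is fully deterministic.
* Problem sizes in the test suite and acceptance script — 100-gene cohorts
  across five seeds and two thresholds for oracle equivalence, a 1,000-gene
  cohort for rate recovery — keep full runs in the seconds range while
  giving ≥ 1,000 events to the equivalence check and ±3 binomial SDs of
  resolution to the recovery check.

## Known limitations

* Only the canonical transcript is modelled; events affecting a
  non-canonical isoform of an annotated gene are reported as
  `NOT_ON_CANONICAL` rather than evaluated against the isoform they hit.
* An event entirely within the 3'UTR that removes junctions downstream of
  the stop is classified by the same distance rule as everything else; a
  gene whose *unmodified* transcript already violates the junction rule
  (e.g. a 3'UTR intron > 50 nt downstream of the stop) would be called NMD
  regardless of the event. The generator only produces such geometry in its
  dedicated no-CDS-change branch, with the stop close to the junction.
* GFF3 input, selenocysteine recoding, stop-codon readthrough and multi-stop
  leaky termination are unsupported.
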