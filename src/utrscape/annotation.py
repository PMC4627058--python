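"""Transcript annotation: in-silico splicing, CDS anchoring, UTR extraction.

Exon coordinates come from a GTF (1-based inclusive); internally all
coordinates are 0-based half-open, and all reported transcript-space
coordinates are 0-based half-open in transcript orientation (5'->3').

The CDS of each transcript is located by exact, case-insensitive matching
of the first and last 30 nt of the supplied reference coding sequence
against the spliced transcript. A transcript is "complete" when both
flanks match, in order, and the implied span length equals the reference
CDS length; completeness failure is a return state, never an error.
Transcripts whose anchored CDS leaves an empty 5' or 3' UTR are flagged
``excluded`` and dropped from group-level statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

FLANK = 30


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as described by the GTF: exons on a chromosome."""

    transcript_id: str
    gene_id: str
    group: str
    chrom: str
    strand: str  # "+" | "-"
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted by start
    expression: float = float("nan")

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"empty or inverted exon ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = end


@dataclass(frozen=True)
class CdsAnchor:
    span: tuple[int, int] | None
    complete: bool
    ambiguous: bool = False
    internal_mismatch: bool = False


@dataclass
class AnnotatedTranscript:
    """A spliced transcript with located CDS and UTR partition."""

    transcript_id: str
    gene_id: str
    group: str
    spliced_seq: str
    exon_seqs: tuple[str, ...]  # exon pieces in transcript orientation
    junctions: tuple[int, ...]  # exon-exon boundaries, transcript coords
    introns: tuple[str, ...]  # intron sequences, transcript orientation
    cds_span: tuple[int, int] | None = None
    complete: bool = False
    ambiguous: bool = False
    internal_mismatch: bool = False
    excluded: bool = False  # complete but missing a UTR
    expression: float = float("nan")

    @property
    def utr5_seq(self) -> str:
        return self.spliced_seq[: self.cds_span[0]] if self.complete else ""

    @property
    def utr3_seq(self) -> str:
        return self.spliced_seq[self.cds_span[1] :] if self.complete else ""

    @property
    def cds_seq(self) -> str:
        return self.spliced_seq[self.cds_span[0] : self.cds_span[1]] if self.complete else ""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    try:
        chrom_seq = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} not in genome") from None
    if start < 0 or end > len(chrom_seq):
        raise ValueError(
            f"interval ({start}, {end}) outside chromosome {chrom!r} "
            f"of length {len(chrom_seq)}"
        )
    return str(chrom_seq[start:end]).upper()


def splice_in_silico(
    model: TranscriptModel, genome: Mapping[str, str]
) -> tuple[str, tuple[int, ...], tuple[str, ...]]:
    """Ligate exon sequences into the mature transcript.

    Returns (spliced sequence 5'->3', junction positions, exon pieces).
    Minus-strand transcripts are reverse-complemented with exon order
    reversed. Junctions are cumulative exon lengths, exclusive of 0 and
    the total length.
    """
    pieces = [_fetch(genome, model.chrom, s, e) for s, e in model.exons]
    if model.strand == "-":
        pieces = [_revcomp(p) for p in reversed(pieces)]
    junctions = []
    total = 0
    for p in pieces[:-1]:
        total += len(p)
        junctions.append(total)
    return "".join(pieces), tuple(junctions), tuple(pieces)


def extract_introns(model: TranscriptModel, genome: Mapping[str, str]) -> tuple[str, ...]:
    """Intron sequences (regions between adjacent exons), transcript
    orientation, in transcript order."""
    introns = [
        _fetch(genome, model.chrom, model.exons[i][1], model.exons[i + 1][0])
        for i in range(len(model.exons) - 1)
    ]
    if model.strand == "-":
        introns = [_revcomp(s) for s in reversed(introns)]
    return tuple(introns)


def anchor_cds(spliced_seq: str, reference_cds: str) -> CdsAnchor:
    """Locate the reference CDS on a spliced transcript by 30-nt flanks.

    Takes the 5'-most head-flank occurrence whose implied span yields the
    reference CDS length with a matching tail flank; any further valid
    pair sets the ambiguity flag. A span containing N is not complete.
    """
    seq = spliced_seq.upper()
    ref = reference_cds.upper()
    if len(ref) < 2 * FLANK:
        raise ValueError(f"reference CDS shorter than {2 * FLANK} nt")
    head, tail = ref[:FLANK], ref[-FLANK:]
    n = len(ref)
    valid_starts = []
    pos = seq.find(head)
    while pos != -1:
        if seq[pos + n - FLANK : pos + n] == tail:
            valid_starts.append(pos)
        pos = seq.find(head, pos + 1)
    if not valid_starts:
        return CdsAnchor(None, False)
    start = valid_starts[0]
    span = (start, start + n)
    if "N" in seq[span[0] : span[1]]:
        return CdsAnchor(None, False)
    return CdsAnchor(
        span,
        True,
        ambiguous=len(valid_starts) > 1,
        internal_mismatch=seq[span[0] : span[1]] != ref,
    )


def extract_utrs(spliced_seq: str, cds_span: tuple[int, int]) -> tuple[str, str, bool]:
    """UTR sequences flanking the CDS; third element flags an empty UTR
    (transcript excluded from group statistics)."""
    start, end = cds_span
    if not (0 <= start <= end <= len(spliced_seq)):
        raise ValueError(f"CDS span {cds_span} out of bounds")
    utr5 = spliced_seq[:start]
    utr3 = spliced_seq[end:]
    return utr5, utr3, not (utr5 and utr3)


def annotate_transcript(
    model: TranscriptModel,
    genome: Mapping[str, str],
    reference_cds: str | None,
) -> AnnotatedTranscript:
    spliced, junctions, exon_seqs = splice_in_silico(model, genome)
    introns = extract_introns(model, genome) if len(model.exons) > 1 else ()
    tx = AnnotatedTranscript(
        transcript_id=model.transcript_id,
        gene_id=model.gene_id,
        group=model.group,
        spliced_seq=spliced,
        exon_seqs=exon_seqs,
        junctions=junctions,
        introns=introns,
        expression=model.expression,
    )
    if reference_cds is None:
        return tx
    anchor = anchor_cds(spliced, reference_cds)
    tx.cds_span = anchor.span
    tx.complete = anchor.complete
    tx.ambiguous = anchor.ambiguous
    tx.internal_mismatch = anchor.internal_mismatch
    if anchor.complete:
        _, _, tx.excluded = extract_utrs(spliced, anchor.span)
    return tx


def annotate_transcripts(
    models: Iterable[TranscriptModel],
    genome: Mapping[str, str],
    cds_by_transcript: Mapping[str, str],
) -> list[AnnotatedTranscript]:
    """Annotate a transcript set; transcripts with no reference CDS record
    are carried through as incomplete."""
    return [
        annotate_transcript(m, genome, cds_by_transcript.get(m.transcript_id))
        for m in models
    ]
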