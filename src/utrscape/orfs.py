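"""Upstream ORF detection and NMD-architecture classification.

A uORF is an AUG-initiated reading frame starting in the 5'UTR, extended
in-frame to the first stop codon anywhere in the transcript. Records are
kept when they satisfy a minimum length, a relaxed Kozak context (purine
at -3 OR G at the first base after the AUG codon), and do not fully
contain the main ORF (a uORF whose reading frame swallows the main ORF
could support re-initiation and escape NMD, which is what the filter is
meant to screen out).

NMD-inducing architecture is the classic exon-junction rule: a transcript
whose most 3' exon-exon junction lies at least 55 nt downstream of the
main-ORF stop codon is flagged as a likely NMD substrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
PURINES = frozenset("AG")

#: Exon-junction distance (nt downstream of the stop codon) at or beyond
#: which a transcript is classified as NMD-inducing.
NMD_JUNCTION_THRESHOLD = 55


@dataclass(frozen=True)
class UorfRecord:
    """One upstream ORF.

    Coordinates are transcript-space, 0-based. ``start`` is the A of the
    AUG; ``stop`` is the first nt of the stop codon; ``length`` runs from
    the AUG through the stop codon inclusive. ``kozak_minus3`` is the base
    at -3 relative to the AUG (A of AUG = +1), empty when the AUG starts
    within the first 3 nt; ``kozak_plus`` is the first base after the AUG
    codon.
    """

    transcript_id: str
    start: int
    stop: int
    length: int
    kozak_minus3: str
    kozak_plus: str
    passes_filters: bool


@dataclass(frozen=True)
class NmdArchitecture:
    transcript_id: str
    #: nt from one past the main stop codon to the most 3' junction;
    #: negative when no junction lies downstream of the stop.
    last_junction_minus_stop: int
    nmd_flag: bool


def find_uorfs(
    spliced_seq: str,
    cds_span: tuple[int, int],
    transcript_id: str = "",
    *,
    min_length: int = 30,
    kozak_plus_offset: int = 3,
    include_failing: bool = False,
) -> list[UorfRecord]:
    """Enumerate uORFs starting in the 5'UTR of a spliced transcript.

    Every AUG upstream of ``cds_span[0]`` is extended in-frame to the
    first stop codon anywhere in the transcript; AUGs with no in-frame
    stop are dropped. A record passes when

    a. length (AUG through stop codon) >= ``min_length`` nt,
    b. Kozak: base at -3 is a purine, OR the base ``kozak_plus_offset``
       nt after the A of the AUG (default 3, i.e. the first base after
       the AUG codon) is G,
    c. the uORF span does not fully contain the main ORF span.

    By default only passing records are returned; ``include_failing=True``
    returns every stop-terminated upstream AUG with its flag.
    """
    if cds_span is None:
        raise ValueError("cds_span is required to scan for uORFs")
    seq = spliced_seq.upper().replace("U", "T")
    cds_start, cds_end = cds_span
    records: list[UorfRecord] = []
    for start in range(cds_start):
        if seq[start : start + 3] != "ATG":
            continue
        stop_pos = None
        for j in range(start + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                stop_pos = j
                break
        if stop_pos is None:
            continue
        length = stop_pos + 3 - start
        minus3 = seq[start - 3] if start >= 3 else ""
        plus = (
            seq[start + kozak_plus_offset]
            if start + kozak_plus_offset < len(seq)
            else ""
        )
        kozak_ok = (minus3 in PURINES) or (plus == "G")
        contains_main = start <= cds_start and stop_pos + 3 >= cds_end
        passes = length >= min_length and kozak_ok and not contains_main
        if passes or include_failing:
            records.append(
                UorfRecord(transcript_id, start, stop_pos, length, minus3, plus, passes)
            )
    return records


def classify_nmd(
    junctions: Sequence[int],
    cds_span: tuple[int, int],
    transcript_id: str = "",
    threshold: int = NMD_JUNCTION_THRESHOLD,
) -> NmdArchitecture:
    """Apply the downstream exon-junction rule.

    ``junctions`` are transcript-coordinate exon-exon boundary positions;
    the distance is measured from one past the end of the stop codon
    (``cds_span[1]``) to the most 3' junction. The flag is inclusive at
    the threshold (a junction exactly 55 nt downstream triggers it).
    """
    stop_end = cds_span[1]
    if junctions:
        distance = max(junctions) - stop_end
    else:
        distance = -stop_end  # no junction at all; certainly not downstream
    return NmdArchitecture(transcript_id, distance, distance >= threshold)


def uorf_summary(
    records_per_transcript: dict[str, list[UorfRecord]],
    groups: dict[str, str],
) -> pd.DataFrame:
    """Per-group uORF burden: % with >=1 uORF, mean count, mean length."""
    rows = []
    for tid, group in groups.items():
        recs = [r for r in records_per_transcript.get(tid, []) if r.passes_filters]
        rows.append(
            {
                "transcript_id": tid,
                "group": group,
                "n_uorfs": len(recs),
                "has_uorf": bool(recs),
                "mean_uorf_length": (
                    sum(r.length for r in recs) / len(recs) if recs else float("nan")
                ),
            }
        )
    if not rows:
        raise ValueError("no transcripts to summarise")
    df = pd.DataFrame(rows)
    return (
        df.groupby("group")
        .agg(
            n_transcripts=("transcript_id", "size"),
            pct_with_uorf=("has_uorf", lambda s: 100.0 * s.mean()),
            mean_uorfs=("n_uorfs", "mean"),
            mean_uorf_length=("mean_uorf_length", "mean"),
        )
        .reset_index()
    )
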