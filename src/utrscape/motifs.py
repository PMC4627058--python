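"""ARE and miRNA seed-site scanning in 3'UTRs.

AU-rich elements (AREs) are destabilising 3'UTR motifs built around the
core pentamer AUUUA; the functional nonamer is WWAUUUAWW with W in {A, U}.
miRNA sites are canonical seed matches between a 3'UTR and nucleotides 2-8
of a mature miRNA, graded 6mer < 7mer-A1 < 7mer-m8 < 8mer.

All sequences are handled on the DNA alphabet (T, not U); patterns are
defined in RNA terms and transcribed internally. Scanning is on the sense
strand of the mature transcript only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

ARE_PENTAMER = "AUUUA"
ARE_NONAMER = "WWAUUUAWW"

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

#: Site-type strength order used for deduplication (strongest first).
SITE_TYPE_RANK = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, "6mer": 3}


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in a transcript region.

    ``offset`` is 0-based within the region (transcript orientation);
    ``matched`` is the matched subsequence as it appears in the region
    (DNA alphabet).
    """

    transcript_id: str
    motif_id: str
    region: str
    offset: int
    matched: str


@dataclass(frozen=True)
class DensityRecord:
    """Per-transcript motif count normalised per kb of region length."""

    transcript_id: str
    motif_id: str
    count: int
    region_length: int

    @property
    def density_per_kb(self) -> float:
        return 1000.0 * self.count / self.region_length


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _w_match(base: str) -> bool:
    # W = A or U (T on the DNA alphabet)
    return base in "AT"


def scan_are(
    utr3_seq: str,
    transcript_id: str = "",
    *,
    allow_overlap: bool = True,
) -> list[MotifHit]:
    """Find all AUUUA pentamer and WWAUUUAWW nonamer occurrences.

    Overlapping matches are counted by default; ``allow_overlap=False``
    advances past each match instead. Returns hits sorted by offset with
    pentamers before nonamers at equal offset.
    """
    seq = _dna(utr3_seq)
    hits: list[MotifHit] = []
    core = "ATTTA"
    i = 0
    while i <= len(seq) - 5:
        if seq[i : i + 5] == core:
            hits.append(MotifHit(transcript_id, "AUUUA", "utr3", i, seq[i : i + 5]))
            i += 1 if allow_overlap else 5
        else:
            i += 1
    i = 0
    while i <= len(seq) - 9:
        window = seq[i : i + 9]
        if (
            window[2:7] == core
            and _w_match(window[0])
            and _w_match(window[1])
            and _w_match(window[7])
            and _w_match(window[8])
        ):
            hits.append(MotifHit(transcript_id, "WWAUUUAWW", "utr3", i, window))
            i += 1 if allow_overlap else 9
        else:
            i += 1
    return sorted(hits, key=lambda h: (h.offset, h.motif_id))


def are_density(hits: Iterable[MotifHit], utr3_length: int, transcript_id: str = "") -> dict[str, DensityRecord]:
    """Per-kb density of each ARE motif for one transcript."""
    if utr3_length <= 0:
        raise ValueError("3'UTR length must be positive for density computation")
    counts = {"AUUUA": 0, "WWAUUUAWW": 0}
    for h in hits:
        if h.motif_id in counts:
            counts[h.motif_id] += 1
    return {
        m: DensityRecord(transcript_id, m, c, utr3_length) for m, c in counts.items()
    }


def mirna_seed(mirna_seq: str) -> str:
    """Nucleotides 2-8 (1-based from the 5' end) of a mature miRNA, as DNA."""
    seq = _dna(mirna_seq)
    if len(seq) < 8:
        raise ValueError(f"mature miRNA too short for seed extraction: {len(seq)} nt")
    return seq[1:8]


def scan_mirna_sites(
    utr3_seq: str,
    mirna_seq: str,
    mirna_name: str = "mirna",
    transcript_id: str = "",
    site_types: Sequence[str] = ("8mer", "7mer-m8", "7mer-A1", "6mer"),
) -> list[MotifHit]:
    """Canonical seed-match site detection on a 3'UTR.

    Site grammar (UTR read 5'->3'; ``rc`` = reverse complement):

    * 6mer     — rc(seed nt 2-7)
    * 7mer-m8  — rc(seed nt 2-8)
    * 7mer-A1  — rc(seed nt 2-7) followed by A (opposite miRNA nt 1)
    * 8mer     — rc(seed nt 2-8) followed by A

    Each maximal site is reported once with its strongest type
    (8mer > 7mer-m8 > 7mer-A1 > 6mer). Offsets are 0-based positions of the
    site start within the UTR; 7mer-m8/8mer sites start one base 5' of the
    6mer core because they include the m8 match.
    """
    utr = _dna(utr3_seq)
    seed = mirna_seed(mirna_seq)  # miRNA nt 2-8
    core6 = reverse_complement(seed[:6])  # rc of nt 2-7
    m8_base = reverse_complement(seed[6])  # UTR base pairing miRNA nt 8
    wanted = set(site_types)
    hits: list[MotifHit] = []
    for i in range(len(utr) - 5):
        if utr[i : i + 6] != core6:
            continue
        has_m8 = i >= 1 and utr[i - 1] == m8_base
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            stype, start, length = "8mer", i - 1, 8
        elif has_m8:
            stype, start, length = "7mer-m8", i - 1, 7
        elif has_a1:
            stype, start, length = "7mer-A1", i, 7
        else:
            stype, start, length = "6mer", i, 6
        if stype in wanted:
            hits.append(
                MotifHit(
                    transcript_id,
                    f"mirna:{mirna_name}:{stype}",
                    "utr3",
                    start,
                    utr[start : start + length],
                )
            )
    return hits


def mirna_site_summary(
    hits_per_transcript: dict[str, list[MotifHit]],
    utr3_lengths: dict[str, int],
    groups: dict[str, str],
) -> pd.DataFrame:
    """Group-level miRNA-site statistics.

    Emits, per group, both the percentage of transcripts carrying at least
    one site and the mean per-kb site density. The two statistics dissociate
    when groups differ in 3'UTR length: with sites planted at equal density,
    short-UTR groups show fewer transcripts with a site even though the
    density is identical — the length confound the density view removes.
    """
    rows = []
    for tid, group in groups.items():
        if tid not in utr3_lengths:
            continue
        n_sites = len(hits_per_transcript.get(tid, []))
        rows.append(
            {
                "transcript_id": tid,
                "group": group,
                "n_sites": n_sites,
                "has_site": n_sites > 0,
                "density_per_kb": 1000.0 * n_sites / utr3_lengths[tid],
            }
        )
    if not rows:
        raise ValueError("no transcripts to summarise")
    df = pd.DataFrame(rows)
    out = (
        df.groupby("group")
        .agg(
            n_transcripts=("transcript_id", "size"),
            pct_with_site=("has_site", lambda s: 100.0 * s.mean()),
            sites_per_kb=("density_per_kb", "mean"),
        )
        .reset_index()
    )
    return out
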