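"""Nucleotide composition per transcript region and splice-site GC profiles.

GC fraction is (G+C)/(A+C+G+T); N bases are excluded from the denominator,
so gc_frac + au_frac == 1 for any N-free sequence. Positional profiles are
computed in transcript orientation across a window of exonic and intronic
flank on each side of every splice site, averaged with equal weight per
site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class CompositionRecord:
    transcript_id: str
    region: str  # utr5 | cds | utr3 | intron | whole
    gc_frac: float
    au_frac: float
    length: int


@dataclass
class JunctionProfile:
    """Per-position GC fraction and base frequencies around splice sites.

    ``site_kind`` is "donor" (exon|intron boundary) or "acceptor"
    (intron|exon boundary). Position +1 is the first base after the
    boundary (first intronic base at a donor, first exonic base at an
    acceptor); -1 is the last base before it; there is no position 0.
    """

    site_kind: str
    positions: np.ndarray  # e.g. -50..-1, 1..50
    gc: np.ndarray  # mean GC per position (nan where no coverage)
    base_freq: np.ndarray  # (n_positions, 4) A,C,G,T frequencies
    n_sites: np.ndarray  # contributing sites per position

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.base_freq, columns=[f"freq_{b}" for b in _BASES])
        df.insert(0, "site_kind", self.site_kind)
        df.insert(1, "position", self.positions)
        df.insert(2, "gc", self.gc)
        df["n_sites"] = self.n_sites
        return df


def composition(seq: str, region: str = "whole", transcript_id: str = "") -> CompositionRecord:
    """GC/AU fractions of one sequence (N excluded from the denominator)."""
    if not seq:
        raise ValueError("cannot compute composition of an empty sequence")
    counts = Counter(seq.upper().replace("U", "T"))
    denom = sum(counts[b] for b in _BASES)
    if denom == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    gc = (counts["G"] + counts["C"]) / denom
    au = (counts["A"] + counts["T"]) / denom
    return CompositionRecord(transcript_id, region, gc, au, len(seq))


def _accumulate(flank_pairs, half_window: int):
    """flank_pairs: iterable of (upstream_seq, downstream_seq) per site,
    each in transcript orientation, possibly shorter than half_window."""
    n_pos = 2 * half_window
    base_counts = np.zeros((n_pos, 4), dtype=np.int64)
    n_sites = np.zeros(n_pos, dtype=np.int64)
    for up, down in flank_pairs:
        up = up.upper()[-half_window:]
        down = down.upper()[:half_window]
        # upstream fills positions -len(up)..-1 (indices half_window-len..half_window-1)
        for offset, base in enumerate(up):
            idx = half_window - len(up) + offset
            if base in _BASE_IDX:
                base_counts[idx, _BASE_IDX[base]] += 1
                n_sites[idx] += 1
        for offset, base in enumerate(down):
            idx = half_window + offset
            if base in _BASE_IDX:
                base_counts[idx, _BASE_IDX[base]] += 1
                n_sites[idx] += 1
    return base_counts, n_sites


def junction_profile_from_flanks(
    flank_pairs: Iterable[tuple[str, str]],
    site_kind: str,
    half_window: int = 50,
) -> JunctionProfile:
    """Build a positional profile from (upstream, downstream) flank pairs.

    Sites with insufficient flank contribute only at the positions they
    cover; the per-position site count tracks this.
    """
    base_counts, n_sites = _accumulate(flank_pairs, half_window)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = base_counts / n_sites[:, None]
        gc = (base_counts[:, 1] + base_counts[:, 2]) / n_sites
    positions = np.concatenate(
        [np.arange(-half_window, 0), np.arange(1, half_window + 1)]
    )
    return JunctionProfile(site_kind, positions, gc, freq, n_sites)


def junction_gc_profile(
    annotated: Iterable,
    half_window: int = 50,
) -> dict[str, JunctionProfile]:
    """Donor and acceptor GC profiles across an annotated transcript set.

    ``annotated`` yields objects with ``exon_seqs`` (spliced exon pieces in
    transcript orientation) and ``introns`` (intron sequences in transcript
    orientation). Each splice site contributes with equal weight.
    """
    donor_pairs: list[tuple[str, str]] = []
    acceptor_pairs: list[tuple[str, str]] = []
    any_intron = False
    for tx in annotated:
        exons = tx.exon_seqs
        introns = tx.introns
        for i, intron in enumerate(introns):
            any_intron = True
            donor_pairs.append((exons[i], intron))
            acceptor_pairs.append((intron, exons[i + 1]))
    if not any_intron:
        raise ValueError("no intron-containing transcripts in the input set")
    return {
        "donor": junction_profile_from_flanks(donor_pairs, "donor", half_window),
        "acceptor": junction_profile_from_flanks(acceptor_pairs, "acceptor", half_window),
    }


def frequency_matrix(flanks: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Column-stochastic base-frequency matrix of aligned flanks.

    Returns ``(freq, ic)`` where ``freq`` has shape (length, 4) in A,C,G,T
    order and ``ic`` is the per-column information content in bits
    (2 - Shannon entropy of the column frequencies).
    """
    if not flanks:
        raise ValueError("no flank sequences given")
    length = len(flanks[0])
    if any(len(f) != length for f in flanks):
        raise ValueError("flank sequences must be aligned and equal-length")
    counts = np.zeros((length, 4), dtype=np.int64)
    for f in flanks:
        for i, base in enumerate(f.upper().replace("U", "T")):
            if base in _BASE_IDX:
                counts[i, _BASE_IDX[base]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("a column contains no A/C/G/T bases")
    freq = counts / totals
    logf = np.zeros_like(freq)
    np.log2(freq, out=logf, where=freq > 0)
    entropy = -(freq * logf).sum(axis=1)
    return freq, 2.0 - entropy
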