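"""Independent brute-force oracles used to validate the scanners.

These deliberately avoid the production code paths: plain sliding
windows, explicit substring construction, and exhaustive structure
enumeration.
"""

from __future__ import annotations

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def brute_pentamer_offsets(seq: str) -> list[int]:
    seq = seq.upper().replace("U", "T")
    return [i for i in range(len(seq) - 4) if seq[i : i + 5] == "ATTTA"]


def brute_nonamer_offsets(seq: str) -> list[int]:
    seq = seq.upper().replace("U", "T")
    out = []
    for i in range(len(seq) - 8):
        w = seq[i : i + 9]
        if (
            w[2:7] == "ATTTA"
            and all(w[j] in "AT" for j in (0, 1, 7, 8))
        ):
            out.append(i)
    return out


def brute_mirna_sites(utr: str, mirna: str) -> set[tuple[int, str]]:
    """All maximal seed sites as (start, type), strongest type per site.

    Built from explicit target strings: t6 = rc(seed nt2-7), t7m8 =
    rc(seed nt2-8), t7a1 = t6 + 'A', t8 = t7m8 + 'A'.
    """
    utr = utr.upper().replace("U", "T")
    mirna = mirna.upper().replace("U", "T")
    seed27 = mirna[1:7]
    seed28 = mirna[1:8]
    t6, t7m8 = rc(seed27), rc(seed28)
    t7a1, t8 = t6 + "A", t7m8 + "A"

    def occ(t):
        return {i for i in range(len(utr) - len(t) + 1) if utr[i : i + len(t)] == t}

    o8, o7m8, o7a1, o6 = occ(t8), occ(t7m8), occ(t7a1), occ(t6)
    sites: set[tuple[int, str]] = set()
    for s in o8:
        sites.add((s, "8mer"))
    for s in o7m8 - o8:
        sites.add((s, "7mer-m8"))
    for s in o7a1:
        if s - 1 not in o8 and s - 1 not in o7m8:
            sites.add((s, "7mer-A1"))
    for s in o6:
        covered = (s - 1 in o7m8) or (s - 1 in o8) or (s in o7a1)
        if not covered:
            sites.add((s, "6mer"))
    return sites


def brute_uorfs(
    spliced: str,
    cds_span: tuple[int, int],
    min_length: int = 30,
) -> set[tuple[int, int]]:
    """(start, stop) of every filter-passing uORF, by exhaustive
    enumeration of AUG x in-frame-stop combinations."""
    seq = spliced.upper().replace("U", "T")
    cds_start, cds_end = cds_span
    stops = {"TAA", "TAG", "TGA"}
    out: set[tuple[int, int]] = set()
    for p in range(cds_start):
        if seq[p : p + 3] != "ATG":
            continue
        inframe_stops = [
            q
            for q in range(p + 3, len(seq) - 2)
            if (q - p) % 3 == 0 and seq[q : q + 3] in stops
        ]
        if not inframe_stops:
            continue
        q = min(inframe_stops)
        length = q + 3 - p
        minus3 = seq[p - 3] if p >= 3 else ""
        plus = seq[p + 3] if p + 3 < len(seq) else ""
        kozak = minus3 in ("A", "G") or plus == "G"
        contains_main = p <= cds_start and q + 3 >= cds_end
        if length >= min_length and kozak and not contains_main:
            out.add((p, q))
    return out


PAIR_WEIGHT = {
    ("A", "T"): 2, ("T", "A"): 2,
    ("C", "G"): 3, ("G", "C"): 3,
    ("G", "T"): 1, ("T", "G"): 1,
}


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every valid set of base pairs (nested, min hairpin loop)."""
    seq = seq.upper().replace("U", "T")

    def gen(i: int, j: int):
        if i > j:
            yield frozenset()
            return
        # base i unpaired
        for s in gen(i + 1, j):
            yield s
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) not in PAIR_WEIGHT:
                continue
            for left in gen(i + 1, k - 1):
                for right in gen(k + 1, j):
                    yield frozenset({(i, k)}) | left | right

    yield from gen(0, len(seq) - 1)


def brute_fold_score(seq: str, min_loop: int = 3) -> float:
    """Optimal (most negative) weighted-pair score over all structures."""
    seq = seq.upper().replace("U", "T")
    best = 0
    for structure in enumerate_structures(seq, min_loop):
        w = sum(PAIR_WEIGHT[(seq[a], seq[b])] for a, b in structure)
        best = max(best, w)
    return -float(best)


def brute_substring_positions(haystack: str, needle: str) -> list[int]:
    return [
        i
        for i in range(len(haystack) - len(needle) + 1)
        if haystack[i : i + len(needle)] == needle
    ]
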