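"""ARE and miRNA seed-site scanner behaviour against brute-force oracles."""

import pytest

from utrscape.motifs import (
    MotifHit,
    are_density,
    mirna_site_summary,
    reverse_complement,
    scan_are,
    scan_mirna_sites,
)

from conftest import random_seq
from oracles import brute_mirna_sites, brute_nonamer_offsets, brute_pentamer_offsets


def pentamer_offsets(hits):
    return [h.offset for h in hits if h.motif_id == "AUUUA"]


def nonamer_offsets(hits):
    return [h.offset for h in hits if h.motif_id == "WWAUUUAWW"]


class TestAreScan:
    @pytest.mark.parametrize(
        "seq,pent,nona",
        [
            ("ATTTA", [0], []),
            ("ATTTATTTA", [0, 4], []),  # overlapping matches both counted
            ("AAATTTAAA", [2], [0]),
            ("CAATTTAAA", [2], []),  # C at a W position kills the nonamer
            ("GCGCGCGC", [], []),
            ("AUUUA", [0], []),  # RNA alphabet accepted
        ],
    )
    def test_known_patterns(self, seq, pent, nona):
        hits = scan_are(seq)
        assert pentamer_offsets(hits) == pent
        assert nonamer_offsets(hits) == nona

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 500))
            seq = random_seq(rng, n, au=float(rng.uniform(0.3, 0.8)))
            hits = scan_are(seq)
            assert pentamer_offsets(hits) == brute_pentamer_offsets(seq)
            assert nonamer_offsets(hits) == brute_nonamer_offsets(seq)

    def test_count_additivity_with_neutral_spacer(self, rng):
        # GC-only spacer cannot take part in any AU-rich match
        for _ in range(30):
            a = random_seq(rng, 120, au=0.7)
            b = random_seq(rng, 80, au=0.7)
            joined = a + "GCGCGCGCG" + b
            assert len(scan_are(joined)) == len(scan_are(a)) + len(scan_are(b))

    def test_no_overlap_mode_advances_past_matches(self):
        hits = scan_are("ATTTATTTA", allow_overlap=False)
        assert pentamer_offsets(hits) == [0]

    def test_density_arithmetic(self):
        hits = scan_are("ATTTA" + "G" * 200 + "ATTTA")
        recs = are_density(hits, 500)
        assert recs["AUUUA"].density_per_kb == pytest.approx(4.0)
        assert recs["WWAUUUAWW"].density_per_kb == 0.0
        with pytest.raises(ValueError):
            are_density([], 0)


class TestMirnaSites:
    MIRNA = "UGAGGUAGUAGGUUGUAUAGUU"  # 22 nt; seed (nt 2-8) = GAGGUAG

    def test_constructed_8mer_and_weaker_variants(self):
        seed28 = self.MIRNA[1:8].replace("U", "T")
        core8 = reverse_complement(seed28)  # pairs miRNA nt 2-8
        utr8 = "CCGG" + core8 + "A" + "CCGG"
        (hit,) = scan_mirna_sites(utr8, self.MIRNA, "let7")
        assert hit.motif_id.endswith("8mer") and hit.offset == 4
        utr7m8 = "CCGG" + core8 + "C" + "CCGG"
        (hit,) = scan_mirna_sites(utr7m8, self.MIRNA, "let7")
        assert hit.motif_id.endswith("7mer-m8") and hit.offset == 4
        # drop the m8 base, keep the A1 anchor
        utr7a1 = "CCGG" + core8[1:] + "A" + "CCGG"
        (hit,) = scan_mirna_sites(utr7a1, self.MIRNA, "let7")
        assert hit.motif_id.endswith("7mer-A1") and hit.offset == 4
        utr6 = "CCGG" + core8[1:] + "C" + "CCGG"
        (hit,) = scan_mirna_sites(utr6, self.MIRNA, "let7")
        assert hit.motif_id.endswith("6mer") and hit.offset == 4

    def test_each_site_reported_once_with_strongest_type(self):
        seed28 = self.MIRNA[1:8].replace("U", "T")
        utr = "GG" + reverse_complement(seed28) + "A" + "GG"
        hits = scan_mirna_sites(utr, self.MIRNA)
        assert len(hits) == 1 and hits[0].motif_id.endswith("8mer")

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            scan_mirna_sites("ACGTACGT", "ACGTACG")

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(300):
            utr = random_seq(rng, int(rng.integers(10, 500)), au=0.6)
            mirna = random_seq(rng, 22, au=0.5)
            got = {
                (h.offset, h.motif_id.rsplit(":", 1)[1])
                for h in scan_mirna_sites(utr, mirna)
            }
            assert got == brute_mirna_sites(utr, mirna)


class TestSiteSummary:
    def test_all_or_none(self):
        hits = {
            "t1": [MotifHit("t1", "mirna:m:6mer", "utr3", 0, "AAAAAA")],
            "t2": [MotifHit("t2", "mirna:m:6mer", "utr3", 3, "AAAAAA")],
        }
        groups = {"t1": "g", "t2": "g"}
        out = mirna_site_summary(hits, {"t1": 100, "t2": 200}, groups)
        assert out.loc[0, "pct_with_site"] == 100.0
        out0 = mirna_site_summary({}, {"t1": 100, "t2": 200}, groups)
        assert out0.loc[0, "pct_with_site"] == 0.0

    def test_equal_density_unequal_percentage_under_length_confound(self, rng):
        # one site per kb planted uniformly: short-UTR group shows fewer
        # transcripts with a site although density is matched
        hits, lengths, groups = {}, {}, {}
        for i in range(300):
            short = i % 2 == 0
            tid = f"t{i}"
            L = 400 if short else 4000
            n_sites = rng.poisson(L / 1000.0)
            hits[tid] = [
                MotifHit(tid, "mirna:m:6mer", "utr3", j, "NNNNNN")
                for j in range(n_sites)
            ]
            lengths[tid] = L
            groups[tid] = "short" if short else "long"
        out = mirna_site_summary(hits, lengths, groups).set_index("group")
        assert out.loc["short", "sites_per_kb"] == pytest.approx(
            out.loc["long", "sites_per_kb"], rel=0.35
        )
        assert out.loc["short", "pct_with_site"] < out.loc["long", "pct_with_site"] - 30
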