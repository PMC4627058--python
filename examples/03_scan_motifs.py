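"""Scan a 3'UTR for ARE motifs and miRNA seed sites.

AREs: the AUUUA pentamer and the WWAUUUAWW nonamer (W = A/U), counted
with overlaps. miRNA sites: canonical seed matches to miRNA nt 2-8,
graded 6mer < 7mer-A1 < 7mer-m8 < 8mer.
"""

from utrscape import are_density, scan_are, scan_mirna_sites
from utrscape.motifs import reverse_complement

utr3 = "GGCC" + "ATTTA" + "CCG" + "AAATTTAAT" + "GG" + "ATTTATTTA" + "CCGG"
hits = scan_are(utr3, "demo-tx")
for h in hits:
    print(f"  {h.motif_id:<10} at {h.offset:>3}  {h.matched}")
dens = are_density(hits, len(utr3), "demo-tx")
print(f"pentamer density: {dens['AUUUA'].density_per_kb:.1f} per kb "
      f"({dens['AUUUA'].count} hits in {len(utr3)} nt)")

# build a UTR carrying one perfect 8mer site for a mature miRNA:
mirna = "UGAGGUAGUAGGUUGUAUAGUU"
seed_match = reverse_complement(mirna[1:8].replace("U", "T"))  # pairs nt 2-8
utr = "CCGGCC" + seed_match + "A" + "GGCCGG"
for h in scan_mirna_sites(utr, mirna, "let-7-like"):
    print(f"  {h.motif_id} at {h.offset}: {h.matched}")
# The site type encodes predicted efficacy: an 8mer (seed match plus the
# A1 anchor) is the strongest canonical site class.
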