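"""Detect upstream ORFs and NMD-inducing transcript architecture.

uORFs must be >=30 nt, have a favourable Kozak context (purine at -3 or
G right after the AUG codon), and must not contain the main ORF. The
NMD rule flags transcripts whose most 3' exon-exon junction lies >=55 nt
downstream of the stop codon.
"""

from utrscape import classify_nmd, find_uorfs

main_orf = "ATG" + "GCT" * 18 + "TAA"

# 5'UTR with one passing uORF (A at -3, 30 nt long)
utr5 = "CC" + "A" + "CC" + "ATG" + "CCT" * 8 + "TAA" + "CCGG"
spliced = utr5 + main_orf + "G" * 200
cds_span = (len(utr5), len(utr5) + len(main_orf))

for u in find_uorfs(spliced, cds_span, "demo-tx"):
    print(
        f"uORF at {u.start}-{u.stop + 3} ({u.length} nt), "
        f"Kozak -3={u.kozak_minus3!r} +4={u.kozak_plus!r}"
    )

# junction 60 nt past the stop codon -> NMD substrate architecture
for dist in (40, 60):
    junctions = [cds_span[0] + 30, cds_span[1] + dist]
    nmd = classify_nmd(junctions, cds_span, "demo-tx")
    print(f"junction {dist} nt past stop: NMD flag = {nmd.nmd_flag}")
# Only the 60-nt case is flagged: the exon-junction complex left behind
# after splicing is far enough downstream of termination to trigger decay.
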