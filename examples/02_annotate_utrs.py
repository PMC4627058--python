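"""Derive UTRs from exon coordinates + reference CDS records.

Splices a transcript in silico from a toy genome, anchors the reference
CDS by its 30-nt terminal flanks, and partitions the transcript into
5'UTR / CDS / 3'UTR.
"""

from utrscape import GroupSpec, annotate_transcripts, simulate_transcriptome

spec = GroupSpec(name="demo", n_genes=3, utr5_len_dist=(120.0, 0.3),
                 utr3_len_dist=(400.0, 0.3))
ds = simulate_transcriptome([spec], seed=2)

annotated = annotate_transcripts(ds.models, ds.genome, ds.cds)
for tx in annotated:
    print(
        f"{tx.transcript_id} [{'complete' if tx.complete else 'incomplete'}] "
        f"5'UTR {len(tx.utr5_seq)} nt | CDS {tx.cds_span} | "
        f"3'UTR {len(tx.utr3_seq)} nt | junctions at {tx.junctions}"
    )

# A corrupted reference CDS (one base flipped inside the 5' flank) can no
# longer be anchored: the transcript is flagged incomplete, not guessed at.
bad_cds = {tid: "A" + cds[1:] if cds[0] != "A" else "C" + cds[1:]
           for tid, cds in ds.cds.items()}
bad = annotate_transcripts(ds.models, ds.genome, bad_cds)
print("complete after flank corruption:", sum(t.complete for t in bad), "of", len(bad))
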