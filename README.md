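# utrscape

Post-transcriptional feature analysis for mRNA families, from genome and
transcript coordinates to group-level statistics — with a synthetic
transcriptome simulator that makes every stage verifiable against planted
ground truth.

## Who this is for

Transcriptomics researchers asking how the untranslated regions of a gene
family shape its expression. The motivating case is the mouse olfactory
receptor (*Olfr*-like) family: hundreds of related mRNAs whose 3′UTRs are
unusually short and AU-rich, dense in AU-rich elements (AREs), poor in
miRNA seed sites, and whose 5′UTRs are uORF-rich and weakly structured —
a profile that correlates with expression. The package implements that
whole analysis as a tested, reusable library for any grouped transcript
set.

## What it computes

Given a genome FASTA, transcript exon coordinates (GTF), reference coding
sequences (FASTA), gene-level expression (TSV) and optional mature miRNA
sequences:

1. **UTR annotation** — exons are spliced in silico (minus-strand
   transcripts reverse-complemented); the reference CDS is anchored by
   exact matching of its first and last 30 nt; transcripts where both
   flanks match with the correct implied length are *complete* and
   partitioned into 5′UTR / CDS / 3′UTR, with exon-exon junction
   positions carried in transcript coordinates.
2. **Composition** — GC/AU fractions per region; positional GC profiles
   (−50…+50) and base-frequency/information-content matrices around
   splice donors and acceptors.
3. **Motif scanning** — ARE occurrences (AUUUA pentamer, WWAUUUAWW
   nonamer, W ∈ {A,U}; overlaps counted) and per-kb densities; canonical
   miRNA seed sites (6mer, 7mer-A1, 7mer-m8, 8mer on miRNA nt 2–8), with
   both percent-of-transcripts-with-site and sites-per-kb summaries so
   the short-3′UTR confound is separable.
4. **uORFs and NMD architecture** — upstream ORFs ≥30 nt with a relaxed
   Kozak filter (purine at −3 **or** G immediately after the AUG codon)
   that do not contain the main ORF; transcripts whose last exon-exon
   junction lies ≥55 nt downstream of the stop codon are flagged as
   NMD-inducing.
5. **5′UTR structure** — a deterministic weighted base-pair DP
   (Nussinov-style; GC=3, AU=2, GU=1, min loop 3) as a built-in structure
   proxy, or RNAfold through a subprocess adapter for true mfe; group
   comparisons are made on length-matched samples (k per group from a
   common 5′UTR-length window).
6. **Statistics** — a per-transcript feature table joined to expression;
   pairwise Mann-Whitney U group comparisons with figure-style
   significance tiers; OLS regressions of log10(FPKM) on any feature,
   deduplicated to one max-expression transcript per gene.

The **synthetic module** generates all the above inputs with planted,
recorded truth (group-specific UTR length distributions, AU content, ARE
density, uORF burden, NMD-architecture fraction, and a linear
feature→expression model), so the pipeline can be validated end to end
without any external data.

## Worked example

```bash
python examples/06_group_statistics.py
```

prints (seed 7, quarter-scale default conditions):

```
309 transcripts analysed

group       n  3UTR med   AU5 %  ARE/kb  uORF %
ctrl      147      1956    40.5     4.9    32.7
gpcr       23      1534    37.9     4.7    34.8
olfr1      14       820    59.7    10.0    64.3
olfr2     125      1234    60.0     9.7    72.8

expression regressions (slope of log10 FPKM on the feature):
  olfr2:are_pentamer_density   slope   0.045  p 0.0017
  olfr2:gc_utr5                slope  -1.577  p 0.19
  gpcr:gc_utr5                 slope   4.097  p 0.4
```

Reading it: the two olfr-like classes have much shorter 3′UTRs and ~60%
5′UTR AU content versus ~40% in controls, about twice the control ARE
density, and roughly double the uORF prevalence; within the large
olfr-like class, expression rises significantly with ARE density. The
remaining examples (`examples/01…05`) walk through each capability —
simulation, annotation, motif scanning, uORF/NMD calling, folding — one
at a time.

A thin CLI wraps the same pipeline:

```bash
utrscape simulate --seed 1 --outdir sim/
utrscape annotate --genome sim/genome.fa --gtf sim/transcripts.gtf \
    --cds sim/cds.fa --expression sim/expression.tsv --outdir out/
utrscape run --seed 1 --outdir out/   # simulate + annotate + report
```

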