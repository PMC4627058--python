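# Methods

This note documents what each stage of the pipeline computes, the
conventions and defaults it uses, what the synthetic generator does and
does not emulate, and the design choices made where the problem was
genuinely open.

## Transcript annotation

Exon coordinates are read from GTF (1-based inclusive) and converted to
0-based half-open internally; every reported transcript-space coordinate
is 0-based half-open, 5′→3′ in transcript orientation. Splicing
concatenates exon sequences; minus-strand transcripts are
reverse-complemented with exon order reversed. Junction positions are
cumulative exon lengths (exclusive of 0 and the total).

The coding region is located by **flank anchoring**: the first and last
30 nt of the supplied reference CDS are matched exactly
(case-insensitively, DNA alphabet) against the spliced transcript. A
transcript is *complete* when a head-flank occurrence and a tail-flank
occurrence imply a span whose length equals the reference CDS length.
Conventions where the procedure is underdetermined:

- multiple valid flank pairs: the 5′-most is taken and an `ambiguous`
  flag is set;
- the interior of the span is *not* required to match the reference
  base-for-base (an `internal_mismatch` flag records when it does not);
  only the implied length must agree;
- any N inside the span marks the transcript incomplete;
- a complete transcript with an empty 5′ or 3′UTR is flagged `excluded`
  and omitted from group statistics (both UTRs must be detectable).

Incompleteness is a return state, never an error: corrupted or
unanchored references simply yield incomplete transcripts.

## Composition and splice-site profiles

GC fraction is (G+C)/(A+C+G+T) with N excluded from the denominator, so
gc + au = 1 on N-free sequence. Splice-site profiles take up to 50 nt of
exonic and intronic flank on each side of every donor (exon|intron) and
acceptor (intron|exon) boundary, in transcript orientation. Position +1
is the first base after the boundary; −1 the last before it; there is no
position 0. Sites contribute with equal weight (per site, not per
transcript), and positions with insufficient flank are skipped with the
per-position site count tracked. Frequency matrices are column-stochastic
with per-column information content 2 − H bits; logo rendering is out of
scope.

## ARE and miRNA seed scanning

Sequences are handled as DNA (T for U) and patterns transcribed
internally. The ARE scanner reports **all** occurrences of AUUUA and
WWAUUUAWW, overlaps included (a `--no-overlap` style flag provides the
alternative); densities are 1000·count/region-length. Scanning is on the
sense strand of the mature transcript only, in the 3′UTR.

miRNA sites use the canonical seed grammar on miRNA nt 2–8 without
conservation or context scoring: reading the UTR 5′→3′, a 6mer is the
reverse complement of seed nt 2–7; adding the m8 match extends it to a
7mer-m8; an A opposite miRNA position 1 gives 7mer-A1; both give an
8mer. Each maximal site is reported once with its strongest type. Group
summaries emit both the percentage of transcripts with ≥1 site and the
per-kb density, because the two dissociate when groups differ in 3′UTR
length — the central confound in comparing short-UTR and long-UTR gene
groups.

## uORFs and NMD architecture

Every AUG upstream of the main-ORF start is extended in frame to the
first stop codon anywhere in the transcript (AUGs with no in-frame stop
are dropped). A record passes when:

1. length ≥ 30 nt, counted AUG through stop codon inclusive (so a
   10-codon ORF passes exactly at the boundary);
2. Kozak: the base at −3 (A of AUG = +1) is a purine, **or** the first
   base after the AUG codon is G. The published rule names "+1" for the
   post-AUG guanine, which is unsatisfiable under the stated A=+1
   numbering; we implement the standard Kozak position (the base at +4
   in that numbering) and expose the offset as a parameter;
3. the uORF span does not fully contain the main ORF span (the most
   literal reading of the containment filter; it screens out upstream
   starts that would simply re-encode the main ORF and permit
   re-initiation). Out-of-frame uORFs overlapping into the CDS are
   allowed; nested or overlapping uORFs each yield their own record.

NMD architecture: a transcript is flagged when its most 3′ exon-exon
junction lies ≥ 55 nt downstream of the position one past the stop
codon. The comparison is inclusive at 55 — the classic exon-junction
rule — and the threshold is a parameter; behaviour at 54/55/56 is
pinned by tests.

## 5′UTR structure scoring

The internal engine is a Nussinov-style dynamic program maximising
stacking-weighted pairs (GC=3, AU=2, GU=1; Watson-Crick plus GU wobble)
with a minimum hairpin loop of 3 nt; the score is the negated optimal
weight, ≤ 0, with 0 for unpairable sequence. It is a deterministic
structure *proxy* on a dimensionless scale, deliberately not a
thermodynamic model: it preserves the shape of the analysis (ranking
more- vs less-structured UTRs) while remaining exactly checkable against
exhaustive structure enumeration. Traceback prefers pairing the 5′-most
base with the smallest valid partner on ties, making the dot-bracket
deterministic. The O(n³) kernel is numba-compiled.

The external engine wraps an RNAfold-dialect executable (sequence on
stdin, "structure (mfe)" out, kcal/mol). Engine resolution happens once
at startup: a requested-but-absent external engine degrades to the
internal one with a warning, while a failure mid-run raises — scores
from different engines are never mixed in one comparison, and every
result carries engine provenance.

Because 5′UTR length itself drives any stability score, group
comparisons fold a **length-matched sample**: k (default 50) transcripts
per group drawn from a common length window. The default window is the
intersection of per-group IQRs; when a short-UTR group makes that empty,
it relaxes to the 10th–90th percentile intersection, then the full-range
intersection, with a warning; truly disjoint distributions are an error.
When fewer than k transcripts fall in the window, the attainable k is
used (or reported, depending on the caller).

## Statistics

The feature table has one row per complete, UTR-bearing transcript.
Expression is gene-level FPKM inherited by the gene's transcripts;
regressions use log10(FPKM) with FPKM ≤ 0 rows excluded, on one
max-expression transcript per gene by default to avoid pseudo-replicating
a gene-level measurement across isoforms. Group contrasts default to
two-sided Mann-Whitney U (Welch t-test by flag) with significance tiers
\*<0.05, \*\*<0.01, \*\*\*<0.001, \*\*\*\*<0.0001; fully degenerate
(all-ties) comparisons return p=1. No multiple-testing correction is
applied by default; Benjamini-Hochberg is available by flag. Report
bundles round floats to 10 digits and serialise with sorted keys, so an
identical (config, seed) pair reproduces byte-identical JSON.

## Synthetic transcriptome generator

The generator is the package's verification instrument: it emits a
genome FASTA, GTF, reference-CDS FASTA, expression TSV, miRNA FASTA and
a truth sidecar, with the truth set by re-scanning the emitted sequences
— recorded truth can therefore never drift from what is actually
present, and the tests additionally require the *intended* planted
counts to equal the re-scan (exactness of planting, not just
bookkeeping).

Per transcript: UTR lengths are log-normal (median, sigma; sigma
defaults to 0.5 where no spread is published); the CDS is a fixed-length
random ORF (default 936 nt, GPCR-scale, configurable); 1–3 introns with
canonical GT…AG boundaries (80–400 nt, 50% GC interiors) are placed
inside the CDS, plus — for the NMD-architecture fraction — one junction
56–200 nt past the stop; genes sit on one chromosome separated by
≥500 nt random spacers (so 30-nt flank anchoring cannot match across
genes), ~50% on the minus strand.

Motif planting is rejection + insertion: background is drawn at the
target AU fraction, accidental pentamer/AUG matches are erased by
composition-preserving substitutions, then a Poisson(rate·len/1000)
number of AUUUA windows (or Poisson(λ) uORFs with A at −3, no internal
AUG, own in-frame stop) are written at random non-overlapping offsets; a
repair pass removes pentamers created incidentally at window boundaries.
Background AU is compensated for the AU-only planted windows so each
region hits its target AU fraction (tested to ±2 points at n ≥ 200).

Expression: log10(FPKM) = baseline + Σ β·feature + N(0, sd), where
features (ARE density, 5′UTR GC/AU, uORF count and length, UTR lengths)
are computed from the emitted sequences before noise is drawn.

Default study conditions (four groups) encode the published group
contrasts for the olfactory-receptor case: 3′UTR medians 786/1121 nt for
the two olfr-like classes vs 1895 (control) and 1800 (GPCR-like); 5′UTR
medians 129/240 vs 212/242 nt; 60% vs 40% 5′UTR AU; ARE rates 10 vs 5
per kb (the 2:1 published ratio; the absolute level is the package's
choice since none is published); uORF λ chosen so P(≥1 uORF) is 67% vs
38%; NMD-architecture fraction ≈2%; group sizes 55/500/92/587; effect
signs β(ARE)>0 and β(GC5′)<0 for olfr-like groups, β(GC5′)>0 for the
GPCR-like group, near-null for controls, with noise sd 0.4 on the log10
scale. The miRNA FASTA contains nine random 22-nt sequences explicitly
labelled synthetic — stand-ins for a neural miRNA panel, used only to
exercise the site-scanning machinery.

What the generator does **not** emulate: read-level noise, alternative
isoforms, splice-site sequence context beyond GT/AG, codon usage,
conservation, real miRNA repertoires, or correlated feature structure
beyond the explicit expression model. Passing tests therefore demonstrate
correctness of the algorithms and recoverability of planted effects
under idealised data, not biological validity on real transcriptomes.

## Verification strategy and problem sizes

Every scanner is checked against an independent brute-force oracle:
sliding-window enumeration for AREs (1,000 random sequences ≤500 nt),
explicit target-string construction for miRNA sites (1,000), exhaustive
AUG×stop enumeration for uORFs (1,000), and full structure enumeration
for the fold DP (500 sequences ≤15 nt). Round-trip tests require exact
UTR/CDS span recovery on a 520-transcript simulation and zero false
completes after flank corruption. Statistical calibration uses 1,000
replicate null regressions (KS test for p-value uniformity) and 1,000
replicate null group tests (type-I error within its binomial CI); power
checks use 100 expression replicates at n=500 with the default effect
sizes. These sizes keep the full suite and the acceptance script fast on
a single CPU while leaving all statistical checks well-powered.

## Known limitations

- The internal fold score is not an energy; only within-engine
  comparisons are meaningful.
- Flank anchoring requires exact 30-nt matches; a single SNV in a flank
  marks a transcript incomplete (by design, mirroring the published
  procedure, but conservative on real data).
- miRNA site counting includes all seed matches; conservation-filtered
  counts would be lower.
- Assignment of reference CDS records to transcripts is the caller's
  responsibility (keyed by transcript id); nearest-reference lookup is
  out of scope.
- Gene-level FPKM inherited by isoforms means isoform-specific
  expression effects are invisible.
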