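"""Synthetic transcriptome generator with planted, recorded ground truth.

Emulates an olfactory-epithelium-like transcript catalogue: two
olfactory-receptor-like gene classes (short 3'UTRs, AU-rich UTRs, high
ARE pentamer density, high uORF burden, expression positively coupled to
ARE density and negatively to 5'UTR GC) plus GPCR-like and control groups
with longer, GC-richer UTRs and no or opposite couplings. Group-level
defaults follow the published contrasts for those gene classes: 3'UTR
length medians 1094 nt (olfr-like overall; 786 class-I-like, 1121
class-II-like) vs 1895 (control) and 1800 (GPCR-like); 5'UTR medians
129/240 vs 212/242 nt; ~60% vs ~40% 5'UTR AU content; 2:1 ARE density;
67% vs 38% of transcripts carrying a uORF; ~2% of transcripts with an
NMD-inducing junction >55 nt past the stop codon.

Planting is by rejection + insertion: background sequence is drawn at the
target AU fraction, accidental motif matches are erased, and motifs are
written at random non-overlapping offsets. Truth counts are nevertheless
set by re-scanning the emitted sequence, so recorded truth can never
disagree with what is actually present.

Everything is emitted on the DNA alphabet (T not U); scanners transcribe
internally. GTF coordinates are 1-based inclusive; roughly half of all
genes are placed on the minus strand; genes are separated by >=500 nt of
random intergenic spacer so CDS flank anchoring cannot match across
genes.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io
from .annotation import TranscriptModel
from .composition import composition
from .motifs import scan_are
from .orfs import classify_nmd, find_uorfs

_BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")

#: features that plant_expression understands, computed on emitted sequences
EXPRESSION_FEATURES = (
    "are_density",
    "nonamer_density",
    "gc_utr5",
    "au_utr5",
    "n_uorfs",
    "mean_uorf_length",
    "utr3_len_kb",
    "utr5_len_kb",
)


@dataclass(frozen=True)
class ExpressionModel:
    """log10(FPKM) = baseline + sum(beta * feature) + Normal(0, sd)."""

    baseline_log10: float = 1.0
    betas: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.4

    def __post_init__(self):
        unknown = set(self.betas) - set(EXPRESSION_FEATURES)
        if unknown:
            raise ValueError(
                f"unknown expression feature(s) {sorted(unknown)}; "
                f"known: {EXPRESSION_FEATURES}"
            )


@dataclass(frozen=True)
class GroupSpec:
    """Generator parameters for one gene group.

    Lengths are drawn log-normally: ``median * exp(sigma * Z)``. All
    fractions are in [0, 1]; ``cds_len`` includes start and stop codons
    and must be a positive multiple of 3.
    """

    name: str
    n_genes: int
    utr5_len_dist: tuple[float, float] = (220.0, 0.5)  # (median nt, sigma)
    utr3_len_dist: tuple[float, float] = (1000.0, 0.5)
    cds_len: int = 936
    au_frac_utr5: float = 0.5
    au_frac_utr3: float = 0.5
    are_rate_per_kb: float = 0.0
    uorf_lambda: float = 0.0
    nmd_arch_frac: float = 0.0
    expr_model: ExpressionModel = field(default_factory=ExpressionModel)

    def __post_init__(self):
        for frac in (self.au_frac_utr5, self.au_frac_utr3):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"AU fraction {frac} outside [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.cds_len % 3 != 0 or self.cds_len < 6:
            raise ValueError("cds_len must be a multiple of 3 and >= 6")
        if min(self.utr5_len_dist[0], self.utr3_len_dist[0]) < 1:
            raise ValueError("UTR length medians must be >= 1 nt")
        if self.are_rate_per_kb < 0 or self.uorf_lambda < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.nmd_arch_frac <= 1.0:
            raise ValueError("nmd_arch_frac outside [0, 1]")
        if self.uorf_lambda > 0 and self.utr5_len_dist[0] < 30:
            raise ValueError(
                "invalid spec: 5'UTR median below 30 nt cannot host planted uORFs"
            )


@dataclass
class TruthRecord:
    """Ground truth for one emitted transcript."""

    transcript_id: str
    gene_id: str
    group: str
    strand: str
    utr5_span: tuple[int, int]
    cds_span: tuple[int, int]
    utr3_span: tuple[int, int]
    junctions: tuple[int, ...]
    planted_pentamers: int
    planted_uorf_starts: tuple[int, ...]
    planted_nmd: bool
    are_pentamer_count: int  # re-scanned from the emitted sequence
    are_nonamer_count: int
    n_uorfs: int
    mean_uorf_length: float
    nmd_flag: bool
    features: dict[str, float]
    log10_expression: float = float("nan")

    @property
    def fpkm(self) -> float:
        return 10.0 ** self.log10_expression


@dataclass
class SimulatedDataset:
    genome: dict[str, str]
    models: list[TranscriptModel]
    cds: dict[str, str]
    expression: pd.DataFrame
    truth: list[TruthRecord]
    mirnas: dict[str, str]

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Write FASTA/GTF/TSV/JSON artifacts; returns {name: path}."""
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "gtf": os.path.join(outdir, "transcripts.gtf"),
            "cds": os.path.join(outdir, "cds.fa"),
            "expression": os.path.join(outdir, "expression.tsv"),
            "mirnas": os.path.join(outdir, "mirnas.fa"),
            "truth": os.path.join(outdir, "truth.json"),
            "truth_tsv": os.path.join(outdir, "truth.tsv"),
        }
        _io.write_fasta(self.genome, paths["genome"])
        _io.write_gtf(self.models, paths["gtf"])
        _io.write_fasta(self.cds, paths["cds"])
        _io.write_expression(self.expression, paths["expression"])
        _io.write_fasta(self.mirnas, paths["mirnas"])
        records = [dataclasses.asdict(t) for t in self.truth]
        with open(paths["truth"], "w") as fh:
            json.dump(records, fh, indent=1, sort_keys=True)
        truth_df = pd.DataFrame(
            [
                {
                    k: v
                    for k, v in dataclasses.asdict(t).items()
                    if not isinstance(v, dict)
                }
                for t in self.truth
            ]
        )
        truth_df.to_csv(paths["truth_tsv"], sep="\t", index=False)
        return paths


def _rand_seq(rng: np.random.Generator, n: int, au_frac: float = 0.5) -> str:
    if n <= 0:
        return ""
    p = [au_frac / 2, (1 - au_frac) / 2, (1 - au_frac) / 2, au_frac / 2]
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def erase_motif(seq: str, motif: str, replace_index: int, replacement: str) -> str:
    """Remove every occurrence of ``motif`` by substituting one base
    (``replace_index`` within the motif) with ``replacement``."""
    chars = list(seq)
    for _ in range(len(seq)):  # safety bound; each pass strictly reduces matches
        changed = False
        i = seq.find(motif)
        while i != -1:
            chars[i + replace_index] = replacement
            changed = True
            i = seq.find(motif, i + 1)
        seq = "".join(chars)
        if not changed or motif not in seq:
            break
    return seq


def plant_motif(
    seq: str,
    motif: str,
    count: int,
    rng: np.random.Generator,
    min_gap: int = 0,
) -> tuple[str, list[int]]:
    """Overwrite ``count`` non-overlapping windows of ``seq`` with
    ``motif`` at uniform random offsets; returns (sequence, offsets).

    Raises when the requested count cannot be placed.
    """
    m = len(motif)
    if count == 0:
        return seq, []
    if count * (m + min_gap) > len(seq):
        raise ValueError(f"cannot place {count} x {m}-nt motifs in {len(seq)} nt")
    placed: list[int] = []
    chars = list(seq)
    for _ in range(count):
        ok = False
        for _attempt in range(200):
            pos = int(rng.integers(0, len(seq) - m + 1))
            if all(pos + m + min_gap <= q or q + m + min_gap <= pos for q in placed):
                placed.append(pos)
                chars[pos : pos + m] = motif
                ok = True
                break
        if not ok:
            raise ValueError("motif placement failed; sequence too crowded")
    return "".join(chars), sorted(placed)


def _random_codons(rng: np.random.Generator, n: int, au_frac: float, forbid_atg: bool) -> str:
    """n codons, none a stop codon, optionally none equal to ATG."""
    out = []
    while len(out) < n:
        codon = _rand_seq(rng, 3, au_frac)
        if codon in STOPS or (forbid_atg and codon == "ATG"):
            continue
        out.append(codon)
    return "".join(out)


def _make_cds(rng: np.random.Generator, length: int, au_frac: float = 0.5) -> str:
    interior = _random_codons(rng, length // 3 - 2, au_frac, forbid_atg=False)
    return "ATG" + interior + STOPS[rng.integers(0, 3)]


def _make_uorf(rng: np.random.Generator, length: int, au_frac: float) -> str:
    """A uORF of ``length`` nt (multiple of 3, >= 33) containing no
    internal ATG in any frame and no in-frame stop before its own."""
    assert length % 3 == 0 and length >= 9
    for _ in range(100):
        body = "ATG" + _random_codons(rng, length // 3 - 2, au_frac, forbid_atg=True)
        body += STOPS[rng.integers(0, 3)]
        if "ATG" not in body[1:]:
            return body
    raise RuntimeError("uORF construction failed")


def sanitize_utr5(
    utr5: list[str], planted_starts: set[int], protected: set[int]
) -> None:
    """Erase every ATG in the 5'UTR that does not start a planted uORF.

    Mutates in place. ``protected`` are positions that must not change
    (planted uORF spans and their -3 Kozak anchors); for any stray ATG at
    least one of its three bases lies outside the protected set.
    """
    while True:
        seq = "".join(utr5)
        dirty = False
        pos = seq.find("ATG")
        while pos != -1:
            if pos not in planted_starts:
                for off in (2, 0, 1):
                    if pos + off not in protected:
                        utr5[pos + off] = "C"
                        dirty = True
                        break
                else:
                    raise RuntimeError("unremovable stray ATG")  # pragma: no cover
            pos = seq.find("ATG", pos + 1)
        if not dirty:
            return


def _build_utr5(
    rng: np.random.Generator, length: int, au_frac: float, n_uorfs: int
) -> tuple[str, list[int]]:
    """5'UTR background with exactly ``n_uorfs`` planted, filter-passing
    uORFs and no other ATG anywhere."""
    utr5 = list(_rand_seq(rng, length, au_frac))
    starts: list[int] = []
    spans: list[tuple[int, int]] = []
    protected: set[int] = set()
    for _ in range(n_uorfs):
        placed = False
        for _attempt in range(100):
            max_len = min(51, ((length - 3) // 3) * 3)
            if max_len < 33:
                break
            ulen = int(rng.integers(33 // 3, max_len // 3 + 1)) * 3
            if ulen < 33:
                ulen = 33
            if length - ulen < 3:
                continue
            start = int(rng.integers(3, length - ulen + 1))
            if any(start < e + 3 and s < start + ulen + 3 for s, e in spans):
                continue
            body = _make_uorf(rng, ulen, au_frac)
            utr5[start : start + ulen] = body
            utr5[start - 3] = "A"  # Kozak -3 purine
            starts.append(start)
            spans.append((start, start + ulen))
            protected.update(range(start, start + ulen))
            protected.add(start - 3)
            placed = True
            break
        if not placed:
            break  # UTR too crowded; plant fewer (truth is re-scanned anyway)
    sanitize_utr5(utr5, set(starts), protected)
    return "".join(utr5), sorted(starts)


def _repair_pentamers(seq: str, planted: list[int]) -> str:
    """Destroy ARE pentamers created incidentally at planted-window
    boundaries (e.g. a planted trailing A completing a background TTTA).

    Only background bases are mutated; the first passes substitute T->A
    (AU-preserving), later passes C (guaranteed progress).
    """
    protected = {p + k for p in planted for k in range(5)}
    chars = list(seq)
    for attempt in range(60):
        current = "".join(chars)
        unwanted = [
            i
            for i in range(len(current) - 4)
            if current[i : i + 5] == "ATTTA" and i not in planted
        ]
        if not unwanted:
            return current
        repl = "A" if attempt < 40 else "C"
        for i in unwanted:
            for off in (2, 1, 3, 0, 4):  # prefer a middle T
                if i + off not in protected:
                    chars[i + off] = repl
                    break
    raise RuntimeError("pentamer repair did not converge")  # pragma: no cover


def _build_utr3(
    rng: np.random.Generator, length: int, au_frac: float, rate_per_kb: float
) -> tuple[str, int, list[int]]:
    """3'UTR with a planted Poisson number of ARE pentamers and no
    accidental ones. Background AU is compensated for the planted AU-only
    windows so the whole region hits the target AU fraction."""
    planted_frac = min(0.9, 5.0 * rate_per_kb / 1000.0)
    bg_au = (au_frac - planted_frac) / (1.0 - planted_frac)
    bg_au = min(1.0, max(0.0, bg_au))
    seq = _rand_seq(rng, length, bg_au)
    seq = erase_motif(seq, "ATTTA", 2, "A")  # middle T->A keeps AU content
    n = int(rng.poisson(rate_per_kb * length / 1000.0))
    n = min(n, length // 6) if length >= 5 else 0
    seq, offsets = plant_motif(seq, "ATTTA", n, rng, min_gap=0)
    seq = _repair_pentamers(seq, offsets)
    return seq, n, offsets


def _gene_structure(
    rng: np.random.Generator,
    utr5: str,
    cds: str,
    utr3: str,
    plant_nmd: bool,
) -> tuple[str, tuple[int, ...], list[tuple[int, int]], bool]:
    """Insert introns: 1-3 inside the CDS, plus one >55 nt past the stop
    when an NMD architecture is requested. Returns (pre-mRNA sense
    sequence, transcript junction positions, exon intervals in pre-mRNA
    coordinates, nmd planted?)."""
    spliced = utr5 + cds + utr3
    cds_start, cds_end = len(utr5), len(utr5) + len(cds)
    n_introns = int(rng.integers(1, 4))
    sites: set[int] = set()
    while len(sites) < n_introns:
        sites.add(int(rng.integers(cds_start + 10, cds_end - 10)))
    nmd_done = False
    if plant_nmd and len(utr3) >= 61:
        hi = min(200, len(utr3) - 1)
        dist = int(rng.integers(56, hi + 1)) if hi >= 56 else 56
        if cds_end + dist < len(spliced):
            sites.add(cds_end + dist)
            nmd_done = True
    junctions = tuple(sorted(sites))
    pieces = []
    exon_bounds = []
    prev = 0
    offset = 0
    for j in list(junctions) + [len(spliced)]:
        exon = spliced[prev:j]
        pieces.append(exon)
        exon_bounds.append((offset, offset + len(exon)))
        offset += len(exon)
        if j != len(spliced):
            intron_len = int(rng.integers(80, 401))
            intron = "GT" + _rand_seq(rng, intron_len - 4, 0.5) + "AG"
            pieces.append(intron)
            offset += len(intron)
        prev = j
    return "".join(pieces), junctions, exon_bounds, nmd_done


def _transcript_features(
    utr5: str, utr3: str, spliced: str, cds_span: tuple[int, int]
) -> tuple[dict[str, float], dict]:
    """Re-scan an emitted transcript with the production scanners."""
    hits = scan_are(utr3)
    n_pent = sum(1 for h in hits if h.motif_id == "AUUUA")
    n_nona = sum(1 for h in hits if h.motif_id == "WWAUUUAWW")
    uorfs = find_uorfs(spliced, cds_span)
    comp5 = composition(utr5, "utr5")
    mean_ulen = (
        float(np.mean([u.length for u in uorfs])) if uorfs else 0.0
    )
    feats = {
        "are_density": 1000.0 * n_pent / len(utr3),
        "nonamer_density": 1000.0 * n_nona / len(utr3),
        "gc_utr5": comp5.gc_frac,
        "au_utr5": comp5.au_frac,
        "n_uorfs": float(len(uorfs)),
        "mean_uorf_length": mean_ulen,
        "utr3_len_kb": len(utr3) / 1000.0,
        "utr5_len_kb": len(utr5) / 1000.0,
    }
    raw = {"n_pent": n_pent, "n_nona": n_nona, "uorfs": uorfs, "mean_ulen": mean_ulen}
    return feats, raw


def synthetic_mirnas(rng: np.random.Generator, n: int = 9) -> dict[str, str]:
    """Synthetic 22-nt mature miRNA sequences (random; names labelled
    synthetic). Stand-ins for a real neural miRNA panel."""
    return {f"syn-miR-{i + 1}": _rand_seq(rng, 22, 0.5) for i in range(n)}


def simulate_transcriptome(
    specs: list[GroupSpec],
    seed: int,
    outdir: str | os.PathLike | None = None,
    n_mirnas: int = 9,
    chrom_name: str = "chr1",
) -> SimulatedDataset:
    """Generate genome FASTA + GTF + reference-CDS FASTA + expression TSV
    + miRNA FASTA with per-transcript recorded ground truth.

    Deterministic under ``seed``. Every transcript has at least one
    intron inside its CDS and non-empty UTRs; ~50% of genes are emitted
    on the minus strand.
    """
    if not specs:
        raise ValueError("at least one GroupSpec is required")
    rng = np.random.default_rng(seed)
    chrom_parts: list[str] = []
    cursor = 0
    models: list[TranscriptModel] = []
    cds_records: dict[str, str] = {}
    truth: list[TruthRecord] = []

    for spec in specs:
        for g in range(spec.n_genes):
            gene_id = f"{spec.name}_g{g:04d}"
            tid = f"{spec.name}_t{g:04d}"
            u5_med, u5_sig = spec.utr5_len_dist
            u3_med, u3_sig = spec.utr3_len_dist
            utr5_len = max(30, int(round(u5_med * math.exp(u5_sig * rng.standard_normal()))))
            utr3_len = max(30, int(round(u3_med * math.exp(u3_sig * rng.standard_normal()))))
            n_uorfs = int(rng.poisson(spec.uorf_lambda))
            if n_uorfs > 0:
                utr5_len = max(utr5_len, 3 + 39 * n_uorfs)
            utr5, uorf_starts = _build_utr5(rng, utr5_len, spec.au_frac_utr5, n_uorfs)
            utr3, n_planted_are, _ = _build_utr3(
                rng, utr3_len, spec.au_frac_utr3, spec.are_rate_per_kb
            )
            cds = _make_cds(rng, spec.cds_len)
            plant_nmd = bool(rng.random() < spec.nmd_arch_frac)
            pre_mrna, junctions, exon_bounds, nmd_planted = _gene_structure(
                rng, utr5, cds, utr3, plant_nmd
            )
            strand = "+" if rng.random() < 0.5 else "-"
            spacer = _rand_seq(rng, 500 + int(rng.integers(0, 501)))
            chrom_parts.append(spacer)
            cursor += len(spacer)
            gene_offset = cursor
            L = len(pre_mrna)
            if strand == "+":
                chrom_parts.append(pre_mrna)
                exons = [(gene_offset + a, gene_offset + b) for a, b in exon_bounds]
            else:
                chrom_parts.append(
                    pre_mrna.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                )
                exons = [
                    (gene_offset + L - b, gene_offset + L - a) for a, b in exon_bounds
                ]
            cursor += L
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    group=spec.name,
                    chrom=chrom_name,
                    strand=strand,
                    exons=tuple(sorted(exons)),
                )
            )
            cds_records[tid] = cds
            spliced = utr5 + cds + utr3
            cds_span = (len(utr5), len(utr5) + len(cds))
            feats, raw = _transcript_features(utr5, utr3, spliced, cds_span)
            nmd = classify_nmd(junctions, cds_span, tid)
            truth.append(
                TruthRecord(
                    transcript_id=tid,
                    gene_id=gene_id,
                    group=spec.name,
                    strand=strand,
                    utr5_span=(0, len(utr5)),
                    cds_span=cds_span,
                    utr3_span=(len(spliced) - len(utr3), len(spliced)),
                    junctions=junctions,
                    planted_pentamers=n_planted_are,
                    planted_uorf_starts=tuple(uorf_starts),
                    planted_nmd=nmd_planted,
                    are_pentamer_count=raw["n_pent"],
                    are_nonamer_count=raw["n_nona"],
                    n_uorfs=len(raw["uorfs"]),
                    mean_uorf_length=raw["mean_ulen"],
                    nmd_flag=nmd.nmd_flag,
                    features=feats,
                )
            )
    tail = _rand_seq(rng, 500 + int(rng.integers(0, 501)))
    chrom_parts.append(tail)
    genome = {chrom_name: "".join(chrom_parts)}

    expr_seed = int(rng.integers(0, 2**31 - 1))
    expression = plant_expression(
        truth, {s.name: s.expr_model for s in specs}, expr_seed
    )
    mirnas = synthetic_mirnas(rng, n_mirnas)
    fpkm_by_gene = dict(zip(expression["gene_id"], expression["fpkm"]))
    models = [
        dataclasses.replace(m, expression=fpkm_by_gene[m.gene_id]) for m in models
    ]
    ds = SimulatedDataset(genome, models, cds_records, expression, truth, mirnas)
    if outdir is not None:
        ds.write(outdir)
    return ds


def plant_expression(
    truth: list[TruthRecord],
    expr_models: dict[str, ExpressionModel] | ExpressionModel,
    seed: int,
) -> pd.DataFrame:
    """Draw expression from the planted feature-effect model.

    ``expr_models`` is one model for all groups or a {group: model} map.
    Updates each TruthRecord's ``log10_expression`` in place and returns
    a gene-level expression table (gene_id, fpkm).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in truth:
        model = (
            expr_models[t.group]
            if isinstance(expr_models, dict)
            else expr_models
        )
        log10 = model.baseline_log10
        for feat, beta in model.betas.items():
            if feat not in t.features:
                raise ValueError(f"unknown feature name in beta map: {feat!r}")
            log10 += beta * t.features[feat]
        log10 += model.noise_sd * rng.standard_normal() if model.noise_sd > 0 else 0.0
        t.log10_expression = log10
        rows.append({"gene_id": t.gene_id, "fpkm": 10.0**log10})
    return pd.DataFrame(rows)


def default_group_specs(scale: float = 1.0) -> list[GroupSpec]:
    """Default study conditions: four gene groups at published group
    sizes and contrasts (see module docstring). ``scale`` shrinks group
    sizes proportionally for quick runs."""

    def n(x: int) -> int:
        return max(3, int(round(x * scale)))

    olfr_betas = {"are_density": 0.04, "gc_utr5": -2.5, "n_uorfs": 0.08}
    return [
        GroupSpec(
            name="olfr1",  # class-I-like: short UTRs, low baseline expression
            n_genes=n(55),
            utr5_len_dist=(129.0, 0.5),
            utr3_len_dist=(786.0, 0.5),
            au_frac_utr5=0.60,
            au_frac_utr3=0.60,
            are_rate_per_kb=10.0,
            uorf_lambda=1.11,
            nmd_arch_frac=0.019,
            expr_model=ExpressionModel(0.3, dict(olfr_betas), 0.4),
        ),
        GroupSpec(
            name="olfr2",  # class-II-like
            n_genes=n(500),
            utr5_len_dist=(240.0, 0.5),
            utr3_len_dist=(1121.0, 0.5),
            au_frac_utr5=0.60,
            au_frac_utr3=0.60,
            are_rate_per_kb=10.0,
            uorf_lambda=1.11,
            nmd_arch_frac=0.019,
            expr_model=ExpressionModel(1.2, dict(olfr_betas), 0.4),
        ),
        GroupSpec(
            name="gpcr",
            n_genes=n(92),
            utr5_len_dist=(242.0, 0.5),
            utr3_len_dist=(1800.0, 0.5),
            au_frac_utr5=0.40,
            au_frac_utr3=0.45,
            are_rate_per_kb=5.0,
            uorf_lambda=0.50,
            nmd_arch_frac=0.02,
            expr_model=ExpressionModel(1.0, {"gc_utr5": 2.5}, 0.4),
        ),
        GroupSpec(
            name="ctrl",
            n_genes=n(587),
            utr5_len_dist=(212.0, 0.5),
            utr3_len_dist=(1895.0, 0.5),
            au_frac_utr5=0.40,
            au_frac_utr3=0.45,
            are_rate_per_kb=5.0,
            uorf_lambda=0.48,
            nmd_arch_frac=0.02,
            expr_model=ExpressionModel(1.0, {"are_density": -0.02}, 0.4),
        ),
    ]
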