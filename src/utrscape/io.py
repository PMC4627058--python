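"""File I/O: genome/CDS/miRNA FASTA, transcript GTF, expression TSV.

GTF coordinates are 1-based inclusive on disk and converted to 0-based
half-open on read. Exon features carry gene_id, transcript_id and an
optional ``group`` attribute labelling the gene group (olfr-like classes,
GPCR-like, control).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

from .annotation import AnnotatedTranscript, TranscriptModel


def load_genome(path: str | os.PathLike) -> dict[str, str]:
    """Read a genome FASTA into a {chrom: sequence} dict (uppercase)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_dict(path: str | os.PathLike) -> dict[str, str]:
    """Read any FASTA keyed by record id (uppercase sequences)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


read_cds_fasta = read_fasta_dict
read_mirna_fasta = read_fasta_dict


def write_fasta(records: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Expression TSV with columns gene_id, fpkm."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "fpkm"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression table must have columns {sorted(required)}")
    return df


def write_expression(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_transcript_models(
    gtf_path: str | os.PathLike,
    expression: Mapping[str, float] | None = None,
) -> list[TranscriptModel]:
    """Parse exon features from a GTF into TranscriptModels.

    ``expression`` maps gene_id to FPKM; transcripts of a gene inherit the
    gene-level value.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes["transcript_id"][0]
        gid = exon.attributes["gene_id"][0]
        group = exon.attributes.get("group", ["unassigned"])[0]
        # GTF 1-based inclusive -> 0-based half-open
        by_tx.setdefault(tid, []).append((exon.start - 1, exon.end))
        meta[tid] = (gid, group, exon.seqid, exon.strand)
    models = []
    for tid, exons in by_tx.items():
        gid, group, chrom, strand = meta[tid]
        fpkm = float("nan")
        if expression is not None and gid in expression:
            fpkm = float(expression[gid])
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                group=group,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons)),
                expression=fpkm,
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | os.PathLike) -> None:
    """Write exon features, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        for m in models:
            for start, end in m.exons:
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                    f'group "{m.group}";'
                )
                fh.write(
                    f"{m.chrom}\tutrscape\texon\t{start + 1}\t{end}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def write_annotation_table(
    annotated: Iterable[AnnotatedTranscript], path: str | os.PathLike
) -> pd.DataFrame:
    """TSV summary of an annotated transcript set (one row per transcript)."""
    rows = []
    for tx in annotated:
        rows.append(
            {
                "transcript_id": tx.transcript_id,
                "gene_id": tx.gene_id,
                "group": tx.group,
                "length": len(tx.spliced_seq),
                "utr5_len": len(tx.utr5_seq),
                "cds_len": (tx.cds_span[1] - tx.cds_span[0]) if tx.complete else 0,
                "utr3_len": len(tx.utr3_seq),
                "n_junctions": len(tx.junctions),
                "junctions": ",".join(map(str, tx.junctions)),
                "complete": tx.complete,
                "ambiguous": tx.ambiguous,
                "excluded": tx.excluded,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_annotated_fasta(
    annotated: Iterable[AnnotatedTranscript], path: str | os.PathLike
) -> None:
    """Spliced transcript FASTA with CDS span metadata in headers."""
    with open(path, "w") as fh:
        for tx in annotated:
            span = f"{tx.cds_span[0]}-{tx.cds_span[1]}" if tx.complete else "NA"
            fh.write(
                f">{tx.transcript_id} gene={tx.gene_id} group={tx.group} "
                f"cds={span} complete={int(tx.complete)}\n"
            )
            seq = tx.spliced_seq
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
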