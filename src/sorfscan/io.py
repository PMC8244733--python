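"""Reading and writing the pipeline's interchange formats.

Formats: genome FASTA; annotation GTF (1-based inclusive, attributes
``gene_id``, ``transcript_id``, ``transcript_biotype``); P-site tracks as TSV
(``transcript_id, position0based, count, sample``); RNA fragment counts TSV
(``transcript_id, fragments, sample``); peptide table TSV
(``peptide, sample``).

GTF dialect note: CDS features written by this package span the start codon
through the stop codon inclusive.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .models import InputValidationError, TranscriptModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "transcript_gtf_lines",
    "write_gtf",
    "read_gtf_features",
    "transcripts_from_gtf",
    "read_psites",
    "write_psites",
    "read_rna_counts",
    "write_rna_counts",
    "read_peptides",
    "write_peptides",
]

PSITE_COLUMNS = ["transcript_id", "position0based", "count", "sample"]
RNA_COLUMNS = ["transcript_id", "fragments", "sample"]
PEPTIDE_COLUMNS = ["peptide", "sample"]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GTF


def _gtf_line(
    chrom: str,
    source: str,
    feature: str,
    start0: int,
    end0: int,
    strand: str,
    attrs: Mapping[str, str],
) -> str:
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs.items())
    return (
        f"{chrom}\t{source}\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attr_str}"
    )


def transcript_gtf_lines(model: TranscriptModel, source: str = "sorfscan") -> list[str]:
    """GTF records (transcript, exons, CDS) for one transcript model."""
    attrs = {
        "gene_id": model.gene_id,
        "transcript_id": model.transcript_id,
        "transcript_biotype": model.biotype,
    }
    span = (min(s for s, _ in model.exons), max(e for _, e in model.exons))
    lines = [_gtf_line(model.chrom, source, "transcript", *span, model.strand, attrs)]
    for gs, ge in sorted(model.exons):
        lines.append(_gtf_line(model.chrom, source, "exon", gs, ge, model.strand, attrs))
    if model.cds is not None:
        for gs, ge in model.to_genomic(*model.cds):
            lines.append(_gtf_line(model.chrom, source, "CDS", gs, ge, model.strand, attrs))
    return lines


def write_gtf(lines: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line.rstrip("\n") + "\n")


def read_gtf_features(path: str | os.PathLike):
    """Parse a GTF file into gffutils Feature objects (comments skipped)."""
    features = []
    with open(path) as fh:
        for raw in fh:
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            features.append(feature_from_line(raw, dialect=None))
    return features


def transcripts_from_gtf(
    gtf_path: str | os.PathLike, genome: Mapping[str, str]
) -> list[TranscriptModel]:
    """Assemble :class:`TranscriptModel` objects from a GTF and genome FASTA.

    Exon and CDS features are grouped by ``transcript_id``; the spliced
    sequence is cut from the genome (reverse-complemented on the minus
    strand) and genomic CDS blocks are lifted to transcript coordinates.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds_blocks: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    for feat in read_gtf_features(gtf_path):
        try:
            tid = feat.attributes["transcript_id"][0]
        except KeyError:
            continue
        info = meta.setdefault(
            tid,
            {
                "gene_id": (feat.attributes.get("gene_id") or [tid])[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "biotype": (feat.attributes.get("transcript_biotype") or [None])[0],
            },
        )
        interval = (feat.start - 1, feat.end)  # to 0-based half-open
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(interval)
        elif feat.featuretype == "CDS":
            cds_blocks.setdefault(tid, []).append(interval)

    models = []
    for tid, info in meta.items():
        if tid not in exons:
            continue
        strand = info["strand"]
        ordered = sorted(exons[tid], reverse=(strand == "-"))
        chrom_seq = genome.get(info["chrom"])
        if chrom_seq is None:
            raise InputValidationError(f"chromosome {info['chrom']} absent from FASTA")
        pieces = []
        for gs, ge in ordered:
            piece = chrom_seq[gs:ge]
            if strand == "-":
                piece = str(Seq(piece).reverse_complement())
            pieces.append(piece)
        seq = "".join(pieces)

        cds = None
        if tid in cds_blocks:
            tpos = sorted(
                t
                for gs, ge in cds_blocks[tid]
                for t in _genomic_to_transcript_range(ordered, strand, gs, ge)
            )
            cds = (tpos[0], tpos[-1] + 1)
        biotype = info["biotype"] or ("protein_coding" if cds else "non_coding")
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=strand,
                exons=tuple(ordered),
                sequence=seq,
                cds=cds,
                biotype=biotype,
            )
        )
    return models


def _genomic_to_transcript_range(
    exons_5to3: list[tuple[int, int]], strand: str, gs: int, ge: int
) -> list[int]:
    """Transcript positions covered by genomic interval [gs, ge)."""
    out = []
    offset = 0
    for es, ee in exons_5to3:
        lo, hi = max(gs, es), min(ge, ee)
        if lo < hi:
            for g in range(lo, hi):
                if strand == "+":
                    out.append(offset + (g - es))
                else:
                    out.append(offset + (ee - 1 - g))
        offset += ee - es
    if not out:
        raise InputValidationError(
            f"genomic interval [{gs}, {ge}) does not map onto the exon chain"
        )
    return out


# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing columns {missing}")
    return df[columns]


def read_psites(path) -> pd.DataFrame:
    return _read_tsv(path, PSITE_COLUMNS)


def write_psites(df: pd.DataFrame, path) -> None:
    df[PSITE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_rna_counts(path) -> pd.DataFrame:
    return _read_tsv(path, RNA_COLUMNS)


def write_rna_counts(df: pd.DataFrame, path) -> None:
    df[RNA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_peptides(path) -> pd.DataFrame:
    return _read_tsv(path, PEPTIDE_COLUMNS)


def write_peptides(df: pd.DataFrame, path) -> None:
    df[PEPTIDE_COLUMNS].to_csv(path, sep="\t", index=False)
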