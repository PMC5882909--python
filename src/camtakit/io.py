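"""Readers/writers for the plain-text formats used throughout the toolkit.

FASTA goes through Bio.SeqIO; GFF3 is the minimal gene/exon subset the
synthetic generator emits (1-based, inclusive, strand column +/-) and
round-trips through :func:`write_gff3` / :func:`read_gff3`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, ValidationError


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def write_gff3(models: list[GeneModel], path: str | Path, source: str = "camtakit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(
                "\t".join(
                    [g.chromosome, source, "gene", str(g.start), str(g.end), ".",
                     g.strand, ".", f"ID={g.id}"]
                )
                + "\n"
            )
            for i, (a, b) in enumerate(g.exons, start=1):
                fh.write(
                    "\t".join(
                        [g.chromosome, source, "exon", str(a), str(b), ".",
                         g.strand, ".", f"ID={g.id}.exon{i};Parent={g.id}"]
                    )
                    + "\n"
                )


def _attr(field: str, key: str) -> str | None:
    for part in field.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse the gene/exon GFF3 subset written by :func:`write_gff3`."""
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValidationError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype == "gene":
                gid = _attr(attrs, "ID")
                if gid is None:
                    raise ValidationError(f"{path}:{lineno}: gene without ID")
                genes[gid] = GeneModel(
                    id=gid, chromosome=chrom, strand=strand,
                    start=int(start), end=int(end), exons=[],
                )
            elif ftype == "exon":
                parent = _attr(attrs, "Parent")
                if parent is None:
                    raise ValidationError(f"{path}:{lineno}: exon without Parent")
                exons.setdefault(parent, []).append((int(start), int(end)))
    out = []
    for gid, g in genes.items():
        out.append(
            GeneModel(id=gid, chromosome=g.chromosome, strand=g.strand,
                      start=g.start, end=g.end, exons=exons.get(gid, []))
        )
    return out


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression matrix: rows = genes (index), columns = stages."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate gene ids")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
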