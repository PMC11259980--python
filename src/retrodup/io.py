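"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA I/O goes through Biopython; tabular formats (BED, BED12, depth and
truth tables) through pandas.  All coordinates are BED-convention 0-based
half-open.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GeneModel, GenomeAssembly

DEPTH_COLUMNS = ["chrom", "start", "end", "unmasked", "gc", "depth"]


def write_fasta(asm: GenomeAssembly, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in asm.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, mask_bed=None) -> GenomeAssembly:
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    mask = read_bed(mask_bed) if mask_bed else {}
    return GenomeAssembly(sequences, mask)


def write_bed(by_chrom: dict, path, scores: dict | None = None) -> None:
    with open(path, "w") as fh:
        for chrom in by_chrom:
            for iv in by_chrom[chrom]:
                row = [chrom, str(iv[0]), str(iv[1])]
                if scores is not None:
                    row += [".", str(scores.get((chrom, iv[0], iv[1]), 0))]
                fh.write("\t".join(row) + "\n")


def read_bed(path) -> dict:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return {c: sorted(v) for c, v in out.items()}


def write_bed12(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s - g.start) for s, _ in g.exons) + ","
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                        g.cds_start, g.cds_end, 0, len(g.exons), sizes, starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path) -> list[GeneModel]:
    """Read gene models written by :func:`write_bed12`.

    Columns 7/8 carry the transcript-relative coding offsets (this package's
    convention, in place of genomic thickStart/thickEnd).
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start = f[0], int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [[start + o, start + o + sz] for o, sz in zip(offs, sizes)]
            genes.append(
                GeneModel(
                    gene_id=f[3], chrom=chrom, strand=f[5], exons=exons,
                    cds_start=int(f[6]), cds_end=int(f[7]),
                )
            )
    return genes


def write_depth(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False)


def read_depth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truths: list, path) -> None:
    rows = [dataclasses.asdict(t) for t in truths]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
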