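"""Flat-file interchange: FASTA/FASTQ via Biopython, PNG masks, TSV tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .methylation import IslandCriteria, MethylationCallTable, PromoterRegion

__all__ = [
    "write_fasta",
    "read_region_fasta",
    "write_fastq",
    "read_fastq",
    "write_mask_png",
    "read_mask_png",
    "write_islands_bed",
    "write_site_table",
    "write_cohort_tsv",
    "read_cohort_tsv",
]


def write_fasta(region: PromoterRegion, path: str | Path) -> None:
    desc = f"span={region.span} strand={region.strand}" if region.span else f"strand={region.strand}"
    rec = SeqRecord(Seq(region.sequence), id=region.name, description=desc)
    SeqIO.write([rec], str(path), "fasta")


def read_region_fasta(path: str | Path, criteria: IslandCriteria | None = None) -> PromoterRegion:
    with open(path) as fh:
        rec = next(SeqIO.parse(fh, "fasta"))
    return PromoterRegion.from_sequence(rec.id, str(rec.seq), criteria=criteria)


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write ``(id, sequence, quality)`` triples as Phred+33 FASTQ."""
    records = []
    for read_id, seq, qual in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """0 = background, 255 = foreground."""
    iio.imwrite(str(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_mask_png(path: str | Path) -> np.ndarray:
    img = iio.imread(str(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0


def write_islands_bed(region: PromoterRegion, path: str | Path) -> None:
    """Islands as BED (0-based half-open), named island_1..island_k."""
    chrom = region.span.chrom if region.span else region.name
    offset = region.span.start - 1 if region.span else 0
    with open(path, "w") as fh:
        for i, (a, b) in enumerate(region.islands, start=1):
            fh.write(f"{chrom}\t{offset + a}\t{offset + b}\tisland_{i}\n")


def write_site_table(table: MethylationCallTable, region: PromoterRegion, path: str | Path) -> None:
    df = table.site_counts()
    offset = region.span.start if region.span else 1
    df.insert(1, "genomic_pos", df["site_offset"] + offset)
    df.to_csv(path, sep="\t", index=False)


def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
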