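"""Readers and writers for the pipeline's file dialects.

* SNP table: TSV with header ``chrom  pos  allele1  allele2  human_window
  chimp_window  orang_window`` — windows are 21-mers (10 bp of flank on each
  side of the site), ``.`` marks a missing outgroup window.
* Accepted mutations: TSV ``chrom  pos  ancestral  derived  window``.
* Regions: BED3 (0-based half-open), read into interval trees.
* Genomes: FASTA (read via pyfaidx, written via Bio.SeqIO).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import MutationRecord, SnpRecord

SNP_COLUMNS = [
    "chrom",
    "pos",
    "allele1",
    "allele2",
    "human_window",
    "chimp_window",
    "orang_window",
]
MUTATION_COLUMNS = ["chrom", "pos", "ancestral", "derived", "window"]

MISSING = "."


class FormatError(ValueError):
    """Raised for malformed input files, naming the file and line."""


def read_snp_table(path: str | Path) -> Iterator[SnpRecord]:
    """Stream SNP records from a TSV table."""
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty SNP table") from None
        if header != SNP_COLUMNS:
            raise FormatError(f"{path}:1: expected header {SNP_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(SNP_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(SNP_COLUMNS)} columns")
            chrom, pos, a1, a2, hw, cw, ow = row
            try:
                yield SnpRecord(
                    chrom=chrom,
                    pos=int(pos),
                    alleles=(a1, a2),
                    human_window=hw,
                    chimp_window=None if cw == MISSING else cw,
                    orang_window=None if ow == MISSING else ow,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc


def write_snp_table(snps: Iterable[SnpRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SNP_COLUMNS)
        for s in snps:
            writer.writerow(
                [
                    s.chrom,
                    s.pos,
                    s.alleles[0],
                    s.alleles[1],
                    s.human_window,
                    s.chimp_window or MISSING,
                    s.orang_window or MISSING,
                ]
            )


def read_mutations(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if list(df.columns) != MUTATION_COLUMNS:
        raise FormatError(f"{path}: expected columns {MUTATION_COLUMNS}")
    return [
        MutationRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            ancestral=row.ancestral,
            derived=row.derived,
            window=row.window,
        )
        for row in df.itertuples()
    ]


def write_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MUTATION_COLUMNS)
        for r in records:
            writer.writerow([r.chrom, r.pos, r.ancestral, r.derived, r.window])


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """BED3 intervals (0-based half-open); empty file → no intervals."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str},
        comment="#",
    )
    return [(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load all sequences (uppercased) — suitable for the scales used here."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), rebuild=True)
    try:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    finally:
        fa.close()
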