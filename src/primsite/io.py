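"""Readers and writers for the plain-text formats the pipeline speaks.

FASTA/FASTQ parsing goes through Biopython.  The writers are local so that
output bytes are fully deterministic (fixed line width, fixed field order,
seed recorded in headers), which the pipeline's reproducibility contract
depends on.

Coordinates are 0-based half-open in memory; BED is written 0-based
half-open and GFF3 1-based closed, per those standards.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqRead(NamedTuple):
    """A single read: identifier, sequence, per-base Phred string."""

    name: str
    sequence: str
    quality: str


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping.

    The name is the header token up to the first whitespace, verbatim
    (no "chr"-prefix normalisation).  Sequences are uppercased.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(
    path: str | os.PathLike,
    seqs: Mapping[str, str],
    *,
    seed: int | None = None,
    width: int = 60,
) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            tag = f" seed={seed}" if seed is not None else ""
            fh.write(f">{name}{tag}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | os.PathLike) -> list[FastqRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_fastq(
    path: str | os.PathLike, reads: Iterable[FastqRead], *, seed: int | None = None
) -> None:
    tag = f" seed={seed}" if seed is not None else ""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}{tag}\n{r.sequence}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# BED6 site tables

SITE_COLUMNS = ["chromosome", "position", "orientation", "support_reads", "site_id"]


def write_sites_bed(
    path: str | os.PathLike, sites: pd.DataFrame, *, seed: int | None = None
) -> None:
    """Write a site table as BED6: start=position, end=position+2 (the TA),
    name=site_id, score=support_reads, strand=orientation."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"#seed={seed}\n")
        for row in sites.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.position}\t{row.position + 2}\t"
                f"{row.site_id}\t{row.support_reads}\t{row.orientation}\n"
            )


def read_sites_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED6 site table written by :func:`write_sites_bed`."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(parts)}")
            chrom, start, end, name, score, strand = parts[:6]
            rows.append(
                {
                    "chromosome": chrom,
                    "position": int(start),
                    "orientation": strand,
                    "support_reads": int(score),
                    "site_id": name,
                }
            )
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return df.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Generic TSV helpers


def write_tsv(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
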