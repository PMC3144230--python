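"""File I/O: FASTA/FASTQ via Biopython, TSV/BED/JSON report writers.

All writers are atomic (write to a temporary file in the target directory,
then rename), so a failed stage never leaves a truncated output behind.
Written coordinates follow the conventions stated per format: BED is 0-based
half-open; tabular structure reports are 1-based inclusive.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthdata import SmallRead

FASTQ_QUALITY_CHAR = "I"  # constant Sanger-offset quality for simulated reads


@contextmanager
def atomic_path(path: str | os.PathLike):
    """Yield a temporary path that is renamed onto ``path`` on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        yield tmp
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with atomic_path(path) as tmp:
        SeqIO.write(records, tmp, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list[SmallRead], path) -> None:
    with atomic_path(path) as tmp, open(tmp, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{FASTQ_QUALITY_CHAR * r.length}\n")


def read_reads(path) -> list[SmallRead]:
    """Read small-RNA reads from FASTQ or FASTA (by extension)."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    return [SmallRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(p, fmt)]


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    with atomic_path(path) as tmp:
        df.to_csv(tmp, sep="\t", index=False, lineterminator="\n", float_format=float_format)


def write_bed(intervals: list[tuple[str, int, int, str, float, str]], path) -> None:
    """BED6 (chrom, start, end, name, score, strand), 0-based half-open."""
    with atomic_path(path) as tmp, open(tmp, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def write_json(obj, path) -> None:
    with atomic_path(path) as tmp, open(tmp, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
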