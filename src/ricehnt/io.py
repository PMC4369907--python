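"""Plain-text readers and writers for the pipeline's tables and FASTQ files.

Tables are tab-separated with a header row.  FASTQ is the standard
4-line record layout with Phred+33 qualities (gzipped files are handled
transparently by extension).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ricehnt.expression import CountMatrix
from ricehnt.simulate import ReadRecord


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV: transcript_id, length_bp, then samples."""
    out = cm.counts.copy()
    out.insert(0, "length_bp", cm.lengths)
    out.to_csv(path, sep="\t", index=True, index_label="transcript_id")


def read_counts(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    lengths = df.pop("length_bp")
    return CountMatrix(counts=df, lengths=lengths)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write 4-line FASTQ; read ids get a ``/mate`` suffix. Returns count."""
    n = 0
    with _open_text(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}/{read.mate}\n{read.sequence}\n+\n{read.quality}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate ReadRecords from a 4-line FASTQ file (optionally .gz)."""
    with _open_text(path, "r") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            read_id = title.split()[0]
            mate = 1
            if read_id.endswith(("/1", "/2")):
                mate = int(read_id[-1])
                read_id = read_id[:-2]
            yield ReadRecord(read_id, seq, qual, mate)
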