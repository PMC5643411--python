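"""FASTQ and CSV I/O helpers (gzip-transparent by filename suffix)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

FastqTriple = tuple[str, str, str]  # (read id, sequence, quality string)


def open_text(path: str | Path, mode: str = "rt") -> TextIO:
    """Open a text file, decompressing/compressing if the name ends in .gz."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, compresslevel=2)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqTriple]:
    """Iterate (id, sequence, quality) over a FASTQ(.gz) file."""
    with open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq_record(fh: TextIO, read_id: str, seq: str, qual: str) -> None:
    fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def phred(qual_char: str) -> int:
    """Phred quality of a single Sanger-encoded quality character."""
    return ord(qual_char) - 33
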