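"""Demultiplexing of R1/R2/I1 FASTQ triples into per-sample FASTQ files.

Each sequencing run yields three synchronized FASTQ streams: R1 (the V(D)J
read, starting with 6 random bases then the 6-base within-R1 sample index),
R2 (whose first 30 bases cover the spacer/UMI region of the ligation
oligonucleotide) and I1 (the 6-base Illumina index read).  A composite read
concatenates UMI region + I1 hexamer + R1 hexamer + full R1; demultiplexing
routes composites to samples by their index pair and writes per-sample FASTQ
whose sequence is ``umi_region + r1`` (the downstream input contract — the
index hexamers are consumed at this stage).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from . import layout
from .io import FastqTriple, open_text, read_fastq, write_fastq_record

_SAFE_NAME = re.compile(r"^[A-Za-z0-9._-]+$")
_CHAIN_WORDS = {
    "alpha": "alpha", "tra": "alpha", "tcra": "alpha",
    "beta": "beta", "trb": "beta", "tcrb": "beta",
    "gamma": "gamma", "trg": "gamma", "tcrg": "gamma",
    "delta": "delta", "trd": "delta", "tcrd": "delta",
}


def detect_chain(name: str) -> str | None:
    """Infer the TCR chain from a sample/file name, if it names one."""
    tokens = re.split(r"[^A-Za-z]+", name.lower())
    for tok in tokens:
        if tok in _CHAIN_WORDS:
            return _CHAIN_WORDS[tok]
    return None


@dataclass(frozen=True)
class SampleRow:
    name: str
    index1: str  # matched against the I1 read
    index2: str  # matched against the within-R1 hexamer
    chain: str | None = None


@dataclass
class SampleSheet:
    rows: list[SampleRow]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        names: set[str] = set()
        for row in self.rows:
            if not _SAFE_NAME.match(row.name):
                raise ValueError(f"sample name {row.name!r} is not filesystem-safe")
            if row.name in names:
                raise ValueError(f"duplicate sample name {row.name!r}")
            names.add(row.name)
            for idx in (row.index1, row.index2):
                if len(idx) != layout.INDEX_LEN or set(idx) - set("ACGT"):
                    raise ValueError(f"sample {row.name}: bad index {idx!r}")
            pair = (row.index1, row.index2)
            if pair in seen:
                raise ValueError(f"duplicate index pair {pair} in sample sheet")
            seen.add(pair)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSheet":
        rows = []
        with open(path, newline="") as fh:
            for raw in csv.reader(fh):
                if not raw or raw[0].startswith("#") or raw[0] == "sample_name":
                    continue
                name, i1, i2 = raw[0], raw[1].upper(), raw[2].upper()
                chain = raw[3] if len(raw) > 3 and raw[3] else detect_chain(name)
                rows.append(SampleRow(name, i1, i2, chain))
        return cls(rows)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            for row in self.rows:
                w.writerow([row.name, row.index1, row.index2, row.chain or ""])


@dataclass(frozen=True)
class CompositeRead:
    read_id: str
    umi_region: str
    umi_quality: str
    i1_hexamer: str
    r1_hexamer: str
    r1_full: str
    r1_quality: str

    @property
    def sequence(self) -> str:
        """Serialized composite: UMI region, both index hexamers, full R1."""
        return self.umi_region + self.i1_hexamer + self.r1_hexamer + self.r1_full


@dataclass
class DemuxLog:
    total: int = 0
    dropped_short: int = 0
    ambiguous: int = 0
    per_sample: dict[str, int] = field(default_factory=dict)
    undetermined: int = 0

    def conserved(self) -> bool:
        assigned = sum(self.per_sample.values())
        return assigned + self.undetermined + self.dropped_short == self.total

    def write(self, txt_path: str | Path, csv_path: str | Path) -> None:
        with open(txt_path, "w") as fh:
            fh.write(f"reads_in: {self.total}\n")
            fh.write(f"dropped_short: {self.dropped_short}\n")
            fh.write(f"ambiguous: {self.ambiguous}\n")
            fh.write(f"undetermined: {self.undetermined}\n")
            for name, n in sorted(self.per_sample.items()):
                fh.write(f"sample {name}: {n}\n")
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample", "reads"])
            for name, n in sorted(self.per_sample.items()):
                w.writerow([name, n])
            w.writerow(["undetermined", self.undetermined])
            w.writerow(["dropped_short", self.dropped_short])


def _read_key(read_id: str) -> str:
    # First whitespace token, without any legacy /1 /2 pair suffix.
    token = read_id.split(None, 1)[0]
    return token[:-2] if token.endswith(("/1", "/2", "/3")) else token


def compose_reads(
    r1: Iterable[FastqTriple],
    r2: Iterable[FastqTriple],
    i1: Iterable[FastqTriple],
    log: DemuxLog | None = None,
) -> Iterator[CompositeRead]:
    """Combine synchronized R1/R2/I1 records into composite reads.

    Streams must be record-synchronized; a read-ID mismatch is a hard error.
    Records with R2 shorter than the 30-base UMI region or R1 shorter than
    the 12 bases holding the random hexamer plus index are dropped and
    counted.
    """
    log = log if log is not None else DemuxLog()
    for (id1, s1, q1), (id2, s2, _q2), (idi, si, _qi) in zip(r1, r2, i1, strict=True):
        log.total += 1
        if not (_read_key(id1) == _read_key(id2) == _read_key(idi)):
            raise ValueError(
                f"desynchronized FASTQ streams at record {log.total}: "
                f"{id1!r} / {id2!r} / {idi!r}"
            )
        if len(s2) < layout.UMI_REGION_LEN or len(s1) < layout.R1_INDEX_SLOT[1]:
            log.dropped_short += 1
            continue
        a, b = layout.R1_INDEX_SLOT
        yield CompositeRead(
            read_id=id1,
            umi_region=s2[: layout.UMI_REGION_LEN],
            umi_quality=_q2[: layout.UMI_REGION_LEN],
            i1_hexamer=si[: layout.INDEX_LEN],
            r1_hexamer=s1[a:b],
            r1_full=s1,
            r1_quality=q1,
        )


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def assign_read(
    i1_hexamer: str,
    r1_hexamer: str,
    sheet: SampleSheet,
    max_index_mismatches: int = 1,
) -> str | None:
    """Sample name for an index pair, or None (unassigned/ambiguous).

    A read is assigned only when exactly one sheet row matches both indices
    within the mismatch tolerance; multiple matching rows are ambiguous and
    the read goes to the undetermined pool.
    """
    matches = [
        row.name
        for row in sheet.rows
        if _mismatches(i1_hexamer, row.index1, max_index_mismatches) <= max_index_mismatches
        and _mismatches(r1_hexamer, row.index2, max_index_mismatches) <= max_index_mismatches
    ]
    if len(matches) == 1:
        return matches[0]
    return None


def demultiplex(
    reads: Iterable[CompositeRead],
    sheet: SampleSheet,
    outdir: str | Path,
    max_index_mismatches: int = 1,
    gzip_output: bool = True,
    log: DemuxLog | None = None,
) -> DemuxLog:
    """Route composite reads to per-sample FASTQ files.

    Output records carry the 30-base UMI region prepended to the full R1
    sequence (with concatenated qualities).  Returns the summary log; the
    plain-text and CSV logs are written alongside the FASTQ files.  Pass the
    log used by :func:`compose_reads` to keep one conserved tally of input
    triples, drops and assignments.
    """
    if max_index_mismatches not in (0, 1):
        raise ValueError("max_index_mismatches must be 0 or 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".fq.gz" if gzip_output else ".fq"
    if log is None:
        log = DemuxLog()
    log.per_sample = {row.name: 0 for row in sheet.rows}
    processed = 0

    handles = {
        row.name: open_text(outdir / f"{row.name}{ext}", "wt") for row in sheet.rows
    }
    undet = open_text(outdir / f"undetermined{ext}", "wt")
    # Exact-match fast path; fall back to per-row scan for mismatches.
    exact = {(row.index1, row.index2): row.name for row in sheet.rows}
    try:
        for read in reads:
            processed += 1
            name = exact.get((read.i1_hexamer, read.r1_hexamer))
            if name is None:
                name = assign_read(read.i1_hexamer, read.r1_hexamer, sheet, max_index_mismatches)
            if name is None:
                log.undetermined += 1
                fh = undet
            else:
                log.per_sample[name] += 1
                fh = handles[name]
            write_fastq_record(
                fh,
                read.read_id,
                read.umi_region + read.r1_full,
                read.umi_quality + read.r1_quality,
            )
    finally:
        for fh in handles.values():
            fh.close()
        undet.close()
    if log.total == 0:
        log.total = processed
    log.write(outdir / "demultiplex.log", outdir / "demultiplex.counts.csv")
    return log


def demultiplex_run(
    r1_path: str | Path,
    r2_path: str | Path,
    i1_path: str | Path,
    sheet: SampleSheet,
    outdir: str | Path,
    max_index_mismatches: int = 1,
    gzip_output: bool = True,
) -> DemuxLog:
    """File-level entry point: compose the three FASTQ files, then split."""
    log = DemuxLog()
    reads = compose_reads(
        read_fastq(r1_path), read_fastq(r2_path), read_fastq(i1_path), log
    )
    return demultiplex(reads, sheet, outdir, max_index_mismatches, gzip_output, log=log)
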