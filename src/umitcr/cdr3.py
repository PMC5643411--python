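"""CDR3 extraction and productivity classification.

A five-part identifier is first expanded back into the full rearranged
nucleotide sequence, translated in the V gene's reading frame (anchored so
the conserved-cysteine codon is in frame), and the CDR3 is reported as the
amino-acid span from that cysteine through the phenylalanine of the J
gene's "FGXG" motif, both inclusive.  Rearrangements are non-productive
when the junction breaks the frame, an in-frame stop precedes the J motif,
or either anchor motif is absent (per-gene motif patterns accommodate
non-canonical CDR3 motifs; X matches any residue).
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .collapse import CollapsedClone, read_freq
from .decombine import TcrIdentifier, reconstruct
from .io import open_text
from .references import ReferenceSet

FAIL_REASONS = ("stop_codon", "out_of_frame", "missing_motif", "none")


@dataclass(frozen=True)
class Cdr3Record:
    cdr3_aa: str
    identifier: TcrIdentifier | None
    frequency: int
    productive: bool
    fail_reason: str  # one of FAIL_REASONS

    def __post_init__(self) -> None:
        if self.productive:
            assert self.fail_reason == "none" and self.cdr3_aa
        else:
            assert self.cdr3_aa == "" and self.fail_reason != "none"


def _translate(nt: str) -> str:
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def extract_cdr3(
    identifier: TcrIdentifier,
    ref: ReferenceSet,
    frequency: int = 1,
) -> Cdr3Record:
    """Reconstruct, translate, and extract the CDR3 for one identifier."""
    v_gene = ref.v_genes[identifier.v_index]
    j_gene = ref.j_genes[identifier.j_index]
    seq = reconstruct(identifier, ref)

    def fail(reason: str) -> Cdr3Record:
        return Cdr3Record("", identifier, frequency, False, reason)

    v_len = len(v_gene.sequence) - identifier.v_deletions
    # anchors must survive the junctional deletions
    if v_len < v_gene.motif_anchor + 3 or j_gene.motif_anchor < identifier.j_deletions:
        return fail("missing_motif")
    j_anchor = v_len + len(identifier.insert) + (j_gene.motif_anchor - identifier.j_deletions)
    if (j_anchor - v_gene.motif_anchor) % 3 != 0:
        return fail("out_of_frame")

    frame = v_gene.motif_anchor % 3
    aa = _translate(seq[frame:])
    v_res = (v_gene.motif_anchor - frame) // 3
    j_res = (j_anchor - frame) // 3
    if j_res >= len(aa):
        return fail("missing_motif")
    if "*" in aa[: j_res + 1]:
        return fail("stop_codon")
    for offset, want in enumerate(v_gene.motif_pattern):
        pos = v_res + offset
        if want != "X" and (pos >= len(aa) or aa[pos] != want):
            return fail("missing_motif")
    for offset, want in enumerate(j_gene.motif_pattern):
        pos = j_res + offset
        if want != "X" and (pos >= len(aa) or aa[pos] != want):
            return fail("missing_motif")
    return Cdr3Record(aa[v_res : j_res + 1], identifier, frequency, True, "none")


@dataclass
class TranslationSummary:
    productive: int = 0
    non_productive: dict[str, int] | None = None
    v_usage: Counter | None = None
    j_usage: Counter | None = None

    def __post_init__(self) -> None:
        if self.non_productive is None:
            self.non_productive = {r: 0 for r in FAIL_REASONS if r != "none"}
        self.v_usage = self.v_usage or Counter()
        self.j_usage = self.j_usage or Counter()

    def write(self, path: str | Path, ref: ReferenceSet) -> None:
        with open(path, "w") as fh:
            fh.write(f"productive: {self.productive}\n")
            for reason, n in (self.non_productive or {}).items():
                fh.write(f"non_productive_{reason}: {n}\n")
            for cls, usage in (("V", self.v_usage), ("J", self.j_usage)):
                for idx, n in sorted((usage or {}).items()):
                    fh.write(f"{cls}_usage {ref.index_to_name(cls, idx)}: {n}\n")


def translate_repertoire(
    clones: Sequence[CollapsedClone],
    ref: ReferenceSet,
    mode: str = "cdr3",
) -> tuple[list[Cdr3Record], TranslationSummary]:
    """Translate a collapsed repertoire.

    ``mode="cdr3"``: unique productive CDR3s with summed frequencies
    (several rearrangements can encode the same CDR3).  ``mode="dcrcdr3"``:
    one record per identifier, keeping the five-part index.
    """
    if mode not in ("cdr3", "dcrcdr3"):
        raise ValueError(f"mode must be 'cdr3' or 'dcrcdr3', got {mode!r}")
    summary = TranslationSummary()
    per_identifier: list[Cdr3Record] = []
    for clone in clones:
        rec = extract_cdr3(clone.identifier, ref, frequency=clone.abundance)
        if rec.productive:
            summary.productive += clone.abundance
            summary.v_usage[clone.identifier.v_index] += clone.abundance  # type: ignore[index]
            summary.j_usage[clone.identifier.j_index] += clone.abundance  # type: ignore[index]
        else:
            summary.non_productive[rec.fail_reason] += clone.abundance  # type: ignore[index]
        per_identifier.append(rec)
    if mode == "dcrcdr3":
        return per_identifier, summary
    merged: dict[str, int] = defaultdict(int)
    for rec in per_identifier:
        if rec.productive:
            merged[rec.cdr3_aa] += rec.frequency
    out = [
        Cdr3Record(cdr3, None, freq, True, "none")
        for cdr3, freq in sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return out, summary


def write_cdr3(records: Iterable[Cdr3Record], path: str | Path, mode: str = "cdr3") -> int:
    n = 0
    with open_text(path, "wt") as fh:
        w = csv.writer(fh)
        for rec in records:
            if mode == "cdr3":
                w.writerow([rec.cdr3_aa, rec.frequency])
            else:
                i = rec.identifier
                w.writerow(
                    [i.v_index, i.j_index, i.v_deletions, i.j_deletions, i.insert,
                     rec.cdr3_aa, rec.frequency]
                )
            n += 1
    return n


def read_cdr3(path: str | Path) -> dict[str, int]:
    """Read a ``.cdr3`` file into a CDR3 -> frequency mapping."""
    out: dict[str, int] = {}
    with open_text(path) as fh:
        for row in csv.reader(fh):
            if row:
                out[row[0]] = out.get(row[0], 0) + int(row[1])
    return out


def translate_file(
    freq_path: str | Path,
    ref: ReferenceSet,
    mode: str = "cdr3",
    out_path: str | Path | None = None,
    log_path: str | Path | None = None,
) -> tuple[Path, TranslationSummary]:
    """Translate a ``.freq`` file to ``.cdr3`` or ``.dcrcdr3``."""
    freq_path = Path(freq_path)
    ext = ".cdr3" if mode == "cdr3" else ".dcrcdr3"
    if out_path is None:
        out_path = freq_path.with_suffix(ext)
    out_path = Path(out_path)
    clones = [
        CollapsedClone(ident, abundance, 0) for ident, abundance in read_freq(freq_path)
    ]
    records, summary = translate_repertoire(clones, ref, mode=mode)
    write_cdr3(records, out_path, mode=mode)
    summary.write(log_path or out_path.with_suffix(ext + ".log"), ref)
    return out_path, summary
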