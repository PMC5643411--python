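"""Tag-based identification of rearranged TCRs in demultiplexed reads.

V and J genes are recognized by short gene-specific tags searched with an
Aho-Corasick automaton.  A single base mismatch per tag is tolerated by
expanding every tag to all of its Hamming-distance-1 variants and running a
pure exact-match automaton over the expanded set (equivalent to per-position
Hamming checks).  A read with exactly one V gene hit upstream of exactly one
J gene hit is decomposed into the five-part identifier

    (V index, J index, V 3' deletions, J 5' deletions, junction insert)

which, given a reference set, uniquely encodes the rearranged nucleotide
sequence.  The canonical decomposition is V-greedy: minimal V deletions
first, then minimal J deletions, so junction bases that coincide with
germline are attributed to the germline side.

The per-read output record has exactly 10 fields: the five identifier
fields, the FASTQ read id, the intertag sequence (read bases between the V
and J tags, spanning the junction) with its qualities, and the 30-base UMI
region with its qualities.  Serialized as CSV with extension ``.n12``.
"""

from __future__ import annotations

import csv
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from . import layout
from .io import open_text, read_fastq
from .references import ReferenceSet

_BASES = "ACGT"
_ENCODE = bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))


class AhoCorasick:
    """Multi-pattern exact string matcher over the DNA alphabet.

    Classic goto/fail construction compiled to a dense DFA (one transition
    per state and base), so scanning is a single table lookup per character.
    Characters outside ACGT reset the automaton to the root.
    """

    def __init__(self, patterns: Iterable[tuple[str, object]]):
        goto: list[list[int]] = [[0, 0, 0, 0]]
        out: list[list[object]] = [[]]
        plen: list[list[int]] = [[]]
        for pattern, payload in patterns:
            state = 0
            enc = pattern.encode().translate(_ENCODE)
            for b in enc:
                nxt = goto[state][b]
                if nxt == 0:
                    # 0 is the root, never a trie-edge target: no edge yet
                    goto.append([0, 0, 0, 0])
                    out.append([])
                    plen.append([])
                    nxt = len(goto) - 1
                    goto[state][b] = nxt
                state = nxt
            out[state].append(payload)
            plen[state].append(len(pattern))
        # BFS: turn goto into a dense DFA and propagate outputs via fail links
        fail = [0] * len(goto)
        queue: deque[int] = deque()
        for b in range(4):
            s = goto[0][b]
            if s:
                fail[s] = 0
                queue.append(s)
        while queue:
            state = queue.popleft()
            f = fail[state]
            if out[f]:
                out[state] = out[state] + out[f]
                plen[state] = plen[state] + plen[f]
            for b in range(4):
                nxt = goto[state][b]
                if nxt:
                    fail[nxt] = goto[f][b]
                    queue.append(nxt)
                else:
                    goto[state][b] = goto[f][b]
        # flatten
        self._dfa: list[int] = [t for row in goto for t in row]
        self._out: list[tuple[tuple[int, object], ...] | None] = [
            tuple(zip(pl, o)) if o else None for o, pl in zip(out, plen)
        ]

    def iter_matches(self, text: str) -> Iterator[tuple[int, int, object]]:
        """Yield (start, length, payload) for every pattern occurrence."""
        dfa = self._dfa
        outs = self._out
        state = 0
        for i, b in enumerate(text.encode().translate(_ENCODE)):
            state = dfa[4 * state + b] if b < 4 else 0
            hits = outs[state]
            if hits is not None:
                for length, payload in hits:
                    yield i + 1 - length, length, payload


class TagHit(NamedTuple):
    segment_class: str
    gene_index: int
    start: int
    mismatches: int
    length: int


def _hamming1_variants(tag: str) -> Iterator[str]:
    for i, orig in enumerate(tag):
        for b in _BASES:
            if b != orig:
                yield tag[:i] + b + tag[i + 1 :]


def build_tag_automaton(ref: ReferenceSet) -> "TagMatcher":
    return TagMatcher(ref)


class TagMatcher:
    """Single-mismatch multi-tag search over a reference set.

    Every tag is expanded to itself plus its 3L Hamming-1 variants; a
    variant claimed by one tag exactly and by another at one mismatch
    belongs to the exact owner.  A variant claimed at one mismatch by two
    different tags (possible when tags sit at Hamming distance 2) keeps
    both owners; such a read then reports hits for multiple genes and is
    discarded downstream as ambiguous.
    """

    def __init__(self, ref: ReferenceSet):
        variant_owners: dict[str, list[tuple[str, int, int]]] = {}
        for cls in ("V", "J"):
            for idx, gene in enumerate(ref.genes(cls)):
                variant_owners.setdefault(gene.tag, []).insert(0, (cls, idx, 0))
                for var in _hamming1_variants(gene.tag):
                    variant_owners.setdefault(var, []).append((cls, idx, 1))
        patterns: list[tuple[str, object]] = []
        for var, owners in variant_owners.items():
            exact = [o for o in owners if o[2] == 0]
            patterns.append((var, tuple(exact) if exact else tuple(owners)))
        self._automaton = AhoCorasick(patterns)

    def find_tags(self, seq: str) -> list[TagHit]:
        hits = []
        for start, length, owners in self._automaton.iter_matches(seq):
            for cls, idx, mm in owners:  # type: ignore[union-attr]
                hits.append(TagHit(cls, idx, start, mm, length))
        return hits


class TcrIdentifier(NamedTuple):
    """Five-part rearrangement descriptor."""

    v_index: int
    j_index: int
    v_deletions: int
    j_deletions: int
    insert: str


@dataclass(frozen=True)
class DecombinedRecord:
    identifier: TcrIdentifier
    read_id: str
    intertag_sequence: str
    intertag_quality: str
    umi_region: str
    umi_quality: str

    def to_fields(self) -> list[str]:
        i = self.identifier
        return [
            str(i.v_index),
            str(i.j_index),
            str(i.v_deletions),
            str(i.j_deletions),
            i.insert,
            self.read_id,
            self.intertag_sequence,
            self.intertag_quality,
            self.umi_region,
            self.umi_quality,
        ]

    @classmethod
    def from_fields(cls, fields: list[str]) -> "DecombinedRecord":
        if len(fields) != 10:
            raise ValueError(f"expected 10 fields, got {len(fields)}")
        ident = TcrIdentifier(
            int(fields[0]), int(fields[1]), int(fields[2]), int(fields[3]), fields[4]
        )
        return cls(ident, fields[5], fields[6], fields[7], fields[8], fields[9])


NO_CALL_REASONS = (
    "short_read",
    "no_v_tag",
    "no_j_tag",
    "multiple_v",
    "multiple_j",
    "vj_order",
    "negative_insert",
)


def _match_forward(read: str, germline: str, start: int, stop: int) -> int:
    """Length of the exact match of germline against read[start:stop]."""
    n = 0
    limit = min(stop - start, len(germline), len(read) - start)
    while n < limit and read[start + n] == germline[n]:
        n += 1
    return n


def _match_backward(read: str, germline: str, end: int, floor: int) -> int:
    """Length of the exact match of germline's tail ending at read[end]."""
    n = 0
    limit = min(end - floor, len(germline))
    while n < limit and read[end - 1 - n] == germline[len(germline) - 1 - n]:
        n += 1
    return n


def decombine_read(
    seq: str,
    qual: str,
    read_id: str,
    matcher: TagMatcher,
    ref: ReferenceSet,
) -> tuple[DecombinedRecord | None, str | None, tuple[int, int]]:
    """Assign one demultiplexed read (30-base UMI region + R1).

    Returns ``(record, no_call_reason, (tag_mismatch_bases, tag_bases))``;
    exactly one of record / reason is set.  The mismatch tally covers the
    two accepted tag hits and feeds the per-base error-rate lower bound.
    """
    u = layout.UMI_REGION_LEN
    min_tag_span = min(
        (len(g.tag) for g in (*ref.v_genes, *ref.j_genes)), default=0
    )
    if len(seq) < u + min_tag_span:
        return None, "short_read", (0, 0)
    r1 = seq[u:]
    hits = matcher.find_tags(r1)
    v_hits = [h for h in hits if h.segment_class == "V"]
    j_hits = [h for h in hits if h.segment_class == "J"]
    if not v_hits:
        return None, "no_v_tag", (0, 0)
    if not j_hits:
        return None, "no_j_tag", (0, 0)
    if len({h.gene_index for h in v_hits}) > 1:
        return None, "multiple_v", (0, 0)
    if len({h.gene_index for h in j_hits}) > 1:
        return None, "multiple_j", (0, 0)
    # multiple hits of the same gene: leftmost V, rightmost compatible J
    v_hit = min(v_hits, key=lambda h: h.start)
    v_end = v_hit.start + v_hit.length
    compatible = [h for h in j_hits if h.start >= v_end]
    if not compatible:
        if all(h.start + h.length <= v_hit.start for h in j_hits):
            return None, "vj_order", (0, 0)
        return None, "negative_insert", (0, 0)
    j_hit = max(compatible, key=lambda h: h.start)

    v_gene = ref.v_genes[v_hit.gene_index]
    j_gene = ref.j_genes[j_hit.gene_index]
    # minimal V deletions: extend the germline match right of the tag,
    # stopping at the J tag start (V-greedy canonical form)
    v_suffix = v_gene.sequence[v_gene.tag_offset + len(v_gene.tag) :]
    matched_v = _match_forward(r1, v_suffix, v_end, j_hit.start)
    v_del = len(v_suffix) - matched_v
    ve = v_end + matched_v
    # minimal J deletions given the V attribution
    j_prefix = j_gene.sequence[: j_gene.tag_offset]
    matched_j = _match_backward(r1, j_prefix, j_hit.start, ve)
    j_del = len(j_prefix) - matched_j
    js = j_hit.start - matched_j
    insert = r1[ve:js]

    ident = TcrIdentifier(v_hit.gene_index, j_hit.gene_index, v_del, j_del, insert)
    record = DecombinedRecord(
        identifier=ident,
        read_id=read_id,
        intertag_sequence=r1[v_end : j_hit.start],
        intertag_quality=qual[u + v_end : u + j_hit.start],
        umi_region=seq[:u],
        umi_quality=qual[:u],
    )
    tag_bases = v_hit.length + j_hit.length
    return record, None, (v_hit.mismatches + j_hit.mismatches, tag_bases)


def error_rate_lower_bound(tag_hits: Iterable[tuple[int, int]]) -> float | None:
    """Per-base error-rate lower bound from tag mismatches.

    ``tag_hits`` yields (mismatching bases, tag bases inspected) per
    accepted hit or read.  Returns mismatches / bases pooled over all hits,
    or None when no tag bases were inspected.
    """
    mm = bases = 0
    for m, b in tag_hits:
        mm += m
        bases += b
    if bases == 0:
        return None
    return mm / bases


@dataclass
class DecombineLog:
    reads_in: int = 0
    assigned: int = 0
    no_call: dict[str, int] | None = None
    tag_mismatch_bases: int = 0
    tag_bases: int = 0

    def __post_init__(self) -> None:
        if self.no_call is None:
            self.no_call = {r: 0 for r in NO_CALL_REASONS}

    @property
    def error_rate(self) -> float | None:
        if self.tag_bases == 0:
            return None
        return self.tag_mismatch_bases / self.tag_bases

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"reads_in: {self.reads_in}\n")
            fh.write(f"assigned: {self.assigned}\n")
            for reason, n in (self.no_call or {}).items():
                fh.write(f"no_call_{reason}: {n}\n")
            rate = self.error_rate
            fh.write(
                "error_rate_lower_bound: "
                + (f"{rate:.6g}" if rate is not None else "not-available")
                + "\n"
            )


def decombine_stream(
    reads: Iterable[tuple[str, str, str]],
    ref: ReferenceSet,
    matcher: TagMatcher | None = None,
    log: DecombineLog | None = None,
) -> Iterator[DecombinedRecord]:
    """Assign a stream of (id, seq, qual) demultiplexed reads."""
    matcher = matcher or TagMatcher(ref)
    log = log if log is not None else DecombineLog()
    for read_id, seq, qual in reads:
        log.reads_in += 1
        record, reason, (mm, bases) = decombine_read(seq, qual, read_id, matcher, ref)
        if record is None:
            log.no_call[reason] += 1  # type: ignore[index]
            continue
        log.assigned += 1
        log.tag_mismatch_bases += mm
        log.tag_bases += bases
        yield record


def write_n12(records: Iterable[DecombinedRecord], path: str | Path) -> int:
    n = 0
    with open_text(path, "wt") as fh:
        w = csv.writer(fh)
        for rec in records:
            w.writerow(rec.to_fields())
            n += 1
    return n


def read_n12(path: str | Path) -> Iterator[DecombinedRecord]:
    with open_text(path) as fh:
        for fields in csv.reader(fh):
            if fields:
                yield DecombinedRecord.from_fields(fields)


def decombine_file(
    fastq_path: str | Path,
    ref: ReferenceSet,
    out_path: str | Path | None = None,
    log_path: str | Path | None = None,
) -> tuple[Path, DecombineLog]:
    """Run assignment on a demultiplexed FASTQ(.gz), writing ``.n12`` output."""
    fastq_path = Path(fastq_path)
    if out_path is None:
        stem = fastq_path.name
        for suffix in (".gz", ".fq", ".fastq"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        out_path = fastq_path.parent / f"{stem}.n12"
    out_path = Path(out_path)
    log = DecombineLog()
    write_n12(decombine_stream(read_fastq(fastq_path), ref, log=log), out_path)
    log.write(log_path or out_path.with_suffix(out_path.suffix + ".log"))
    return out_path, log


def reconstruct(identifier: TcrIdentifier, ref: ReferenceSet) -> str:
    """Full rearranged nucleotide sequence encoded by a five-part identifier."""
    v_gene = ref.v_genes[identifier.v_index]
    j_gene = ref.j_genes[identifier.j_index]
    if not (0 <= identifier.v_deletions <= v_gene.max_v_deletions):
        raise ValueError(
            f"v_deletions {identifier.v_deletions} outside 0..{v_gene.max_v_deletions} "
            f"for {v_gene.name}"
        )
    if not (0 <= identifier.j_deletions <= j_gene.max_j_deletions):
        raise ValueError(
            f"j_deletions {identifier.j_deletions} outside 0..{j_gene.max_j_deletions} "
            f"for {j_gene.name}"
        )
    v_part = v_gene.sequence[: len(v_gene.sequence) - identifier.v_deletions]
    return v_part + identifier.insert + j_gene.sequence[identifier.j_deletions :]


def canonicalize(identifier: TcrIdentifier, ref: ReferenceSet) -> TcrIdentifier:
    """The V-greedy canonical identifier encoding the same rearrangement.

    The (deletions, insert) decomposition of a junction is not unique when
    inserted bases coincide with germline; assignment always reports the
    canonical form, so ground-truth tables must be canonicalized too.
    """
    seq = reconstruct(identifier, ref)
    v_gene = ref.v_genes[identifier.v_index]
    j_gene = ref.j_genes[identifier.j_index]
    v_tag_end = v_gene.tag_offset + len(v_gene.tag)
    # J tag position in the reconstruction
    j_tag_start = (
        len(seq)
        - (len(j_gene.sequence) - identifier.j_deletions)
        + (j_gene.tag_offset - identifier.j_deletions)
    )
    v_suffix = v_gene.sequence[v_tag_end:]
    matched_v = _match_forward(seq, v_suffix, v_tag_end, j_tag_start)
    ve = v_tag_end + matched_v
    j_prefix = j_gene.sequence[: j_gene.tag_offset]
    matched_j = _match_backward(seq, j_prefix, j_tag_start, ve)
    js = j_tag_start - matched_j
    return TcrIdentifier(
        identifier.v_index,
        identifier.j_index,
        len(v_suffix) - matched_v,
        len(j_prefix) - matched_j,
        seq[ve:js],
    )
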