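"""UMI-based error correction of assigned reads into clonotypes.

Records are grouped by their 12-nt UMI (two 6-nt random slots read out of
the 30-base UMI region).  Within each UMI, near-identical intertag
sequences are clustered greedily from most to least abundant — each cluster
is taken to descend from one cDNA molecule, with the most frequent variant
as its true sequence.  Across UMIs, clusters carrying the same (or nearly
the same) TCR under near-identical UMIs are merged into a single molecule.
A clonotype's abundance ("clone size") is the number of UMI-defined
molecules supporting its identifier; the number of reads absorbed per
molecule is the PCR-amplification readout.

Output dialect: CSV with extension ``.freq`` — the five identifier fields
plus the abundance as a sixth field.
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

from . import layout
from .decombine import DecombinedRecord, TcrIdentifier, read_n12
from .io import open_text

DEFAULT_SEQ_DIVERGENCE = 0.10
DEFAULT_UMI_MISMATCHES = 2
DEFAULT_TCR_MISMATCHES = 2
DEFAULT_MIN_UMI_QUALITY = 20
DEFAULT_SPACER_MISMATCHES = 2


def mismatch_count(a: str, b: str, limit: int | None = None) -> int:
    """Mismatches between two sequences: Hamming over the shorter length
    plus one per missing base (indel-free comparison).

    With ``limit`` the count aborts (returning limit + 1) as soon as it is
    exceeded; callers that only test a threshold use this.
    """
    if len(a) > len(b):
        a, b = b, a
    n = len(b) - len(a)
    if limit is not None:
        if n > limit:
            return limit + 1
        if a == b[: len(a)]:
            return n
        for x, y in zip(a, b):
            if x != y:
                n += 1
                if n > limit:
                    return n
        return n
    for x, y in zip(a, b):
        if x != y:
            n += 1
    return n


def divergence(a: str, b: str) -> float:
    """Per-base divergence: mismatch count over the longer length."""
    longer = max(len(a), len(b))
    if longer == 0:
        return 0.0
    return mismatch_count(a, b) / longer


class ExtractedUmi(NamedTuple):
    umi: str | None
    reject_reason: str | None  # None | "length" | "quality" | "spacer"


def extract_umi(
    umi_region: str,
    umi_quality: str,
    min_quality: int = DEFAULT_MIN_UMI_QUALITY,
    spacers: tuple[str, str] = (layout.DEFAULT_SPACER1, layout.DEFAULT_SPACER2),
    max_spacer_mismatches: int = DEFAULT_SPACER_MISMATCHES,
) -> ExtractedUmi:
    """Pull the 12-nt UMI out of the 30-base region, with quality gating.

    Rejects when the region is not 30 bases, when any UMI base is below the
    Phred threshold (barcode errors create phantom molecules), or when
    either 8-base spacer slot diverges grossly from the expected spacer
    (mis-ligation artifact).
    """
    if len(umi_region) != layout.UMI_REGION_LEN:
        return ExtractedUmi(None, "length")
    for (lo, hi), expected in zip((layout.SPACER1_SLOT, layout.SPACER2_SLOT), spacers):
        observed = umi_region[lo:hi]
        if sum(x != y for x, y in zip(observed, expected)) > max_spacer_mismatches:
            return ExtractedUmi(None, "spacer")
    a1, b1 = layout.UMI1_SLOT
    a2, b2 = layout.UMI2_SLOT
    umi = umi_region[a1:b1] + umi_region[a2:b2]
    quals = umi_quality[a1:b1] + umi_quality[a2:b2]
    if any(ord(q) - 33 < min_quality for q in quals):
        return ExtractedUmi(None, "quality")
    return ExtractedUmi(umi, None)


@dataclass(frozen=True)
class UmiCluster:
    """One within-UMI cluster: a candidate single molecule."""

    umi: str
    sequence: str  # representative (most frequent) intertag sequence
    identifier: TcrIdentifier
    absorbed: int  # reads merged into this cluster


def collapse_within_umi(
    members: Sequence[tuple[str, TcrIdentifier]],
    umi: str,
    max_seq_divergence: float = DEFAULT_SEQ_DIVERGENCE,
) -> list[UmiCluster]:
    """Greedy abundance-ordered clustering of intertag sequences in one UMI.

    Distinct sequences are visited from most to least abundant (ties broken
    lexicographically); every remaining sequence within the divergence
    threshold of the current reference is absorbed into it, then the
    procedure repeats on the residue.  Each cluster inherits the identifier
    of its reference sequence (majority identifier among reads with that
    sequence, ties to the smallest).
    """
    if not members:
        return []
    counts: Counter[str] = Counter(seq for seq, _ in members)
    ident_votes: dict[str, Counter[TcrIdentifier]] = defaultdict(Counter)
    for seq, ident in members:
        ident_votes[seq][ident] += 1
    remaining = sorted(counts, key=lambda s: (-counts[s], s))
    clusters: list[UmiCluster] = []
    while remaining:
        ref_seq = remaining[0]
        kept: list[str] = []
        absorbed = 0
        for seq in remaining:
            if seq == ref_seq or divergence(seq, ref_seq) < max_seq_divergence:
                absorbed += counts[seq]
            else:
                kept.append(seq)
        votes = ident_votes[ref_seq]
        top = max(votes.values())
        ident = min(i for i, n in votes.items() if n == top)
        clusters.append(UmiCluster(umi, ref_seq, ident, absorbed))
        remaining = kept
    return clusters


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


# Sequences at least this long use pigeonhole chunk blocking; shorter ones
# fall back to pairwise comparison within length-stratified buckets.
_BLOCK_SPAN = 30


def _window_chunks(seq: str, end: int, budget: int) -> list[tuple[int, str]]:
    """Chunk the _BLOCK_SPAN bases ending at ``end`` into budget + 1
    pieces; a pair within ``budget`` mismatches over the compared region
    (which contains that window) agrees exactly on one piece.

    The window is anchored at the end of the compared region because in
    V(D)J repertoires many sequences share a long germline prefix while the
    junction — the discriminating part — sits toward the end.
    """
    n = budget + 1
    size = _BLOCK_SPAN // n
    start = end - _BLOCK_SPAN
    return [(c, seq[start + c * size : start + (c + 1) * size]) for c in range(n)]


def similar_sequence_pairs(seqs: Sequence[str], max_mm: int) -> set[tuple[int, int]]:
    """Index pairs (i < j) with mismatch_count(seqs[i], seqs[j]) <= max_mm.

    Candidates come from pigeonhole blocking stratified by sequence
    length: a length difference of d consumes d of the mismatch budget,
    leaving at most ``max_mm - d`` mismatches over the shared prefix, so
    the pair must agree on one of ``max_mm - d + 1`` chunks of the 30-base
    window ending where the shared prefix ends.
    """
    pairs: set[tuple[int, int]] = set()

    def check(i: int, j: int) -> None:
        key = (i, j) if i < j else (j, i)
        if key not in pairs and mismatch_count(seqs[i], seqs[j], max_mm) <= max_mm:
            pairs.add(key)

    by_len: dict[int, list[int]] = defaultdict(list)
    for i, s in enumerate(seqs):
        by_len[len(s)].append(i)
    for l, group in by_len.items():
        for d in range(max_mm + 1):
            other = by_len.get(l + d)
            if other is None or (d == 0 and len(group) < 2):
                continue
            if l < _BLOCK_SPAN:  # short sequences: direct comparison
                if d == 0:
                    for x, i in enumerate(group):
                        for j in group[x + 1 :]:
                            check(i, j)
                else:
                    for i in group:
                        for j in other:
                            check(i, j)
                continue
            # the compared region is the shared prefix of length l
            budget = max_mm - d
            buckets: dict[tuple[int, str], list[int]] = defaultdict(list)
            for i in group:
                for key in _window_chunks(seqs[i], l, budget):
                    buckets[key].append(i)
            if d == 0:
                for members in buckets.values():
                    for x, i in enumerate(members):
                        for j in members[x + 1 :]:
                            check(i, j)
            else:
                for j in other:
                    for key in _window_chunks(seqs[j], l, budget):
                        for i in buckets.get(key, ()):
                            check(i, j)
    return pairs


class SequenceNeighborIndex:
    """Incremental index answering "is any stored sequence within max_mm
    mismatches of this one?" with the same length-stratified blocking
    scheme as :func:`similar_sequence_pairs`."""

    def __init__(self, max_mm: int):
        self.max_mm = max_mm
        self._short: dict[int, list[str]] = defaultdict(list)
        # stored under (shared prefix length, budget, chunk index, chunk)
        self._buckets: dict[tuple[int, int, int, str], list[str]] = defaultdict(list)

    def has_neighbor(self, seq: str) -> bool:
        l = len(seq)
        for l2 in range(l - self.max_mm, l + self.max_mm + 1):
            budget = self.max_mm - abs(l2 - l)
            m = min(l, l2)
            if m < _BLOCK_SPAN:
                for other in self._short.get(l2, ()):
                    if mismatch_count(seq, other, self.max_mm) <= self.max_mm:
                        return True
            else:
                for c, piece in _window_chunks(seq, m, budget):
                    for other in self._buckets.get((m, budget, c, piece), ()):
                        if (
                            len(other) == l2
                            and mismatch_count(seq, other, self.max_mm) <= self.max_mm
                        ):
                            return True
        return False

    def add(self, seq: str) -> None:
        l = len(seq)
        if l < _BLOCK_SPAN + self.max_mm:
            self._short[l].append(seq)
        if l >= _BLOCK_SPAN:
            # index under every shared-prefix length this sequence can have
            # with a partner no more than max_mm shorter
            for d in range(self.max_mm + 1):
                m = l - d
                if m < _BLOCK_SPAN:
                    break
                for budget in range(self.max_mm - d + 1):
                    for c, piece in _window_chunks(seq, m, budget):
                        self._buckets[(m, budget, c, piece)].append(seq)


@dataclass(frozen=True)
class CollapsedClone:
    identifier: TcrIdentifier
    abundance: int  # distinct UMI-defined molecules
    reads_absorbed: int


def merge_umis(
    clusters: Sequence[UmiCluster],
    max_umi_mismatches: int = DEFAULT_UMI_MISMATCHES,
    max_tcr_mismatches: int = DEFAULT_TCR_MISMATCHES,
) -> tuple[list[CollapsedClone], list[int]]:
    """Merge within-UMI clusters that stem from the same labeled molecule.

    Clusters carrying the same (or within ``max_tcr_mismatches``) intertag
    sequence under UMIs within ``max_umi_mismatches`` are joined by
    single-linkage into connected components; each component counts as one
    molecule, attributed to the identifier of its largest member.  Returns
    the clonotype table and the reads-absorbed-per-molecule histogram data
    (one entry per molecule).
    """
    if not clusters:
        return [], []
    distinct_seqs = sorted({c.sequence for c in clusters})
    seq_index = {s: k for k, s in enumerate(distinct_seqs)}
    by_seq: dict[int, list[int]] = defaultdict(list)
    for i, c in enumerate(clusters):
        by_seq[seq_index[c.sequence]].append(i)

    uf = _UnionFind(len(clusters))
    min_umi_len = min(len(c.umi) for c in clusters)
    global_chunk = min_umi_len // (max_umi_mismatches + 1)

    def verify(i: int, j: int) -> None:
        if uf.find(i) != uf.find(j):
            umi_i, umi_j = clusters[i].umi, clusters[j].umi
            if mismatch_count(umi_i, umi_j, max_umi_mismatches) <= max_umi_mismatches:
                uf.union(i, j)

    def umi_chunk_keys(umi: str, chunk: int) -> list[tuple[int, str]]:
        return [
            (c, umi[c * chunk : (c + 1) * chunk])
            for c in range(max_umi_mismatches + 1)
        ]

    def link(group_a: list[int], group_b: list[int] | None = None) -> None:
        # pigeonhole blocking on UMI chunks keeps large clones (many UMIs
        # under one sequence) from costing quadratic UMI comparisons
        others = group_a if group_b is None else group_b
        chunk = global_chunk
        pairwise_cost = (
            len(group_a) * (len(group_a) - 1) // 2
            if group_b is None
            else len(group_a) * len(group_b)
        )
        if chunk == 0 or pairwise_cost <= 4096:
            if group_b is None:
                for x, i in enumerate(group_a):
                    for j in group_a[x + 1 :]:
                        verify(i, j)
            else:
                for i in group_a:
                    for j in group_b:
                        verify(i, j)
            return
        buckets: dict[tuple[int, str], list[int]] = defaultdict(list)
        for i in others:
            for key in umi_chunk_keys(clusters[i].umi, chunk):
                buckets[key].append(i)
        if group_b is None:
            for members in buckets.values():
                for x, i in enumerate(members):
                    for j in members[x + 1 :]:
                        verify(i, j)
        else:
            for i in group_a:
                for key in umi_chunk_keys(clusters[i].umi, chunk):
                    for j in buckets.get(key, ()):
                        verify(i, j)

    for group in by_seq.values():
        link(group)
    for a, b in similar_sequence_pairs(distinct_seqs, max_tcr_mismatches):
        link(by_seq[a], by_seq[b])

    components: dict[int, list[int]] = defaultdict(list)
    for i in range(len(clusters)):
        components[uf.find(i)].append(i)

    molecule_reads: list[int] = []
    per_ident: dict[TcrIdentifier, list[int]] = defaultdict(list)
    for comp in components.values():
        reads = sum(clusters[i].absorbed for i in comp)
        rep = min(comp, key=lambda i: (-clusters[i].absorbed, clusters[i].identifier, clusters[i].umi))
        per_ident[clusters[rep].identifier].append(reads)
        molecule_reads.append(reads)
    clones = [
        CollapsedClone(ident, abundance=len(reads), reads_absorbed=sum(reads))
        for ident, reads in per_ident.items()
    ]
    clones.sort(key=lambda c: (-c.abundance, c.identifier))
    return clones, sorted(molecule_reads)


@dataclass
class CollapseLog:
    records_in: int = 0
    rejected: dict[str, int] = field(
        default_factory=lambda: {"length": 0, "quality": 0, "spacer": 0}
    )
    n_umis: int = 0
    n_molecules: int = 0
    n_clonotypes: int = 0
    reads_per_molecule: list[int] = field(default_factory=list)

    @property
    def retained(self) -> int:
        return self.records_in - sum(self.rejected.values())

    def write(self, path: str | Path) -> None:
        hist = Counter(self.reads_per_molecule)
        with open(path, "w") as fh:
            fh.write(f"records_in: {self.records_in}\n")
            for reason, n in self.rejected.items():
                fh.write(f"rejected_umi_{reason}: {n}\n")
            fh.write(f"umi_count: {self.n_umis}\n")
            fh.write(f"molecule_count: {self.n_molecules}\n")
            fh.write(f"clonotype_count: {self.n_clonotypes}\n")
            fh.write("reads_per_molecule_histogram:\n")
            for reads, n in sorted(hist.items()):
                fh.write(f"  {reads}: {n}\n")


def collapse_records(
    records: Iterable[DecombinedRecord],
    max_seq_divergence: float = DEFAULT_SEQ_DIVERGENCE,
    max_umi_mismatches: int = DEFAULT_UMI_MISMATCHES,
    max_tcr_mismatches: int = DEFAULT_TCR_MISMATCHES,
    min_umi_quality: int = DEFAULT_MIN_UMI_QUALITY,
    spacers: tuple[str, str] = (layout.DEFAULT_SPACER1, layout.DEFAULT_SPACER2),
    max_spacer_mismatches: int = DEFAULT_SPACER_MISMATCHES,
    log: CollapseLog | None = None,
) -> list[CollapsedClone]:
    """Full collapsing procedure: UMI grouping, within-UMI clustering, and
    across-UMI molecule merging."""
    log = log if log is not None else CollapseLog()
    groups: dict[str, list[tuple[str, TcrIdentifier]]] = defaultdict(list)
    for rec in records:
        log.records_in += 1
        umi, reason = extract_umi(
            rec.umi_region,
            rec.umi_quality,
            min_quality=min_umi_quality,
            spacers=spacers,
            max_spacer_mismatches=max_spacer_mismatches,
        )
        if umi is None:
            log.rejected[reason] += 1  # type: ignore[index]
            continue
        groups[umi].append((rec.intertag_sequence, rec.identifier))
    log.n_umis = len(groups)
    clusters: list[UmiCluster] = []
    for umi in sorted(groups):
        clusters.extend(collapse_within_umi(groups[umi], umi, max_seq_divergence))
    clones, molecule_reads = merge_umis(clusters, max_umi_mismatches, max_tcr_mismatches)
    log.n_molecules = len(molecule_reads)
    log.n_clonotypes = len(clones)
    log.reads_per_molecule = molecule_reads
    return clones


def write_freq(clones: Iterable[CollapsedClone], path: str | Path) -> int:
    n = 0
    with open_text(path, "wt") as fh:
        w = csv.writer(fh)
        for c in clones:
            i = c.identifier
            w.writerow([i.v_index, i.j_index, i.v_deletions, i.j_deletions, i.insert, c.abundance])
            n += 1
    return n


def read_freq(path: str | Path) -> Iterator[tuple[TcrIdentifier, int]]:
    with open_text(path) as fh:
        for row in csv.reader(fh):
            if row:
                yield TcrIdentifier(int(row[0]), int(row[1]), int(row[2]), int(row[3]), row[4]), int(row[5])


def collapse_file(
    n12_path: str | Path,
    out_path: str | Path | None = None,
    log_path: str | Path | None = None,
    **params,
) -> tuple[Path, CollapseLog]:
    n12_path = Path(n12_path)
    if out_path is None:
        out_path = n12_path.with_suffix(".freq")
    out_path = Path(out_path)
    log = CollapseLog()
    clones = collapse_records(read_n12(n12_path), log=log, **params)
    write_freq(clones, out_path)
    log.write(log_path or out_path.with_suffix(".freq.log"))
    return out_path, log
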