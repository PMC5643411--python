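"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's data structures and optimizations:
straight nested loops, no blocking indices, no automata.
"""

from __future__ import annotations

from collections import Counter


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def naive_mismatches(a: str, b: str) -> int:
    """Mismatch count: Hamming over the shorter prefix + length penalty."""
    m = min(len(a), len(b))
    return hamming(a[:m], b[:m]) + abs(len(a) - len(b))


def scan_tags(query: str, tags: dict) -> list[tuple]:
    """All (payload, position, mismatches<=1) tag occurrences by direct
    per-position Hamming scanning."""
    hits = []
    for payload, tag in tags.items():
        for pos in range(len(query) - len(tag) + 1):
            mm = hamming(query[pos : pos + len(tag)], tag)
            if mm <= 1:
                hits.append((payload, pos, mm))
    return hits


def all_decompositions(read: str, v_seq: str, v_tag_end_read: int, v_tag_end_gene: int,
                       j_seq: str, j_tag_start_read: int, j_tag_start_gene: int):
    """Every (v_del, j_del, insert) consistent with exact germline matching
    outside the junction, by exhaustive enumeration."""
    v_suffix = v_seq[v_tag_end_gene:]
    j_prefix = j_seq[:j_tag_start_gene]
    out = []
    for v_del in range(len(v_suffix) + 1):
        keep_v = v_suffix[: len(v_suffix) - v_del]
        ve = v_tag_end_read + len(keep_v)
        if ve > j_tag_start_read or read[v_tag_end_read:ve] != keep_v:
            continue
        for j_del in range(len(j_prefix) + 1):
            keep_j = j_prefix[j_del:]
            js = j_tag_start_read - len(keep_j)
            if js < ve or read[js:j_tag_start_read] != keep_j:
                continue
            out.append((v_del, j_del, read[ve:js]))
    return out


def collapse_brute_force(
    records: list[tuple[str, str, tuple]],
    max_seq_divergence: float = 0.10,
    max_umi_mismatches: int = 2,
    max_tcr_mismatches: int = 2,
) -> dict:
    """Literal implementation of the three collapsing steps on
    (umi, intertag_seq, identifier) records.

    (a/b) within each UMI, iterate greedily from the most abundant distinct
    sequence (ties lexicographic), absorbing sequences whose per-base
    divergence is below the threshold; (c) single-linkage components over
    (umi, sequence) clusters joined when sequences are within the mismatch
    threshold and UMIs within the UMI threshold.  Returns identifier ->
    (abundance, reads_absorbed).
    """
    by_umi: dict[str, list[tuple[str, tuple]]] = {}
    for umi, seq, ident in records:
        by_umi.setdefault(umi, []).append((seq, ident))

    clusters = []  # (umi, seq, ident, absorbed)
    for umi in sorted(by_umi):
        members = by_umi[umi]
        counts = Counter(seq for seq, _ in members)
        idents: dict[str, Counter] = {}
        for seq, ident in members:
            idents.setdefault(seq, Counter())[ident] += 1
        remaining = sorted(counts, key=lambda s: (-counts[s], s))
        while remaining:
            ref_seq = remaining[0]
            absorbed = counts[ref_seq]
            rest = []
            for seq in remaining[1:]:
                div = naive_mismatches(seq, ref_seq) / max(len(seq), len(ref_seq))
                if div < max_seq_divergence:
                    absorbed += counts[seq]
                else:
                    rest.append(seq)
            top = max(idents[ref_seq].values())
            ident = min(i for i, n in idents[ref_seq].items() if n == top)
            clusters.append((umi, ref_seq, ident, absorbed))
            remaining = rest

    n = len(clusters)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if naive_mismatches(clusters[i][1], clusters[j][1]) <= max_tcr_mismatches \
                    and naive_mismatches(clusters[i][0], clusters[j][0]) <= max_umi_mismatches:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    table: dict[tuple, list[int]] = {}
    for comp in comps.values():
        rep = min(comp, key=lambda i: (-clusters[i][3], clusters[i][2], clusters[i][0]))
        ident = clusters[rep][2]
        reads = sum(clusters[i][3] for i in comp)
        table.setdefault(ident, [0, 0])
        table[ident][0] += 1
        table[ident][1] += reads
    return {k: tuple(v) for k, v in table.items()}
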