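"""UMI extraction, within-UMI clustering, and molecule merging."""

import random

import pytest

from oracles import collapse_brute_force, naive_mismatches
from umitcr import layout
from umitcr.collapse import (
    CollapseLog,
    collapse_records,
    collapse_within_umi,
    extract_umi,
    merge_umis,
    mismatch_count,
    similar_sequence_pairs,
    SequenceNeighborIndex,
    UmiCluster,
)
from umitcr.decombine import DecombinedRecord, TcrIdentifier

SP1, SP2 = layout.DEFAULT_SPACER1, layout.DEFAULT_SPACER2
HI = "D" * 30  # Phred 35


def _region(u1="AAAAAA", u2="CCCCCC", sp1=SP1, sp2=SP2):
    # 28 layout bases plus 2 bases of downstream sequence = 30
    return sp1 + u1 + sp2 + u2 + "GG"


class TestExtractUmi:
    def test_umi_read_from_the_two_random_slots(self):
        got = extract_umi(_region(), HI)
        assert got.umi == "AAAAAACCCCCC"

    def test_low_quality_umi_base_rejected(self):
        qual = list(HI)
        qual[layout.UMI1_SLOT[0]] = "+"  # Phred 10 at first UMI base
        got = extract_umi(_region(), "".join(qual))
        assert got.umi is None and got.reject_reason == "quality"

    def test_corrupted_spacer_rejected_as_ligation_artifact(self):
        bad_sp2 = "TTT" + SP2[3:]  # 3 mismatches
        got = extract_umi(_region(sp2=bad_sp2), HI)
        assert got.umi is None and got.reject_reason == "spacer"

    def test_two_spacer_mismatches_tolerated(self):
        flip = lambda c: "T" if c != "T" else "A"
        near = flip(SP1[0]) + flip(SP1[1]) + SP1[2:]
        assert extract_umi(_region(sp1=near), HI).umi == "AAAAAACCCCCC"

    def test_wrong_length_rejected(self):
        got = extract_umi("ACGT", "DDDD")
        assert got.reject_reason == "length"


I0 = TcrIdentifier(0, 0, 0, 0, "")
I1 = TcrIdentifier(1, 1, 0, 0, "")


class TestWithinUmi:
    def test_identical_sequences_collapse_to_one_cluster(self):
        members = [("ACGT" * 12, I0)] * 10
        clusters = collapse_within_umi(members, "A" * 12)
        assert len(clusters) == 1
        assert clusters[0].absorbed == 10

    def test_minor_variant_absorbed_into_the_most_common(self):
        x = "ACGT" * 13  # length 52; 1 mismatch ~ 2% < 10%
        y = "T" + x[1:]
        members = [(x, I0)] * 9 + [(y, I1)]
        clusters = collapse_within_umi(members, "A" * 12)
        assert len(clusters) == 1
        assert clusters[0].sequence == x
        assert clusters[0].identifier == I0
        assert clusters[0].absorbed == 10

    def test_divergent_sequences_stay_separate(self):
        x = "A" * 50
        y = "A" * 30 + "G" * 20  # 40% divergence
        members = [(x, I0)] * 5 + [(y, I1)] * 5
        clusters = collapse_within_umi(members, "A" * 12)
        assert sorted(c.absorbed for c in clusters) == [5, 5]

    def test_tie_broken_to_lexicographically_smallest(self):
        x, y = "C" * 40, "G" * 40
        clusters = collapse_within_umi([(y, I1), (x, I0)], "A" * 12)
        assert clusters[0].sequence == x


class TestMergeUmis:
    def test_near_identical_umis_with_same_tcr_are_one_molecule(self):
        seq = "ACGT" * 12
        clusters = [UmiCluster("A" * 12, seq, I0, 3),
                    UmiCluster("A" * 11 + "T", seq, I0, 1)]
        clones, per_mol = merge_umis(clusters)
        assert len(clones) == 1
        assert clones[0].abundance == 1
        assert clones[0].reads_absorbed == 4
        assert per_mol == [4]

    def test_distant_umis_are_separate_molecules(self):
        seq = "ACGT" * 12
        clusters = [UmiCluster("A" * 12, seq, I0, 1),
                    UmiCluster("A" * 6 + "G" * 6, seq, I0, 1)]
        clones, _ = merge_umis(clusters)
        assert clones[0].abundance == 2

    def test_one_umi_carrying_two_distinct_tcrs_gives_two_clones(self):
        clusters = [UmiCluster("A" * 12, "C" * 40, I0, 2),
                    UmiCluster("A" * 12, "G" * 40, I1, 2)]
        clones, _ = merge_umis(clusters)
        assert sorted((c.identifier, c.abundance) for c in clones) == [(I0, 1), (I1, 1)]


def _random_records(rng, n):
    """Records over a tiny clone pool with UMI and sequence perturbations."""
    base_seqs = ["ACGTAGGCTA" * 4, "TTGACCGTAA" * 4, "ACGTAGGCTA" * 3 + "ACGTAGGCTT"]
    idents = [I0, I1, TcrIdentifier(2, 1, 1, 0, "AA")]
    umis = ["".join(rng.choice("ACGT") for _ in range(12)) for _ in range(4)]
    records = []
    for _ in range(n):
        k = rng.randrange(3)
        seq = base_seqs[k]
        if rng.random() < 0.3:  # sequencing error
            pos = rng.randrange(len(seq))
            seq = seq[:pos] + rng.choice("ACGT") + seq[pos + 1 :]
        umi = rng.choice(umis)
        if rng.random() < 0.2:  # UMI error
            pos = rng.randrange(12)
            umi = umi[:pos] + rng.choice("ACGT") + umi[pos + 1 :]
        records.append((umi, seq, idents[k]))
    return records


def test_collapse_matches_brute_force_on_small_instances(ref):
    """Randomized instances of <= 30 records reproduce the literal
    three-step procedure implemented independently."""
    rng = random.Random(42)
    for trial in range(60):
        records = _random_records(rng, rng.randrange(1, 31))
        dec = [
            DecombinedRecord(ident, f"r{i}",
                             seq, "D" * len(seq),
                             _region(u1=umi[:6], u2=umi[6:]), HI)
            for i, (umi, seq, ident) in enumerate(records)
        ]
        log = CollapseLog()
        clones = collapse_records(dec, log=log)
        got = {c.identifier: (c.abundance, c.reads_absorbed) for c in clones}
        want = collapse_brute_force(records)
        assert got == want, f"trial {trial}"
        assert sum(c.reads_absorbed for c in clones) == log.retained == len(records)


def test_monotone_reduction_and_conservation(ref):
    rng = random.Random(7)
    records = _random_records(rng, 200)
    dec = [
        DecombinedRecord(ident, f"r{i}", seq, "D" * len(seq),
                         _region(u1=umi[:6], u2=umi[6:]), HI)
        for i, (umi, seq, ident) in enumerate(records)
    ]
    log = CollapseLog()
    clones = collapse_records(dec, log=log)
    from collections import Counter

    before = Counter(r[2] for r in records)
    assert len(clones) <= len(before)  # clonotype count never inflates
    assert max(c.abundance for c in clones) <= max(before.values())
    assert log.n_molecules <= len(records)
    assert sum(c.reads_absorbed for c in clones) == log.retained


class TestMismatchHelpers:
    @pytest.mark.parametrize("a,b", [
        ("ACGT", "ACGT"), ("ACGT", "ACGA"), ("ACGT", "ACG"), ("ACGTAA", "ACTT"),
        ("", "AAA"), ("AAAA", "TTTT"),
    ])
    def test_mismatch_count_matches_naive(self, a, b):
        want = naive_mismatches(a, b)
        assert mismatch_count(a, b) == want
        for limit in range(6):
            got = mismatch_count(a, b, limit)
            assert (got <= limit) == (want <= limit)

    def test_similar_pairs_match_quadratic_scan(self):
        rng = random.Random(12)
        germ = "ACGTAGGCTAACGTAGGCTAACGTAGGCTA"  # shared 30-nt prefix
        seqs = []
        for _ in range(80):
            tail = "".join(rng.choice("ACGT") for _ in range(rng.randrange(0, 15)))
            s = germ + tail
            if rng.random() < 0.5 and s:
                pos = rng.randrange(len(s))
                s = s[:pos] + rng.choice("ACGT") + s[pos + 1 :]
            seqs.append(s)
        seqs += ["ACGT", "ACGA", "ACG"]  # short-sequence path
        for max_mm in (1, 2):
            want = {
                (i, j)
                for i in range(len(seqs))
                for j in range(i + 1, len(seqs))
                if naive_mismatches(seqs[i], seqs[j]) <= max_mm
            }
            assert similar_sequence_pairs(seqs, max_mm) == want

    def test_neighbor_index_agrees_with_direct_scan(self):
        rng = random.Random(13)
        stored = []
        index = SequenceNeighborIndex(2)
        for step in range(150):
            base = "ACGTAGGCTA" * 3
            s = base[: rng.randrange(25, 31)] + "".join(
                rng.choice("ACGT") for _ in range(rng.randrange(0, 8))
            )
            want = any(naive_mismatches(s, t) <= 2 for t in stored)
            assert index.has_neighbor(s) == want, f"step {step}"
            if not want:
                index.add(s)
                stored.append(s)
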