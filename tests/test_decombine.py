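"""Tag search, five-part identifier assignment, and the 10-field record."""

import csv
import io
import random

import pytest

from oracles import all_decompositions, scan_tags
from umitcr import layout
from umitcr.decombine import (
    AhoCorasick,
    DecombinedRecord,
    TcrIdentifier,
    canonicalize,
    decombine_read,
    decombine_stream,
    DecombineLog,
    error_rate_lower_bound,
    reconstruct,
)
from umitcr.simulate import SimConfig, simulate_repertoire

UMI30 = layout.DEFAULT_SPACER1 + "AAAAAA" + layout.DEFAULT_SPACER2 + "CCCCCC" + "TT"
assert len(UMI30) == layout.UMI_REGION_LEN


def _read(r1_insert: str) -> tuple[str, str]:
    seq = UMI30 + "ACGT" + r1_insert + "TGCA"
    return seq, "D" * len(seq)


def _rearrangement(ref, v, j, v_del, j_del, insert):
    return reconstruct(TcrIdentifier(v, j, v_del, j_del, insert), ref)


class TestAhoCorasick:
    def test_finds_all_overlapping_occurrences(self):
        ac = AhoCorasick([("ACAC", 1), ("CACA", 2)])
        hits = sorted(ac.iter_matches("GACACACG"))
        assert hits == [(1, 4, 1), (2, 4, 2), (3, 4, 1)]

    def test_non_alphabet_characters_reset_the_scan(self):
        ac = AhoCorasick([("ACGT", "p")])
        assert list(ac.iter_matches("ACNGTACGT")) == [(5, 4, "p")]


class TestTagSearch:
    def test_exact_tag_hit_reports_gene_and_position(self, ref, matcher):
        tag = ref.v_genes[2].tag
        query = "T" * 17 + tag + "A" * 10
        hits = [h for h in matcher.find_tags(query) if h.mismatches == 0]
        assert [(h.segment_class, h.gene_index, h.start) for h in hits] == [("V", 2, 17)]

    @pytest.mark.parametrize("n_sub,expect_hit", [(1, True), (2, False)])
    def test_substitutions_against_brute_force_scan(self, ref, matcher, n_sub, expect_hit):
        rng = random.Random(17 + n_sub)
        tags = {("V", i): g.tag for i, g in enumerate(ref.v_genes)}
        tags.update({("J", i): g.tag for i, g in enumerate(ref.j_genes)})
        for _ in range(40):
            cls_i, tag = rng.choice(list(tags.items()))
            mutated = list(tag)
            for pos in rng.sample(range(len(tag)), n_sub):
                mutated[pos] = rng.choice([b for b in "ACGT" if b != mutated[pos]])
            query = "".join(rng.choice("ACGT") for _ in range(12)) + "".join(mutated)
            got = {(h.segment_class, h.gene_index, h.start, h.mismatches)
                   for h in matcher.find_tags(query)}
            want = {(p[0], p[1], pos, mm) for p, pos, mm in scan_tags(query, tags)}
            assert got == want
            assert bool(got) == expect_hit


class TestDecombineRead:
    def test_constructed_junction_yields_expected_identifier(self, ref, matcher):
        # insert TTT shares no bases with the flanking germline, so the
        # generating decomposition is already canonical
        seq, qual = _read(_rearrangement(ref, 0, 1, 2, 1, "TTT"))
        rec, reason, _ = decombine_read(seq, qual, "rid", matcher, ref)
        assert reason is None
        assert rec.identifier == TcrIdentifier(0, 1, 2, 1, "TTT")
        assert rec.read_id == "rid"
        assert rec.umi_region == UMI30

    def test_junction_bases_coinciding_with_germline_fold_into_it(self, ref, matcher):
        # toy J1 starts with G runs, so a G insert is partially attributed
        # to germline by the canonical (V-greedy, minimal-deletion) form
        ident = TcrIdentifier(0, 1, 2, 1, "GGG")
        seq, qual = _read(_rearrangement(ref, *ident))
        rec, reason, _ = decombine_read(seq, qual, "rid", matcher, ref)
        assert reason is None
        assert rec.identifier == canonicalize(ident, ref)
        assert reconstruct(rec.identifier, ref) == reconstruct(ident, ref)

    def test_identity_case_zero_deletions_empty_insert(self, ref, matcher):
        seq, qual = _read(_rearrangement(ref, 3, 2, 0, 0, ""))
        rec, reason, _ = decombine_read(seq, qual, "r", matcher, ref)
        assert rec.identifier == TcrIdentifier(3, 2, 0, 0, "")

    def test_no_j_tag_is_a_categorized_no_call(self, ref, matcher):
        v = ref.v_genes[0].sequence
        seq = UMI30 + "AAAA" + v + "AAAA"
        rec, reason, _ = decombine_read(seq, "D" * len(seq), "r", matcher, ref)
        assert rec is None and reason == "no_j_tag"

    def test_intertag_sequence_contains_insert_and_matches_read(self, ref, matcher):
        insert = "TTAACC"
        seq, qual = _read(_rearrangement(ref, 1, 0, 4, 3, insert))
        rec, _, _ = decombine_read(seq, qual, "r", matcher, ref)
        assert insert in rec.intertag_sequence
        assert rec.intertag_sequence in seq
        assert len(rec.intertag_quality) == len(rec.intertag_sequence)

    def test_soundness_reconstruction_matches_read_between_anchors(self, ref, matcher):
        rng = random.Random(5)
        for _ in range(50):
            v = rng.randrange(4)
            j = rng.randrange(3)
            ident = canonicalize(
                TcrIdentifier(
                    v, j,
                    rng.randrange(ref.v_genes[v].max_v_deletions + 1),
                    rng.randrange(ref.j_genes[j].max_j_deletions + 1),
                    "".join(rng.choice("ACGT") for _ in range(rng.randrange(12))),
                ),
                ref,
            )
            rearr = reconstruct(ident, ref)
            seq, qual = _read(rearr)
            rec, reason, _ = decombine_read(seq, qual, "r", matcher, ref)
            assert reason is None
            assert reconstruct(rec.identifier, ref) == rearr

    def test_minimal_deletions_match_exhaustive_decomposition(self, ref, matcher):
        rng = random.Random(6)
        for _ in range(50):
            v, j = rng.randrange(4), rng.randrange(3)
            v_gene, j_gene = ref.v_genes[v], ref.j_genes[j]
            ident = TcrIdentifier(
                v, j,
                rng.randrange(v_gene.max_v_deletions + 1),
                rng.randrange(j_gene.max_j_deletions + 1),
                "".join(rng.choice("ACGT") for _ in range(rng.randrange(10))),
            )
            rearr = reconstruct(ident, ref)
            prefix = UMI30 + "ACGT"
            read = prefix + rearr + "TGCA"
            rec, reason, _ = decombine_read(read, "D" * len(read), "r", matcher, ref)
            assert reason is None
            r1 = read[30:]
            v_tag_end_read = 4 + v_gene.tag_offset + len(v_gene.tag)
            j_tag_start_read = (
                4 + len(rearr) - (len(j_gene.sequence) - ident.j_deletions)
                + (j_gene.tag_offset - ident.j_deletions)
            )
            options = all_decompositions(
                r1, v_gene.sequence, v_tag_end_read,
                v_gene.tag_offset + len(v_gene.tag),
                j_gene.sequence, j_tag_start_read, j_gene.tag_offset,
            )
            canonical = min(options)  # minimal v_del, then minimal j_del
            assert (rec.identifier.v_deletions, rec.identifier.j_deletions,
                    rec.identifier.insert) == canonical


class TestRecordFormat:
    def test_serialized_record_has_exactly_ten_fields(self):
        rec = DecombinedRecord(
            TcrIdentifier(1, 2, 3, 4, "ACGT"), "id x", "ACGTACGT", "DD,DDDDD",
            "A" * 30, "D" * 30,
        )
        buf = io.StringIO()
        csv.writer(buf).writerow(rec.to_fields())
        parsed = next(csv.reader(io.StringIO(buf.getvalue())))
        assert len(parsed) == 10
        assert DecombinedRecord.from_fields(parsed) == rec

    def test_wrong_field_count_rejected(self):
        with pytest.raises(ValueError, match="10 fields"):
            DecombinedRecord.from_fields(["1"] * 9)


class TestErrorRateLowerBound:
    def test_all_exact_hits_give_zero(self):
        assert error_rate_lower_bound([(0, 20)] * 100) == 0.0

    def test_ten_single_mismatches_in_hundred_hits(self):
        hits = [(1, 20)] * 10 + [(0, 20)] * 90
        assert error_rate_lower_bound(hits) == pytest.approx(10 / 2000)

    def test_pooled_ratio_equals_recount(self):
        rng = random.Random(3)
        hits = [(rng.randrange(2), rng.choice([20, 21])) for _ in range(200)]
        mm = sum(h[0] for h in hits)
        bases = sum(h[1] for h in hits)
        assert error_rate_lower_bound(hits) == pytest.approx(mm / bases)

    def test_no_hits_is_not_available(self):
        assert error_rate_lower_bound([]) is None


def test_completeness_on_clean_simulated_reads(ref, matcher):
    cfg = SimConfig(ref=ref, n_clones=30, seed=21, clone_size_law=("uniform", 2),
                    amplification=("constant", 2), error_rate=0.0)
    run = simulate_repertoire(cfg)
    log = DecombineLog()
    recs = list(decombine_stream(run.demultiplexed_stream(), ref, matcher=matcher, log=log))
    assert log.assigned == log.reads_in == len(run.reads)
    truth = {c.clone_index: c.identifier for c in run.truth.clones}
    by_mol = {m.molecule_index: m.clone_index for m in run.truth.molecules}
    for rec in recs:
        mol = int(rec.read_id.split(".")[1][1:])
        assert rec.identifier == truth[by_mol[mol]]
    assert log.error_rate == 0.0
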