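import numpy as np
import pytest

from srnakit.nat import (
    COINCIDED,
    CONVERGENT,
    DIVERGENT,
    ENCLOSED,
    NatPair,
    assign_nat_sirnas,
    assign_trans_nat_sirnas,
    classify_orientation,
    duplex_filter,
    duplex_filter_sequences,
    enrichment_profile,
    find_cis_nats,
    find_trans_nats,
)
from srnakit.sequence_io import (
    AlignmentHit,
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
)


def tx(tid, start, end, strand, ref="c", exons=None):
    iv = GenomicInterval(ref, start, end, strand)
    return TranscriptModel(tid, tid, iv, exons or ())


class TestFindCisNats:
    def test_fifty_nt_overlap_pairs(self):
        pairs = find_cis_nats([tx("A", 100, 600, "+"), tx("B", 550, 900, "-")])
        assert len(pairs) == 1
        assert pairs[0].overlap_length == 50

    def test_fortynine_nt_no_pair(self):
        assert find_cis_nats([tx("A", 100, 600, "+"), tx("B", 551, 900, "-")]) == []

    def test_same_strand_no_pair(self):
        assert find_cis_nats([tx("A", 100, 600, "+"), tx("B", 550, 900, "+")]) == []

    def test_different_reference_no_pair(self):
        assert find_cis_nats(
            [tx("A", 100, 600, "+"), tx("B", 100, 600, "-", ref="d")]
        ) == []

    def test_pair_reported_once_sorted(self):
        pairs = find_cis_nats([tx("B", 550, 900, "-"), tx("A", 100, 600, "+")])
        assert pairs[0].transcript_a == "A"


class TestClassifyOrientation:
    def test_convergent_partial_overlap(self):
        a = GenomicInterval("c", 100, 600, "+")
        b = GenomicInterval("c", 550, 900, "-")
        assert classify_orientation(a, b) == CONVERGENT

    def test_divergent_partial_overlap(self):
        a = GenomicInterval("c", 100, 600, "-")
        b = GenomicInterval("c", 550, 900, "+")
        assert classify_orientation(a, b) == DIVERGENT

    def test_enclosed(self):
        a = GenomicInterval("c", 100, 900, "+")
        b = GenomicInterval("c", 300, 500, "-")
        assert classify_orientation(a, b) == ENCLOSED

    def test_coincided(self):
        a = GenomicInterval("c", 100, 600, "+")
        b = GenomicInterval("c", 100, 600, "-")
        assert classify_orientation(a, b) == COINCIDED

    def test_shared_endpoint_is_enclosed(self):
        a = GenomicInterval("c", 100, 600, "+")
        b = GenomicInterval("c", 100, 500, "-")
        assert classify_orientation(a, b) == ENCLOSED

    def test_same_strand_rejected(self):
        a = GenomicInterval("c", 100, 600, "+")
        with pytest.raises(ValueError):
            classify_orientation(a, a)

    def test_total_and_matches_terminus_oracle(self, rng):
        # brute-force re-derivation from terminus positions over random
        # overlapping opposite-strand pairs
        for _ in range(300):
            s1 = int(rng.integers(0, 500))
            e1 = s1 + int(rng.integers(50, 400))
            s2 = int(rng.integers(max(0, s1 - 200), e1 - 1))
            e2 = s2 + int(rng.integers(50, 400))
            if min(e1, e2) - max(s1, s2) < 1:
                continue
            strand_a = "+" if rng.random() < 0.5 else "-"
            strand_b = "-" if strand_a == "+" else "+"
            a = GenomicInterval("c", s1, e1, strand_a)
            b = GenomicInterval("c", s2, e2, strand_b)
            got = classify_orientation(a, b)
            # oracle
            if (s1, e1) == (s2, e2):
                expected = COINCIDED
            elif (s1 <= s2 and e2 <= e1) or (s2 <= s1 and e1 <= e2):
                expected = ENCLOSED
            else:
                left_plus = strand_a == "+" if s1 < s2 else strand_b == "+"
                expected = CONVERGENT if left_plus else DIVERGENT
            assert got == expected, (a, b)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestFindTransNats:
    def test_exact_complementary_block_found(self, rng):
        a = random_seq(rng, 400)
        b = random_seq(rng, 120) + reverse_complement(a[100:250]) + random_seq(rng, 120)
        pairs = find_trans_nats({"a": a, "b": b})
        assert len(pairs) == 1
        assert pairs[0].overlap_length >= 100
        s, e = pairs[0].span_a
        assert s >= 95 and e <= 255

    def test_short_block_rejected(self, rng):
        a = random_seq(rng, 400)
        b = random_seq(rng, 150) + reverse_complement(a[100:180]) + random_seq(rng, 150)
        assert find_trans_nats({"a": a, "b": b}) == []

    def test_self_pair_skipped(self, rng):
        a = random_seq(rng, 400)
        assert find_trans_nats({"a": a}) == []

    def test_excluded_ids_skipped(self, rng):
        a = random_seq(rng, 400)
        b = random_seq(rng, 100) + reverse_complement(a[100:250]) + random_seq(rng, 100)
        assert find_trans_nats({"a": a, "b": b}, exclude={"a"}) == []

    def test_random_pairs_not_called(self, rng):
        seqs = {f"t{i}": random_seq(rng, 400) for i in range(6)}
        assert find_trans_nats(seqs) == []


def columns_pair(cols):
    return NatPair(kind="trans", transcript_a="a", transcript_b="b",
                   overlap_length=len(cols), columns=cols)


class TestDuplexFilter:
    def test_perfect_fifty_accepted(self):
        cols = [("A", "A")] * 50
        fraction, accepted = duplex_filter(columns_pair(cols))
        assert accepted and fraction == 1.0

    def test_gu_columns_count_as_paired(self):
        cols = [("G", "A"), ("T", "C")] * 25
        fraction, accepted = duplex_filter(columns_pair(cols))
        assert accepted and fraction == 1.0

    def test_spread_mismatches_rejected(self):
        # 100 columns, a mismatch every 6th position + extras: no 50-window
        # reaches 90%
        cols = []
        for i in range(100):
            cols.append(("A", "C") if i % 6 == 0 else ("A", "A"))
        fraction, accepted = duplex_filter(columns_pair(cols))
        assert not accepted
        assert fraction < 0.9

    def test_boundary_fiftyfour_of_sixty(self):
        cols = [("A", "C")] * 3 + [("A", "A")] * 54 + [("A", "C")] * 3
        fraction, accepted = duplex_filter(columns_pair(cols))
        assert accepted  # the 60-nt window holds exactly 90%

    def test_too_short_rejected(self):
        fraction, accepted = duplex_filter(columns_pair([("A", "A")] * 49))
        assert not accepted

    def test_matches_sliding_window_oracle(self, rng):
        # brute-force window pairing count on random 200-column alignments
        paired_set = {("A", "A"), ("C", "C"), ("G", "G"), ("T", "T"),
                      ("G", "A"), ("T", "C")}
        for _ in range(100):
            cols = []
            for _ in range(200):
                if rng.random() < 0.85:
                    b = rng.choice(list("ACGT"))
                    cols.append((b, b))
                else:
                    cols.append(tuple(rng.choice(list("ACGT"), 2)))
            pair = columns_pair(cols)
            fraction, accepted = duplex_filter(pair)
            flags = [1 if c in paired_set else 0 for c in cols]
            expected_accept = False
            best = 0.0
            for w in range(50, 201):
                for s in range(0, 201 - w):
                    f = sum(flags[s : s + w]) / w
                    if f >= 0.9 - 1e-12:
                        expected_accept = True
                        best = max(best, f)
            assert accepted == expected_accept
            if accepted:
                assert fraction == pytest.approx(best)

    def test_sequence_wrapper_on_real_pair(self, rng):
        a = random_seq(rng, 300)
        b = random_seq(rng, 100) + reverse_complement(a[100:220]) + random_seq(rng, 100)
        fraction, accepted = duplex_filter_sequences(a, b)
        assert accepted and fraction == 1.0


def ghit(seq, start, strand="+", ref="c"):
    return AlignmentHit(seq, GenomicInterval(ref, start, start + len(seq), strand))


class TestAssignNatSirnas:
    def setup_method(self):
        self.ta = tx("A", 100, 600, "+", exons=((100, 300), (400, 600)))
        self.tb = tx("B", 550, 900, "-", exons=((550, 900),))
        self.pairs = find_cis_nats([self.ta, self.tb])
        self.models = {"A": self.ta, "B": self.tb}

    def test_overlap_exon_plus(self):
        out = assign_nat_sirnas(
            [ghit("T" * 21, 560)], self.pairs, self.models, {"T" * 21: 9}
        )
        assert (out[0].region, out[0].feature, out[0].strand) == ("overlap", "exon", "plus")
        assert out[0].reads == 9

    def test_non_overlap(self):
        out = assign_nat_sirnas(
            [ghit("T" * 21, 150)], self.pairs, self.models, {"T" * 21: 1}
        )
        assert out[0].region == "non_overlap"

    def test_intron_label(self):
        out = assign_nat_sirnas(
            [ghit("T" * 21, 320)], self.pairs, self.models, {"T" * 21: 1}
        )
        assert out[0].feature == "intron"

    def test_straddling_hit_midpoint_rule(self):
        # hit [540, 561): midpoint 550 is the first overlap base -> overlap;
        # hit [539, 560): midpoint 549 -> non_overlap  (derived by the rule)
        out1 = assign_nat_sirnas([ghit("T" * 21, 540)], self.pairs, self.models, {})
        out2 = assign_nat_sirnas([ghit("G" * 21, 539)], self.pairs, self.models, {})
        assert out1[0].region == "overlap"
        assert out2[0].region == "non_overlap"

    def test_outside_pair_ignored(self):
        assert assign_nat_sirnas([ghit("T" * 21, 2000)], self.pairs, self.models, {}) == []

    def test_trans_assignment_overlap(self, rng):
        a = random_seq(rng, 400)
        b = random_seq(rng, 120) + reverse_complement(a[100:250]) + random_seq(rng, 120)
        pairs = find_trans_nats({"a": a, "b": b})
        hits = [ghit(a[150:171], 150, "+", ref="a"), ghit(a[0:21], 0, "+", ref="a")]
        out = assign_trans_nat_sirnas(hits, pairs, {a[150:171]: 3, a[0:21]: 2})
        regions = {h.sequence: h.region for h in out}
        assert regions[a[150:171]] == "overlap"
        assert regions[a[0:21]] == "non_overlap"


class TestEnrichment:
    def test_all_overlap(self):
        out = assign_nat_sirnas_stub = None
        from srnakit.nat import NatSirnaAssignment

        rows = [NatSirnaAssignment("s1", "p", "overlap", "exon", "plus", 10)]
        table = enrichment_profile(rows)
        overlap = table[(table.dimension == "region") & (table.key == "overlap")]
        assert overlap.iloc[0]["fraction"] == 1.0

    def test_strand_fractions(self):
        from srnakit.nat import NatSirnaAssignment

        rows = [
            NatSirnaAssignment("s1", "p", "overlap", "exon", "plus", 66),
            NatSirnaAssignment("s2", "p", "overlap", "exon", "minus", 34),
        ]
        table = enrichment_profile(rows)
        plus = table[(table.dimension == "strand") & (table.key == "plus")]
        assert plus.iloc[0]["fraction"] == pytest.approx(0.66)

    def test_each_dichotomy_sums_to_one(self, default_pipeline_results):
        table = default_pipeline_results["enrichment"]
        if table.empty:
            pytest.skip("no nat assignments in this simulation")
        for dim in ("region", "feature", "strand"):
            total = table[table.dimension == dim]["fraction"].sum()
            assert total == pytest.approx(1.0)

    def test_empty(self):
        assert enrichment_profile([]).empty


class TestSyntheticNatRecovery:
    def test_orientations_all_correct(self, default_simulation, default_pipeline_results):
        _, reference, _ = default_simulation
        truth = {p["pair_id"]: p["orientation"] for p in reference.manifest.cis_pairs}
        called = {p.pair_id: p.orientation for p in default_pipeline_results["cis_pairs"]}
        assert called == truth

    def test_trans_pairs_pass_and_decoys_fail(self, default_simulation, default_pipeline_results):
        _, reference, _ = default_simulation
        truth = {p["pair_id"] for p in reference.manifest.trans_pairs}
        decoys = {p["pair_id"] for p in reference.manifest.trans_decoys}
        called = {p.pair_id for p in default_pipeline_results["trans_pairs"]}
        assert truth <= called
        assert not (called & decoys)
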