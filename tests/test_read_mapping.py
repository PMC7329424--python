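import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dropsketch import Params, ReadPair, SequenceRecord, Taxonomy
from dropsketch.barcodes import Whitelist
from dropsketch.read_mapping import (
    DiscardReason,
    best_range_score,
    lookup_hits,
    map_read,
    resolve_gene,
    score_read,
    select_candidates,
    sketch_read,
)
from dropsketch.reference_db import WindowSpan, build_database, sketch_window

from conftest import random_seq
from oracles import brute_force_scores


class TestSketchRead:
    def test_default_read_has_33_feature_capacity(self, default_params, rng):
        seq = random_seq(rng, 98)
        sketches = sketch_read(seq, default_params)
        assert [w for w, _ in sketches] == [0, 1, 2]
        # windows hold 41, 41 and 1 k-mers; sketch caps the first two at s=16
        assert [len(sk) for _, sk in sketches] == [16, 16, 1]
        assert sum(len(sk) for _, sk in sketches) == 33

    def test_read_of_length_k(self, default_params):
        sketches = sketch_read("ACGTACGTACGTACGT", default_params)
        assert len(sketches) == 1 and len(sketches[0][1]) == 1

    def test_read_shorter_than_k_empty(self, default_params):
        assert sketch_read("ACGT", default_params) == []

    def test_read_equal_to_reference_window(self, toy_reference, default_params):
        records, _ = toy_reference
        seq = records[0].sequence
        window = seq[:56]
        read_sk = sketch_read(window, default_params)[0][1]
        ref_sk = sketch_window(seq, WindowSpan(0, 56), default_params)
        assert read_sk == ref_sk


class TestLookupHits:
    def test_foreign_read_no_hits(self, toy_db, default_params):
        # homopolymer k-mers do not occur in the random toy reference
        sketches = sketch_read("A" * 98, default_params)
        assert all(f not in toy_db.table for _, sk in sketches for f in sk)
        assert lookup_hits(toy_db, sketches) == {}

    def test_window_copy_scores_full_sketch(self, toy_db, toy_reference, default_params):
        records, _ = toy_reference
        window = records[2].sequence[:56]  # txB, window 0
        sketches = sketch_read(window, default_params)
        acc = lookup_hits(toy_db, sketches)
        assert acc[2][0] >= 16  # all s features of window 0 hit

    def test_duplicate_feature_counts_twice(self, default_params):
        tax = Taxonomy()
        tax.add("t", "g")
        block = random_seq(np.random.default_rng(3), 56)
        ref = [SequenceRecord("t", block)]
        db = build_database(ref, tax, default_params)
        # the same feature value appearing in two read windows increments
        # its target windows once per occurrence
        sk = sketch_read(block, default_params)
        acc_once = lookup_hits(db, sk)
        acc_twice = lookup_hits(db, sk + sk)
        assert acc_twice[0][0] == 2 * acc_once[0][0]


class TestBestRangeScore:
    def test_adjacent_windows_aggregate(self):
        assert best_range_score({0: 3, 2: 5, 3: 2}, 2) == 7

    def test_r1_is_max_single_window(self):
        assert best_range_score({0: 3, 2: 5, 3: 2}, 1) == 5

    def test_distant_hits_never_aggregate(self):
        assert best_range_score({0: 3, 10: 5}, 2) == 5

    def test_empty_map_scores_zero(self):
        assert best_range_score({}, 3) == 0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=100)
    def test_matches_naive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        hits = {
            int(w): int(rng.integers(1, 10))
            for w in rng.choice(30, size=rng.integers(0, 10), replace=False)
        }
        r = int(rng.integers(1, 6))
        naive = 0
        for start in range(-5, 35):
            naive = max(naive, sum(c for w, c in hits.items() if start <= w < start + r))
        assert best_range_score(hits, r) == naive

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_r(self, seed):
        rng = np.random.default_rng(seed)
        hits = {int(w): int(rng.integers(1, 10)) for w in rng.choice(20, size=6, replace=False)}
        scores = [best_range_score(hits, r) for r in range(1, 8)]
        assert scores == sorted(scores)


class TestSelectAndResolve:
    def test_threshold_inclusive(self):
        assert select_candidates({1: 30, 2: 27}, 28) == {1: 30}
        assert select_candidates({1: 28}, 28) == {1: 28}

    def test_all_below_threshold_empty(self):
        assert select_candidates({1: 5, 2: 27}, 28) == {}

    def test_growing_threshold_shrinks_candidates(self):
        scores = {1: 10, 2: 20, 3: 30}
        prev = None
        for thr in (5, 15, 25, 35):
            cur = set(select_candidates(scores, thr))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_same_gene_takes_max_score(self, toy_db):
        # txA1 (index 0) and txA2 (index 1) are both geneA
        assert resolve_gene({0: 30, 1: 29}, toy_db) == ("geneA", 30)

    def test_two_genes_ambiguous(self, toy_db):
        assert resolve_gene({0: 30, 2: 30}, toy_db) is DiscardReason.AMBIGUOUS_GENE

    def test_single_candidate(self, toy_db):
        assert resolve_gene({2: 28}, toy_db) == ("geneB", 28)

    def test_empty_unmapped(self, toy_db):
        assert resolve_gene({}, toy_db) is None


class TestMapRead:
    WL = Whitelist.from_members({"A" * 16})

    def _pair(self, m2, cb="A" * 16, umi="C" * 10):
        return ReadPair(name="r", mate1_seq=cb + umi, mate2_seq=m2)

    def test_clean_read_maps_to_true_gene(self, toy_db, toy_reference, default_params):
        records, _ = toy_reference
        read = records[2].sequence[:98]  # txB from its window grid origin
        rec = map_read(toy_db, self._pair(read), self.WL, default_params)
        assert rec.mapped and rec.gene == "geneB"
        assert rec.score >= 32
        assert rec.umi == "C" * 10

    def test_shared_isoform_region_resolves_to_gene(self, toy_db, toy_reference, default_params):
        records, _ = toy_reference
        read = records[0].sequence[:98]  # shared prefix of txA1/txA2
        rec = map_read(toy_db, self._pair(read), self.WL, default_params)
        assert rec.mapped and rec.gene == "geneA"

    def test_cb_distance_two_discarded(self, toy_db, toy_reference, default_params):
        records, _ = toy_reference
        rec = map_read(
            toy_db,
            self._pair(records[2].sequence[:98], cb="TT" + "A" * 14),
            self.WL,
            default_params,
        )
        assert rec.reason is DiscardReason.CB_UNMATCHED

    def test_shared_block_two_genes_ambiguous(self, default_params):
        rng = np.random.default_rng(9)
        block = random_seq(rng, 160)
        tax = Taxonomy()
        tax.add("t1", "gX")
        tax.add("t2", "gY")
        refs = [
            SequenceRecord("t1", block + random_seq(rng, 100)),
            SequenceRecord("t2", block + random_seq(rng, 140)),
        ]
        db = build_database(refs, tax, default_params)
        rec = map_read(db, self._pair(block[:98]), self.WL, default_params)
        assert rec.reason is DiscardReason.AMBIGUOUS_GENE

    def test_unmappable_read(self, toy_db, default_params):
        rec = map_read(toy_db, self._pair("A" * 98), self.WL, default_params)
        assert rec.reason in (DiscardReason.UNMAPPED, DiscardReason.AMBIGUOUS_GENE)
        assert rec.reason is DiscardReason.UNMAPPED

    def test_malformed_precedence(self, toy_db, default_params):
        short_m1 = ReadPair(name="r", mate1_seq="ACGT", mate2_seq="A" * 98)
        assert map_read(toy_db, short_m1, self.WL, default_params).reason is DiscardReason.MALFORMED
        short_m2 = self._pair("ACGT")
        assert map_read(toy_db, short_m2, self.WL, default_params).reason is DiscardReason.MALFORMED


def _random_instance(seed, n_tx_max=12, len_max=400):
    """Small random reference + a batch of reads (half copied, half random)."""
    rng = np.random.default_rng(seed)
    n_tx = int(rng.integers(2, n_tx_max))
    tax = Taxonomy()
    records = []
    for i in range(n_tx):
        tx = f"t{i}"
        tax.add(tx, f"g{i % max(1, n_tx // 2)}")
        records.append(SequenceRecord(tx, random_seq(rng, int(rng.integers(60, len_max)))))
    reads = []
    for _ in range(6):
        if rng.random() < 0.5:
            src = records[rng.integers(0, n_tx)].sequence
            L = min(len(src), 98)
            start = int(rng.integers(0, len(src) - L + 1))
            read = src[start : start + L]
            if rng.random() < 0.3:  # sprinkle errors
                pos = int(rng.integers(0, len(read)))
                read = read[:pos] + "ACGT"[rng.integers(0, 4)] + read[pos + 1 :]
        else:
            read = random_seq(rng, int(rng.integers(20, 98)))
        reads.append(read)
    return records, tax, reads


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_scores_equal_brute_force(self, seed):
        """Hash-table mapping scores match direct all-window sketch comparison."""
        records, tax, reads = _random_instance(seed)
        params = Params(max_locations=5 if seed % 3 == 0 else 1000)
        db = build_database(records, tax, params)
        for read in reads:
            expected = brute_force_scores(records, read, params)
            got = score_read(db, read, params)
            got = {t: s for t, s in got.items() if s > 0}
            assert got == expected


class TestDeterminism:
    def test_read_order_independent(self, toy_db, toy_reference, default_params):
        records, _ = toy_reference
        wl = Whitelist.from_members({"A" * 16})
        pairs = [
            ReadPair(name=f"r{i}", mate1_seq="A" * 16 + "C" * 10, mate2_seq=rec.sequence[:98])
            for i, rec in enumerate(records)
        ]
        fwd = [map_read(toy_db, p, wl, default_params) for p in pairs]
        rev = [map_read(toy_db, p, wl, default_params) for p in reversed(pairs)]
        assert fwd == list(reversed(rev))
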