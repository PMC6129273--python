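"""Seeding, chaining, extension and the end-to-end pipeline."""

import pytest

from cnescan.core import Anchor, Chain, CneHit, Params, Region, identity_score
from cnescan.discover import (
    dedup_hits,
    discover_cnes,
    extend_chain,
    find_mems,
    merge_anchors,
)
from cnescan.synth import SynthSpec, generate_pair, mutate_sequence, score_recovery

from .oracles import brute_force_mems, dp_edit_distance, random_dna_string


def region(seq, name="r", offset=0):
    return Region(name, offset, seq)


class TestFindMems:
    @pytest.mark.parametrize(
        "x,y,l_min,expected",
        [
            ("ACGTACGT", "ACGT", 4, {(0, 0, 4), (4, 0, 4)}),
            ("AAAA", "AAAA", 4, {(0, 0, 4)}),
            ("AAAA", "CCCC", 1, set()),
            ("ACGT", "", 1, set()),
            ("ACGNACG", "ACGT", 3, {(0, 0, 3), (4, 0, 3)}),  # N splits matches
        ],
    )
    def test_examples(self, x, y, l_min, expected):
        got = {(a.ref_start, a.query_start, a.length) for a in find_mems(region(x), region(y), l_min)}
        assert got == expected

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            lx, ly = rng.integers(0, 150, size=2)
            with_n = bool(rng.integers(0, 2))
            x = random_dna_string(rng, lx, with_n)
            y = random_dna_string(rng, ly, with_n)
            for l_min in (3, 5, 8):
                got = {
                    (a.ref_start, a.query_start, a.length)
                    for a in find_mems(region(x), region(y), l_min)
                }
                assert got == brute_force_mems(x, y, l_min)

    def test_seed_cap_handles_large_l_min(self, rng):
        """L_min above the 31-bp packing cap still yields the exact MEM set."""
        x = random_dna_string(rng, 300)
        y = x[50:150] + random_dna_string(rng, 100)
        got = {
            (a.ref_start, a.query_start, a.length)
            for a in find_mems(region(x), region(y), 40)
        }
        assert got == brute_force_mems(x, y, 40)

    def test_output_sorted_and_worker_invariant(self, rng):
        x = random_dna_string(rng, 400)
        y = random_dna_string(rng, 300)
        base = find_mems(region(x), region(y), 4, n_workers=1)
        assert base == sorted(base, key=lambda a: (a.ref_start, a.query_start))
        for workers in (2, 3, 7):
            assert find_mems(region(x), region(y), 4, n_workers=workers) == base


class TestMergeAnchors:
    p = Params(min_len=10, max_len=100, identity_t=0.8, min_chain_coverage=10)

    def test_bridges_small_gap(self, rng):
        """Two anchors split by a 2-bp mismatch merge into one chain."""
        seq = random_dna_string(rng, 22)
        x = seq[:10] + "AA" + seq[12:]
        y = seq[:10] + "CC" + seq[12:]
        anchors = [Anchor(0, 0, 10), Anchor(12, 12, 10)]
        chains = merge_anchors(anchors, region(x), region(y), self.p)
        assert len(chains) == 1
        ch = chains[0]
        assert ch.ref_span == (0, 22) and ch.query_span == (0, 22)
        assert ch.gap_edit == dp_edit_distance(x[10:12], y[10:12]) == 2

    def test_single_anchor_chain(self):
        anchors = [Anchor(0, 0, 12)]
        x = y = region("ACGTACGTACGT")
        chains = merge_anchors(anchors, x, y, self.p)
        assert len(chains) == 1
        assert chains[0].gap_edit == 0
        assert chains[0].anchors == anchors

    def test_overlapping_anchors_never_merge(self, rng):
        anchors = [Anchor(0, 0, 10), Anchor(5, 20, 10)]
        x = region(random_dna_string(rng, 40))
        y = region(random_dna_string(rng, 40))
        chains = merge_anchors(anchors, x, y, self.p)
        assert all(len(c.anchors) == 1 for c in chains)
        assert len(chains) == 2

    def test_coverage_filter(self, rng):
        p = Params(min_len=10, max_len=100, identity_t=0.8, min_chain_coverage=50)
        x = y = region(random_dna_string(rng, 30))
        assert merge_anchors([Anchor(0, 0, 30)], x, y, p) == []

    def test_span_cannot_exceed_max_len(self, rng):
        p = Params(min_len=10, max_len=20, identity_t=0.8, min_chain_coverage=10)
        seq = random_dna_string(rng, 50)
        x = y = region(seq)
        chains = merge_anchors([Anchor(0, 0, 50)], x, y, p)
        assert chains == []


class TestExtendChain:
    def test_identical_regions_nothing_to_extend(self, rng):
        seq = random_dna_string(rng, 200)
        x = y = region(seq)
        p = Params(min_len=200, max_len=500, identity_t=0.9)
        chain = Chain([Anchor(0, 0, 200)], 0, (0, 200), (0, 200))
        hit = extend_chain(chain, x, y, p)
        assert hit is not None
        assert (hit.ref_start, hit.ref_end) == (0, 200)
        assert hit.identity == 1.0 and hit.edit_distance == 0

    def test_recovers_planted_flanks(self, rng):
        """A chain seeded inside a planted element grows back out to it."""
        core = random_dna_string(rng, 300)
        mut, n_sub, n_ind, _ = mutate_sequence(core, 0.02, 0.0, rng)
        x = region(random_dna_string(rng, 200) + core + random_dna_string(rng, 200))
        y = region(random_dna_string(rng, 100) + mut + random_dna_string(rng, 100))
        p = Params(min_len=200, max_len=500, identity_t=0.9)
        anchors = find_mems(x, y, 9)
        chains = merge_anchors(anchors, x, y, p)
        hits = [h for c in chains if (h := extend_chain(c, x, y, p))]
        assert hits, "planted element not recovered"
        best = max(hits, key=lambda h: h.identity)
        ov = min(best.ref_end, 500) - max(best.ref_start, 200)
        assert ov / 300 >= 0.95
        # the hit may lawfully overshoot into background while identity
        # stays above threshold; the planted core itself is near-identical
        assert best.identity >= 0.9 - 1e-9
        assert identity_score(core, mut) >= 1 - (n_sub + n_ind) / 300

    def test_hostile_flanks_leave_chain_hull(self, rng):
        """With maximally dissimilar flanks the hit equals the chain hull."""
        seq = random_dna_string(rng, 200)
        x = region("A" * 50 + seq + "A" * 50)
        y = region("C" * 50 + seq + "C" * 50)
        p = Params(min_len=200, max_len=300, identity_t=1.0)
        chain = Chain([Anchor(50, 50, 200)], 0, (50, 250), (50, 250))
        hit = extend_chain(chain, x, y, p)
        assert hit is not None
        assert (hit.ref_start, hit.ref_end) == (50, 250)

    def test_too_short_after_extension_returns_none(self, rng):
        seq = random_dna_string(rng, 50)
        x = region("A" * 20 + seq + "A" * 20)
        y = region("C" * 20 + seq + "C" * 20)
        p = Params(min_len=200, max_len=500, identity_t=0.95)
        chain = Chain([Anchor(20, 20, 50)], 0, (20, 70), (20, 70))
        assert extend_chain(chain, x, y, p) is None


class TestDedupHits:
    @staticmethod
    def hit(rs, re, qs, qe, ident):
        return CneHit("chrA", rs, re, "chrB", qs, qe, 5, ident)

    def test_identical_hits_collapse(self):
        h = self.hit(0, 300, 0, 300, 0.95)
        assert dedup_hits([h, h]) == [h]

    def test_disjoint_hits_kept(self):
        a = self.hit(0, 300, 0, 300, 0.95)
        b = self.hit(1000, 1300, 1000, 1300, 0.95)
        assert dedup_hits([b, a]) == [a, b]

    def test_higher_identity_survives(self):
        a = self.hit(0, 300, 0, 300, 0.96)
        b = self.hit(10, 310, 10, 310, 0.93)
        assert dedup_hits([a, b]) == [a]

    def test_query_disjoint_hits_both_kept(self):
        a = self.hit(0, 300, 0, 300, 0.96)
        b = self.hit(10, 310, 5000, 5300, 0.93)
        assert dedup_hits([a, b]) == [a, b]


class TestDiscoverPipeline:
    def test_exact_match_limit(self, rng):
        """t=1 on x == y reports only character-identical substring pairs."""
        seq = random_dna_string(rng, 10_000)
        x = y = region(seq, "chr")
        p = Params(min_len=200, max_len=10_000, identity_t=1.0)
        hits = discover_cnes(x, y, p)
        assert hits
        for h in hits:
            assert seq[h.ref_start:h.ref_end] == seq[h.query_start:h.query_end]
            assert h.edit_distance == 0 and h.identity == 1.0

    def test_all_n_reference_yields_nothing(self):
        x = region("N" * 1000)
        y = region("ACGT" * 250)
        p = Params(min_len=20, max_len=500, identity_t=0.9)
        assert discover_cnes(x, y, p) == []

    def test_planted_recovery_small(self, small_pair):
        pair = small_pair
        x = region(pair.ref[pair.spec.ref_name], pair.spec.ref_name)
        y = region(pair.query[pair.spec.query_name], pair.spec.query_name)
        p = Params(min_len=200, max_len=400, identity_t=0.9)
        hits = discover_cnes(x, y, p)
        report = score_recovery(hits, pair.truth, min_overlap=0.8)
        assert report.sensitivity >= 0.85
        for h in hits:  # soundness on every hit
            ident = identity_score(
                pair.ref[h.ref_name][h.ref_start:h.ref_end],
                pair.query[h.query_name][h.query_start:h.query_end],
            )
            assert ident >= 0.9 - 1e-9
            assert 200 <= h.ref_len <= 400 and 200 <= h.query_len <= 400

    def test_raising_threshold_keeps_hits_sound(self, small_pair):
        pair = small_pair
        x = region(pair.ref[pair.spec.ref_name], pair.spec.ref_name)
        y = region(pair.query[pair.spec.query_name], pair.spec.query_name)
        low = discover_cnes(x, y, Params(200, 400, 0.85))
        high = discover_cnes(x, y, Params(200, 400, 0.95))
        assert all(h.identity >= 0.95 - 1e-9 for h in high)
        assert all(h.identity >= 0.85 - 1e-9 for h in low)

    def test_worker_count_does_not_change_output(self, small_pair):
        pair = small_pair
        x = region(pair.ref[pair.spec.ref_name], pair.spec.ref_name)
        y = region(pair.query[pair.spec.query_name], pair.spec.query_name)
        p = Params(min_len=200, max_len=400, identity_t=0.9)
        assert discover_cnes(x, y, p, n_workers=1) == discover_cnes(x, y, p, n_workers=4)
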