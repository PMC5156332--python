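import numpy as np
import pytest

from c2kit.io import Genome, reverse_complement
from c2kit.mosaic import (
    MosaicSegmentation,
    count_events,
    maximal_parent_matches,
    per_position_match,
    segment_mosaic,
)
from c2kit.simulate import generate_hybrid, generate_phage_pair

from _oracles import min_switches_bruteforce, naive_match_track


def _rand_seq(rng, n):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


def _mutate_at(seq, positions):
    """Flip the base at each 1-based position."""
    s = list(seq)
    for p in positions:
        s[p - 1] = "ACGT"[("ACGT".index(s[p - 1]) + 1) % 4]
    return "".join(s)


class TestPerPositionMatch:
    def test_identical_sequences_fully_marked(self, rng):
        seq = _rand_seq(rng, 500)
        track = per_position_match(Genome("h", seq), Genome("p", seq), k=21)
        assert track.all()

    def test_single_snp_unmarks_only_where_no_long_run_covers(self, rng):
        seq = _rand_seq(rng, 2000)
        hyb = _mutate_at(seq, [1000])
        track = per_position_match(Genome("h", hyb), Genome("p", seq), k=21)
        assert not track[999]
        assert track[:999].all() and track[1000:].all()

    def test_equals_naive_all_substrings_oracle(self, rng):
        for trial in range(8):
            parent = _rand_seq(rng, 600)
            # hybrid: a mangled copy with substitutions and a shuffled insert
            hyb = _mutate_at(parent, rng.integers(1, 601, size=6))
            hyb = hyb[:200] + _rand_seq(rng, 40) + hyb[200:]
            got = per_position_match(Genome("h", hyb), Genome("p", parent), k=11)
            assert got.tolist() == naive_match_track(hyb, parent, 11)

    def test_reverse_complement_only_parent_matches_nothing(self, rng):
        seq = _rand_seq(rng, 300)
        track = per_position_match(
            Genome("h", seq), Genome("p", reverse_complement(seq)), k=21
        )
        assert not track.any()

    def test_parameter_validation(self, rng):
        g = Genome("g", _rand_seq(rng, 100))
        with pytest.raises(ValueError, match="k must be"):
            per_position_match(g, g, k=5)
        with pytest.raises(ValueError, match="shorter than k"):
            per_position_match(g, Genome("p", "ACGTACGTACGTACGTACGT"), k=21)


class TestSegmentMosaic:
    def test_hybrid_equal_to_one_parent(self, rng):
        a = Genome("a", _rand_seq(rng, 2000))
        b = Genome("b", _mutate_at(a.seq, range(50, 2000, 80)))
        seg = segment_mosaic(Genome("h", a.seq), a, b, topology="linear")
        assert seg.switches == 0 and seg.events == 0
        assert seg.origin_sequence().count("B") == 0

    def test_two_parent_splice_with_shared_tract(self, rng):
        # A[1..5000] + B[5001..] with a 300 nt identical tract at the junction
        base = _rand_seq(rng, 10000)
        a_seq = _mutate_at(base, list(range(100, 4800, 250)))
        b_seq = _mutate_at(base, list(range(5350, 9900, 250)))
        # parents agree on [4801..5349]; crossover at 5000 sits inside it
        hyb = a_seq[:5000] + b_seq[5000:]
        a, b = Genome("a", a_seq), Genome("b", b_seq)
        seg = segment_mosaic(Genome("h", hyb), a, b, topology="linear")
        assert seg.origin_sequence()[0] == "A" and seg.origin_sequence()[-1] == "B"
        assert seg.switches == 1 and seg.events == 1
        assert len(seg.crossover_intervals) == 1
        lo, hi = seg.crossover_intervals[0]
        assert lo <= 5000 <= hi

    def test_blocks_tile_the_hybrid_and_abut(self, cohort):
        h, _ = generate_hybrid(cohort.genome_a, cohort.genome_b, 2, seed=42)
        seg = segment_mosaic(h, cohort.genome_a, cohort.genome_b)
        assert seg.blocks[0].start == 1
        assert seg.blocks[-1].end == h.length
        for x, y in zip(seg.blocks, seg.blocks[1:]):
            assert y.start == x.end + 1

    def test_non_recombinant_rejected(self, rng):
        h = Genome("h", _rand_seq(rng, 500))
        a = Genome("a", _rand_seq(rng, 500))
        b = Genome("b", _rand_seq(rng, 500))
        with pytest.raises(ValueError, match="not a recombinant"):
            segment_mosaic(h, a, b)

    def test_parent_swap_symmetry(self, cohort):
        h, _ = generate_hybrid(cohort.genome_a, cohort.genome_b, 2, seed=7)
        seg1 = segment_mosaic(h, cohort.genome_a, cohort.genome_b)
        seg2 = segment_mosaic(h, cohort.genome_b, cohort.genome_a)
        relabel = {"A": "B", "B": "A", "both": "both", "neither": "neither"}
        assert [(b.start, b.end, relabel[b.origin]) for b in seg1.blocks] == [
            (b.start, b.end, b.origin) for b in seg2.blocks
        ]
        assert seg1.switches == seg2.switches and seg1.events == seg2.events

    def test_reconstruction_from_blocks(self, cohort):
        """Splicing parental sequence at any point inside each crossover
        interval reproduces the hybrid exactly."""
        a, b = cohort.genome_a, cohort.genome_b
        for seed in (1, 2, 3):
            h, truth = generate_hybrid(a, b, 1, seed=seed)
            seg = segment_mosaic(h, a, b)
            cuts = [int((lo + hi) // 2) for lo, hi in seg.crossover_intervals]
            origins = seg.origin_sequence()
            first = origins[0]
            order = [first]
            for _ in cuts:
                order.append("B" if order[-1] == "A" else "A")
            bounds = [0] + cuts + [h.length]
            parts = []
            for k, orig in enumerate(order):
                src = a.seq if orig == "A" else b.seq
                parts.append(src[bounds[k] : bounds[k + 1]])
            assert "".join(parts) == h.seq


class TestEventCounting:
    def _seg(self, origins, topology="circular"):
        from c2kit.mosaic import OriginBlock

        blocks = []
        pos = 1
        for o in origins:
            blocks.append(OriginBlock(pos, pos + 9, o))
            pos += 10
        switches = sum(1 for x, y in zip(origins, origins[1:]) if x != y)
        if topology == "circular" and origins[0] != origins[-1]:
            switches += 1
        return MosaicSegmentation("h", tuple(blocks), (), switches,
                                  switches // 2 if topology == "circular" else switches,
                                  topology)

    def test_single_block_zero_events(self):
        seg = self._seg(["A"])
        assert count_events(seg, "linear") == 0
        assert count_events(seg, "circular") == 0

    def test_bab_pattern_is_one_circular_event(self):
        seg = self._seg(["B", "A", "B"])
        assert count_events(seg, "linear") == 2
        assert count_events(seg, "circular") == 1

    def test_five_block_alternation_is_two_circular_events(self):
        seg = self._seg(["A", "B", "A", "B", "A"])
        assert count_events(seg, "circular") == 2

    def test_wraparound_transition_counted_on_circular_maps(self):
        # A|B reads as one switch linearly, but the circular map closes the
        # loop with a second (reciprocal) crossover: one event
        seg = self._seg(["A", "B"], topology="linear")
        assert count_events(seg, "linear") == 1
        assert count_events(seg, "circular") == 1


class TestMinimalityAndRecall:
    def test_switches_equal_bruteforce_minimum_on_small_instances(self, rng):
        # craft parents with a handful of discriminating sites -> few runs
        for trial in range(6):
            base = _rand_seq(rng, 1600)
            a_sites = sorted(rng.choice(np.arange(100, 700), 2, replace=False))
            b_sites = sorted(rng.choice(np.arange(900, 1500), 2, replace=False))
            a_seq = _mutate_at(base, b_sites)  # B carries variants at b_sites
            b_seq = _mutate_at(base, a_sites)
            hyb = a_seq[:800] + b_seq[800:]
            a, b = Genome("a", a_seq), Genome("b", b_seq)
            seg = segment_mosaic(Genome("h", hyb), a, b, topology="linear")
            tA = per_position_match(Genome("h", hyb), a)
            tB = per_position_match(Genome("h", hyb), b)
            cat = tA.astype(int) + 2 * tB.astype(int)
            cats = []
            for c in cat:
                label = {0: "neither", 1: "A", 2: "B", 3: "both"}[int(c)]
                if not cats or cats[-1] != label:
                    cats.append(label)
            assert len(cats) <= 9
            assert seg.switches == min_switches_bruteforce(cats, "linear")

    def test_maximal_matches_overlap_at_crossovers(self, cohort):
        a, b = cohort.genome_a, cohort.genome_b
        h, truth = generate_hybrid(a, b, 1, seed=13)
        mm_a = maximal_parent_matches(h, a)
        mm_b = maximal_parent_matches(h, b)
        for x in truth.crossovers:
            assert any(lo <= x <= hi for lo, hi in mm_a)
            assert any(lo <= x <= hi for lo, hi in mm_b)
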