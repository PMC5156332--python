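import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c2kit.align import Scoring, align_pair
from c2kit.compare import (
    find_variable_region,
    format_percent,
    global_identity,
    mean_pairwise_identity,
    region_identity,
    windowed_identity_profile,
)

from _oracles import affine_align_oracle

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def _rand_seq(rng, n):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


class TestAlignEngine:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(dna, dna)
    def test_gotoh_matches_exhaustive_dp(self, a, b):
        aln = align_pair(a, b, method="gotoh")
        score, matches = affine_align_oracle(a, b)
        assert aln.score == score
        assert aln.n_matches == matches

    def test_emitted_columns_reconstruct_inputs(self, rng):
        for _ in range(20):
            a, b = _rand_seq(rng, int(rng.integers(1, 400))), _rand_seq(rng, int(rng.integers(1, 400)))
            for method in ("gotoh", "edlib"):
                aln = align_pair(a, b, method=method)
                assert "".join(a[p - 1] for p in aln.a_pos if p) == a
                assert "".join(b[p - 1] for p in aln.b_pos if p) == b

    def test_custom_scoring_is_honoured(self):
        # with free gaps the aligner should align only the matching letters
        aln = align_pair("AAAA", "AATT", scoring=Scoring(1, -10, 0, 0), method="gotoh")
        assert aln.n_matches == 2

    def test_anchored_engine_equals_gotoh_on_mid_size_pairs(self, rng):
        a = _rand_seq(rng, 1500)
        b = list(a)
        for i in rng.choice(1500, size=15, replace=False):
            b[i] = "ACGT"[(("ACGT".index(b[i]) + 1) % 4)]
        b = "".join(b)
        g = align_pair(a, b, method="gotoh")
        anc = align_pair(a, b, method="anchored")
        assert anc.n_matches == g.n_matches
        assert anc.n_columns == g.n_columns

    def test_n_never_matches(self):
        aln = align_pair("ANNA", "ANNA", method="gotoh")
        assert aln.n_matches == 2

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty"):
            align_pair("", "ACGT")
        with pytest.raises(ValueError, match="alphabet"):
            align_pair("ACGT", "MKLV")


class TestGlobalIdentity:
    def test_identical_and_single_mismatch(self):
        assert global_identity("ACGT", "ACGT").pct_identity == 100.0
        assert global_identity("ACGT", "ACGA").pct_identity == 75.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(dna, dna)
    def test_symmetry(self, a, b):
        ab = global_identity(a, b, method="gotoh")
        ba = global_identity(b, a, method="gotoh")
        assert ab.pct_identity == pytest.approx(ba.pct_identity, abs=1e-9)

    def test_hamming_closed_form_for_indel_free_pairs(self, rng):
        # substitution-only pairs at modest divergence align gap-free
        a = _rand_seq(rng, 800)
        b = list(a)
        idx = rng.choice(800, size=40, replace=False)
        for i in idx:
            b[i] = "ACGT"[("ACGT".index(b[i]) + 1) % 4]
        res = global_identity(a, "".join(b), method="gotoh")
        assert res.matches == 760
        assert res.aln_length == 800

    def test_rounding_convention(self):
        assert format_percent(90.65) == "90.7"
        assert format_percent(51.85) == "51.9"
        assert format_percent(91.35) == "91.4"


class TestRegionIdentity:
    def test_whole_sequence_region_equals_global(self, rng):
        a, b = _rand_seq(rng, 300), _rand_seq(rng, 300)
        g = global_identity(a, b, method="gotoh")
        r = region_identity(a, b, (1, 300))
        assert (r.matches, r.aln_length) == (g.matches, g.aln_length)

    def test_scrambled_second_half(self, rng):
        a = _rand_seq(rng, 400)
        b = a[:200] + _rand_seq(rng, 200)
        res = region_identity(a, b, (1, 200))
        assert res.pct_identity == 100.0

    def test_concatenation_consistency(self, rng):
        a, b = _rand_seq(rng, 500), _rand_seq(rng, 500)
        aln = align_pair(a, b, method="gotoh")
        whole = region_identity(a, b, (1, 500), alignment=aln)
        parts = [region_identity(a, b, (s, s + 99), alignment=aln)
                 for s in range(1, 500, 100)]
        assert sum(p.matches for p in parts) == whole.matches
        assert sum(p.aln_length for p in parts) == whole.aln_length
        combined = 100.0 * sum(p.matches for p in parts) / sum(p.aln_length for p in parts)
        assert combined == pytest.approx(whole.pct_identity, abs=1e-9)

    def test_planted_divergence_region_tracks_generator_truth(self, cohort):
        """Aligned identity in the half-identity region sits at or slightly
        above the generating substitution identity: optimal alignment finds
        spurious local colinearity, a one-sided effect bounded by ~3 points
        at the default affine scores."""
        truth_var = cohort.realized_identity["variable"]
        res = region_identity(cohort.genome_a.seq, cohort.genome_b.seq,
                              cohort.variable_region)
        assert truth_var - 0.1 <= res.pct_identity <= truth_var + 3.0
        truth_all = cohort.realized_identity["overall"]
        g = global_identity(cohort.genome_a, cohort.genome_b)
        assert abs(g.pct_identity - truth_all) <= 0.2

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            region_identity("ACGT", "ACGT", (3, 2))


class TestMeanPairwise:
    def test_identical_sequences(self):
        assert mean_pairwise_identity(["ACGT"] * 3) == 100.0

    def test_small_worked_example(self):
        got = mean_pairwise_identity(["AAAA", "AAAA", "TTTT"])
        assert got == pytest.approx(100.0 / 3, abs=1e-9)

    def test_matches_pair_by_pair_enumeration(self, rng):
        seqs = [_rand_seq(rng, 120) for _ in range(5)]
        expected = []
        for i in range(5):
            for j in range(i + 1, 5):
                expected.append(global_identity(seqs[i], seqs[j], method="gotoh").pct_identity)
        assert mean_pairwise_identity(seqs) == pytest.approx(np.mean(expected), abs=1e-9)

    def test_needs_two(self):
        with pytest.raises(ValueError):
            mean_pairwise_identity(["ACGT"])


class TestProfileAndVariableRegion:
    def test_identical_genomes_profile_is_flat(self):
        seq = "ACGT" * 500
        prof = windowed_identity_profile(seq, seq, window=200, step=50)
        assert all(v == 100.0 for v in prof.identities())
        assert find_variable_region(prof) is None

    def test_step_doubling_halves_points(self, cohort):
        a, b = cohort.genome_a, cohort.genome_b
        aln = align_pair(a.seq, b.seq)
        p1 = windowed_identity_profile(a, b, window=500, step=100, alignment=aln)
        p2 = windowed_identity_profile(a, b, window=500, step=200, alignment=aln)
        assert abs(len(p1.points) - 2 * len(p2.points)) <= 1

    def test_oversized_window_collapses_to_one_point(self):
        prof = windowed_identity_profile("ACGT" * 30, "ACGT" * 30, window=1000)
        assert len(prof.points) == 1

    def test_minimum_falls_in_planted_segment(self, cohort):
        prof = windowed_identity_profile(cohort.genome_a, cohort.genome_b)
        pos = prof.positions()[int(np.argmin(prof.identities()))]
        vs, ve = cohort.variable_region
        assert vs <= pos <= ve

    def test_region_with_global_minimum_is_returned(self):
        # two depressed runs; the one holding the minimum wins
        from c2kit.compare import IdentityProfile

        pts = [(i * 100, 99.0) for i in range(1, 31)]
        for i in (5, 6, 7):
            pts[i] = (pts[i][0], 60.0)
        for i in (20, 21):
            pts[i] = (pts[i][0], 50.0)
        prof = IdentityProfile(window=500, step=100, points=tuple(pts))
        lo, hi = find_variable_region(prof)
        assert (lo, hi) == (pts[20][0], pts[21][0])

    def test_planted_region_recovered(self, cohort):
        prof = windowed_identity_profile(cohort.genome_a, cohort.genome_b)
        called = find_variable_region(prof)
        assert called is not None
        vs, ve = cohort.variable_region
        lo, hi = called
        inter = max(0, min(hi, ve) - max(lo, vs) + 1)
        assert inter / (hi - lo + 1) >= 0.9
        assert inter / (ve - vs + 1) >= 0.9
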