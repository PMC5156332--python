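import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c2kit.annotate import (
    STOP_CODONS,
    MutationCall,
    PrematureStopError,
    call_orfs,
    classify_mutation,
    predict_truncation,
    translate_cds,
)
from c2kit.io import Genome, reverse_complement
from c2kit.simulate import _random_cds, generate_host_mutant


def _orf_scan_oracle(seq: str, min_codons: int, starts={"ATG", "GTG", "TTG"}):
    """Independent 6-frame ORF oracle by direct codon walking on both strands.

    Returns a set of (start, end, strand) in forward 1-based coordinates.
    """
    found = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            first_start = None
            for pos in range(frame, len(s) - 2, 3):
                codon = s[pos : pos + 3]
                if codon in STOP_CODONS:
                    if first_start is not None:
                        if (pos + 3 - first_start) // 3 >= min_codons:
                            a, b = first_start + 1, pos + 3
                            if strand == "-":
                                a, b = L - b + 1, L - a + 1
                            found.add((a, b, strand))
                    first_start = None
                elif first_start is None and codon in starts:
                    first_start = pos
    return found


class TestTranslate:
    def test_simple_product(self):
        assert translate_cds("ATGAAATAA") == "MK"

    def test_alternative_starts_become_methionine(self):
        assert translate_cds("GTGAAATAA")[0] == "M"
        assert translate_cds("TTGAAATAA")[0] == "M"

    def test_membrane_receptor_gene_lengths(self):
        # the two lactococcal receptor genes: 2400 nt -> 799 aa, 2706 nt -> 901 aa
        for nt, aa in ((2400, 799), (2706, 901)):
            gene = _random_cds(np.random.default_rng(nt), nt)
            assert len(translate_cds(gene)) == aa

    def test_internal_stop_carries_codon_index(self):
        with pytest.raises(PrematureStopError) as exc:
            translate_cds("ATGTAAAAATAA")
        assert exc.value.codon_index == 2

    def test_length_and_start_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            translate_cds("ATGAA")
        with pytest.raises(ValueError, match="start"):
            translate_cds("CCCAAATAA")

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=3, max_value=200))
    def test_protein_length_is_codons_minus_stop(self, n_codons):
        gene = _random_cds(np.random.default_rng(n_codons), 3 * max(n_codons, 3))
        assert len(translate_cds(gene)) == len(gene) // 3 - 1


class TestCallOrfs:
    def test_minimal_orf(self):
        (orf,) = call_orfs(Genome("g", "ATGAAATAA"), min_codons=2)
        assert (orf.start, orf.end, orf.strand) == (1, 9, "+")
        assert orf.protein == "MK"

    def test_strand_symmetry(self):
        g = Genome("g", reverse_complement("ATGAAATAA"))
        (orf,) = call_orfs(g, min_codons=2)
        assert (orf.start, orf.end, orf.strand) == (1, 9, "-")

    def test_leftmost_start_is_used(self):
        # two in-frame starts before the stop: the ORF is maximal
        (orf,) = call_orfs(Genome("g", "ATGATGAAATAA"), min_codons=2)
        assert (orf.start, orf.end) == (1, 12)

    def test_short_genome_returns_empty(self):
        assert call_orfs(Genome("g", "ACGT"), min_codons=25) == []

    def test_matches_six_frame_oracle_on_random_sequences(self, rng):
        for _ in range(50):
            seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 300))
            got = {(o.start, o.end, o.strand) for o in call_orfs(Genome("g", seq), min_codons=5)}
            assert got == _orf_scan_oracle(seq, 5)


class TestClassifyMutation:
    def test_nonsense_substitution(self):
        rng = np.random.default_rng(0)
        wt = _random_cds(rng, 2400)
        # force codon 320 to CAA so that C>T at nt 958 creates TAA
        wt = wt[:957] + "CAA" + wt[960:]
        mut = wt[:957] + "T" + wt[958:]
        call = classify_mutation(wt, mut)
        assert call == MutationCall("substitution", "nonsense", 958, "C>T")

    def test_homopolymer_deletion_is_left_normalised(self):
        # single A removed from an A7 run at 186-192 reports position 186
        rng = np.random.default_rng(1)
        wt = _random_cds(rng, 600)
        wt = wt[:184] + "G" + "A" * 7 + "G" + wt[193:]  # run at 186..192
        mut = wt[:189] + wt[190:]  # delete one A mid-run
        call = classify_mutation(wt, mut)
        assert call == MutationCall("deletion", "frameshift", 186, "ΔA")

    def test_element_insertion(self):
        rng = np.random.default_rng(2)
        wt = _random_cds(rng, 900)
        mut, truth = generate_host_mutant(wt, "element_insertion", seed=3,
                                          element_length=1200)
        call = classify_mutation(wt, mut)
        assert call.mclass == "element_insertion"
        assert call == truth
        assert len(mut) - len(wt) == 1200

    def test_synonymous_and_missense(self):
        wt = "ATGCTTAAATAA"
        assert classify_mutation(wt, "ATGCTGAAATAA").consequence == "synonymous"
        assert classify_mutation(wt, "ATGCATAAATAA").consequence == "missense"

    def test_identical_and_multidiff_rejected(self):
        with pytest.raises(ValueError, match="no mutation"):
            classify_mutation("ATGAAATAA", "ATGAAATAA")
        with pytest.raises(ValueError, match="(separated|one difference)"):
            classify_mutation("ATGAAAAAATAA", "TTGAAAAAAGAA")

    @pytest.mark.parametrize("mtype", ["nonsense", "frameshift_ins",
                                       "frameshift_del", "element_insertion"])
    def test_recovers_random_generated_edits(self, mtype, rng):
        wt = _random_cds(np.random.default_rng(99), 1200)
        n = 250
        for i in range(n):
            mut, truth = generate_host_mutant(wt, mtype, seed=int(rng.integers(2**31)))
            assert classify_mutation(wt, mut) == truth


class TestPredictTruncation:
    def test_receptor_gene_truncation_arithmetic(self):
        # C>T at nt 958 -> TAA in codon 320 -> 319 aa product
        call = MutationCall("substitution", "nonsense", 958, "C>T")
        res = predict_truncation(call, cds_length=2400)
        assert (res.stop_codon_index, res.truncated_length) == (320, 319)

    def test_stop_in_second_codon(self):
        call = MutationCall("substitution", "nonsense", 4, "A>T")
        res = predict_truncation(call, cds_length=300)
        assert res.truncated_length == 1

    def test_position_monotonicity(self):
        last = 0
        for pos in range(1, 2401, 7):
            idx = predict_truncation(
                MutationCall("substitution", "nonsense", pos, "C>T"), cds_length=2400
            ).stop_codon_index
            assert idx >= last
            last = idx

    def test_frameshift_truncation_matches_direct_translation(self):
        wt = _random_cds(np.random.default_rng(5), 300)
        mut, truth = generate_host_mutant(wt, "frameshift_del", seed=8)
        res = predict_truncation(truth, mutated_seq=mut)
        # oracle: directly walk the deleted sequence to its first stop
        n_aa = 0
        for c in range(len(mut) // 3):
            if mut[3 * c : 3 * c + 3] in STOP_CODONS:
                break
            n_aa += 1
        assert res.truncated_length == n_aa
        assert res.mechanism == "frameshift"

    def test_nonsense_requires_stop_in_context(self):
        wt = _random_cds(np.random.default_rng(6), 300)
        call = MutationCall("substitution", "nonsense", 10, "C>T")
        with pytest.raises(ValueError, match="does not create a stop"):
            predict_truncation(call, cds_length=300, mutated_seq=wt)
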