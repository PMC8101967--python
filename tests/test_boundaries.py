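"""TIR/TSD detection and boundary inference, incl. brute-force oracles."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from merlintools import boundaries as bnd
from merlintools.simgenome import (FamilySpec, build_element, random_dna,
                                   revcomp)


def make_element_with_tir(rng, tir_len=30, mismatches=0, interior=200,
                          terminal_gg=True):
    spec = FamilySpec("f", tir_length=tir_len, tir_mismatches=mismatches,
                      terminal_gg=terminal_gg, orf_length=120,
                      element_length=max(interior + 2 * tir_len, 600))
    element, _, _ = build_element(spec, rng)
    return element


class TestFindTirs:
    def test_perfect_planted_tir_is_top_ranked(self, rng):
        element = make_element_with_tir(rng, tir_len=30, mismatches=0)
        tirs = bnd.find_tirs(element)
        assert tirs
        top = tirs[0]
        assert (top.length, top.mismatches) == (30, 0)
        assert top.terminal_gg

    def test_highly_imperfect_tir_recoverable(self, rng):
        """12 mismatches in 26 positions: present in the candidate list even
        though a cleaner shorter repeat may rank first."""
        element = make_element_with_tir(rng, tir_len=26, mismatches=12)
        tirs = bnd.find_tirs(element, require_gg=False)
        full = [t for t in tirs if t.length == 26 and t.start5 == 0
                and t.end3 == len(element)]
        assert full and full[0].mismatches == 12

    def test_brute_force_oracle_on_300bp_toys(self):
        """Top-ranked score equals exhaustive enumeration over all anchor
        pairs and admissible lengths."""
        comp = str.maketrans("ACGT", "TGCA")

        def brute(seq, min_len=10, max_frac=0.5, slack=8, run_stop=4):
            n = len(seq)
            best = None
            for s in range(slack + 1):
                for e in range(n, n - slack - 1, -1):
                    limit = (e - s) // 2
                    mm = run = 0
                    for i in range(limit):
                        a = seq[s + i]
                        b = seq[e - 1 - i].translate(comp)
                        if a == b:
                            run = 0
                        else:
                            mm += 1
                            run += 1
                            if run >= run_stop:
                                break
                        L = i + 1
                        if a == b and L >= min_len and mm / L <= max_frac:
                            cand = (L - 2 * mm, L)
                            if best is None or cand > best:
                                best = cand
            return best

        for seed in range(8):
            rng = np.random.default_rng(seed)
            element = make_element_with_tir(rng, tir_len=20,
                                            mismatches=seed % 4,
                                            interior=260)
            seq = element[:150] + element[-150:]  # 300-bp toy
            tirs = bnd.find_tirs(seq)
            expected = brute(seq)
            if expected is None:
                assert tirs == []
            else:
                assert tirs[0].score == expected[0]

    def test_strand_symmetry(self, rng):
        element = make_element_with_tir(rng, tir_len=24, mismatches=3)
        fwd = bnd.find_tirs(element)
        rev = bnd.find_tirs(revcomp(element))
        assert fwd and rev
        assert fwd[0].score == rev[0].score
        assert fwd[0].tir5 == revcomp(rev[0].tir3)

    def test_no_repeat_returns_empty(self):
        # homopolymer: every terminal comparison is A vs comp(A)=T
        assert bnd.find_tirs("A" * 80, min_len=15) == []

    def test_mismatch_accounting_is_recomputable(self, rng):
        element = make_element_with_tir(rng, tir_len=30, mismatches=5)
        for t in bnd.find_tirs(element)[:10]:
            assert bnd.hamming_tir(t.tir5, t.tir3) == t.mismatches


class TestFindTsd:
    def test_simple_8mer(self):
        tsd = bnd.find_tsd("A" * 20 + "ACGTACGT", "ACGTACGT" + "C" * 20)
        assert tsd is not None and tsd.k == 8 and tsd.left == "ACGTACGT"

    def test_longest_k_wins(self):
        # both a 9-mer and its 8-mer suffix match; 9 must be returned
        core = "ACGTACGTA"
        tsd = bnd.find_tsd("T" * 20 + core, core + "G" * 20)
        assert tsd is not None and tsd.k == 9

    def test_truncated_flank_returns_none(self):
        assert bnd.find_tsd("ACG", "ACGTACGTAA" * 3) is None

    def test_jitter_recovers_shifted_boundary(self):
        rng = np.random.default_rng(4)
        tsd_seq = "GATTACAG"
        elem = "TG" + random_dna(rng, 118)
        flank5 = random_dna(rng, 40) + tsd_seq
        # ensure the duplication cannot extend past 8 bp by chance
        flank3 = tsd_seq + "AA" + random_dna(rng, 38)
        # boundaries mis-called by 2 bp into the element on the 5' side
        shifted5 = flank5 + elem[:2]
        shifted_elem = elem[2:]
        tsd = bnd.find_tsd(shifted5, flank3, shifted_elem)
        assert tsd is not None
        assert tsd.left == tsd_seq and tsd.jitter5 == -2

    def test_simulated_family_tsds_match_truth(self):
        from merlintools.simgenome import simulate_genome
        spec = FamilySpec("f", n_copies=3, tsd_length=9)
        genome, truth = simulate_genome([spec], 30000, seed=31)
        contig = genome["chr1"]
        found = []
        for c in truth.copies:
            f5 = contig[max(0, c.start - 30):c.start]
            f3 = contig[c.end:c.end + 30]
            elem = contig[c.start:c.end]
            if c.strand == "-":
                f5, f3 = revcomp(f3), revcomp(f5)
                elem = revcomp(elem)
            tsd = bnd.find_tsd(f5, f3, elem)
            assert tsd is not None and tsd.k == 9
            expected = c.tsd if c.strand == "+" else revcomp(c.tsd)
            assert tsd.left == expected
            found.append(tsd.left)
        assert len(set(found)) == len(found)  # differ across copies


class TestClassifyCopy:
    def test_tir_tsd_motif_is_family_candidate(self):
        tir = bnd.TirPair("GGAAAATTTT", "AAAATTTTCC", 10, 0, True)
        tsd = bnd.Tsd(8, "ACGTACGT", "ACGTACGT", True)
        assert bnd.classify_copy(None, tir, tsd, "intact") == \
            "family_candidate"

    def test_motif_without_tir_tsd_is_group_member(self):
        assert bnd.classify_copy(None, None, None, "intact") == \
            "group_member"

    def test_truncated_orf_no_tir_is_remnant(self):
        assert bnd.classify_copy(None, None, None, "remnant") == "remnant"

    def test_gg_requirement_for_family(self):
        tir = bnd.TirPair("TTAAAATTTT", "AAAATTTTAA", 10, 0, False)
        tsd = bnd.Tsd(8, "ACGTACGT", "ACGTACGT", True)
        assert bnd.classify_copy(None, tir, tsd, "intact") == "group_member"


class TestInferBoundaries:
    def _aligned_copies(self, seed, div=0.05, n=3, elem_len=400,
                        flank=120, shared_flanks=False):
        from merlintools._align import center_star_align
        from merlintools.simgenome import mutate_copy
        rng = np.random.default_rng(seed)
        elem = random_dna(rng, elem_len)
        if shared_flanks:
            l = random_dna(rng, flank)
            r = random_dna(rng, flank)
        rows = []
        for i in range(n):
            copy = mutate_copy(elem, div, 0.0, seed=1000 + i)
            if not shared_flanks:
                l = random_dna(rng, flank)
                r = random_dna(rng, flank)
            rows.append(l + copy + r)
        return center_star_align(rows), flank, elem_len

    def test_boundaries_within_3bp_of_truth(self):
        aligned, flank, elem_len = self._aligned_copies(1)
        call = bnd.infer_boundaries(aligned)
        assert call.confidence5 != "unresolved"
        assert call.confidence3 != "unresolved"
        s = bnd.column_to_row_position(aligned[0], call.start_col)
        e = bnd.column_to_row_position(aligned[0], call.end_col)
        # row 0 was built as flank + copy + flank with no indels
        assert abs(s - flank) <= 3
        assert abs(e - (flank + elem_len)) <= 3

    def test_identical_shared_flanks_unresolved(self):
        aligned, _, _ = self._aligned_copies(2, div=0.0, shared_flanks=True)
        call = bnd.infer_boundaries(aligned)
        assert "unresolved" in (call.confidence5, call.confidence3)

    def test_no_flanks_unresolved(self):
        aligned, flank, elem_len = self._aligned_copies(3, div=0.02,
                                                        flank=0)
        call = bnd.infer_boundaries([r for r in aligned])
        assert call.confidence5 == "unresolved" or \
            call.confidence3 == "unresolved"

    def test_single_copy_unresolved(self):
        call = bnd.infer_boundaries(["ACGTACGTACGTACGTACGT"])
        assert call.confidence5 == "unresolved"
        assert call.support == 1


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_tir_hamming_invariant_on_random_sequences(seed):
    """Every returned TirPair's mismatch count is recomputable from its
    sequences (property over random inputs)."""
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 120)
    for t in bnd.find_tirs(seq, min_len=6):
        assert bnd.hamming_tir(t.tir5, t.tir3) == t.mismatches
        assert t.mismatches <= t.length
        assert t.terminal_gg == (t.tir5.startswith("GG")
                                 and t.tir3.endswith("CC"))
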