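"""ORF discovery and DDE-motif scanning against independent oracles."""

import numpy as np
import pytest
from Bio.Seq import Seq

from merlintools import orf_domain
from merlintools.orf_domain import (BlockProfile, block_presence,
                                    classify_protein, find_orfs, scan_dde)
from merlintools.simgenome import random_dna


def brute_force_orfs(contig: str, min_aa: int) -> set:
    """Independent six-frame enumeration via direct codon walking."""
    out = set()
    n = len(contig)
    for strand in "+-":
        seq = contig if strand == "+" else \
            str(Seq(contig).reverse_complement())
        for frame in range(3):
            codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
            prot = "".join(str(Seq(c).translate()) for c in codons)
            start = None
            for i, aa in enumerate(prot):
                if aa == "M" and start is None:
                    start = i
                if aa == "*":
                    if start is not None and i - start >= min_aa:
                        s = frame + 3 * start
                        e = frame + 3 * (i + 1)
                        if strand == "-":
                            s, e = n - e, n - s
                        out.add((s, e, strand, prot[start:i]))
                    start = None
    return out


class TestFindOrfs:
    def test_hand_translatable_minimal_orf(self):
        orfs = find_orfs("ATGAAATAA", min_aa=2)
        assert len(orfs) == 1
        o = orfs[0]
        assert (o.start, o.end, o.strand, o.protein) == (0, 9, "+", "MK")

    def test_matches_brute_force_on_random_sequence(self):
        contig = random_dna(np.random.default_rng(17), 10000)
        got = {(o.start, o.end, o.strand, o.protein)
               for o in find_orfs(contig, 100)}
        assert got == brute_force_orfs(contig, 100)

    def test_reverse_complement_swaps_strands_same_proteins(self):
        contig = random_dna(np.random.default_rng(23), 5000)
        fwd = find_orfs(contig, 50)
        rev = find_orfs(str(Seq(contig).reverse_complement()), 50)
        assert sorted(o.protein for o in fwd) == \
            sorted(o.protein for o in rev)
        assert {o.strand for o in fwd} == \
            {"+-"[("+-".index(o.strand) + 1) % 2] for o in rev} or fwd == []

    def test_ambiguous_bases_translate_as_x(self):
        orfs = find_orfs("ATGNNNAAATAA", min_aa=3)
        assert orfs and orfs[0].protein == "MXK"

    def test_empty_input(self):
        assert find_orfs("", 5) == []


def _embed_blocks(rng, profile, link12=60, link23=20, prefix=30, suffix=40):
    aas = orf_domain.AA_ALPHABET
    b1, b2, b3 = profile.consensus_blocks()
    rand = lambda k: "".join(rng.choice(list(aas), k))
    prot = rand(prefix) + b1 + rand(link12) + b2 + rand(link23) + b3 \
        + rand(suffix)
    positions = (prefix, prefix + len(b1) + link12,
                 prefix + len(b1) + link12 + len(b2) + link23)
    return prot, positions


class TestScanDde:
    def test_construct_and_recover_exact_positions(self, profile, rng):
        prot, positions = _embed_blocks(rng, profile)
        m = scan_dde(prot, profile)
        assert m is not None
        assert m.block_positions == positions
        assert m.conserved and m.catalytic_residues == ("D", "D", "E")

    def test_polyalanine_negative_control(self, profile):
        assert scan_dde("A" * 300, profile) is None

    def test_block2_d_to_n_variant_found_but_not_conserved(self, profile,
                                                           rng):
        prot, positions = _embed_blocks(rng, profile)
        p2 = positions[1] + profile.anchors[1]
        variant = prot[:p2] + "N" + prot[p2 + 1:]
        m = scan_dde(variant, profile)
        assert m is not None and not m.conserved
        assert m.catalytic_residues == ("D", "N", "E")

    def test_translation_invariance_under_padding(self, profile, rng):
        prot, _ = _embed_blocks(rng, profile)
        pad = "".join(rng.choice(list(orf_domain.AA_ALPHABET), 50))
        m0 = scan_dde(prot, profile)
        m1 = scan_dde(pad + prot + pad, profile)
        assert m0 is not None and m1 is not None
        assert m1.catalytic_residues == m0.catalytic_residues
        assert m1.block_positions == tuple(p + 50
                                           for p in m0.block_positions)

    def test_false_positive_rate_below_one_percent(self, profile):
        rng = np.random.default_rng(99)
        aas = list(orf_domain.AA_ALPHABET)
        hits = sum(scan_dde("".join(rng.choice(aas, 400)), profile)
                   is not None for _ in range(1000))
        assert hits / 1000 < 0.01

    def test_agrees_with_exhaustive_placement_enumeration(self, profile):
        rng = np.random.default_rng(7)
        prot, _ = _embed_blocks(rng, profile, link12=45, link23=12,
                                prefix=10, suffix=10)
        assert len(prot) <= 200
        m = scan_dde(prot, profile, score_threshold=-1e9)
        L1, L2, L3 = profile.block_lengths
        lo12, hi12 = profile.spacing12
        lo23, hi23 = profile.spacing23
        best = None
        for p1 in range(len(prot) - L1 + 1):
            for p2 in range(p1 + L1 + lo12,
                            min(p1 + L1 + hi12, len(prot) - L2) + 1):
                for p3 in range(p2 + L2 + lo23,
                                min(p2 + L2 + hi23, len(prot) - L3) + 1):
                    s = (profile.block_score(0, prot[p1:p1 + L1])
                         + profile.block_score(1, prot[p2:p2 + L2])
                         + profile.block_score(2, prot[p3:p3 + L3]))
                    if best is None or s > best[0] + 1e-12:
                        best = (s, (p1, p2, p3))
        assert m.block_positions == best[1]
        assert m.total_score == pytest.approx(best[0])

    def test_short_protein_returns_none(self, profile):
        assert scan_dde("MKL", profile) is None


class TestClassify:
    def test_full_motif_is_intact(self, profile, rng):
        prot, _ = _embed_blocks(rng, profile)
        m = scan_dde(prot, profile)
        assert classify_protein(m, 1.0) == "intact"

    def test_partial_blocks_are_truncated_domain(self, profile, rng):
        b2, b3 = profile.consensus_blocks()[1:]
        aas = list(orf_domain.AA_ALPHABET)
        prot = b2 + "".join(rng.choice(aas, 20)) + b3
        present = block_presence(prot, profile)
        assert present == [False, True, True]
        assert classify_protein(None, 1.0,
                                blocks_present=present) == "truncated_domain"

    def test_no_blocks_is_absent(self, profile):
        present = block_presence("A" * 200, profile)
        assert classify_protein(None, 1.0,
                                blocks_present=present) == "absent"

    def test_bad_coverage_rejected(self):
        with pytest.raises(ValueError):
            classify_protein(None, 1.5)


def test_profile_json_roundtrip(tmp_path, profile):
    path = tmp_path / "profile.json"
    profile.to_json(path)
    back = BlockProfile.from_json(path)
    assert back.consensus_blocks() == profile.consensus_blocks()
    assert back.own_consensus_score() == \
        pytest.approx(profile.own_consensus_score())
    assert back.spacing12 == profile.spacing12


def test_pwm_columns_are_normalized(profile):
    for pwm in profile.pwms:
        freqs = np.exp2(pwm) * 0.05
        assert np.allclose(freqs.sum(axis=1), 1.0)
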