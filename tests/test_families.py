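"""p-distance, neighbor joining, bootstrap, consensus and family calls."""

import itertools

import numpy as np
import pytest

from merlintools import families as fam
from merlintools.boundaries import TirPair, Tsd
from merlintools.families import (CopyCall, assign_families,
                                  bootstrap_support, date_activity,
                                  degenerate_consensus, nj_tree,
                                  p_distance_matrix)
from merlintools.simgenome import FamilySpec, mutate_copy, random_dna


class TestPDistance:
    def test_identical_pair_is_zero(self):
        d = p_distance_matrix({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert d.matrix[0, 1] == 0.0

    def test_hand_computed_quarter(self):
        d = p_distance_matrix({"a": "ACGT", "b": "ACGA"})
        assert d.matrix[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_of_gaps(self):
        d = p_distance_matrix({"a": "AC-T", "b": "ACGA"})
        # 3 comparable sites, 1 mismatch
        assert d.matrix[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_sites_flagged_undefined(self):
        d = p_distance_matrix({"a": "--AA", "b": "CC--"})
        assert d.undefined[0, 1]

    def test_symmetry_and_zero_diagonal_enforced(self):
        with pytest.raises(ValueError):
            fam.DistanceMatrix(["a", "b"], np.array([[0.0, 0.1],
                                                     [0.2, 0.0]]),
                               np.zeros((2, 2), bool))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            p_distance_matrix({"a": "ACG", "b": "ACGT"})


def _additive_matrix(tree_dists, labels):
    n = len(labels)
    m = np.zeros((n, n))
    for (a, b), v in tree_dists.items():
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = v
    return fam.DistanceMatrix(labels, m, np.zeros((n, n), bool))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # star tree: branch lengths solve the three pair equations exactly
        d = _additive_matrix({("a", "b"): 0.3, ("a", "c"): 0.4,
                              ("b", "c"): 0.5}, ["a", "b", "c"])
        tree = nj_tree(d)
        bl = {c.name: l for c, l in tree.children}
        assert bl["a"] == pytest.approx(0.1)
        assert bl["b"] == pytest.approx(0.2)
        assert bl["c"] == pytest.approx(0.3)

    def test_four_taxon_additive_topology(self):
        # ((a,b),(c,d)) with internal branch 0.2
        dists = {("a", "b"): 0.2, ("c", "d"): 0.2,
                 ("a", "c"): 0.5, ("a", "d"): 0.5,
                 ("b", "c"): 0.5, ("b", "d"): 0.5}
        tree = nj_tree(_additive_matrix(dists, list("abcd")))
        assert frozenset({"a", "b"}) in tree.splits() or \
            frozenset({"c", "d"}) in tree.splits()

    def test_five_taxon_vs_exhaustive_least_squares(self):
        """NJ on an additive matrix finds the same topology as exhaustive
        least-squares over all 15 unrooted 5-taxon topologies."""
        labels = list("abcde")
        rng = np.random.default_rng(5)
        for trial in range(5):
            # random additive tree: cherries {a,b} and {c,d}, e central
            pend = rng.uniform(0.05, 0.4, size=5)
            internal = rng.uniform(0.1, 0.3, size=2)
            true_cherries = [("a", "b"), ("c", "d")]
            pd = dict(zip(labels, pend))
            d = {}
            for x, y in itertools.combinations(labels, 2):
                v = pd[x] + pd[y]
                in_ab = {x, y} <= {"a", "b"}
                in_cd = {x, y} <= {"c", "d"}
                if not in_ab and {x, y} & {"a", "b"}:
                    v += internal[0]
                if not in_cd and {x, y} & {"c", "d"}:
                    v += internal[1]
                d[(x, y)] = v
            dm = _additive_matrix(d, labels)

            def sse_for_topology(c1, c2):
                # unknowns: 5 pendant + 2 internal branch lengths
                rows, rhs = [], []
                for x, y in itertools.combinations(labels, 2):
                    row = [0.0] * 7
                    row[labels.index(x)] = 1
                    row[labels.index(y)] = 1
                    if not {x, y} <= set(c1) and {x, y} & set(c1):
                        row[5] = 1
                    if not {x, y} <= set(c2) and {x, y} & set(c2):
                        row[6] = 1
                    rows.append(row)
                    rhs.append(d[(x, y)] if (x, y) in d else d[(y, x)])
                sol, res, *_ = np.linalg.lstsq(np.array(rows),
                                               np.array(rhs), rcond=None)
                fit = np.array(rows) @ sol
                return float(((fit - np.array(rhs)) ** 2).sum())

            topologies = []
            for c1 in itertools.combinations(labels, 2):
                rest = [t for t in labels if t not in c1]
                for c2 in itertools.combinations(rest, 2):
                    key = frozenset({frozenset(c1), frozenset(c2)})
                    if key not in [t[0] for t in topologies]:
                        topologies.append((key, sse_for_topology(c1, c2)))
            best = min(topologies, key=lambda t: t[1])[0]
            assert best == frozenset({frozenset("ab"), frozenset("cd")})

            nj_splits = nj_tree(dm).splits()
            nj_cherries = {s if len(s) == 2 else frozenset(labels) - s
                           for s in nj_splits}
            assert nj_cherries == {frozenset("ab"), frozenset("cd")}

    def test_matches_scikit_bio_on_additive_input(self):
        """Independent cross-check against an established NJ implementation."""
        skbio = pytest.importorskip("skbio")
        labels = list("abcde")
        dists = {("a", "b"): 0.3, ("c", "d"): 0.25,
                 ("a", "c"): 0.7, ("a", "d"): 0.65, ("a", "e"): 0.5,
                 ("b", "c"): 0.8, ("b", "d"): 0.75, ("b", "e"): 0.6,
                 ("c", "e"): 0.55, ("d", "e"): 0.5}
        dm = _additive_matrix(dists, labels)
        ours = nj_tree(dm).splits()
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.matrix, labels))
        theirs = set()
        for node in sk.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= 3:
                side = below if "a" not in below else \
                    frozenset(labels) - below
                theirs.add(side)
        assert ours == theirs

    def test_jackknife_preserves_uninvolved_splits(self):
        labels = list("abcde")
        dists = {("a", "b"): 0.3, ("c", "d"): 0.25,
                 ("a", "c"): 0.7, ("a", "d"): 0.65, ("a", "e"): 0.5,
                 ("b", "c"): 0.8, ("b", "d"): 0.75, ("b", "e"): 0.6,
                 ("c", "e"): 0.55, ("d", "e"): 0.5}
        dm = _additive_matrix(dists, labels)
        full = nj_tree(dm).splits()
        assert frozenset("cd") in full
        # drop taxon b (not part of the {c,d} split side)
        keep = [l for l in labels if l != "b"]
        idx = [labels.index(l) for l in keep]
        sub = fam.DistanceMatrix(keep, dm.matrix[np.ix_(idx, idx)],
                                 np.zeros((4, 4), bool))
        assert frozenset("cd") in nj_tree(sub).splits()

    def test_undefined_entry_raises_with_pair_names(self):
        m = np.array([[0, .1, np.nan], [.1, 0, .2], [np.nan, .2, 0]])
        undef = np.isnan(m)
        d = fam.DistanceMatrix(list("abc"), m, undef)
        with pytest.raises(ValueError, match="'a'.*'c'"):
            nj_tree(d)

    def test_fewer_than_three_taxa_rejected(self):
        d = p_distance_matrix({"a": "ACGT", "b": "ACGA"})
        with pytest.raises(ValueError):
            nj_tree(d)


class TestBootstrap:
    @staticmethod
    def _two_cluster_alignment(cols=100):
        rng = np.random.default_rng(8)
        core_a = random_dna(rng, cols)
        core_b = random_dna(rng, cols)
        return {
            "a1": core_a, "a2": mutate_copy(core_a, 0.02, seed=1),
            "b1": core_b, "b2": mutate_copy(core_b, 0.02, seed=2),
        }

    def test_separated_clusters_get_high_support(self):
        seqs = self._two_cluster_alignment()
        support = bootstrap_support(seqs, replicates=200, seed=3)
        split = frozenset({"b1", "b2"})
        assert support[split] >= 0.95

    def test_zero_replicates_empty(self):
        assert bootstrap_support(self._two_cluster_alignment(),
                                 replicates=0) == {}

    def test_fixed_seed_reproducible(self):
        seqs = self._two_cluster_alignment()
        s1 = bootstrap_support(seqs, replicates=50, seed=7)
        s2 = bootstrap_support(seqs, replicates=50, seed=7)
        assert s1 == s2


class TestDegenerateConsensus:
    @pytest.mark.parametrize("rows,expected", [
        (["AG", "AG"], "AG"),
        (["AA", "GA"], "RA"),          # tied A/G column -> R
        (["AT", "AA", "AC", "AG"], "AN"),
        (["A-", "A-"], "A"),           # all-gap column dropped
        (["CA", "TA"], "YA"),
        (["GA", "CA"], "SA"),
    ])
    def test_code_table(self, rows, expected):
        assert degenerate_consensus(rows) == expected

    def test_majority_wins(self):
        assert degenerate_consensus(["A", "A", "G"]) == "A"

    def test_idempotent(self):
        rows = ["ACGTAC", "ACGAAC", "TCGTAC"]
        cons = degenerate_consensus(rows)
        assert degenerate_consensus([cons]) == cons


class TestDateActivity:
    def test_identical_family_with_distinct_tsds_is_recent(self):
        assert date_activity(0.0, 3, True) == "recent"

    def test_diverged_tirless_group_is_ancient(self):
        assert date_activity(0.20, 0, False) == "ancient"

    def test_single_copy_unclear(self):
        assert date_activity(float("nan"), 1, True) == "unclear"


def _make_calls(rng, n_families=2, copies_each=3, div=0.02):
    calls = []
    truth = {}
    for f in range(n_families):
        elem = random_dna(rng, 500)
        tir5 = "GG" + elem[2:22]
        for c in range(copies_each):
            cid = f"f{f}_c{c}"
            seq = mutate_copy(elem, div, seed=100 * f + c)
            tir = TirPair(tir5, "A" * 20 + "CC", 22, 2, True)
            tsd_seq = random_dna(rng, 8)
            calls.append(CopyCall(cid, seq, "family_candidate", tir,
                                  Tsd(8, tsd_seq, tsd_seq, True)))
            truth[cid] = f
    return calls, truth


class TestAssignFamilies:
    def test_two_planted_families_recovered(self, rng):
        calls, truth = _make_calls(rng)
        fams, groups = assign_families(calls)
        assert len(fams) == 2 and not groups
        for f in fams:
            assert len({truth[m] for m in f.members}) == 1

    def test_all_remnants_zero_families(self, rng):
        calls = [CopyCall(f"r{i}", random_dna(rng, 300), "remnant")
                 for i in range(4)]
        fams, groups = assign_families(calls)
        assert fams == [] and groups == []

    def test_permutation_invariance(self, rng):
        calls, _ = _make_calls(rng, n_families=3, copies_each=2)
        fams1, _ = assign_families(calls)
        fams2, _ = assign_families(list(reversed(calls)))
        assert [set(f.members) for f in fams1] == \
            [set(f.members) for f in fams2]

    def test_ids_numbered_by_descending_size(self, rng):
        calls, _ = _make_calls(rng, n_families=2, copies_each=2)
        calls = calls + _make_calls(rng, n_families=1, copies_each=4)[0]
        fams, _ = assign_families(calls)
        sizes = [len(f.members) for f in fams]
        assert fams[0].id == "F1" and sizes == sorted(sizes, reverse=True)

    def test_group_members_form_groups(self, rng):
        elem = random_dna(rng, 400)
        calls = [CopyCall(f"g{i}", mutate_copy(elem, 0.05, seed=i),
                          "group_member") for i in range(3)]
        fams, groups = assign_families(calls)
        assert not fams and len(groups) == 1
        assert groups[0].id == "G1" and len(groups[0].members) == 3
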