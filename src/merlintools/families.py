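"""Family/group clustering, p-distances, NJ trees and degenerate consensus.

Copies that share TIRs and TSDs within a species are clustered into
families (F1, F2, ... by descending size); conserved coding copies without
TIR+TSD evidence form groups (G1, G2, ...).  Divergence is measured as the
p-distance (mismatch fraction over compared sites, pairwise deletion of
gapped/ambiguous columns) and trees are built by neighbor joining with
column-resampling bootstrap.  Consensus sequences use IUPAC degeneracy for
columns without a majority base, exactly as family TIRs are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from merlintools._align import (center_star_align, global_identity,
                                pairwise_pdistance, GAP)
from merlintools.boundaries import TirPair, Tsd, hamming_tir

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with undefined-entry tracking."""

    labels: list[str]
    matrix: np.ndarray
    undefined: np.ndarray  # boolean; True where no comparable sites

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")


@dataclass
class Family:
    """Copies sharing TIRs and TSDs, i.e. products of transposition."""

    id: str
    members: list[str]
    consensus: str = ""
    tir_consensus: TirPair | None = None
    modal_tsd_length: int | None = None
    activity_evidence: str = "unclear"
    mean_pdistance: float = float("nan")


@dataclass
class Group:
    """Related coding sequences lacking TIR+TSD evidence."""

    id: str
    members: list[str]
    mean_pdistance: float = float("nan")


def p_distance_matrix(seqs: dict[str, str] | list[tuple[str, str]],
                      protein: bool = False) -> DistanceMatrix:
    """Pairwise p-distances on equal-length aligned sequences.

    Columns where either sequence is gapped or ambiguous are deleted
    pairwise; a pair with zero comparable sites is flagged undefined.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    labels = [k for k, _ in items]
    rows = [v.upper() for _, v in items]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError("aligned sequences must have equal lengths")
    n = len(rows)
    ambiguous = {GAP, "N"} if not protein else {GAP, "X"}
    mat = np.zeros((n, n))
    undef = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            compared = mismatches = 0
            for a, b in zip(rows[i], rows[j]):
                if a in ambiguous or b in ambiguous:
                    continue
                compared += 1
                if a != b:
                    mismatches += 1
            if compared == 0:
                undef[i, j] = undef[j, i] = True
                mat[i, j] = mat[j, i] = np.nan
            else:
                mat[i, j] = mat[j, i] = mismatches / compared
    return DistanceMatrix(labels, mat, undef)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class TreeNode:
    """Minimal unrooted-tree node (root is an arbitrary trifurcation)."""

    __slots__ = ("name", "children", "support")

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[tuple["TreeNode", float]] = []
        self.support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, with_support: bool = False) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, ws: bool) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._newick(ws)}:{bl:.6f}"
                         for c, bl in self.children)
        label = ""
        if ws and self.support is not None:
            label = f"{self.support:.2f}"
        return f"({inner}){label}"

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each named by the side that excludes
        the lexicographically smallest leaf."""
        all_leaves = set(self.leaves())
        ref = min(all_leaves)
        out: set[frozenset] = set()

        def walk(node: TreeNode):
            below = set(node.leaves())
            if 2 <= len(below) <= len(all_leaves) - 2:
                side = below if ref not in below else all_leaves - below
                out.add(frozenset(side))
            for child, _ in node.children:
                walk(child)

        walk(self)
        return out


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Neighbor joining (Saitou & Nei) with smallest-index tie-breaking."""
    if len(d.labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if d.undefined.any():
        i, j = map(int, np.argwhere(d.undefined)[0])
        raise ValueError(f"undefined distance between {d.labels[i]!r} "
                         f"and {d.labels[j]!r}")
    nodes = [TreeNode(lbl) for lbl in d.labels]
    dist = d.matrix.astype(float).copy()
    active = list(range(len(nodes)))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * dist[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = dist[i, j] - vi
        parent = TreeNode()
        parent.children = [(nodes[i], max(vi, 0.0)),
                           (nodes[j], max(vj, 0.0))]
        new = len(nodes)
        nodes.append(parent)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
            dist[new, k] = dist[k, new] = dk
        active = [k for k in active if k not in (i, j)] + [new]
    root = TreeNode()
    if len(active) == 3:
        i, j, k = active
        bi = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
        bj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
        bk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
        root.children = [(nodes[i], max(bi, 0.0)), (nodes[j], max(bj, 0.0)),
                         (nodes[k], max(bk, 0.0))]
    else:  # exactly 2
        i, j = active
        root.children = [(nodes[i], dist[i, j] / 2),
                         (nodes[j], dist[i, j] / 2)]
    return root


def bootstrap_support(seqs: dict[str, str], replicates: int = 1000,
                      seed: int = 0, protein: bool = False
                      ) -> dict[frozenset, float]:
    """Column-resampling bootstrap support for every internal split."""
    if replicates == 0:
        return {}
    labels = list(seqs)
    rows = [seqs[k] for k in labels]
    n_cols = len(rows[0])
    if n_cols < 2:
        raise ValueError("alignment must have >= 2 columns")
    base_splits = nj_tree(p_distance_matrix(seqs, protein)).splits()
    counts = {s: 0 for s in base_splits}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = {lbl: "".join(row[c] for c in cols)
                     for lbl, row in zip(labels, rows)}
        try:
            rep_splits = nj_tree(p_distance_matrix(resampled,
                                                   protein)).splits()
        except ValueError:
            continue
        for s in base_splits:
            if s in rep_splits:
                counts[s] += 1
    return {s: c / replicates for s, c in counts.items()}


# ---------------------------------------------------------------------------
# consensus and family assignment
# ---------------------------------------------------------------------------

def degenerate_consensus(aligned: list[str]) -> str:
    """Majority-rule consensus; ties/minorities become IUPAC codes.

    A base is called when a strict majority (> 50%) of non-gap residues
    agree; exact ties (e.g. the two rows of a TIR pair disagreeing) and
    split columns get the minimal IUPAC code covering the observed bases.
    All-gap columns are dropped.
    """
    if not aligned:
        return ""
    lengths = {len(r) for r in aligned}
    if len(lengths) > 1:
        raise ValueError("sequences must have equal aligned lengths")
    out = []
    for col in zip(*[r.upper() for r in aligned]):
        bases = [c for c in col if c != GAP]
        if not bases:
            continue
        vals, counts = np.unique(bases, return_counts=True)
        order = np.argsort(-counts, kind="stable")
        if counts[order[0]] * 2 > len(bases):
            out.append(vals[order[0]])
        else:
            observed = frozenset(v for v in vals if v in "ACGT")
            out.append(IUPAC.get(observed, "N"))
    return "".join(out)


def element_distance(a: str, b: str) -> float:
    """Clustering divergence between unaligned elements: 1 - global
    identity (matches / alignment length).  Near the p-distance for
    closely related copies; saturates toward ~0.5-0.6 for unrelated DNA."""
    return 1.0 - global_identity(a, b)


def date_activity(mean_pdistance: float, n_distinct_tsds: int,
                  has_tir_tsd: bool) -> str:
    """Recency heuristic: near-identical copies with multiple distinct TSDs
    mean recent transposition; diverged TIR-less sequences are ancient."""
    if np.isnan(mean_pdistance):
        return "unclear"
    if has_tir_tsd and mean_pdistance <= 0.02 and n_distinct_tsds >= 2:
        return "recent"
    if not has_tir_tsd and mean_pdistance >= 0.15:
        return "ancient"
    return "unclear"


@dataclass
class CopyCall:
    """Per-copy evidence bundle handed to family assignment."""

    copy_id: str
    element_seq: str
    classification: str  # family_candidate | group_member | remnant
    tir: TirPair | None = None
    tsd: Tsd | None = None


def _single_linkage(ids: list[str], dist, threshold: float
                    ) -> list[list[str]]:
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in ids:
        for b in ids:
            if a < b and dist(a, b) <= threshold:
                parent[find(a)] = find(b)
    clusters: dict[str, list[str]] = {}
    for i in ids:
        clusters.setdefault(find(i), []).append(i)
    return [sorted(v) for v in clusters.values()]


def assign_families(calls: list[CopyCall], family_linkage: float = 0.25,
                    tir_split: float = 0.30
                    ) -> tuple[list[Family], list[Group]]:
    """Cluster family candidates into families and the rest into groups.

    Single-linkage clustering on element p-distance (pairwise global
    alignments) at ``family_linkage``; clusters whose members' TIRs differ
    at more than ``tir_split`` of positions are split.  Ids are numbered by
    descending member count (ties: first member id), families F1..Fn and
    groups G1..Gn.
    """
    by_id = {c.copy_id: c for c in calls}
    dcache: dict[tuple[str, str], float] = {}

    def dist(a: str, b: str) -> float:
        # gap-inclusive divergence: pairwise-deletion p-distance understates
        # how different unrelated sequences are (the aligner pairs whatever
        # it can), so clustering uses 1 - matches/alignment-length
        key = (a, b) if a < b else (b, a)
        if key not in dcache:
            dcache[key] = element_distance(by_id[a].element_seq,
                                           by_id[b].element_seq)
        return dcache[key]

    def tir_dist(a: str, b: str) -> float:
        ta, tb = by_id[a].tir, by_id[b].tir
        if ta is None or tb is None:
            return 1.0
        L = min(ta.length, tb.length)
        mm = sum(1 for x, y in zip(ta.tir5[:L], tb.tir5[:L]) if x != y)
        return mm / L if L else 1.0

    fam_ids = sorted(c.copy_id for c in calls
                     if c.classification == "family_candidate")
    clusters = _single_linkage(fam_ids, dist, family_linkage)
    refined: list[list[str]] = []
    for cl in clusters:
        refined.extend(_single_linkage(cl, tir_dist, tir_split))
    refined.sort(key=lambda cl: (-len(cl), cl[0]))

    families = []
    for rank, members in enumerate(refined, start=1):
        elems = [by_id[m].element_seq for m in members]
        aligned = center_star_align(elems) if len(elems) > 1 else elems
        consensus = degenerate_consensus(aligned)
        tirs5 = [by_id[m].tir.tir5 for m in members if by_id[m].tir]
        tirs3 = [by_id[m].tir.tir3 for m in members if by_id[m].tir]
        tir_consensus = None
        if tirs5:
            L = min(len(t) for t in tirs5 + tirs3)
            c5 = degenerate_consensus([t[:L] for t in tirs5])
            c3 = degenerate_consensus([t[-L:] for t in tirs3])
            tir_consensus = TirPair(c5, c3, L, hamming_tir(c5, c3),
                                    c5.startswith("GG") and c3.endswith("CC"))
        tsd_lengths = [by_id[m].tsd.k for m in members if by_id[m].tsd]
        modal = (int(np.bincount(tsd_lengths).argmax())
                 if tsd_lengths else None)
        if len(members) > 1:
            pd = [dist(a, b) for i, a in enumerate(members)
                  for b in members[i + 1:]]
            mean_pd = float(np.mean(pd))
        else:
            mean_pd = float("nan")
        tsds = {by_id[m].tsd.left for m in members if by_id[m].tsd}
        families.append(Family(
            id=f"F{rank}", members=members, consensus=consensus,
            tir_consensus=tir_consensus, modal_tsd_length=modal,
            activity_evidence=date_activity(mean_pd, len(tsds), True),
            mean_pdistance=mean_pd))

    grp_ids = sorted(c.copy_id for c in calls
                     if c.classification == "group_member")
    gclusters = _single_linkage(grp_ids, dist, family_linkage)
    gclusters.sort(key=lambda cl: (-len(cl), cl[0]))
    groups = []
    for rank, members in enumerate(gclusters, start=1):
        if len(members) > 1:
            pd = [dist(a, b) for i, a in enumerate(members)
                  for b in members[i + 1:]]
            mean_pd = float(np.mean(pd))
        else:
            mean_pd = float("nan")
        groups.append(Group(id=f"G{rank}", members=members,
                            mean_pdistance=mean_pd))
    return families, groups
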