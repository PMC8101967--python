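"""Pairwise and progressive alignment helpers shared across modules.

Thin wrappers around :class:`Bio.Align.PairwiseAligner` plus a center-star
progressive aligner used for within-family multiple alignments.  Externally
produced alignments (aligned FASTA) can be used everywhere a multiple
alignment is consumed; the center-star aligner is the self-contained default.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"


@lru_cache(maxsize=None)
def _dna_global() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


@lru_cache(maxsize=None)
def _dna_local() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


@lru_cache(maxsize=None)
def _protein_global() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


@lru_cache(maxsize=None)
def _protein_local() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def _sanitize_protein(seq: str) -> str:
    """BLOSUM62 lacks some ambiguity codes; map them to X."""
    allowed = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(c if c.upper() in allowed else "X" for c in seq.upper())


def aligned_pair_strings(a: str, b: str, *, protein: bool = False,
                         local: bool = False) -> tuple[str, str, float]:
    """Align two sequences and return gapped strings plus the score."""
    if protein:
        aligner = _protein_local() if local else _protein_global()
        a, b = _sanitize_protein(a), _sanitize_protein(b)
    else:
        aligner = _dna_local() if local else _dna_global()
        a, b = a.upper(), b.upper()
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sa, sb, float(aln.score)


def global_identity(a: str, b: str, *, protein: bool = False) -> float:
    """Identity = matches / alignment length of a global pairwise alignment.

    This is the clustering identity definition used by the phylo-prep stage.
    """
    if not a or not b:
        return 0.0
    sa, sb, _ = aligned_pair_strings(a, b, protein=protein)
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != GAP)
    return matches / len(sa)


def local_identity(query: str, subject: str, *,
                   protein: bool = False) -> tuple[float, float]:
    """Best local alignment: (identity over aligned region, query coverage)."""
    if not query or not subject:
        return 0.0, 0.0
    sa, sb, _ = aligned_pair_strings(query, subject, protein=protein,
                                     local=True)
    cols = sum(1 for x, y in zip(sa, sb) if x != GAP and y != GAP)
    if cols == 0:
        return 0.0, 0.0
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != GAP)
    aligned_query = sum(1 for x in sa if x != GAP)
    return matches / cols, aligned_query / len(query)


def pairwise_pdistance(a: str, b: str, *, protein: bool = False) -> float:
    """p-distance from a global pairwise alignment with pairwise deletion.

    Gapped or ambiguous columns are skipped; distance is the mismatch
    fraction over the remaining compared sites.
    """
    sa, sb, _ = aligned_pair_strings(a, b, protein=protein)
    # N is an ambiguity code for DNA but asparagine in proteins
    ambiguous = {"X", GAP} if protein else {"N", "X", GAP}
    compared = mismatches = 0
    for x, y in zip(sa, sb):
        if x in ambiguous or y in ambiguous:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        return float("nan")
    return mismatches / compared


def _merge_into_master(master: list[str], center_gapped: str,
                       other_gapped: str) -> list[str]:
    """Merge a (center, other) pairwise alignment into the running master.

    master[0] is the center row (with accumulated gaps).  Standard
    once-a-gap-always-a-gap column merging.
    """
    out = [[] for _ in range(len(master) + 1)]
    i = j = 0  # i: master columns, j: pairwise columns
    m_center = master[0]
    while i < len(m_center) or j < len(center_gapped):
        mc = m_center[i] if i < len(m_center) else None
        pc = center_gapped[j] if j < len(center_gapped) else None
        if mc == GAP and (pc != GAP or pc is None):
            for r, row in enumerate(master):
                out[r].append(row[i])
            out[-1].append(GAP)
            i += 1
        elif pc == GAP and (mc != GAP or mc is None):
            for r in range(len(master)):
                out[r].append(GAP)
            out[-1].append(other_gapped[j])
            j += 1
        else:  # both consume a center residue (or both gap columns)
            for r, row in enumerate(master):
                out[r].append(row[i])
            out[-1].append(other_gapped[j])
            i += 1
            j += 1
    return ["".join(r) for r in out]


def center_star_align(seqs: list[str], *, protein: bool = False) -> list[str]:
    """Progressive center-star multiple alignment.

    The center is the sequence with the highest total pairwise score against
    the others (ties: first).  Every other sequence is aligned to the center
    and merged column-wise.  Returned rows follow the input order.
    """
    n = len(seqs)
    if n == 0:
        return []
    if n == 1:
        return [seqs[0]]
    scores = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            _, _, s = aligned_pair_strings(seqs[i], seqs[j], protein=protein)
            scores[i][j] = scores[j][i] = s
    center = max(range(n), key=lambda i: (sum(scores[i]), -i))
    master = [seqs[center]]
    order = [center]
    for j in range(n):
        if j == center:
            continue
        cg, og, _ = aligned_pair_strings(master[0].replace(GAP, ""), seqs[j],
                                         protein=protein)
        master = _merge_into_master(master, cg, og)
        order.append(j)
    rows = [None] * n
    for pos, idx in enumerate(order):
        rows[idx] = master[pos]
    return rows
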