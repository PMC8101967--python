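"""Element boundary inference, imperfect-TIR search and TSD detection.

A Class II element's limits are where alignment conservation between copies
drops into the (unrelated) flanking sequence.  Its terminal inverted repeats
are found by aligning the element against its own reverse complement from
candidate anchor pairs and extending inward while the mismatch fraction
stays acceptable; the paper's families show this can be very forgiving (up
to 12 mismatches in 26 positions), so the stop rule is a local run of
consecutive mismatches rather than the first mismatch.  Target site
duplications are exact k-mer matches (k = 7-10, preferring the longest)
immediately flanking the element, allowing +/-3 bp of boundary jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
GAP = "-"


def _comp(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class TirPair:
    """A candidate terminal inverted repeat pair.

    ``mismatches`` is the Hamming distance between the 5' TIR and the
    reverse complement of the 3' TIR.  ``extendable`` marks candidates whose
    inward extension was stopped by the mismatch-run rule, i.e. a longer
    (more mismatched) repeat may exist.
    """

    tir5: str
    tir3: str
    length: int
    mismatches: int
    terminal_gg: bool
    extendable: bool = False
    start5: int = 0   # offset of tir5 within the searched sequence
    end3: int = 0     # end offset (exclusive) of tir3

    def __post_init__(self):
        if len(self.tir5) != self.length or len(self.tir3) != self.length:
            raise ValueError("TIR length inconsistent with sequences")
        if self.mismatches > self.length:
            raise ValueError("mismatches cannot exceed length")

    @property
    def score(self) -> int:
        return self.length - 2 * self.mismatches


@dataclass(frozen=True)
class Tsd:
    """Target site duplication flanking one element copy."""

    k: int
    left: str
    right: str
    exact: bool
    jitter5: int = 0
    jitter3: int = 0

    def __post_init__(self):
        if self.exact and self.left != self.right:
            raise ValueError("exact TSD requires identical left/right k-mers")


@dataclass
class BoundaryCall:
    """Refined element limits on a copies+flanks multiple alignment."""

    start_col: int
    end_col: int
    confidence5: str  # sharp | fuzzy | unresolved
    confidence3: str
    support: int
    uncertainty5: int = 0
    uncertainty3: int = 0


def hamming_tir(tir5: str, tir3: str) -> int:
    """Mismatches between tir5 and the reverse complement of tir3."""
    rc3 = str(Seq(tir3).reverse_complement())
    return sum(1 for a, b in zip(tir5, rc3) if a != b)


def _is_terminal_gg(tir5: str, tir3: str) -> bool:
    return tir5.startswith("GG") and tir3.endswith("CC")


def tir_at_length(seq: str, length: int, offset5: int = 0,
                  offset3: int = 0) -> TirPair:
    """The TIR pair of a fixed length at the sequence termini.

    Useful to quantify TIR imperfection at a length established from other
    evidence (e.g. copy alignment), as for highly imperfect repeats where
    the best-scoring inverted repeat is shorter than the structural one.
    """
    tir5 = seq[offset5:offset5 + length]
    end = len(seq) - offset3
    tir3 = seq[end - length:end]
    return TirPair(tir5, tir3, length, hamming_tir(tir5, tir3),
                   _is_terminal_gg(tir5, tir3), False, offset5, end)


def find_tirs(element_with_slack: str, min_len: int = 10, max_len: int = 462,
              max_mismatch_frac: float = 0.5, require_gg: bool = False,
              anchor_slack: int = 8, max_mismatch_run: int = 4
              ) -> list[TirPair]:
    """Ranked inverted-repeat candidates at the termini of a sequence.

    Every (5'-start, 3'-end) anchor pair within ``anchor_slack`` of the
    sequence ends is extended inward while the cumulative mismatch fraction
    stays <= ``max_mismatch_frac``; extension stops at ``max_mismatch_run``
    consecutive mismatches.  For each anchor both the best-scoring length
    (score = length - 2*mismatches) and the longest admissible length are
    reported; candidates are ranked by score.
    """
    seq = element_with_slack.upper()
    n = len(seq)
    if n <= 2 * min_len:
        return []
    candidates: dict[tuple[str, str], TirPair] = {}
    for s in range(min(anchor_slack + 1, n)):
        for e in range(n, max(n - anchor_slack - 1, 2 * min_len + s), -1):
            span = e - s
            limit = min(max_len, span // 2)
            if limit < min_len:
                continue
            mm = 0
            run = 0
            records = []  # (length, mismatches) ending on a match
            stopped_by_run = False
            for i in range(limit):
                match = seq[s + i] == _comp(seq[e - 1 - i])
                if match:
                    run = 0
                else:
                    mm += 1
                    run += 1
                    if run >= max_mismatch_run:
                        stopped_by_run = True
                        break
                length = i + 1
                if (match and length >= min_len
                        and mm / length <= max_mismatch_frac):
                    records.append((length, mm))
            if not records:
                continue
            best = max(records, key=lambda r: (r[0] - 2 * r[1], r[0]))
            longest = records[-1]
            for (length, m), ext in ((best, False),
                                     (longest, stopped_by_run)):
                tir5 = seq[s:s + length]
                tir3 = seq[e - length:e]
                key = (tir5, tir3)
                pair = TirPair(tir5, tir3, length, m,
                               _is_terminal_gg(tir5, tir3),
                               ext, s, e)
                old = candidates.get(key)
                if old is None or pair.score > old.score:
                    candidates[key] = pair
    out = list(candidates.values())
    if require_gg:
        out = [t for t in out if t.terminal_gg]
    out.sort(key=lambda t: (-t.score, -t.length, t.start5, -t.end3))
    return out


def find_tsd(flank5: str, flank3: str, element: str | None = None,
             k_range: tuple[int, ...] = (7, 8, 9, 10), jitter: int = 3,
             exact: bool = True,
             preferred: tuple[int, ...] = (8, 9)) -> Tsd | None:
    """Exact direct repeat immediately flanking the element.

    With the element sequence provided, the element/flank boundaries may be
    shifted by up to ``jitter`` bp on each side (unclear internal borders).
    A duplication whose first/last base chance-matches the adjacent flank
    or element admits several rotated parses, so candidates are ranked by
    biological evidence rather than first-match: parses whose implied
    element starts with GG and ends with CC win, then k in ``preferred``
    (the superfamily's 8/9-bp duplications), then the smallest boundary
    shift, then the longest k.  Returns ``None`` when the flanks are too
    short or no duplication is found.
    """
    ks = sorted(k_range, reverse=True)
    if len(flank5) < max(ks) or len(flank3) < max(ks):
        return None
    if element is None:
        full = flank5 + flank3
        e_start = e_end = len(flank5)
        jit = 0
    else:
        full = flank5 + element + flank3
        e_start = len(flank5)
        e_end = e_start + len(element)
        jit = jitter
    candidates = []
    for k in ks:
        for d5 in range(-jit, jit + 1):
            for d3 in range(-jit, jit + 1):
                ls, le = e_start + d5 - k, e_start + d5
                rs, re = e_end + d3, e_end + d3 + k
                if ls < 0 or re > len(full) or le > rs:
                    continue
                if full[ls:le] == full[rs:re]:
                    bonus = (full[le:le + 2] == "GG") + \
                            (full[rs - 2:rs] == "CC")
                    candidates.append(
                        ((-bonus, k not in preferred, abs(d5) + abs(d3),
                          -k, abs(d5), d5, d3),
                         Tsd(k, full[ls:le], full[rs:re], True, d5, d3)))
    if not candidates:
        return None
    return min(candidates)[1]


def classify_copy(copy, tir: TirPair | None, tsd: Tsd | None,
                  motif_status: str) -> str:
    """Copy class: family_candidate, group_member or remnant.

    A bona fide transposition product has a GG-terminal TIR pair and a TSD;
    a conserved coding copy without them is a group member (candidate
    domesticate); everything else is a remnant.
    """
    if tir is not None and tir.terminal_gg and tsd is not None:
        return "family_candidate"
    if motif_status == "intact":
        return "group_member"
    return "remnant"


# ---------------------------------------------------------------------------
# boundary inference from a copies+flanks alignment
# ---------------------------------------------------------------------------

def column_identities(rows: list[str]) -> np.ndarray:
    """Mean pairwise identity per alignment column.

    Pairs where either row is gapped count as non-identical, so columns in
    gappy unrelated regions (aligned flanks) score low instead of being
    inflated by pairwise deletion.
    """
    n_cols = len(rows[0])
    ident = np.zeros(n_cols)
    arr = np.array([list(r.upper()) for r in rows])
    n_rows = len(rows)
    all_pairs = n_rows * (n_rows - 1) / 2
    for c in range(n_cols):
        col = arr[:, c]
        col = col[col != GAP]
        vals, counts = np.unique(col, return_counts=True)
        same = sum(int(k) * (int(k) - 1) / 2
                   for v, k in zip(vals, counts) if v != "N")
        ident[c] = same / all_pairs
    return ident


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def _find_edge(ident: np.ndarray, smooth: np.ndarray, core: int,
               direction: int, threshold: float, window: int
               ) -> tuple[int | None, int]:
    """Walk from the core outward; return (boundary column, width)."""
    n = len(ident)
    c = core
    coarse = None
    run = 0
    while 0 <= c < n:
        if smooth[c] < threshold:
            run += 1
            if run >= 8:  # sustained drop, not a transient dip
                coarse = c - direction * (run - 1)
                break
        else:
            run = 0
        c += direction
    if coarse is None and run > 0:
        coarse = c - direction * run  # drop runs into the alignment end
    if coarse is None:
        return None, 0  # conservation never drops: unresolved
    # changepoint refinement within +/- window columns of the coarse cross
    lo = max(0, coarse - window)
    hi = min(n - 1, coarse + window)
    best_b, best_score = coarse, -np.inf
    for b in range(lo, hi + 1):
        if direction < 0:  # 5' edge: cols >= b conserved, cols < b not
            inside = ident[b:min(n, b + window)]
            outside = ident[max(0, b - window):b]
        else:              # 3' edge: cols <= b conserved
            inside = ident[max(0, b - window + 1):b + 1]
            outside = ident[b + 1:min(n, b + 1 + window)]
        score = ((inside - threshold).sum() if len(inside) else 0) + \
                ((threshold - outside).sum() if len(outside) else 0)
        if score > best_score:
            best_score, best_b = score, b
    # transition width: raw-identity drop cleanliness around the boundary
    if direction < 0:
        inner = ident[best_b:best_b + 5].mean() if best_b + 5 <= n else 1.0
        outer = ident[max(0, best_b - 5):best_b]
        outer = outer.mean() if len(outer) else 0.0
    else:
        inner = ident[max(0, best_b - 4):best_b + 1].mean()
        outer = ident[best_b + 1:best_b + 6]
        outer = outer.mean() if len(outer) else 0.0
    width = 0 if inner - outer >= 0.4 else 8
    return best_b, width


def infer_boundaries(aligned_copies: list[str], threshold: float = 0.5,
                     window: int = 15) -> BoundaryCall:
    """Element limits: outermost columns of sustained inter-copy identity.

    Scanning outward from the most conserved core column, the boundary sits
    where windowed mean pairwise identity drops below the threshold; a
    changepoint fit refines it.  Because a pairwise aligner inflates the
    apparent identity of unrelated flanks (it pairs whatever matches), the
    effective threshold is raised to halfway between the flank null
    (estimated from the outermost columns) and the conserved-core peak,
    never below ``threshold``.  An end where conservation never drops (no
    flanks, or identical flanks as in segmental duplications) is
    ``unresolved``.
    """
    support = len(aligned_copies)
    n_cols = len(aligned_copies[0]) if aligned_copies else 0
    if support < 2 or n_cols < window:
        return BoundaryCall(0, n_cols, "unresolved", "unresolved", support)
    ident = column_identities(aligned_copies)
    smooth = _smooth(ident, window)
    core = int(np.argmax(smooth))
    edge = min(30, n_cols // 4)
    null = float(np.concatenate([smooth[:edge], smooth[-edge:]]).mean())
    peak = float(smooth[core])
    if peak - null < 0.15:
        return BoundaryCall(0, n_cols, "unresolved", "unresolved", support)
    threshold = max(threshold, null + 0.5 * (peak - null))
    b5, w5 = _find_edge(ident, smooth, core, -1, threshold, window)
    b3, w3 = _find_edge(ident, smooth, core, +1, threshold, window)
    conf5 = "unresolved" if b5 is None else ("sharp" if w5 <= 5 else "fuzzy")
    conf3 = "unresolved" if b3 is None else ("sharp" if w3 <= 5 else "fuzzy")
    start = 0 if b5 is None else b5
    end = n_cols if b3 is None else b3 + 1
    return BoundaryCall(start, end, conf5, conf3, support, w5, w3)


def column_to_row_position(row: str, col: int) -> int:
    """Ungapped sequence offset of an alignment column in one row."""
    return sum(1 for c in row[:col] if c != GAP)
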