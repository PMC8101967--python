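"""Tandem repeats inside elements and conserved/divergent region maps.

Several element families carry internal tandem arrays (e.g. 2.3 units of a
52-bp repeat that itself contains 5 units of a 6-bp repeat, or a 163-bp
unit present in 4 copies).  Detection compares the sequence against itself
shifted by each candidate period and calls maximal runs of sufficient match
fraction; nested repeats are reported at both scales, while harmonic calls
(periods that are exact multiples of an equally good smaller period) are
suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from merlintools.boundaries import column_identities


@dataclass(frozen=True)
class TandemRepeat:
    """One tandem array call on element coordinates (0-based half-open)."""

    start: int
    end: int
    period: int
    copy_number: float
    unit_consensus: str
    percent_match: float

    def __post_init__(self):
        if self.period < 2:
            raise ValueError("period must be >= 2")
        if self.copy_number < 1.5:
            raise ValueError("copy_number below reporting floor (1.5)")
        if abs((self.end - self.start) - self.period * self.copy_number) \
                > self.period:
            raise ValueError("span inconsistent with period * copy_number")

    @property
    def score(self) -> float:
        return self.copy_number * self.period * self.percent_match


@dataclass
class RegionArchitecture:
    """Alignment tiled into conserved/divergent segments.

    Each segment is (start_col, end_col, label, mean_identity) with label
    'conserved' or 'divergent'; segments tile the alignment without overlap.
    """

    segments: list[tuple[int, int, str, float]]

    def divergent(self) -> list[tuple[int, int, str, float]]:
        return [s for s in self.segments if s[2] == "divergent"]


def _maximal_segments(scores: np.ndarray) -> list[tuple[int, int]]:
    """Ruzzo-Tompa all-maximal-scoring-subsequences decomposition.

    Canonical (direction-independent), so repeat calls mirror cleanly
    under sequence reversal.
    """
    stack: list[list] = []  # [start, end, Lcum, Rcum]
    cum = 0.0
    for i, s in enumerate(scores):
        nxt = cum + s
        if s > 0:
            k = [i, i + 1, cum, nxt]
            while True:
                j = None
                for idx in range(len(stack) - 1, -1, -1):
                    if stack[idx][2] < k[2]:
                        j = idx
                        break
                if j is None or stack[j][3] >= k[3]:
                    stack.append(k)
                    break
                k = [stack[j][0], k[1], stack[j][2], k[3]]
                del stack[j:]
        cum = nxt
    return [(int(s), int(e)) for s, e, _, _ in stack]


def _runs_for_period(match: np.ndarray, period: int, min_units: float,
                     min_match: float) -> list[tuple[int, int, int]]:
    """High-match runs of the shifted self-comparison.

    Positions score (match - min_match), so every maximal positive segment
    has match fraction >= min_match.  Returns (start, end, n_matches) over
    the match array; the repeat region on the sequence is
    [start, end + period).
    """
    min_span = max(1, int(np.ceil((min_units - 1) * period)))
    scores = match.astype(float) - min_match + 1e-9
    runs = []
    for s, e in _maximal_segments(scores):
        # trim to match-bounded ends (always possible: ends score > 0)
        while s < e and not match[s]:
            s += 1
        while e > s and not match[e - 1]:
            e -= 1
        if e - s >= min_span:
            runs.append((s, e, int(match[s:e].sum())))
    return runs


def _unit_consensus(seq: str, start: int, end: int, period: int) -> str:
    out = []
    for k in range(period):
        col = [seq[p] for p in range(start + k, end, period)]
        vals, counts = np.unique(col, return_counts=True)
        out.append(vals[np.argmax(counts)])
    return "".join(out)


def find_tandem_repeats(seq: str, min_period: int = 2, max_period: int = 200,
                        min_units: float = 1.5, min_match: float = 0.8
                        ) -> list[TandemRepeat]:
    """Self-comparison tandem repeat finder.

    For every period the sequence is compared against itself shifted by the
    period; maximal runs with match fraction >= ``min_match`` become calls
    with fractional copy number (span / period).  Overlapping calls whose
    period is a multiple of a comparably clean smaller period are removed;
    nested repeats with unrelated periods are both reported.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_period:
        raise ValueError("sequence shorter than 2 * min_period")
    calls: list[TandemRepeat] = []
    for period in range(min_period, min(max_period, n // 2) + 1):
        m = np.frombuffer(seq.encode(), dtype="S1")
        match = (m[:-period] == m[period:]).astype(np.int64)
        for start, stop, n_match in _runs_for_period(match, period,
                                                     min_units, min_match):
            span = stop - start
            copy_number = span / period + 1.0
            pm = n_match / span
            if copy_number < min_units or pm < min_match:
                continue
            calls.append(TandemRepeat(
                start=start, end=stop + period, period=period,
                copy_number=round(copy_number, 2),
                unit_consensus=_unit_consensus(seq, start, stop + period,
                                               period),
                percent_match=round(pm, 3)))
    # suppress harmonic duplicates (period multiples of a cleaner call)
    calls.sort(key=lambda t: (t.period, -t.score))
    kept: list[TandemRepeat] = []
    for t in calls:
        redundant = False
        for k in kept:
            overlap = min(t.end, k.end) - max(t.start, k.start)
            if t.period == k.period and \
                    overlap > 0.5 * min(t.end - t.start, k.end - k.start):
                redundant = True
                break
            # a harmonic (multiple period) call must cover the same region
            # on BOTH sides to be suppressed by the smaller-period call
            if (t.period % k.period == 0
                    and overlap > 0.5 * (t.end - t.start)
                    and overlap > 0.5 * (k.end - k.start)
                    and k.percent_match >= t.percent_match - 0.05):
                redundant = True
                break
        if not redundant:
            kept.append(t)
    kept.sort(key=lambda t: (-t.score, t.start))
    return kept


def region_architecture(aligned: list[str], window: int = 50,
                        threshold: float = 0.6) -> RegionArchitecture:
    """Sliding-window identity map of an aligned family.

    Non-overlapping 50-column windows are labeled divergent below the
    identity threshold; adjacent windows with the same label merge.  With
    fewer than two rows a single conserved segment with undefined identity
    is returned.
    """
    if len(aligned) < 2:
        n = len(aligned[0]) if aligned else 0
        return RegionArchitecture([(0, n, "conserved", float("nan"))])
    ident = column_identities(aligned)
    n = len(ident)
    segments: list[list] = []
    for start in range(0, n, window):
        end = min(start + window, n)
        mean_id = float(ident[start:end].mean())
        label = "divergent" if mean_id < threshold else "conserved"
        if segments and segments[-1][2] == label:
            prev = segments[-1]
            total = prev[3] * (prev[1] - prev[0]) + mean_id * (end - start)
            prev[1] = end
            prev[3] = total / (prev[1] - prev[0])
        else:
            segments.append([start, end, label, mean_id])
    return RegionArchitecture([tuple(s) for s in segments])
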